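"""Ground-truth labeling of actions from motor-imagery EEG.

For each action, left- vs right-hand MI trials (8–30 Hz filtered, 12
channels) are projected through two pairs of CSP filters; the four
log-variance features feed a small 4-100-50-10-2 feed-forward network
(sigmoid hidden units, softmax output, L2 weight decay 0.05) evaluated by
stratified ten-fold cross-validation (72 train / 8 test per fold). The
action with the highest mean left/right accuracy (MI-ACC) is the
subject's "strong" action; all others are "weak". These labels are the
ground truth the cognitive-EEG classifier is trained against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .brain_networks import CSPModel, fit_csp
from .preprocess import EEGEpochs, preprocess_mi
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)

DNN_LAYERS = (4, 100, 50, 10, 2)


@dataclass
class MICSPModel:
    """CSP filter pairs for left/right MI: top and bottom ``n_pairs``
    generalized eigenvectors (2n_pairs filters total)."""

    filters: np.ndarray          # (2*n_pairs, n_channels)
    n_pairs: int
    n_channels: int
    full_model: CSPModel = field(repr=False)
    classes: tuple[str, str] = ("left", "right")


@dataclass
class DNNConfig:
    learning_rate: float = 0.01
    weight_decay: float = 0.05
    epochs: int = 300
    seed: int = 0


@dataclass
class ActionLabeling:
    """Per-subject outcome of the MI ground-truth pipeline."""

    subject_id: int
    mean_acc: np.ndarray           # (% per action)
    strong_action: int
    tie: bool
    trial_labels: np.ndarray       # per cognitive trial: 1 strong / 0 weak

    def to_dict(self) -> dict:
        return {
            "subject_id": int(self.subject_id),
            "mean_acc": [float(a) for a in self.mean_acc],
            "strong_action": int(self.strong_action),
            "tie": bool(self.tie),
            "trial_labels": [int(v) for v in self.trial_labels],
        }


def fit_mi_csp(left: np.ndarray, right: np.ndarray,
               n_pairs: int = 2) -> MICSPModel:
    """CSP on left/right trial sets, keeping the ``n_pairs`` most
    discriminative filters from each end of the eigenvalue spectrum."""
    model = fit_csp(left, right, classes=("left", "right"))
    s = model.n_channels
    if 2 * n_pairs > s:
        raise ValueError(f"{n_pairs} pairs need >= {2 * n_pairs} channels")
    keep = list(range(n_pairs)) + list(range(s - n_pairs, s))
    return MICSPModel(model.filters[keep], n_pairs, s, model)


def extract_mi_features(trial: np.ndarray, model: MICSPModel) -> np.ndarray:
    """Log of normalized variance of each CSP-projected component."""
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    if trial.shape[0] != model.n_channels:
        raise ValueError("channel count mismatch with fitted CSP")
    proj = model.filters @ trial
    var = proj.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero-variance trial")
    return np.log(var / total)


# --------------------------------------------------------------------------
# the small feed-forward classifier
# --------------------------------------------------------------------------

def _init_dnn(rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(DNN_LAYERS[:-1], DNN_LAYERS[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _dnn_forward(x, weights, biases):
    acts = [x]
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        h = 1.0 / (1.0 + np.exp(-(h @ w + b)))     # sigmoid hidden layers
        acts.append(h)
    logits = h @ weights[-1] + biases[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return acts, e / e.sum(axis=1, keepdims=True)


def _train_dnn(x, y, cfg: DNNConfig, rng: np.random.Generator):
    """Full-batch Adam on softmax cross-entropy with decoupled L2 decay.

    The decay is applied as a per-step shrinkage w -= lr * decay * w
    (classic SGD semantics of the 0.05 coefficient); routing it through
    Adam's normalized update would overwhelm the data gradient and
    collapse the network.
    """
    weights, biases = _init_dnn(rng)
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    n = len(y)
    shrink = 1.0 - cfg.learning_rate * cfg.weight_decay
    for t in range(1, cfg.epochs + 1):
        acts, probs = _dnn_forward(x, weights, biases)
        delta = (probs - np.eye(2)[y]) / n
        for li in range(len(weights) - 1, -1, -1):
            gw = acts[li].T @ delta
            gb = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ weights[li].T) * acts[li] * (1 - acts[li])
            mw[li] = b1 * mw[li] + (1 - b1) * gw
            vw[li] = b2 * vw[li] + (1 - b2) * gw * gw
            mb[li] = b1 * mb[li] + (1 - b1) * gb
            vb[li] = b2 * vb[li] + (1 - b2) * gb * gb
            weights[li] *= shrink
            weights[li] -= cfg.learning_rate * (mw[li] / (1 - b1**t)) / (
                np.sqrt(vw[li] / (1 - b2**t)) + eps)
            biases[li] -= cfg.learning_rate * (mb[li] / (1 - b1**t)) / (
                np.sqrt(vb[li] / (1 - b2**t)) + eps)
    return weights, biases


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint folds covering all trials, class-balanced within folds."""
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk)
    return [np.sort(np.array(f)) for f in folds]


def train_eval_dnn_cv(features: np.ndarray, labels: np.ndarray,
                      cfg: DNNConfig | None = None,
                      n_folds: int = 10) -> float:
    """Mean stratified 10-fold CV accuracy (%) of the feed-forward net.

    With the standard 80-trial, 40/40 left-right design every fold splits
    into 72 training and 8 test trials.
    """
    cfg = cfg or DNNConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[1] != DNN_LAYERS[0]:
        raise ValueError(f"features must be (n, {DNN_LAYERS[0]})")
    counts = np.bincount(labels)
    if len(counts) != 2 or counts[0] != counts[1]:
        raise ValueError("need a balanced binary label set")
    if counts[0] < n_folds:
        logger.info("only %d trials per class: using %d folds",
                    counts[0], counts[0])
        n_folds = int(counts[0])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    folds = _stratified_folds(labels, n_folds, rng)
    accs = []
    for test_idx in folds:
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        # standardize on training statistics only
        mu = features[train_mask].mean(axis=0)
        sd = features[train_mask].std(axis=0) + 1e-12
        z = (features - mu) / sd
        w, b = _train_dnn(z[train_mask], labels[train_mask], cfg, rng)
        _, probs = _dnn_forward(z[test_idx], w, b)
        accs.append(np.mean(probs.argmax(axis=1) == labels[test_idx]))
    return float(np.mean(accs) * 100.0)


# --------------------------------------------------------------------------
# strong/weak assignment
# --------------------------------------------------------------------------

def assign_action_labels(per_action_acc, cognitive_actions,
                         subject_id: int = 0) -> ActionLabeling:
    """Strong = argmax of per-action MI-ACC (ties -> lowest index, logged);
    cognitive trials of the strong action get label 1, all others 0."""
    acc = np.asarray(per_action_acc, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 actions to rank")
    strong = int(np.argmax(acc))
    tie = bool(np.sum(acc == acc.max()) > 1)
    if tie:
        logger.warning(
            "subject %s: tied MI-ACC %s, choosing lowest action index %d",
            subject_id, acc.tolist(), strong,
        )
    actions = np.asarray(cognitive_actions, dtype=int)
    labels = (actions == strong).astype(int)
    return ActionLabeling(subject_id, acc, strong, tie, labels)


def label_subject(subject: SubjectDataset,
                  dnn_cfg: DNNConfig | None = None,
                  n_pairs: int = 2) -> ActionLabeling:
    """Full pipeline for one subject: MI preprocessing → per-action CSP +
    feature extraction → ten-fold CV accuracy → strong/weak assignment."""
    mi = preprocess_mi(subject.mi_epochs)
    return label_from_preprocessed(mi, subject.cognitive_epochs,
                                   subject.subject_id, dnn_cfg, n_pairs)


def label_from_preprocessed(mi: EEGEpochs, cognitive: EEGEpochs,
                            subject_id: int,
                            dnn_cfg: DNNConfig | None = None,
                            n_pairs: int = 2) -> ActionLabeling:
    dnn_cfg = dnn_cfg or DNNConfig(seed=subject_id)
    ann = mi.annotations
    accs = []
    for action in sorted(ann["action"].unique()):
        sel = ann["action"] == action
        left = mi.data[(sel & (ann["hand"] == "left")).to_numpy()]
        right = mi.data[(sel & (ann["hand"] == "right")).to_numpy()]
        model = fit_mi_csp(left, right, n_pairs)
        trials = np.concatenate([left, right])
        labels = np.array([0] * len(left) + [1] * len(right))
        feats = np.array([extract_mi_features(t, model) for t in trials])
        accs.append(train_eval_dnn_cv(feats, labels, dnn_cfg))
    return assign_action_labels(
        accs, cognitive.annotations["action"].to_numpy(), subject_id)
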