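"""Leave-one-subject-out evaluation, voting, and performance metrics.

The evaluation protocol is subject-independent: for each fold one subject
is held out, the cognitive-domain CSP and the graph classifier are fitted
on the remaining subjects only, and the held-out subject's trials are
predicted. Per-trial strong/weak predictions are then aggregated by
majority voting within each action; the action with the most "strong"
votes is the subject's predicted personalized motor-imagery action.

Metrics: confusion counts (positive = strong), F1, sensitivity,
specificity, accuracy, Cohen's kappa, and the binary clustering
coefficient of proportionally thresholded brain networks.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mgcn
from .brain_networks import (
    band_decompose, csp_spatial_feature, downsample_average, fit_csp,
    md_adjacency, pcc_adjacency, plv_adjacency, welch_psd, DomainGraph,
)
from .mi_labeling import ActionLabeling, DNNConfig, label_subject
from .preprocess import preprocess_cognitive
from .synthetic_data import SubjectDataset

logger = logging.getLogger(__name__)

#: flag value for metrics whose defining ratio is 0/0
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_and_metrics(preds, labels) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and derived scores; strong (1) is the positive
    class. Ratios with zero denominator come back as NaN with a flag in
    ``metrics['undefined']``."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    counts = ConfusionCounts(
        tp=int(np.sum((preds == 1) & (labels == 1))),
        fn=int(np.sum((preds == 0) & (labels == 1))),
        fp=int(np.sum((preds == 1) & (labels == 0))),
        tn=int(np.sum((preds == 0) & (labels == 0))),
    )
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return UNDEFINED
        return num / den

    metrics = {
        "f1": ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1"),
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        "specificity": ratio(counts.tn, counts.fp + counts.tn, "specificity"),
        "accuracy": ratio(counts.tp + counts.tn, counts.total, "accuracy"),
    }
    metrics["kappa"] = kappa(counts)
    if np.isnan(metrics["kappa"]):
        undefined.append("kappa")
    metrics["undefined"] = undefined
    return counts, metrics


def kappa(counts: ConfusionCounts) -> float:
    """Cohen's kappa from a 2×2 table: (p_o − p_e) / (1 − p_e) with the
    chance agreement p_e from the row/column marginals."""
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion table")
    p_o = (counts.tp + counts.tn) / n
    p_e = ((counts.tp + counts.fn) * (counts.tp + counts.fp)
           + (counts.fp + counts.tn) * (counts.fn + counts.tn)) / n**2
    if p_e == 1.0:
        return UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


def clustering_coefficient(A: np.ndarray,
                           binarize_threshold: float = 0.3
                           ) -> tuple[float, np.ndarray]:
    """Mean and per-node binary clustering coefficient.

    The weighted adjacency is binarized by keeping the top
    ``binarize_threshold`` proportion of off-diagonal weights (ties at the
    cut are kept, so an unweighted graph passes through unchanged). Nodes
    with degree < 2 contribute 0.
    """
    A = np.asarray(A, dtype=float)
    n = len(A)
    if n == 0:
        raise ValueError("empty graph")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not (0 < binarize_threshold < 1):
        raise ValueError("binarize_threshold must be in (0, 1)")
    off = ~np.eye(n, dtype=bool)
    vals = A[off]
    cut = np.quantile(vals, 1.0 - binarize_threshold)
    # a zero weight is "no connection" regardless of the quantile cut
    B = ((A >= cut) & (A > 0) & off).astype(int)
    B = B | B.T
    deg = B.sum(axis=1)
    ci = np.zeros(n)
    for i in range(n):
        if deg[i] < 2:
            continue
        nbrs = np.flatnonzero(B[i])
        e_i = B[np.ix_(nbrs, nbrs)].sum() / 2
        ci[i] = e_i / (deg[i] * (deg[i] - 1) / 2)
    return float(ci.mean()), ci


def vote_action(predictions, actions) -> tuple[int, dict[int, int], bool]:
    """Count "strong" predictions per action and pick the argmax.

    Ties (including the all-weak degenerate case) resolve to the lowest
    action index and set the tie flag.
    """
    predictions = np.asarray(predictions, dtype=int)
    actions = np.asarray(actions, dtype=int)
    if predictions.shape != actions.shape or predictions.size == 0:
        raise ValueError("predictions/actions must be equal-length, nonempty")
    uniq = np.sort(np.unique(actions))
    counts = {int(a): int(predictions[actions == a].sum()) for a in uniq}
    best = max(counts.values())
    winners = [a for a, c in counts.items() if c == best]
    chosen = min(winners)
    tie = len(winners) > 1
    if tie and best == 0:
        logger.warning("all-weak predictions: zero-confidence vote")
    elif tie:
        logger.warning("vote tie among actions %s: choosing %d",
                       winners, chosen)
    return chosen, counts, tie


@dataclass
class PredictionReport:
    """Per-subject outcome of one LOSO fold."""

    subject_id: int
    predictions: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    actions: np.ndarray = field(repr=False)
    vote_counts: dict[int, int]
    chosen_action: int
    vote_tie: bool
    true_strong_action: int
    labeled_strong_action: int
    counts: ConfusionCounts
    metrics: dict
    #: fingerprints of the fold's training artifacts (CSP, model weights);
    #: must be independent of anything about the held-out subject
    artifact_hashes: dict = field(default_factory=dict)

    @property
    def recovered(self) -> bool:
        """Did voting select the generator's true strong action?"""
        return self.chosen_action == self.true_strong_action

    def to_dict(self) -> dict:
        return {
            "subject_id": int(self.subject_id),
            "predictions": [int(p) for p in self.predictions],
            "vote_counts": {str(k): int(v) for k, v in self.vote_counts.items()},
            "chosen_action": int(self.chosen_action),
            "vote_tie": bool(self.vote_tie),
            "true_strong_action": int(self.true_strong_action),
            "labeled_strong_action": int(self.labeled_strong_action),
            "confusion": {"tp": self.counts.tp, "fn": self.counts.fn,
                          "fp": self.counts.fp, "tn": self.counts.tn},
            "metrics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                        for k, v in self.metrics.items()},
        }


# --------------------------------------------------------------------------
# LOSO cross-validation
# --------------------------------------------------------------------------

def _fold_seed(base_seed: int, test_subject_id: int) -> int:
    # stable per held-out subject so training artifacts are independent of
    # anything about the test subject's data
    return int(np.random.SeedSequence(
        [base_seed, int(test_subject_id)]).generate_state(1)[0] % 2**31)


def _time_freq_graphs(cog, n_points):
    """CSP-independent parts of the per-trial graph triples."""
    out = []
    for j in range(cog.n_trials):
        trial = cog.data[j]
        ann = cog.annotations.iloc[j].to_dict()
        xt = downsample_average(trial, n_points)
        bands = band_decompose(trial, cog.fs)
        out.append((DomainGraph(xt, pcc_adjacency(xt), dict(ann)),
                    DomainGraph(welch_psd(bands), plv_adjacency(bands),
                                dict(ann))))
    return out


def loso_cv(cohort: list[SubjectDataset],
            train_cfg: mgcn.TrainConfig | None = None,
            dnn_cfg: DNNConfig | None = None,
            n_points: int = 40,
            labelings: list[ActionLabeling] | None = None,
            ) -> list[PredictionReport]:
    """Leave-one-subject-out evaluation of the full pipeline.

    Per-subject strong/weak ground truth comes from each subject's own MI
    data (``labelings``, computed here if absent). In every fold the
    cognitive-domain CSP and the classifier are fitted on the training
    subjects only; the held-out subject's MI-derived labels are used
    solely to score the predictions.
    """
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    train_cfg = train_cfg or mgcn.TrainConfig()
    if labelings is None:
        labelings = [label_subject(s, dnn_cfg) for s in cohort]

    cog = [preprocess_cognitive(s.cognitive_epochs) for s in cohort]
    tf_graphs = [_time_freq_graphs(c, n_points) for c in cog]

    reports = []
    for fold, test_subject in enumerate(cohort):
        train_ids = [i for i in range(len(cohort)) if i != fold]
        # cognitive-domain CSP from training subjects' labeled trials only
        strong_trials, weak_trials = [], []
        for i in train_ids:
            lab = labelings[i].trial_labels.astype(bool)
            strong_trials.append(cog[i].data[lab])
            weak_trials.append(cog[i].data[~lab])
        csp = fit_csp(np.concatenate(strong_trials),
                      np.concatenate(weak_trials))

        def triples_for(i):
            out = []
            for j, (tg, fg) in enumerate(tf_graphs[i]):
                xs = csp_spatial_feature(cog[i].data[j], csp)
                sg = DomainGraph(xs, md_adjacency(xs), dict(tg.annotations))
                out.append((tg, fg, sg))
            return out

        train_triples, train_labels = [], []
        for i in train_ids:
            train_triples.extend(triples_for(i))
            train_labels.extend(labelings[i].trial_labels.tolist())
        fold_cfg = mgcn.TrainConfig(
            learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
            cheb_order=train_cfg.cheb_order, dropout=train_cfg.dropout,
            batch_size=train_cfg.batch_size,
            seed=_fold_seed(train_cfg.seed, test_subject.subject_id),
            class_weighting=train_cfg.class_weighting,
        )
        params = mgcn.train_mgcn(train_triples, fold_cfg,
                                 labels=np.array(train_labels))
        csp_hash = hashlib.sha256(
            np.ascontiguousarray(csp.filters).tobytes()).hexdigest()

        test_triples = triples_for(fold)
        preds, probs = mgcn.predict_trials(params, test_triples)
        actions = cog[fold].annotations["action"].to_numpy()
        chosen, vote_counts, tie = vote_action(preds, actions)
        counts, metrics = confusion_and_metrics(
            preds, labelings[fold].trial_labels)
        reports.append(PredictionReport(
            subject_id=test_subject.subject_id,
            predictions=preds, probabilities=probs, actions=actions,
            vote_counts=vote_counts, chosen_action=chosen, vote_tie=tie,
            true_strong_action=test_subject.true_strong_action,
            labeled_strong_action=labelings[fold].strong_action,
            counts=counts, metrics=metrics,
            artifact_hashes={"csp": csp_hash,
                             "model": mgcn.params_digest(params)},
        ))
    return reports


def summarize_reports(reports: list[PredictionReport]
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-subject metric table plus pooled confusion counts/metrics."""
    rows = []
    for r in reports:
        row = {"subject_id": r.subject_id,
               "chosen_action": r.chosen_action,
               "true_strong_action": r.true_strong_action,
               "recovered": r.recovered}
        row.update({k: v for k, v in r.metrics.items() if k != "undefined"})
        rows.append(row)
    table = pd.DataFrame(rows)
    pooled_counts = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        fn=sum(r.counts.fn for r in reports),
        fp=sum(r.counts.fp for r in reports),
        tn=sum(r.counts.tn for r in reports),
    )
    pooled = {
        "n_trials": pooled_counts.total,
        "accuracy": (pooled_counts.tp + pooled_counts.tn) / pooled_counts.total,
        "kappa": kappa(pooled_counts),
        "recovery_rate": float(np.mean([r.recovered for r in reports])),
        "n_recovered": int(sum(r.recovered for r in reports)),
        "n_subjects": len(reports),
    }
    return table, pooled


# --------------------------------------------------------------------------
# strong vs weak network contrast
# --------------------------------------------------------------------------

@dataclass
class NetworkContrast:
    mean_adjacency: dict[str, dict[str, np.ndarray]] = field(repr=False)
    ccoef_strong: dict[str, float]
    ccoef_weak: dict[str, float]
    ccoef_diff: dict[str, float]
    p_value: dict[str, float]
    n_permutations: int


def compare_strong_weak_networks(triples, n_permutations: int = 1000,
                                 binarize_threshold: float = 0.3,
                                 seed: int = 0) -> NetworkContrast:
    """Domain-wise strong-vs-weak contrast of trial networks.

    ``triples`` are per-trial (time, frequency, spatial) graphs whose
    annotations carry ``label`` (1 strong / 0 weak) and ``subject_id``.
    For each domain the trial adjacencies are averaged per condition, and
    the difference in mean binary clustering coefficient is tested with a
    two-sided permutation test that shuffles condition labels within
    subject.
    """
    if not triples:
        raise ValueError("no trials supplied")
    domains = [g.domain for g in triples[0]]
    labels = np.array([t[0].annotations["label"] for t in triples], dtype=int)
    subjects = np.array([t[0].annotations["subject_id"] for t in triples])
    if len(np.unique(labels)) < 2:
        raise ValueError("need both strong and weak trials")
    adj = {d: np.stack([t[k].A.values for t in triples])
           for k, d in enumerate(domains)}
    ccoef = {d: np.array([clustering_coefficient(a, binarize_threshold)[0]
                          for a in adj[d]]) for d in domains}

    def diff(lab, d):
        return ccoef[d][lab == 1].mean() - ccoef[d][lab == 0].mean()

    rng = np.random.default_rng(seed)
    observed = {d: diff(labels, d) for d in domains}
    exceed = {d: 0 for d in domains}
    for _ in range(n_permutations):
        perm = labels.copy()
        for s in np.unique(subjects):
            m = subjects == s
            perm[m] = rng.permutation(perm[m])
        for d in domains:
            if abs(diff(perm, d)) >= abs(observed[d]) - 1e-15:
                exceed[d] += 1
    p = {d: (exceed[d] + 1) / (n_permutations + 1) for d in domains}
    mean_adj = {
        d: {"strong": adj[d][labels == 1].mean(axis=0),
            "weak": adj[d][labels == 0].mean(axis=0)}
        for d in domains
    }
    return NetworkContrast(
        mean_adjacency=mean_adj,
        ccoef_strong={d: float(ccoef[d][labels == 1].mean()) for d in domains},
        ccoef_weak={d: float(ccoef[d][labels == 0].mean()) for d in domains},
        ccoef_diff={d: float(observed[d]) for d in domains},
        p_value=p, n_permutations=n_permutations,
    )
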