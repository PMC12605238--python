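"""Three-branch spectral graph convolutional classifier.

One branch per network domain (time / frequency / spatial). Each branch
applies two first-order Chebyshev graph convolutions (32 then 16 hidden
units, ReLU, dropout 0.5) using the trial's own adjacency through the
renormalized propagation operator P = D̃^{-1/2} (A + I) D̃^{-1/2}, then
mean-pools over the 19 nodes. The three 16-vectors are concatenated,
batch-standardized, and mapped by a dense layer + softmax to the binary
strong/weak decision.

Everything is NumPy with hand-written backpropagation and Adam, seeded for
bit-reproducible training; no GPU or deep-learning framework is required
at the problem sizes involved (hundreds of 19-node graphs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .brain_networks import DomainGraph

_BN_EPS = 1e-5
HIDDEN = (32, 16)
N_CLASSES = 2
LABEL_WEAK, LABEL_STRONG = 0, 1


# --------------------------------------------------------------------------
# graph spectral operators
# --------------------------------------------------------------------------

@dataclass
class GraphSpectralOperator:
    """Laplacians and propagation operator derived from one adjacency."""

    A: np.ndarray
    D: np.ndarray               # degree diagonal matrix
    L: np.ndarray               # combinatorial Laplacian D - A
    L_norm: np.ndarray          # I - D^{-1/2} A D^{-1/2}
    P: np.ndarray               # D̃^{-1/2} (A+I) D̃^{-1/2}


def normalized_laplacian(A: np.ndarray) -> GraphSpectralOperator:
    """Build degree matrix, Laplacian, symmetric-normalized Laplacian and
    the renormalized propagation operator from a symmetric adjacency."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        bad = np.flatnonzero(deg <= 0).tolist()
        raise ValueError(f"isolated node(s) with zero degree: {bad}")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.diag(deg) - A
    L_norm = np.eye(len(A)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    A_tilde = A + np.eye(len(A))
    dt_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    P = dt_inv_sqrt[:, None] * A_tilde * dt_inv_sqrt[None, :]
    return GraphSpectralOperator(A, np.diag(deg), L, L_norm, P)


def _t2_operator(op: GraphSpectralOperator) -> np.ndarray:
    """Second Chebyshev polynomial T_2(L̂) with L̂ = 2 L̃ / λ_max − I and
    λ_max fixed at its upper bound 2."""
    l_hat = op.L_norm - np.eye(len(op.A))
    return 2.0 * l_hat @ l_hat - np.eye(len(op.A))


def cheb_graph_conv(x: np.ndarray, op: GraphSpectralOperator,
                    weights: list[np.ndarray], K: int = 1) -> np.ndarray:
    """One graph-convolution layer (no activation).

    K = 1 computes the renormalized first-order propagation P x W; K = 2
    adds a T_2(L̂) x W' term. ``weights`` holds one matrix per term.
    """
    if K not in (1, 2):
        raise ValueError("Chebyshev order K must be 1 or 2")
    if len(weights) != K:
        raise ValueError(f"K={K} needs {K} weight matrices")
    x = np.asarray(x, dtype=float)
    if x.shape[0] != op.P.shape[0]:
        raise ValueError("feature/operator node-count mismatch")
    out = op.P @ x @ weights[0]
    if K == 2:
        out = out + _t2_operator(op) @ x @ weights[1]
    return out


# --------------------------------------------------------------------------
# parameters and configuration
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the 1-40-0.5 scheme
    (first-order Chebyshev, 40 time points, dropout 0.5) with the stated
    learning rate 0.001 and 1000 epochs."""

    learning_rate: float = 0.001
    epochs: int = 1000
    cheb_order: int = 1
    dropout: float = 0.5
    batch_size: int | None = None
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.cheb_order not in (1, 2):
            raise ValueError(
                f"cheb_order must be 1 or 2, got {self.cheb_order}"
            )
        if self.dropout not in (0.25, 0.5):
            raise ValueError(
                f"dropout must be 0.25 or 0.5, got {self.dropout}"
            )
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("invalid learning rate or epoch count")


@dataclass
class MGCNParams:
    """All learnable state of the classifier plus training metadata."""

    branches: dict[str, list[list[np.ndarray]]]   # domain -> [layer][term]
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    dense_w: np.ndarray
    dense_b: np.ndarray
    cheb_order: int = 1
    dropout: float = 0.5
    seed: int = 0
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def domains(self) -> list[str]:
        return list(self.branches)

    def save(self, path) -> None:
        """Single-file serialization: JSON header + binary weight payload."""
        arrays = {"bn_gamma": self.bn_gamma, "bn_beta": self.bn_beta,
                  "bn_mean": self.bn_mean, "bn_var": self.bn_var,
                  "dense_w": self.dense_w, "dense_b": self.dense_b,
                  "loss_trace": self.loss_trace}
        for d, layers in self.branches.items():
            for li, terms in enumerate(layers):
                for ti, w in enumerate(terms):
                    arrays[f"branch_{d}_{li}_{ti}"] = w
        header = {"cheb_order": self.cheb_order, "dropout": self.dropout,
                  "seed": self.seed,
                  "branches": {d: [len(t) for t in layers]
                               for d, layers in self.branches.items()}}
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MGCNParams":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            branches = {
                d: [[z[f"branch_{d}_{li}_{ti}"] for ti in range(nt)]
                    for li, nt in enumerate(layer_terms)]
                for d, layer_terms in header["branches"].items()
            }
            return cls(branches, z["bn_gamma"], z["bn_beta"], z["bn_mean"],
                       z["bn_var"], z["dense_w"], z["dense_b"],
                       header["cheb_order"], header["dropout"],
                       header["seed"], z["loss_trace"])


def params_digest(params: MGCNParams) -> str:
    """SHA-256 over all weight arrays (training-artifact fingerprint)."""
    h = hashlib.sha256()
    for d in params.domains:
        for layer in params.branches[d]:
            for w in layer:
                h.update(np.ascontiguousarray(w).tobytes())
    for arr in (params.bn_gamma, params.bn_beta, params.bn_mean,
                params.bn_var, params.dense_w, params.dense_b):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(feature_dims: dict[str, int], cfg: TrainConfig) -> MGCNParams:
    """Seeded variance-scaled initialization for all branches and the
    output block. ``feature_dims`` maps domain -> node feature width."""
    rng = np.random.default_rng(cfg.seed)
    branches = {}
    for domain, f_in in feature_dims.items():
        layers = []
        sizes = [f_in, *HIDDEN]
        for li in range(len(HIDDEN)):
            terms = [_glorot(rng, sizes[li], sizes[li + 1])
                     for _ in range(cfg.cheb_order)]
            layers.append(terms)
        branches[domain] = layers
    n_concat = HIDDEN[-1] * len(feature_dims)
    return MGCNParams(
        branches=branches,
        bn_gamma=np.ones(n_concat), bn_beta=np.zeros(n_concat),
        bn_mean=np.zeros(n_concat), bn_var=np.ones(n_concat),
        dense_w=_glorot(rng, n_concat, N_CLASSES),
        dense_b=np.zeros(N_CLASSES),
        cheb_order=cfg.cheb_order, dropout=cfg.dropout, seed=cfg.seed,
    )


# --------------------------------------------------------------------------
# batched tensors
# --------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Stacked per-trial operators/features for fast batched training."""

    x: dict[str, np.ndarray]        # domain -> (B, S, f)
    p: dict[str, np.ndarray]        # domain -> (B, S, S)
    t2: dict[str, np.ndarray] | None
    px: dict[str, np.ndarray]       # precomputed P @ x
    t2x: dict[str, np.ndarray] | None
    labels: np.ndarray | None
    annotations: list[dict]

    @property
    def n_trials(self) -> int:
        return next(iter(self.x.values())).shape[0]

    def subset(self, idx) -> "GraphBatch":
        sel = {d: v[idx] for d, v in self.x.items()}
        return GraphBatch(
            sel, {d: v[idx] for d, v in self.p.items()},
            {d: v[idx] for d, v in self.t2.items()} if self.t2 else None,
            {d: v[idx] for d, v in self.px.items()},
            {d: v[idx] for d, v in self.t2x.items()} if self.t2x else None,
            self.labels[idx] if self.labels is not None else None,
            [self.annotations[i] for i in np.atleast_1d(idx)],
        )


def prepare_batch(
    triples: list[tuple[DomainGraph, DomainGraph, DomainGraph]],
    labels=None,
    cheb_order: int = 1,
) -> GraphBatch:
    """Stack a list of (time, frequency, spatial) graph triples into
    contiguous tensors, precomputing the constant P x products."""
    if not triples:
        raise ValueError("empty graph list")
    domains = [g.domain for g in triples[0]]
    x = {d: [] for d in domains}
    p = {d: [] for d in domains}
    t2 = {d: [] for d in domains} if cheb_order == 2 else None
    anns = []
    for triple in triples:
        for g in triple:
            if np.any(~np.isfinite(g.x.values)):
                raise ValueError("non-finite node features")
            op = normalized_laplacian(g.A.values)
            x[g.domain].append(g.x.values)
            p[g.domain].append(op.P)
            if t2 is not None:
                t2[g.domain].append(_t2_operator(op))
        anns.append(dict(triple[0].annotations))
    x = {d: np.stack(v) for d, v in x.items()}
    p = {d: np.stack(v) for d, v in p.items()}
    if t2 is not None:
        t2 = {d: np.stack(v) for d, v in t2.items()}
    if labels is None and all("label" in a for a in anns):
        labels = np.array([a["label"] for a in anns], dtype=int)
    elif labels is not None:
        labels = np.asarray(labels, dtype=int)
    px = {d: p[d] @ x[d] for d in domains}
    t2x = {d: t2[d] @ x[d] for d in domains} if t2 is not None else None
    return GraphBatch(x, p, t2, px, t2x, labels, anns)


# --------------------------------------------------------------------------
# forward / backward
# --------------------------------------------------------------------------

def _branch_forward(params, domain, batch, train, rng, caches):
    keep = 1.0 - params.dropout
    w = params.branches[domain]
    z1 = batch.px[domain] @ w[0][0]
    if params.cheb_order == 2:
        z1 = z1 + batch.t2x[domain] @ w[0][1]
    h1 = np.maximum(z1, 0.0)
    if train:
        m1 = (rng.random(h1.shape, dtype=np.float32) < keep) / keep
        h1 = h1 * m1
    else:
        m1 = None
    ph1 = batch.p[domain] @ h1
    z2 = ph1 @ w[1][0]
    if params.cheb_order == 2:
        t2h1 = batch.t2[domain] @ h1
        z2 = z2 + t2h1 @ w[1][1]
    else:
        t2h1 = None
    h2 = np.maximum(z2, 0.0)
    if train:
        m2 = (rng.random(h2.shape, dtype=np.float32) < keep) / keep
        h2 = h2 * m2
    else:
        m2 = None
    pooled = h2.mean(axis=1)                       # (B, 16)
    caches[domain] = dict(z1=z1, m1=m1, h1=h1, ph1=ph1, t2h1=t2h1,
                          z2=z2, m2=m2, h2=h2)
    return pooled


def _forward(params: MGCNParams, batch: GraphBatch, train: bool,
             rng: np.random.Generator | None):
    """Full forward pass; returns probabilities and a cache for backprop."""
    if train and rng is None:
        raise ValueError("training-mode forward needs an RNG for dropout")
    caches: dict = {}
    pooled = [_branch_forward(params, d, batch, train, rng, caches)
              for d in params.domains]
    feat = np.concatenate(pooled, axis=1)          # (B, 48)
    if train:
        mu = feat.mean(axis=0)
        var = feat.var(axis=0)
    else:
        mu, var = params.bn_mean, params.bn_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    feat_hat = (feat - mu) * inv_std
    bn_out = params.bn_gamma * feat_hat + params.bn_beta
    logits = bn_out @ params.dense_w + params.dense_b
    logits = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache = dict(caches=caches, feat=feat, feat_hat=feat_hat,
                 inv_std=inv_std, bn_out=bn_out, mu=mu, var=var)
    return probs, cache


def _backward(params: MGCNParams, batch: GraphBatch, probs, cache,
              sample_weight) -> dict:
    """Gradients of the weighted cross-entropy w.r.t. all parameters."""
    y = batch.labels
    b = len(y)
    grads: dict = {}
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits *= sample_weight[:, None]
    grads["dense_w"] = cache["bn_out"].T @ dlogits
    grads["dense_b"] = dlogits.sum(axis=0)
    dbn_out = dlogits @ params.dense_w.T
    grads["bn_gamma"] = (dbn_out * cache["feat_hat"]).sum(axis=0)
    grads["bn_beta"] = dbn_out.sum(axis=0)
    # batch-standardization backward (batch statistics)
    dxhat = dbn_out * params.bn_gamma
    inv_std = cache["inv_std"]
    xhat = cache["feat_hat"]
    dfeat = (dxhat - dxhat.mean(axis=0)
             - xhat * (dxhat * xhat).mean(axis=0)) * inv_std
    n_hidden = HIDDEN[-1]

    def contract(a, b):
        # sum_bs a[b,s,f] * b[b,s,g] -> (f, g), via one BLAS matmul
        return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])

    for bi, domain in enumerate(params.domains):
        c = cache["caches"][domain]
        w = params.branches[domain]
        dpooled = dfeat[:, bi * n_hidden:(bi + 1) * n_hidden]
        s = batch.x[domain].shape[1]
        dh2 = np.broadcast_to(dpooled[:, None, :] / s,
                              c["z2"].shape)
        if c["m2"] is not None:
            dh2 = dh2 * c["m2"]
        dz2 = dh2 * (c["z2"] > 0)
        gw = [[None for _ in layer] for layer in w]
        gw[1][0] = contract(c["ph1"], dz2)
        dh1 = batch.p[domain] @ (dz2 @ w[1][0].T)
        if params.cheb_order == 2:
            gw[1][1] = contract(c["t2h1"], dz2)
            dh1 = dh1 + batch.t2[domain] @ (dz2 @ w[1][1].T)
        if c["m1"] is not None:
            dh1 = dh1 * c["m1"]
        dz1 = dh1 * (c["z1"] > 0)
        gw[0][0] = contract(batch.px[domain], dz1)
        if params.cheb_order == 2:
            gw[0][1] = contract(batch.t2x[domain], dz1)
        grads[f"branch_{domain}"] = gw
    return grads


def _loss(probs, y, sample_weight) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-(sample_weight * np.log(p)).sum())


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, values, grads):
        self.t += 1
        out = []
        for i, (x, g) in enumerate(zip(values, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(x - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _flatten_params(params: MGCNParams):
    refs = []
    for d in params.domains:
        for li, layer in enumerate(params.branches[d]):
            for ti in range(len(layer)):
                refs.append(("branch", d, li, ti))
    refs += [("bn_gamma",), ("bn_beta",), ("dense_w",), ("dense_b",)]
    return refs


def _get(params, ref):
    if ref[0] == "branch":
        return params.branches[ref[1]][ref[2]][ref[3]]
    return getattr(params, ref[0])


def _set(params, ref, value):
    if ref[0] == "branch":
        params.branches[ref[1]][ref[2]][ref[3]] = value
    else:
        setattr(params, ref[0], value)


def _grad_for(grads, ref):
    if ref[0] == "branch":
        return grads[f"branch_{ref[1]}"][ref[2]][ref[3]]
    return grads[ref[0]]


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def forward(graphs, params: MGCNParams, mode: str = "eval",
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Class probabilities for one triple or a prepared batch."""
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    batch = graphs if isinstance(graphs, GraphBatch) else prepare_batch(
        [graphs], cheb_order=params.cheb_order)
    probs, _ = _forward(params, batch, mode == "train", rng)
    return probs[0] if not isinstance(graphs, GraphBatch) and probs.shape[0] == 1 else probs


def train_mgcn(train_graphs, cfg: TrainConfig, labels=None) -> MGCNParams:
    """Train the classifier by cross-entropy with Adam.

    ``train_graphs`` is a list of (time, frequency, spatial) triples or an
    already-prepared :class:`GraphBatch`; labels (0 = weak, 1 = strong)
    come from the argument or from the graphs' ``label`` annotation. The
    returned params carry the per-epoch loss trace; identical data + seed
    reproduce it bit-for-bit.
    """
    batch = (train_graphs if isinstance(train_graphs, GraphBatch)
             else prepare_batch(train_graphs, labels, cfg.cheb_order))
    if batch.labels is None:
        raise ValueError("training requires labels")
    classes = np.unique(batch.labels)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    n = batch.n_trials
    if cfg.class_weighting:
        counts = np.bincount(batch.labels, minlength=N_CLASSES)
        wclass = n / (N_CLASSES * np.maximum(counts, 1))
        weights = wclass[batch.labels]
    else:
        weights = np.ones(n)
    weights = weights / weights.sum()

    feature_dims = {d: batch.x[d].shape[2] for d in batch.x}
    params = init_params(feature_dims, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    refs = _flatten_params(params)
    adam = _Adam([_get(params, r).shape for r in refs], cfg.learning_rate)

    batch_size = cfg.batch_size or (n if n <= 512 else 64)
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if batch_size < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            sub = batch.subset(idx) if len(idx) < n else batch
            sw = weights[idx]
            probs, cache = _forward(params, sub, True, rng)
            epoch_loss += _loss(probs, sub.labels, sw)
            grads = _backward(params, sub, probs, cache, sw)
            new = adam.step([_get(params, r) for r in refs],
                            [_grad_for(grads, r) for r in refs])
            for r, v in zip(refs, new):
                _set(params, r, v)
            # running batch-standardization statistics for eval mode
            momentum = 0.1
            params.bn_mean = (1 - momentum) * params.bn_mean + momentum * cache["mu"]
            params.bn_var = (1 - momentum) * params.bn_var + momentum * cache["var"]
        trace[epoch] = epoch_loss
    params.loss_trace = trace
    return params


def predict_trials(params: MGCNParams, graphs):
    """Deterministic eval-mode predictions.

    Returns (labels, probabilities): labels are 0 (weak) / 1 (strong),
    probabilities an (n, 2) array.
    """
    batch = (graphs if isinstance(graphs, GraphBatch)
             else prepare_batch(graphs, cheb_order=params.cheb_order))
    probs, _ = _forward(params, batch, False, None)
    return probs.argmax(axis=1), probs
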