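"""Multi-domain brain-network construction from cognitive epochs.

For every preprocessed cognitive trial (19 channels × 1000 samples) three
graphs are built, each a node-feature matrix plus a weighted adjacency:

* time domain — 19 × 40 block-averaged time courses; edges are absolute
  Pearson correlations (PCC) between channel feature vectors;
* frequency domain — 19 × 4 mean Welch band powers over 1–4, 4–8, 8–13 and
  13–20 Hz; edges are phase-locking values (PLV) from analytic-signal
  phases, averaged over the four bands;
* spatial domain — 19 × 1 per-component log-variance of CSP-projected
  signals; edges are min–max normalized Manhattan distances converted to
  similarities (1 − distance), so that in every domain a larger weight
  means a stronger connection.

All adjacencies are symmetric, in [0, 1], with unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg, signal

from .preprocess import EEGEpochs

#: analysis bands (Hz): delta/theta/alpha/beta ranges used throughout
BANDS: tuple[tuple[float, float], ...] = ((1, 4), (4, 8), (8, 13), (13, 20))
DOMAINS = ("time", "frequency", "spatial")


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray          # (S, f)
    domain: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


@dataclass
class AdjacencyMatrix:
    values: np.ndarray          # (S, S), symmetric, in [0, 1]
    domain: str

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains non-finite entries")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.values = np.clip((a + a.T) / 2, 0.0, 1.0)


@dataclass
class DomainGraph:
    """One trial's graph in one domain: features + adjacency + annotations."""

    x: NodeFeatureMatrix
    A: AdjacencyMatrix
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x.domain != self.A.domain:
            raise ValueError("feature/adjacency domain mismatch")
        if self.x.values.shape[0] != self.A.values.shape[0]:
            raise ValueError("feature/adjacency node-count mismatch")

    @property
    def domain(self) -> str:
        return self.x.domain


@dataclass
class BandSignals:
    """Band-limited copies of one trial, keyed by (low, high) Hz."""

    signals: dict[tuple[float, float], np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.signals.values()}
        if len(shapes) != 1:
            raise ValueError("band signals must share one shape")


# --------------------------------------------------------------------------
# time domain
# --------------------------------------------------------------------------

def downsample_average(trial: np.ndarray, n_points: int = 40) -> NodeFeatureMatrix:
    """Average-down each channel to ``n_points`` non-overlapping block means.

    1000-sample trials with the default 40 points use 25-sample blocks.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    n = trial.shape[-1]
    if n % n_points:
        raise ValueError(f"{n} samples not divisible into {n_points} blocks")
    block = n // n_points
    out = trial.reshape(trial.shape[0], n_points, block).mean(axis=-1)
    return NodeFeatureMatrix(out, "time")


def pcc_adjacency(x: NodeFeatureMatrix) -> AdjacencyMatrix:
    """Absolute Pearson correlation between node feature rows."""
    v = x.values
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance channel(s) {bad}: PCC undefined")
    r = np.corrcoef(v)
    a = np.abs(r)
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(np.clip(a, 0.0, 1.0), x.domain)


# --------------------------------------------------------------------------
# frequency domain
# --------------------------------------------------------------------------

def band_decompose(trial: np.ndarray, fs: float,
                   backend: str = "bandpass") -> BandSignals:
    """Split a trial into the four analysis bands.

    The default backend reconstructs each band by zero-phase 4th-order
    Butterworth band-pass filtering at the printed band edges. A dyadic
    Daubechies wavelet backend cannot reproduce the non-dyadic 8–13 and
    13–20 Hz edges at 1 kHz and is not provided.
    """
    if backend != "bandpass":
        raise NotImplementedError(
            f"band_decompose backend {backend!r} not available; "
            "only 'bandpass' is implemented"
        )
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    if fs < 2 * BANDS[-1][1]:
        raise ValueError(f"fs={fs} too low for band up to {BANDS[-1][1]} Hz")
    out = {}
    for low, high in BANDS:
        sos = _band_sos(low, high, float(fs))
        out[(low, high)] = signal.sosfiltfilt(sos, trial, axis=-1)
    return BandSignals(out, fs)


@lru_cache(maxsize=32)
def _band_sos(low: float, high: float, fs: float) -> np.ndarray:
    return signal.butter(4, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def welch_psd(bands: BandSignals,
              nperseg: int | None = None) -> NodeFeatureMatrix:
    """Mean Welch power spectral density of each band signal over its own
    frequency range (Hann window, 50% overlap)."""
    n = next(iter(bands.signals.values())).shape[-1]
    seg = min(256, n) if nperseg is None else nperseg
    if seg > n:
        raise ValueError(f"Welch segment {seg} longer than signal {n}")
    cols = []
    for (low, high), sig in bands.signals.items():
        f, pxx = signal.welch(sig, fs=bands.fs, window="hann", nperseg=seg,
                              noverlap=seg // 2, axis=-1)
        sel = (f >= low) & (f <= high)
        cols.append(pxx[..., sel].mean(axis=-1))
    return NodeFeatureMatrix(np.stack(cols, axis=-1), "frequency")


def _band_plv(sig: np.ndarray) -> np.ndarray:
    analytic = signal.hilbert(sig, axis=-1)
    amp = np.abs(analytic)
    if np.any(amp.max(axis=-1) < 1e-12):
        raise ValueError("constant band signal: instantaneous phase undefined")
    z = analytic / np.maximum(amp, 1e-300)           # unit phasors
    t = sig.shape[-1]
    return np.abs(z @ z.conj().T) / t


def plv_adjacency(bands: BandSignals, aggregate: str = "mean") -> AdjacencyMatrix:
    """Phase-locking value |mean_t exp(i Δφ)| per band from the analytic
    signal, pooled over the four bands (``aggregate``: "mean" or "max");
    diagonal set to 1."""
    mats = [_band_plv(sig) for sig in bands.signals.values()]
    if aggregate == "mean":
        a = np.mean(mats, axis=0)
    elif aggregate == "max":
        a = np.max(mats, axis=0)
    else:
        raise ValueError(f"unknown PLV aggregation {aggregate!r}")
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2
    return AdjacencyMatrix(np.clip(a, 0.0, 1.0), "frequency")


# --------------------------------------------------------------------------
# spatial domain (CSP)
# --------------------------------------------------------------------------

@dataclass
class CSPModel:
    """Common-spatial-pattern filter bank.

    ``filters`` rows are spatial filters sorted by descending eigenvalue of
    the first ("strong") class covariance in whitened space; the filters
    jointly diagonalize the two class covariances, and the per-component
    strong/weak normalized variances sum to 1.
    """

    filters: np.ndarray         # (S, S), one filter per row
    eigenvalues: np.ndarray     # (S,), descending, in (0, 1)
    n_channels: int
    classes: tuple[str, str] = ("strong", "weak")
    regularized: bool = False


def _mean_normalized_cov(trials: np.ndarray) -> np.ndarray:
    """Average of per-trial spatial covariances, each normalized by trace."""
    covs = []
    for tr in trials:
        c = tr @ tr.T
        covs.append(c / np.trace(c))
    return np.mean(covs, axis=0)


def fit_csp(strong_trials: np.ndarray, weak_trials: np.ndarray,
            classes: tuple[str, str] = ("strong", "weak"),
            ridge: float = 1e-10) -> CSPModel:
    """Fit CSP by the generalized eigendecomposition of (C_strong,
    C_strong + C_weak); rank-deficient composites get ridge regularization."""
    strong_trials = np.asarray(strong_trials, dtype=float)
    weak_trials = np.asarray(weak_trials, dtype=float)
    if len(strong_trials) < 2 or len(weak_trials) < 2:
        raise ValueError("need >= 2 trials per class")
    if strong_trials.shape[1] != weak_trials.shape[1]:
        raise ValueError("class channel counts differ")
    c1 = _mean_normalized_cov(strong_trials)
    c2 = _mean_normalized_cov(weak_trials)
    comp = c1 + c2
    s = strong_trials.shape[1]
    regularized = False
    if np.linalg.matrix_rank(comp) < s or np.linalg.cond(comp) > 1e10:
        regularized = True
        warnings.warn("rank-deficient composite covariance: applying ridge")
        comp = comp + ridge * np.trace(comp) / s * np.eye(s)
    vals, vecs = linalg.eigh(c1, comp)
    order = np.argsort(vals)[::-1]
    filters = vecs[:, order].T
    return CSPModel(filters, vals[order], s, classes, regularized)


def csp_spatial_feature(trial: np.ndarray, model: CSPModel) -> NodeFeatureMatrix:
    """Per-component log of trace-normalized variance of the CSP-projected
    trial; shape (S, 1)."""
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    if trial.shape[0] != model.n_channels:
        raise ValueError(
            f"trial has {trial.shape[0]} channels, model expects "
            f"{model.n_channels}"
        )
    proj = model.filters @ trial
    var = proj.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("degenerate (zero-variance) trial")
    feat = np.log(var / total)
    return NodeFeatureMatrix(feat[:, None], "spatial")


def md_adjacency(s: NodeFeatureMatrix,
                 convention: str = "similarity") -> AdjacencyMatrix:
    """Manhattan-distance adjacency of the spatial feature vector.

    Raw pairwise distances |s_h1 − s_h2| are min–max normalized over the
    off-diagonal entries. With the default "similarity" convention the
    edge weight is 1 − normalized distance (larger = stronger connection,
    consistent with the other domains) and the diagonal is 1; the
    "distance" convention returns the normalized distances themselves.
    """
    if convention not in ("similarity", "distance"):
        raise ValueError(f"unknown MD convention {convention!r}")
    v = s.values.ravel()
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 nodes")
    dist = np.abs(v[:, None] - v[None, :])
    off = ~np.eye(n, dtype=bool)
    lo, hi = dist[off].min(), dist[off].max()
    if hi == lo:
        warnings.warn("all spatial features identical: uniform adjacency")
        uniform = np.ones((n, n)) if convention == "similarity" else np.zeros((n, n))
        return AdjacencyMatrix(uniform, s.domain)
    norm = np.zeros_like(dist)
    norm[off] = (dist[off] - lo) / (hi - lo)
    if convention == "distance":
        return AdjacencyMatrix(np.clip(norm, 0.0, 1.0), s.domain)
    sim = 1.0 - norm
    np.fill_diagonal(sim, 1.0)
    return AdjacencyMatrix(np.clip(sim, 0.0, 1.0), s.domain)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def build_multidomain_graphs(
    cognitive_epochs: EEGEpochs,
    csp: CSPModel,
    n_points: int = 40,
    extra_annotations: dict | None = None,
) -> list[tuple[DomainGraph, DomainGraph, DomainGraph]]:
    """Per-trial (time, frequency, spatial) graph triples.

    ``cognitive_epochs`` must already be filtered, baseline-corrected and
    cropped; ``csp`` must come from training data only when the triples
    feed a subject-independent evaluation.
    """
    triples = []
    for j in range(cognitive_epochs.n_trials):
        trial = cognitive_epochs.data[j]
        ann = cognitive_epochs.annotations.iloc[j].to_dict()
        if extra_annotations:
            ann.update(extra_annotations)
        xt = downsample_average(trial, n_points)
        time_g = DomainGraph(xt, pcc_adjacency(xt), dict(ann))
        bands = band_decompose(trial, cognitive_epochs.fs)
        freq_g = DomainGraph(welch_psd(bands), plv_adjacency(bands), dict(ann))
        xs = csp_spatial_feature(trial, csp)
        spat_g = DomainGraph(xs, md_adjacency(xs), dict(ann))
        triples.append((time_g, freq_g, spat_g))
    return triples
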