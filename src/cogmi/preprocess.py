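"""Epoched-EEG container and signal conditioning.

Implements the conditioning steps applied before network construction:
zero-phase Butterworth band-pass filtering, pre-stimulus baseline
subtraction, channel selection/reordering, and epoch cropping.

Conventions for the two task types handled by this package:

* cognitive task — 1.2 s epochs (0.2 s pre-stimulus + 1 s post), 19
  channels, 0.5–20 Hz third-order band-pass, baseline over the first
  0.2 s, cropped to the final 1 s (19 × 1000 at 1 kHz);
* motor-imagery task — 6 s epochs, 12 channels, 8–30 Hz fifth-order
  band-pass covering the mu and beta sensorimotor rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .layout import COGNITIVE_CHANNELS, MI_CHANNELS

TASK_COGNITIVE = "cognitive"
TASK_MI = "mi"

#: default cognitive-task filter: third-order Butterworth, 0.5–20 Hz
COGNITIVE_FILTER = (0.5, 20.0, 3)
#: default MI-task filter: fifth-order Butterworth, 8–30 Hz
MI_FILTER = (8.0, 30.0, 5)


@dataclass
class EEGEpochs:
    """Trials × channels × samples array with per-trial annotations.

    ``annotations`` is a DataFrame with one row per trial and columns
    ``task`` ({"cognitive", "mi"}), ``action`` (int index), ``hand``
    ({"left", "right", "none"}) and ``subject_id``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if len(self.annotations) != self.data.shape[0]:
            raise ValueError("one annotation row per trial required")
        self.annotations = self.annotations.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGEpochs":
        return EEGEpochs(
            self.data.copy(), self.fs, list(self.channel_names),
            self.annotations.copy(),
        )

    def with_data(self, data: np.ndarray) -> "EEGEpochs":
        return replace(self, data=data, annotations=self.annotations.copy(),
                       channel_names=list(self.channel_names))


def make_annotations(n_trials: int, task: str, actions, hands=None,
                     subject_id: int = 0) -> pd.DataFrame:
    """Build a trial-annotation table; scalar arguments are broadcast."""
    actions = np.broadcast_to(np.asarray(actions), (n_trials,)).astype(int)
    if hands is None:
        hands = "none"
    hands = np.broadcast_to(np.asarray(hands, dtype=object), (n_trials,))
    return pd.DataFrame({
        "task": task,
        "action": actions,
        "hand": hands,
        "subject_id": subject_id,
    })


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (order is the one-pass order;
    forward–backward application doubles the effective attenuation)."""

    low: float
    high: float
    order: int
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.family != "butterworth":
            raise ValueError("only the Butterworth family is supported")
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"high edge {self.high} Hz violates Nyquist ({fs / 2} Hz)"
            )


def bandpass_filter(epochs: EEGEpochs, spec: FilterSpec) -> EEGEpochs:
    """Zero-phase band-pass per channel (forward–backward, odd reflection
    padding); output shape equals input shape."""
    spec.validate_for(epochs.fs)
    sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                        fs=epochs.fs, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(np.ascontiguousarray(out))


def baseline_correct(epochs: EEGEpochs,
                     baseline: tuple[float, float] = (0.0, 0.2)) -> EEGEpochs:
    """Subtract each trial/channel's mean over ``baseline`` (seconds) from
    the whole trace."""
    t0, t1 = baseline
    i0 = int(round(t0 * epochs.fs))
    i1 = int(round(t1 * epochs.fs))
    if not (0 <= i0 < i1 <= epochs.n_samples):
        raise ValueError(f"baseline window {baseline} outside epoch or empty")
    mean = epochs.data[:, :, i0:i1].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def select_channels(epochs: EEGEpochs, names: list[str]) -> EEGEpochs:
    """Select and reorder channels to match ``names`` exactly."""
    lookup = {n: i for i, n in enumerate(epochs.channel_names)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise KeyError(f"channel(s) not present: {missing}")
    idx = [lookup[n] for n in names]
    return EEGEpochs(epochs.data[:, idx, :], epochs.fs, list(names),
                     epochs.annotations.copy())


def crop(epochs: EEGEpochs, t0: float, t1: float) -> EEGEpochs:
    """Keep samples in [t0, t1); sample count = round((t1-t0)*fs)."""
    if not (0 <= t0 < t1 <= epochs.duration + 1e-9):
        raise ValueError(
            f"crop window [{t0}, {t1}] outside epoch of {epochs.duration} s"
        )
    i0 = int(round(t0 * epochs.fs))
    n = int(round((t1 - t0) * epochs.fs))
    return epochs.with_data(epochs.data[:, :, i0:i0 + n])


def preprocess_cognitive(epochs: EEGEpochs,
                         filter_spec: FilterSpec | None = None,
                         baseline: tuple[float, float] = (0.0, 0.2),
                         crop_window: tuple[float, float] = (0.2, 1.2),
                         channels: list[str] | None = None) -> EEGEpochs:
    """Full cognitive conditioning chain: select → filter → baseline → crop.

    Filtering runs on the full 1.2 s epoch before cropping so that filter
    edge transients fall outside the analysis window. An external-ICA hook
    is deliberately absent: artifact reduction is assumed to have happened
    upstream (synthetic data is artifact-free).
    """
    if filter_spec is None:
        filter_spec = FilterSpec(*COGNITIVE_FILTER)
    if channels is None:
        channels = COGNITIVE_CHANNELS
    out = select_channels(epochs, channels) if list(epochs.channel_names) != list(channels) else epochs
    out = bandpass_filter(out, filter_spec)
    out = baseline_correct(out, baseline)
    return crop(out, *crop_window)


def preprocess_mi(epochs: EEGEpochs,
                  filter_spec: FilterSpec | None = None,
                  channels: list[str] | None = None) -> EEGEpochs:
    """MI conditioning chain: select channels → 8–30 Hz zero-phase filter."""
    if filter_spec is None:
        filter_spec = FilterSpec(*MI_FILTER)
    if channels is None:
        channels = MI_CHANNELS
    out = select_channels(epochs, channels) if list(epochs.channel_names) != list(channels) else epochs
    return bandpass_filter(out, filter_spec)
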