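"""Synthetic EEG cohorts with the statistical structure the method assumes.

The generator emulates a paired cognitive/motor-imagery (MI) experiment in
which each subject has exactly one "strong" imagined action out of three:

* cognitive trials (19 channels × 1.2 s at 1 kHz, 25 trials per action) of
  the strong action mix shared narrow-band oscillatory sources (theta,
  alpha, beta) into sensorimotor channels with a higher mixing gain and
  boosted alpha/beta power, producing denser inter-channel correlation and
  phase locking;
* MI trials (12 channels × 6 s at 1 kHz, 80 trials per action, 40 left /
  40 right hand) carry a lateralized mu rhythm whose contralateral
  attenuation (event-related desynchronization, ERD) is deeper for the
  strong action, so a CSP + classifier pipeline ranks it first.

Background activity is AR(1) (phi = 0.95) plus white noise, giving a
1/f-like spectrum. All randomness flows from one seeded generator per
subject derived from (seed, subject_id), so subjects are reproducible
independently and identical specs yield bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .layout import (
    COGNITIVE_CHANNELS, LEFT_MOTOR_GROUP, MI_CHANNELS, RIGHT_MOTOR_GROUP,
    positions_for,
)
from .preprocess import (
    EEGEpochs, TASK_COGNITIVE, TASK_MI, make_annotations,
)

# Fixed generator internals (not part of the stated experimental design;
# see the methods note for the physiological rationale).
_AR_PHI = 0.95                 # AR(1) coefficient of the background noise
_WHITE_FRACTION = 0.3          # white-noise sd relative to noise_sd
_SOURCE_AMP_FACTOR = 2.0       # oscillatory source amplitude / noise_sd
_MU_AMP_FACTOR = 1.6           # MI mu-rhythm amplitude / noise_sd
_MU_TRIAL_JITTER = 0.25        # log-amplitude sd shared by both hemispheres
_MU_SIDE_JITTER = 0.15         # per-hemisphere log-amplitude sd
_PHASE_JITTER = 0.03           # rad/sample random-walk sd of source phase
_MIX_LENGTH_SCALE = 0.6        # spatial decay (head-radius units)
# one source per band: (low, high, centre frequency Hz, seat electrode)
_COG_SOURCES = (
    (4.0, 8.0, 6.0, "FCZ"),
    (8.0, 13.0, 10.0, "CZ"),
    (13.0, 20.0, 16.0, "CP3"),
)
_COG_BASELINE = 0.2            # s of pre-stimulus, source-free activity
_COG_DURATION = 1.2            # s per cognitive trial
_MI_DURATION = 6.0             # s per MI trial


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort design and effect sizes for the synthetic experiment."""

    n_subjects: int = 10
    n_actions: int = 3
    fs: float = 1000.0
    cognitive_trials_per_action: int = 25
    mi_trials_per_action: int = 80
    cognitive_channels: tuple[str, ...] = tuple(COGNITIVE_CHANNELS)
    mi_channels: tuple[str, ...] = tuple(MI_CHANNELS)
    coupling_strong: float = 0.8
    coupling_weak: float = 0.3
    bandpower_shift: float = 0.5
    erd_depth_strong: float = 0.6
    erd_depth_weak: float = 0.2
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.coupling_strong >= self.coupling_weak >= 0):
            raise ValueError("need coupling_strong >= coupling_weak >= 0")
        for name in ("erd_depth_strong", "erd_depth_weak"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mi_trials_per_action % 2:
            raise ValueError("mi_trials_per_action must be even (left/right)")
        if self.n_actions < 2:
            raise ValueError("need at least 2 actions")
        if self.fs <= 2 * 30:
            raise ValueError("fs too low for the simulated rhythms")
        if len(self.cognitive_channels) < 2 or len(self.mi_channels) < 2:
            raise ValueError("need at least 2 channels per task")


@dataclass
class SubjectDataset:
    subject_id: int
    cognitive_epochs: EEGEpochs = field(repr=False)
    mi_epochs: EEGEpochs = field(repr=False)
    true_strong_action: int


def _background_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      noise_sd: float) -> np.ndarray:
    """AR(1) + white noise along the last axis, stationary sd = noise_sd."""
    drive_sd = noise_sd * np.sqrt(1.0 - _AR_PHI**2)
    e = rng.standard_normal(shape) * drive_sd
    ar = _signal.lfilter([1.0], [1.0, -_AR_PHI], e, axis=-1)
    white = rng.standard_normal(shape) * (_WHITE_FRACTION * noise_sd)
    return ar + white


def _jittered_phase(rng: np.random.Generator, n: int, freq: float,
                    fs: float) -> np.ndarray:
    """Instantaneous phase of a narrow-band source: linear ramp + random
    walk, random initial phase."""
    ramp = 2 * np.pi * freq * np.arange(n) / fs
    walk = np.cumsum(rng.standard_normal(n)) * _PHASE_JITTER
    return ramp + walk + rng.uniform(0, 2 * np.pi)


def _subject_rng(seed: int, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject_id]))


def _cognitive_mixing(channels: list[str]) -> np.ndarray:
    """(n_sources, n_channels) spatial weights decaying with distance from
    each source's seat electrode."""
    pos = positions_for(channels)
    weights = []
    for _, _, _, seat in _COG_SOURCES:
        seat_xy = positions_for([seat])[0]
        d = np.sqrt(((pos - seat_xy) ** 2).sum(-1))
        weights.append(np.exp(-d / _MIX_LENGTH_SCALE))
    return np.array(weights)


def simulate_subject(spec: SimulationSpec, subject_id: int,
                     strong_action: int) -> SubjectDataset:
    """Generate one subject's cognitive and MI epochs.

    Cognitive trials of ``strong_action`` mix the shared band sources with
    gain ``coupling_strong`` (others ``coupling_weak``) and have alpha/beta
    source power scaled by (1 + bandpower_shift). MI trials superimpose a
    10 Hz mu rhythm on the lateral channel groups, attenuated over the
    hemisphere contralateral to the cued hand by the action's ERD depth.
    """
    if not (0 <= strong_action < spec.n_actions):
        raise ValueError(
            f"strong_action {strong_action} out of range for "
            f"{spec.n_actions} actions"
        )
    rng = _subject_rng(spec.seed, subject_id)
    fs = spec.fs
    cog_channels = list(spec.cognitive_channels)
    mi_channels = list(spec.mi_channels)

    # --- cognitive task ---------------------------------------------------
    n_cog = spec.n_actions * spec.cognitive_trials_per_action
    n_samp = int(round(_COG_DURATION * fs))
    n_base = int(round(_COG_BASELINE * fs))
    mixing = _cognitive_mixing(cog_channels)          # (3, n_ch)
    amp = _SOURCE_AMP_FACTOR * spec.noise_sd

    cog = _background_noise(rng, (n_cog, len(cog_channels), n_samp),
                            spec.noise_sd)
    actions = np.repeat(np.arange(spec.n_actions),
                        spec.cognitive_trials_per_action)
    n_task = n_samp - n_base
    for j in range(n_cog):
        strong = actions[j] == strong_action
        gain = spec.coupling_strong if strong else spec.coupling_weak
        for b, (_, _, f0, _) in enumerate(_COG_SOURCES):
            a = amp
            if strong and b >= 1:                     # alpha & beta boost
                a *= np.sqrt(1.0 + spec.bandpower_shift)
            src = a * np.sin(_jittered_phase(rng, n_task, f0, fs))
            cog[j, :, n_base:] += gain * mixing[b][:, None] * src[None, :]
    cog_epochs = EEGEpochs(
        cog, fs, cog_channels,
        make_annotations(n_cog, TASK_COGNITIVE, actions,
                         subject_id=subject_id),
    )

    # --- MI task ----------------------------------------------------------
    n_mi = spec.n_actions * spec.mi_trials_per_action
    m_samp = int(round(_MI_DURATION * fs))
    mi = _background_noise(rng, (n_mi, len(mi_channels), m_samp),
                           spec.noise_sd)
    mi_actions = np.repeat(np.arange(spec.n_actions),
                           spec.mi_trials_per_action)
    half = spec.mi_trials_per_action // 2
    hands = np.tile(np.array(["left"] * half + ["right"] * half,
                             dtype=object), spec.n_actions)
    left_idx = [mi_channels.index(c) for c in LEFT_MOTOR_GROUP
                if c in mi_channels]
    right_idx = [mi_channels.index(c) for c in RIGHT_MOTOR_GROUP
                 if c in mi_channels]
    mu_amp = _MU_AMP_FACTOR * spec.noise_sd
    for j in range(n_mi):
        depth = (spec.erd_depth_strong if mi_actions[j] == strong_action
                 else spec.erd_depth_weak)
        common = np.exp(rng.normal(0.0, _MU_TRIAL_JITTER))
        a_left = mu_amp * common * np.exp(rng.normal(0.0, _MU_SIDE_JITTER))
        a_right = mu_amp * common * np.exp(rng.normal(0.0, _MU_SIDE_JITTER))
        if hands[j] == "right":                       # contralateral ERD
            a_left *= np.sqrt(1.0 - depth)
        else:
            a_right *= np.sqrt(1.0 - depth)
        mu_l = a_left * np.sin(_jittered_phase(rng, m_samp, 10.0, fs))
        mu_r = a_right * np.sin(_jittered_phase(rng, m_samp, 10.0, fs))
        mi[j, left_idx, :] += mu_l[None, :]
        mi[j, right_idx, :] += mu_r[None, :]
    mi_epochs = EEGEpochs(
        mi, fs, mi_channels,
        make_annotations(n_mi, TASK_MI, mi_actions, hands,
                         subject_id=subject_id),
    )

    return SubjectDataset(subject_id, cog_epochs, mi_epochs, strong_action)


def assign_strong_actions(spec: SimulationSpec) -> np.ndarray:
    """Balanced seeded assignment of one strong action per subject (each
    action appears for floor(n/k) or ceil(n/k) subjects)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    reps = -(-spec.n_subjects // spec.n_actions)
    pool = np.tile(np.arange(spec.n_actions), reps)[: spec.n_subjects]
    return rng.permutation(pool)


def simulate_cohort(spec: SimulationSpec) -> list[SubjectDataset]:
    """Generate all subjects of a cohort (requires >= 2 for LOSO)."""
    if spec.n_subjects < 2:
        raise ValueError("leave-one-subject-out needs n_subjects >= 2")
    strong = assign_strong_actions(spec)
    return [simulate_subject(spec, sid, int(strong[sid]))
            for sid in range(spec.n_subjects)]
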