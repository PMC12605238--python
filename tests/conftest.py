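"""Shared fixtures: reduced-size synthetic cohorts and helpers.

Session-scoped fixtures keep the expensive EEG generation to a single run
per test session; all sizes here are deliberately smaller than the full
experimental design (which the acceptance tests exercise).
"""

from __future__ import annotations

import numpy as np
import pytest

from cogmi.brain_networks import build_multidomain_graphs, fit_csp
from cogmi.preprocess import (
    EEGEpochs, make_annotations, preprocess_cognitive,
)
from cogmi.synthetic_data import SimulationSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """Two subjects, reduced trial counts, default effect sizes."""
    return SimulationSpec(
        n_subjects=2,
        cognitive_trials_per_action=6,
        mi_trials_per_action=12,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def cognitive_preprocessed(small_cohort):
    return [preprocess_cognitive(s.cognitive_epochs) for s in small_cohort]


@pytest.fixture(scope="session")
def subject_graphs(small_cohort, cognitive_preprocessed):
    """Per-trial graph triples for subject 0, CSP fitted on its own
    true-strong labels (fine for unit tests; LOSO refits per fold)."""
    cog = cognitive_preprocessed[0]
    strong_mask = (
        cog.annotations["action"] == small_cohort[0].true_strong_action
    ).to_numpy()
    csp = fit_csp(cog.data[strong_mask], cog.data[~strong_mask])
    triples = build_multidomain_graphs(cog, csp)
    return triples, strong_mask


def make_epochs(data: np.ndarray, fs: float = 1000.0,
                channel_names=None, task: str = "cognitive",
                actions=0) -> EEGEpochs:
    """Wrap a raw (trials, channels, samples) array into EEGEpochs."""
    data = np.asarray(data, dtype=float)
    if channel_names is None:
        channel_names = [f"CH{i}" for i in range(data.shape[1])]
    ann = make_annotations(data.shape[0], task, actions)
    return EEGEpochs(data, fs, list(channel_names), ann)
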