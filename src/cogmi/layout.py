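"""Electrode montage constants.

A schematic 2-D projection of the international 10-20 layout (head seen from
above, nose up; unit head radius). The coordinates are only used for
distance-based source mixing in the synthetic generator and for exporting
channel geometry — no source modelling is done with them.
"""

from __future__ import annotations

import numpy as np

# (x, y): x positive toward the right ear, y positive toward the nose.
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.48), "FZ": (0.0, 0.50),
    "F4": (0.55, 0.48), "F8": (0.81, 0.59),
    "FC5": (-0.78, 0.25), "FC3": (-0.50, 0.25), "FC1": (-0.25, 0.25),
    "FCZ": (0.0, 0.25), "FC2": (0.25, 0.25), "FC4": (0.50, 0.25),
    "FC6": (0.78, 0.25),
    "T7": (-1.0, 0.0), "C5": (-0.75, 0.0), "C3": (-0.50, 0.0),
    "C1": (-0.25, 0.0), "CZ": (0.0, 0.0), "C2": (0.25, 0.0),
    "C4": (0.50, 0.0), "C6": (0.75, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.78, -0.25), "CP3": (-0.50, -0.25), "CP1": (-0.25, -0.25),
    "CPZ": (0.0, -0.25), "CP2": (0.25, -0.25), "CP4": (0.50, -0.25),
    "CP6": (0.78, -0.25),
    "P7": (-0.81, -0.59), "P3": (-0.55, -0.48), "PZ": (0.0, -0.50),
    "P4": (0.55, -0.48), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.72), "POZ": (0.0, -0.72), "PO4": (0.35, -0.72),
    "O1": (-0.31, -0.95), "OZ": (0.0, -0.97), "O2": (0.31, -0.95),
}

#: Cognitive-task montage: 19 channels over supplementary motor, motor and
#: visual areas, in the canonical analysis order.
COGNITIVE_CHANNELS: list[str] = [
    "FZ", "FC3", "FCZ", "FC4", "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP3", "CP4", "PO3", "POZ", "PO4", "O1", "OZ", "O2",
]

#: Motor-imagery montage: 12 channels over the sensorimotor strip.
MI_CHANNELS: list[str] = [
    "FC3", "FCZ", "FC4", "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP3", "CP4",
]

#: Left- and right-hemisphere sensorimotor groups used for the lateralized
#: mu rhythm in the synthetic generator.
LEFT_MOTOR_GROUP: list[str] = ["FC3", "C5", "C3", "C1", "CP3"]
RIGHT_MOTOR_GROUP: list[str] = ["FC4", "C2", "C4", "C6", "CP4"]


def positions_for(names: list[str]) -> np.ndarray:
    """Return an (n, 2) array of schematic coordinates for *names*."""
    missing = [n for n in names if n.upper() not in ELECTRODE_POSITIONS]
    if missing:
        raise KeyError(f"no layout position for channel(s): {missing}")
    return np.array([ELECTRODE_POSITIONS[n.upper()] for n in names], dtype=float)


def pairwise_distances(names: list[str]) -> np.ndarray:
    pos = positions_for(names)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(-1))
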