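"""Fe···C≡O angle analysis and B-state classification.

Photodissociated CO in the distal-pocket docking site of myoglobin adopts
two antiparallel orientations distinguished by the angle at the probe C
between the rays toward the heme iron and toward O: an obtuse mode near
115° (the B1 state, C closer to Fe) and an acute mode near 50–55° (B2, O
closer to Fe).  Frames are classified by a hard threshold at 90° — far
from both modes, so the boundary rule does not move populations — and the
B1/B2 ratio is the frame-count ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Angle threshold separating the two orientational states, degrees.
B_STATE_THRESHOLD = 90.0


@dataclass(frozen=True)
class AngleSample:
    """One frame's Fe···C≡O angle, degrees in [0, 180]."""

    frame_index: int
    angle: float

    def __post_init__(self):
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError(f"angle {self.angle} outside [0, 180]")


@dataclass(frozen=True)
class StateCounts:
    """B1/B2 frame counts; the ratio is undefined (inf) when n_b2 = 0."""

    n_b1: int
    n_b2: int

    @property
    def ratio(self) -> float:
        if self.n_b2 == 0:
            warnings.warn("no B2 frames: B1/B2 ratio undefined", stacklevel=2)
            return float("inf")
        return self.n_b1 / self.n_b2


def fe_co_angle(fe_position, c_position, o_position) -> float:
    """Angle at C between the rays toward Fe and toward O, degrees."""
    fe = np.asarray(fe_position, dtype=float)
    c = np.asarray(c_position, dtype=float)
    o = np.asarray(o_position, dtype=float)
    u = fe - c
    v = o - c
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise ValueError("coincident points: angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_state(angle, threshold: float = B_STATE_THRESHOLD):
    """Map angle(s) to state labels: "B1" above the threshold, "B2" at or below.

    The modes sit near 115° and 50°, so the exact tie-break at the
    threshold is population-irrelevant; angles exactly at it go to B2 for
    determinism.
    """
    a = np.asarray(angle, dtype=float)
    if np.any(a < 0.0) or np.any(a > 180.0):
        raise ValueError("angle outside [0, 180]")
    labels = np.where(a > threshold, "B1", "B2")
    return str(labels) if labels.ndim == 0 else labels


def state_ratio(angles, threshold: float = B_STATE_THRESHOLD) -> StateCounts:
    """Classify an angle series and count the two states."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle series")
    labels = classify_state(a, threshold)
    n_b1 = int(np.sum(labels == "B1"))
    return StateCounts(n_b1=n_b1, n_b2=int(a.size - n_b1))


def angle_histogram(angles, bin_width: float = 2.0):
    """Normalized angle density over [0, 180] with uniform bins.

    Returns ``(edges, density)`` with half-open bins [lo, hi) and the last
    bin closed.  ``bin_width`` must divide 180 evenly.
    """
    if bin_width <= 0 or abs(round(180.0 / bin_width) - 180.0 / bin_width) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 180 evenly")
    a = np.asarray(angles, dtype=float)
    if np.any(a < 0.0) or np.any(a > 180.0):
        raise ValueError("angle outside [0, 180]")
    n_bins = int(round(180.0 / bin_width))
    density, edges = np.histogram(a, bins=n_bins, range=(0.0, 180.0), density=True)
    return edges, density
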