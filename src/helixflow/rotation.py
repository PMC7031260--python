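"""Rotation-direction (handedness) classification of pathlines.

Each pathline sample is projected onto the vessel cross-section plane at
the nearest centerline point.  The plane is spanned by

    nx = normalize(n x (1,0,0)),   ny = normalize(nx x n)

with ``n`` the centerline tangent.  For one segment (a sample and its
successor) the handedness is the sign of the shortest signed angle between
the two projected points: a first-to-second-quadrant move is right-handed
(RD+), a fourth-to-third-quadrant move is left-handed (RD−), and for
diagonal quadrants the sign agrees with the side on which the connecting
chord crosses the y-axis.  A pathline's label is the majority vote over
its non-degenerate segments.

Note the chart (nx, ny, n) is deliberately left-handed — that is what the
published construction prescribes — so "RD+" corresponds to clockwise
rotation when viewed along the flow direction.  An orientation flag for
LPS- vs RAS-stored volumes flips only the reported label, never the
internal sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .errors import DomainError
from .pathlines import Pathline

__all__ = ["CrossSectionFrame", "SegmentClassification", "cross_section_frame",
           "classify_segment", "classify_pathline", "classify_pathlines"]

_DEGENERATE_ANGLE = 1e-9
_WORLD_X = np.array([1.0, 0.0, 0.0])
_FALLBACK = np.array([0.0, 1.0, 0.0])


@dataclass
class CrossSectionFrame:
    """Cross-section plane: center c, tangent n, in-plane axes nx, ny."""

    c: np.ndarray
    n: np.ndarray
    nx: np.ndarray
    ny: np.ndarray


@dataclass
class SegmentClassification:
    quadrant_first: int
    quadrant_second: int
    rule: str          # "adjacent" | "diagonal" | "same" | "degenerate"
    rd: int            # +1 | -1 | 0


def _frame_from_tangent(c: np.ndarray, n: np.ndarray) -> CrossSectionFrame:
    cx = np.cross(n, _WORLD_X)
    if np.linalg.norm(cx) < 1e-6:
        # tangent parallel to world x: fall back to world y as crossing axis
        cx = np.cross(n, _FALLBACK)
    nx = cx / np.linalg.norm(cx)
    ny_ = np.cross(nx, n)
    ny_ = ny_ / np.linalg.norm(ny_)
    return CrossSectionFrame(c=np.asarray(c, float), n=np.asarray(n, float),
                             nx=nx, ny=ny_)


def cross_section_frame(cl: Centerline, point: np.ndarray) -> CrossSectionFrame:
    """Frame at the centerline sample nearest to ``point`` (mm)."""
    idx = int(cl.nearest_index(np.asarray(point, float))[0])
    return _frame_from_tangent(cl.points[idx], cl.tangents[idx])


def _quadrant(u: float, v: float) -> int:
    if u >= 0 and v >= 0:
        return 1
    if u < 0 <= v:
        return 2
    if u < 0 and v < 0:
        return 3
    return 4


def classify_segment(p_first: np.ndarray, p_second: np.ndarray,
                     frame: CrossSectionFrame) -> SegmentClassification:
    """Handedness of one pathline segment in the cross-section plane.

    rd = sign of the shortest signed angle from the first to the second
    projected point; zero in-plane radius or vanishing angle is degenerate
    (rd = 0).
    """
    d1 = np.asarray(p_first, float) - frame.c
    d2 = np.asarray(p_second, float) - frame.c
    u1, v1 = float(d1 @ frame.nx), float(d1 @ frame.ny)
    u2, v2 = float(d2 @ frame.nx), float(d2 @ frame.ny)
    q1, q2 = _quadrant(u1, v1), _quadrant(u2, v2)
    r1 = np.hypot(u1, v1)
    r2 = np.hypot(u2, v2)
    if r1 < 1e-12 or r2 < 1e-12:
        return SegmentClassification(q1, q2, "degenerate", 0)
    cross = u1 * v2 - v1 * u2
    dot = u1 * u2 + v1 * v2
    angle = np.arctan2(cross, dot)
    if abs(angle) < _DEGENERATE_ANGLE:
        return SegmentClassification(q1, q2, "degenerate", 0)
    if q1 == q2:
        rule = "same"
    elif (q1, q2) in ((1, 3), (3, 1), (2, 4), (4, 2)):
        rule = "diagonal"
    else:
        rule = "adjacent"
    return SegmentClassification(q1, q2, rule, int(np.sign(angle)))


def classify_pathline(line: Pathline, cl: Centerline,
                      orientation: str = "LPS") -> str:
    """Majority-vote RD label for one pathline: "RD+", "RD-", or
    "indeterminate" on a tie / all-degenerate line.  ``orientation="RAS"``
    flips the reported label (stored-axis handedness differs), never the
    internal segment signs."""
    if len(line) < 2:
        raise DomainError("pathline needs at least 2 samples")
    idx = cl.nearest_index(line.positions)
    votes = np.zeros(3, dtype=int)  # [-1, 0, +1] -> bins 0,1,2
    for k in range(len(line) - 1):
        frame = _frame_from_tangent(cl.points[idx[k]], cl.tangents[idx[k]])
        seg = classify_segment(line.positions[k], line.positions[k + 1], frame)
        votes[seg.rd + 1] += 1
    plus, minus = votes[2], votes[0]
    if plus == minus:
        label = "indeterminate"
    else:
        sign = 1 if plus > minus else -1
        if orientation.upper() == "RAS":
            sign = -sign
        label = "RD+" if sign > 0 else "RD-"
    line.rd_label = label
    return label


def classify_pathlines(lines: list, cl: Centerline,
                       orientation: str = "LPS") -> dict:
    """Classify every line; returns label counts."""
    counts = {"RD+": 0, "RD-": 0, "indeterminate": 0}
    for line in lines:
        counts[classify_pathline(line, cl, orientation)] += 1
    return counts
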