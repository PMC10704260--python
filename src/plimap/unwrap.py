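"""Correction of the decomposition's retardance phase-wrapping artifact.

The inverse-cosine retardance of the polar decomposition is confined to
[0, pi].  When the true retardance crosses pi, the recovered value is
mirrored around pi and the recovered axis jumps by exactly 90 deg.  The
correction is mask-based: the 90-deg axial discontinuities delimit the
wrapped region; inside it the retardance is remapped on the selected branch
(2*pi - R for data mirrored around pi, -R for data mirrored around zero) and
the angle is shifted by 90 deg.

Branch identification is made algorithmic here: the physical model predicts
mean retardance to fall with wavelength, so the branch whose per-wavelength
ROI means are (closest to) monotonically decreasing is selected, with an
ambiguity flag whenever the evidence does not single one out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import (
    AlreadyCorrectedError,
    BranchRequiredError,
    InsufficientDataError,
    InvalidArgumentError,
)

BRANCH_AROUND_PI = "around_pi"
BRANCH_AROUND_ZERO = "around_zero"
_BRANCHES = (BRANCH_AROUND_PI, BRANCH_AROUND_ZERO)


def axial_difference(a, b):
    """Signed axial (180-deg periodic) difference a - b, in (-90, 90]."""
    d = (np.asarray(a, float) - np.asarray(b, float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


@dataclass
class WrapMask:
    """Boolean flags marking wrapped pixels/stations, plus the branch choice.

    ``branch`` may be None until resolved (apply_unwrap refuses to run then);
    ``provenance`` records whether it was user-set or auto-selected.
    """

    flags: np.ndarray
    branch: str | None = None
    provenance: str = "unset"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.branch is not None and self.branch not in _BRANCHES:
            raise InvalidArgumentError(f"unknown branch {self.branch!r}")


@dataclass
class UnwrapResult:
    """Corrected retardance/angle data; carries the corrected flag.

    ``retardance`` is signed on the around_zero branch (the magnitude is the
    physical retardance; the sign only records the mirroring) and plain
    radians on the around_pi branch, where values exceed pi inside the
    corrected region.
    """

    retardance: np.ndarray
    angle: np.ndarray
    mask: WrapMask
    corrected: bool = True


def detect_wrapped_regions(
    angle_data,
    jump_target: float = 90.0,
    tolerance: float = 20.0,
    axis: int = -1,
) -> WrapMask:
    """Flag contiguous regions lying beyond a ~90-deg axial-angle discontinuity.

    Works on 1-D profiles directly; for 2-D maps each line along ``axis`` is
    scanned independently (connected growth along the scan direction).  Jumps
    are measured with the axial (180-deg periodic) distance; each qualifying
    jump toggles the wrapped state, and the station at the discontinuity is
    assigned to the flagged side.
    """
    angle = np.asarray(angle_data, dtype=float)
    if np.count_nonzero(np.isfinite(angle)) < 2:
        raise InsufficientDataError("need at least 2 valid angle samples")
    if angle.ndim == 1:
        flags = _scan_line(angle, jump_target, tolerance)
    else:
        moved = np.moveaxis(angle, axis, -1)
        flat = moved.reshape(-1, moved.shape[-1])
        out = np.stack([_scan_line(line, jump_target, tolerance) for line in flat])
        flags = np.moveaxis(out.reshape(moved.shape), -1, axis)
    return WrapMask(flags=flags, branch=None, provenance="detected")


def _scan_line(line: np.ndarray, jump_target: float, tolerance: float) -> np.ndarray:
    flags = np.zeros(line.shape, dtype=bool)
    finite = np.isfinite(line)
    idx = np.flatnonzero(finite)
    if idx.size < 2:
        return flags
    state = False
    prev = line[idx[0]]
    prev_i = idx[0]
    for i in idx[1:]:
        step = abs(float(axial_difference(line[i], prev)))
        if abs(step - jump_target) <= tolerance:
            state = not state
        # transition station assigned to the flagged side
        flags[prev_i + 1 : i + 1] = state
        prev, prev_i = line[i], i
    if state:
        flags[prev_i:] = True
    return flags


def apply_unwrap(retardance, angle, mask: WrapMask) -> UnwrapResult:
    """Correct flagged entries on the mask's branch; leave the rest untouched.

    around_pi:   R' = 2*pi - R;  around_zero: R' = -R (signed; magnitude is
    the physical value).  Flagged angles are shifted by +90 deg (mod 180).
    Refuses to run twice: passing an UnwrapResult raises AlreadyCorrectedError.
    """
    if isinstance(retardance, UnwrapResult) or getattr(retardance, "corrected", False):
        raise AlreadyCorrectedError("data already carries the corrected flag")
    if mask.branch is None:
        raise BranchRequiredError("wrap mask has no branch; run select_branch or set one")
    R = np.array(retardance, dtype=float, copy=True)
    A = np.array(angle, dtype=float, copy=True)
    if mask.flags.shape != R.shape or mask.flags.shape != A.shape:
        raise InvalidArgumentError("mask shape does not match data shape")
    f = mask.flags
    if mask.branch == BRANCH_AROUND_PI:
        R[f] = 2.0 * np.pi - R[f]
    else:
        R[f] = -R[f]
    A[f] = (A[f] + 90.0) % 180.0
    return UnwrapResult(retardance=R, angle=A, mask=mask)


def unwrap_maps(maps, mask: WrapMask):
    """Apply the correction to a PolarizationMaps object, setting its corrected flag."""
    if maps.corrected:
        raise AlreadyCorrectedError("maps already corrected")
    res = apply_unwrap(maps.retardance, maps.retardance_angle, mask)
    out = maps.copy()
    out.retardance = res.retardance
    out.retardance_angle = res.angle
    out.corrected = True
    out.meta["unwrap_branch"] = mask.branch
    out.meta["unwrap_provenance"] = mask.provenance
    return out


@dataclass
class BranchDecision:
    branch: str | None
    ambiguous: bool
    violations: dict


def select_branch(
    per_wavelength_means: Mapping[str, Sequence[tuple[float, float]]],
) -> BranchDecision:
    """Choose the unwrap branch from candidate per-wavelength ROI mean tables.

    ``per_wavelength_means`` maps each candidate branch name to a sequence of
    (wavelength_nm, mean_retardance_rad) pairs; NaN means are dropped.  The
    branch whose means decrease monotonically with wavelength wins.  Ties go
    to around_pi with the ambiguity flag set; if no branch is monotone no
    decision is made and the flag is set.
    """
    violations: dict[str, int] = {}
    for branch, table in per_wavelength_means.items():
        pairs = [(w, m) for w, m in table if np.isfinite(m)]
        if len(pairs) < 2:
            continue
        pairs.sort(key=lambda p: p[0])
        means = np.array([abs(m) for _, m in pairs])
        violations[branch] = int(np.count_nonzero(np.diff(means) > 0))
    if not violations:
        raise InsufficientDataError("no branch has >= 2 valid wavelength means")
    monotone = [b for b, v in violations.items() if v == 0]
    if len(monotone) == 1:
        return BranchDecision(branch=monotone[0], ambiguous=False, violations=violations)
    if len(monotone) > 1:
        pick = BRANCH_AROUND_PI if BRANCH_AROUND_PI in monotone else sorted(monotone)[0]
        return BranchDecision(branch=pick, ambiguous=True, violations=violations)
    return BranchDecision(branch=None, ambiguous=True, violations=violations)
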