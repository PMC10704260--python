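"""Lu-Chipman polar decomposition and pixelwise polarization-property maps.

A measured Mueller matrix M is factored as

    M = M_depol . M_ret . M_diatt

(depolarizer times retarder times diattenuator, in that fixed order).  From
the factors the scalar maps are extracted:

* retardance           R = arccos(tr(M_ret)/2 - 1), radians in [0, pi];
* retardance angle     fast-axis orientation from the retardance vector;
* diattenuation        D = |first row| / m00, with its linear axis;
* depolarization power Delta = 1 - |tr(M_depol) - 1| / 3.

The arccos range is the root of the phase-wrapping artifact handled by
:mod:`plimap.unwrap`: a true retardance delta > pi comes back as 2*pi - delta
with the axis flipped by 90 deg.

All heavy routines are batched over leading axes so whole image stacks
decompose in a handful of LAPACK calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import (
    DecompositionError,
    InvalidArgumentError,
    InvalidRetarderError,
)
from .mueller import ANGLE_CONVENTION, MuellerImageStack

#: Below this retardance / diattenuation magnitude the axis is meaningless
#: (atan2 on numerical noise) and is reported as NaN.
AXIS_UNDEFINED_TOL = 1e-6

#: Eigenvalues of m' m'^T are clamped here to keep the depolarizer inversion
#: defined; pixels needing the clamp are flagged degenerate.
EIGEN_CLAMP = 1e-12

_I3 = np.eye(3)


@dataclass
class DecompositionResult:
    """Factors of one Mueller matrix in the order M = M_depol . M_ret . M_diatt."""

    M_depol: np.ndarray
    M_ret: np.ndarray
    M_diatt: np.ndarray
    residual: float = 0.0
    degenerate: bool = False

    def reconstruct(self) -> np.ndarray:
        return self.M_depol @ self.M_ret @ self.M_diatt


@dataclass
class PolarizationMaps:
    """Per-wavelength pixel maps of the five polarization properties.

    Angles follow the shared axial convention; pixels where the angle is
    undefined (retardance or diattenuation below tolerance) hold NaN while
    remaining valid.  Invalid pixels (validity False) hold NaN everywhere and
    are excluded from all statistics.
    """

    retardance: np.ndarray
    retardance_angle: np.ndarray
    diattenuation: np.ndarray
    diattenuation_angle: np.ndarray
    depolarization: np.ndarray
    wavelength: float
    validity: np.ndarray
    corrected: bool = False
    meta: dict = field(default_factory=lambda: {"angle_convention": ANGLE_CONVENTION})

    def __post_init__(self) -> None:
        shape = np.asarray(self.retardance).shape
        for name in ("retardance_angle", "diattenuation", "diattenuation_angle",
                     "depolarization", "validity"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise InvalidArgumentError(f"{name} shape differs from retardance map")

    @property
    def shape(self) -> tuple[int, ...]:
        return np.asarray(self.retardance).shape

    def copy(self) -> "PolarizationMaps":
        return PolarizationMaps(
            retardance=np.array(self.retardance, copy=True),
            retardance_angle=np.array(self.retardance_angle, copy=True),
            diattenuation=np.array(self.diattenuation, copy=True),
            diattenuation_angle=np.array(self.diattenuation_angle, copy=True),
            depolarization=np.array(self.depolarization, copy=True),
            wavelength=self.wavelength,
            validity=np.array(self.validity, copy=True),
            corrected=self.corrected,
            meta=dict(self.meta),
        )


def _lu_chipman_batch(M: np.ndarray):
    """Batched polar decomposition of (..., 4, 4) matrices.

    Returns (M_depol, M_ret, M_diatt, valid, degenerate).  M_diatt carries the
    full m00 scale; M_depol and M_ret are unit-transmittance.
    """
    M = np.asarray(M, dtype=float)
    m00 = M[..., 0, 0]
    valid = np.all(np.isfinite(M), axis=(-2, -1)) & (m00 > 0)
    degenerate = np.zeros_like(valid)

    safe_m00 = np.where(valid, m00, 1.0)
    Mn = np.where(valid[..., None, None], M, np.eye(4)) / safe_m00[..., None, None]

    # --- diattenuator from the first row -------------------------------
    D = Mn[..., 0, 1:]
    Dmag = np.linalg.norm(D, axis=-1)
    over = Dmag >= 1.0 - 1e-9
    degenerate |= over & valid
    scale = np.where(over, (1.0 - 1e-9) / np.where(Dmag > 0, Dmag, 1.0), 1.0)
    D = D * scale[..., None]
    Dmag = np.minimum(Dmag * scale, 1.0 - 1e-9)

    a = np.sqrt(1.0 - Dmag**2)
    Dhat = np.where(
        (Dmag > 0)[..., None], D / np.where(Dmag > 0, Dmag, 1.0)[..., None],
        np.array([1.0, 0.0, 0.0]),
    )
    mD = a[..., None, None] * _I3 + (1.0 - a)[..., None, None] * (
        Dhat[..., :, None] * Dhat[..., None, :]
    )
    MD = np.zeros(Mn.shape)
    MD[..., 0, 0] = 1.0
    MD[..., 0, 1:] = D
    MD[..., 1:, 0] = D
    MD[..., 1:, 1:] = mD
    Mp = Mn @ np.linalg.inv(MD)

    # --- depolarizer from the square root of m' m'^T -------------------
    mp = Mp[..., 1:, 1:]
    C = mp @ np.swapaxes(mp, -1, -2)
    lam = np.linalg.eigvalsh(C)  # ascending
    degenerate |= (lam[..., 0] < EIGEN_CLAMP) & valid
    lam = np.clip(lam, EIGEN_CLAMP, None)
    s1, s2, s3 = lam[..., 0] ** 0.5, lam[..., 1] ** 0.5, lam[..., 2] ** 0.5
    sign = np.where(np.linalg.det(mp) < 0, -1.0, 1.0)
    A = C + (s1 * s2 + s2 * s3 + s3 * s1)[..., None, None] * _I3
    B = (s1 + s2 + s3)[..., None, None] * C + (s1 * s2 * s3)[..., None, None] * _I3
    mdel = sign[..., None, None] * (np.linalg.inv(A) @ B)

    Mdepol = np.zeros(Mn.shape)
    Mdepol[..., 0, 0] = 1.0
    Mdepol[..., 1:, 0] = Mp[..., 1:, 0]
    Mdepol[..., 1:, 1:] = mdel

    # --- retarder is what remains --------------------------------------
    mR = np.linalg.solve(mdel, mp)
    MR = np.zeros(Mn.shape)
    MR[..., 0, 0] = 1.0
    MR[..., 1:, 1:] = mR

    Mdiatt = MD * safe_m00[..., None, None]

    finite = np.all(np.isfinite(Mdepol), axis=(-2, -1)) & np.all(
        np.isfinite(MR), axis=(-2, -1)
    )
    valid &= finite
    return Mdepol, MR, Mdiatt, valid, degenerate


def lu_chipman_decompose(M: np.ndarray) -> DecompositionResult:
    """Decompose a single Mueller matrix into depolarizer, retarder, diattenuator.

    Raises
    ------
    DecompositionError
        If M is non-finite, has m00 <= 0, or the factors cannot reconstruct
        the input to a sane residual (grossly non-physical input).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise InvalidArgumentError("M must be 4x4")
    Mdepol, MR, Mdiatt, valid, degenerate = _lu_chipman_batch(M)
    if not valid:
        raise DecompositionError("matrix is non-finite, singular, or m00 <= 0")
    recon = Mdepol @ MR @ Mdiatt
    residual = float(np.max(np.abs(recon - M)))
    if not degenerate and residual > 1e-6 * max(1.0, abs(M[0, 0])):
        raise DecompositionError(f"reconstruction residual {residual:.3e} too large")
    return DecompositionResult(Mdepol, MR, Mdiatt, residual, bool(degenerate))


def _retardance_batch(MR: np.ndarray):
    """Batched retardance magnitude and fast-axis angle from retarder factors."""
    mR = MR[..., 1:, 1:]
    tr = np.trace(mR, axis1=-2, axis2=-1)
    R = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
    sinR = np.sin(R)

    # generic path: retardance vector from the antisymmetric part
    safe = np.where(sinR > 1e-7, sinR, 1.0)
    r1 = (mR[..., 1, 2] - mR[..., 2, 1]) / (2 * safe)
    r2 = (mR[..., 2, 0] - mR[..., 0, 2]) / (2 * safe)

    # near R = pi the antisymmetric part vanishes; use the dyadic diagonal
    p1 = np.sqrt(np.clip((mR[..., 0, 0] + 1.0) / 2.0, 0.0, None))
    p2 = np.sqrt(np.clip((mR[..., 1, 1] + 1.0) / 2.0, 0.0, None))
    p2 = np.where(mR[..., 0, 1] + mR[..., 1, 0] < 0, -p2, p2)
    near_pi = sinR <= 1e-7
    r1 = np.where(near_pi, p1, r1)
    r2 = np.where(near_pi, p2, r2)

    axis = np.degrees(0.5 * np.arctan2(r2, r1)) % 180.0
    axis = np.where(R < AXIS_UNDEFINED_TOL, np.nan, axis)
    return R, axis


def retardance_params(M_ret: np.ndarray, tol: float = 1e-6) -> tuple[float, float]:
    """Retardance (radians, in [0, pi]) and fast-axis angle (deg) of a retarder.

    The axis is NaN when the retardance is below tolerance.  Raises
    InvalidRetarderError when the 3x3 block is not orthogonal within ``tol``.
    """
    M_ret = np.asarray(M_ret, dtype=float)
    if M_ret.shape != (4, 4):
        raise InvalidArgumentError("M_ret must be 4x4")
    mR = M_ret[1:, 1:]
    if np.max(np.abs(mR @ mR.T - _I3)) > max(tol, 1e-8):
        raise InvalidRetarderError("lower-right 3x3 block is not orthogonal")
    R, axis = _retardance_batch(M_ret)
    return float(R), float(axis)


def diattenuation_params(M: np.ndarray) -> tuple[float, float]:
    """Diattenuation magnitude and linear transmission-axis angle (deg).

    D = sqrt(m01^2 + m02^2 + m03^2)/m00; the linear axis is
    0.5 atan2(m02, m01) mapped to [0, 180), NaN when D is below tolerance.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise InvalidArgumentError("M must be 4x4")
    m00 = M[0, 0]
    if not np.isfinite(m00) or m00 <= 0:
        raise InvalidArgumentError("m00 must be positive")
    D = float(np.linalg.norm(M[0, 1:]) / m00)
    D = min(D, 1.0)
    if D < AXIS_UNDEFINED_TOL:
        return D, float("nan")
    axis = np.degrees(0.5 * np.arctan2(M[0, 2], M[0, 1])) % 180.0
    return D, float(axis)


def depolarization_power(M_depol: np.ndarray) -> float:
    """Depolarization power Delta = 1 - |tr(M_depol) - 1| / 3, in [0, 1]."""
    M_depol = np.asarray(M_depol, dtype=float)
    if not np.all(np.isfinite(M_depol)):
        raise InvalidArgumentError("M_depol must be finite")
    delta = 1.0 - abs(np.trace(M_depol) - 1.0) / 3.0
    return float(np.clip(delta, 0.0, 1.0))


def decompose_stack(stack: MuellerImageStack) -> list[PolarizationMaps]:
    """Decompose every valid pixel of a stack into polarization-property maps.

    Pixels where the decomposition fails are marked invalid in the output and
    hold NaN; they are never silently filled.  The per-wavelength failure
    count is appended to ``stack.meta['decomposition_failures']``.
    """
    if stack.n_wavelengths == 0:
        raise InvalidArgumentError("stack is empty")
    out: list[PolarizationMaps] = []
    failures: list[int] = []
    for k in range(stack.n_wavelengths):
        M = stack.matrices[k]
        Mdepol, MR, Mdiatt, valid, degenerate = _lu_chipman_batch(M)
        valid &= stack.validity[k]
        ok = valid & ~degenerate

        R, axis = _retardance_batch(MR)
        D = np.minimum(
            np.linalg.norm(Mdiatt[..., 0, 1:], axis=-1)
            / np.where(Mdiatt[..., 0, 0] > 0, Mdiatt[..., 0, 0], 1.0),
            1.0,
        )
        d_axis = np.degrees(
            0.5 * np.arctan2(Mdiatt[..., 0, 2], Mdiatt[..., 0, 1])
        ) % 180.0
        d_axis = np.where(D < AXIS_UNDEFINED_TOL, np.nan, d_axis)
        tr_del = np.trace(Mdepol, axis1=-2, axis2=-1)
        depol = np.clip(1.0 - np.abs(tr_del - 1.0) / 3.0, 0.0, 1.0)

        nanmask = ~ok
        maps = PolarizationMaps(
            retardance=np.where(nanmask, np.nan, R),
            retardance_angle=np.where(nanmask, np.nan, axis),
            diattenuation=np.where(nanmask, np.nan, D),
            diattenuation_angle=np.where(nanmask, np.nan, d_axis),
            depolarization=np.where(nanmask, np.nan, depol),
            wavelength=float(stack.wavelengths[k]),
            validity=ok,
            meta={
                "angle_convention": ANGLE_CONVENTION,
                "pixel_pitch": stack.pixel_pitch,
            },
        )
        out.append(maps)
        failures.append(int(np.count_nonzero(stack.validity[k] & ~ok)))
    stack.meta["decomposition_failures"] = failures
    return out
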