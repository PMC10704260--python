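"""Mueller-matrix algebra: elementary polarization elements and frame rotation.

Conventions shared by the whole package
---------------------------------------
* A Mueller matrix is a real 4x4 array, row-major: row = output Stokes
  component, column = input Stokes component.
* Axis angles are degrees on [0, 180) (axial data), 0 deg horizontal pointing
  to the right (+x), counterclockwise positive.
* The angle reported for a retarder is its FAST axis.  The convention is
  exposed as :data:`FAST_AXIS_CONVENTION` rather than hard-wired into
  downstream metadata, because instruments differ on fast vs slow reporting.
* Elementary constructors emit unit-maximum-transmittance elements; the
  diattenuator therefore carries m00 = 1/(1+d), which reduces to the familiar
  0.5-scale ideal polarizer at d = 1 and to the identity at d = 0.

All constructors broadcast: scalar arguments give a (4, 4) array, array
arguments of shape S give (S + (4, 4)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._exceptions import InvalidArgumentError

#: Default imaging wavelengths (nm) of the five-channel polarimeter emulated here.
DEFAULT_WAVELENGTHS: tuple[int, ...] = (405, 442, 473, 532, 632)

#: Whether retarder constructors interpret/report the FAST or SLOW axis.
FAST_AXIS_CONVENTION: str = "fast"

#: Human-readable statement of the axial-angle convention, stamped into metadata.
ANGLE_CONVENTION: str = (
    "degrees in [0,180), 0 deg horizontal pointing right, counterclockwise "
    "positive; retarder angle denotes the fast axis"
)


def _as_finite_array(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} must be finite")
    return arr


def _assemble(rows: list[list[np.ndarray]]) -> np.ndarray:
    """Stack 16 broadcastable scalar fields into a (..., 4, 4) array."""
    flat = [np.asarray(e, dtype=float) for row in rows for e in row]
    shape = np.broadcast_shapes(*(e.shape for e in flat))
    out = np.empty(shape + (4, 4))
    for i in range(4):
        for j in range(4):
            out[..., i, j] = np.broadcast_to(flat[4 * i + j], shape)
    return out


def stokes_rotation(phi: Any) -> np.ndarray:
    """Rotation of the Stokes frame by ``phi`` degrees (acts on S1/S2 only)."""
    phi = _as_finite_array(phi, "phi")
    c2, s2 = np.cos(2 * np.radians(phi)), np.sin(2 * np.radians(phi))
    one, zero = np.ones_like(c2), np.zeros_like(c2)
    return _assemble(
        [
            [one, zero, zero, zero],
            [zero, c2, -s2, zero],
            [zero, s2, c2, zero],
            [zero, zero, zero, one],
        ]
    )


def rotate_element(M: np.ndarray, phi: Any) -> np.ndarray:
    """Express element ``M`` with its axis rotated by ``phi`` degrees.

    Implements the conjugation R(phi) . M . R(-phi); m00 is untouched.
    """
    M = _as_finite_array(M, "M")
    if M.shape[-2:] != (4, 4):
        raise InvalidArgumentError("M must have trailing shape (4, 4)")
    R = stokes_rotation(phi)
    Rinv = stokes_rotation(-np.asarray(phi, dtype=float))
    return R @ M @ Rinv


def make_linear_retarder(delta: Any, axis: Any) -> np.ndarray:
    """Linear retarder with retardance ``delta`` (radians), fast axis ``axis`` (deg).

    Closed form of the rotation conjugation R(axis) . M0(delta) . R(-axis),
    where M0 is the retarder with horizontal fast axis.  The lower-right 3x3
    block is a proper rotation; delta = 0 gives the identity and delta = pi
    the half-wave plate diag(1, 1, -1, -1) at axis 0.
    """
    delta = _as_finite_array(delta, "delta")
    theta = np.radians(_as_finite_array(axis, "axis") % 180.0)
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    one = np.ones(np.broadcast_shapes(delta.shape, theta.shape))
    zero = np.zeros_like(one)
    return _assemble(
        [
            [one, zero, zero, zero],
            [zero, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [zero, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [zero, s * sd, -c * sd, cd * one],
        ]
    )


def make_linear_diattenuator(d: Any, axis: Any) -> np.ndarray:
    """Linear diattenuator of magnitude ``d`` with transmission axis ``axis`` (deg).

    Unit maximum transmittance (Tmax = 1, Tmin = (1-d)/(1+d)); the matrix is
    symmetric and its first row encodes the diattenuation vector of length d.
    """
    d = _as_finite_array(d, "d")
    if np.any(d < 0) or np.any(d > 1):
        raise InvalidArgumentError("diattenuation d must lie in [0, 1]")
    theta = np.radians(_as_finite_array(axis, "axis") % 180.0)
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    t1 = 1.0 / (1.0 + d)          # (Tmax + Tmin) / 2
    t2 = d / (1.0 + d)            # (Tmax - Tmin) / 2
    t3 = np.sqrt(np.clip(1.0 - d * d, 0.0, None)) / (1.0 + d)  # sqrt(Tmax Tmin)
    zero = np.zeros(np.broadcast_shapes(d.shape, theta.shape))
    return _assemble(
        [
            [t1 + zero, t2 * c, t2 * s, zero],
            [t2 * c, t1 * c * c + t3 * s * s, (t1 - t3) * c * s, zero],
            [t2 * s, (t1 - t3) * c * s, t1 * s * s + t3 * c * c, zero],
            [zero, zero, zero, t3 + zero],
        ]
    )


def make_depolarizer(a: Any, b: Any, c: Any) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, b, c); (1,1,1) is no depolarization."""
    a, b, c = (_as_finite_array(x, n) for x, n in ((a, "a"), (b, "b"), (c, "c")))
    for x in (a, b, c):
        if np.any(x < 0) or np.any(x > 1):
            raise InvalidArgumentError("depolarizer coefficients must lie in [0, 1]")
    one = np.ones(np.broadcast_shapes(a.shape, b.shape, c.shape))
    zero = np.zeros_like(one)
    return _assemble(
        [
            [one, zero, zero, zero],
            [zero, a + zero, zero, zero],
            [zero, zero, b + zero, zero],
            [zero, zero, zero, c + zero],
        ]
    )


def is_passive(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True where m00 >= 0 and every |mij| <= m00 (within ``tol``)."""
    M = np.asarray(M, dtype=float)
    m00 = M[..., 0, 0]
    return (m00 >= -tol) & np.all(np.abs(M) <= m00[..., None, None] + tol, axis=(-2, -1))


@dataclass
class MuellerImageStack:
    """Multi-wavelength grid of per-pixel Mueller matrices with a validity mask.

    Attributes
    ----------
    wavelengths : (n_wl,) float array, nm, strictly ascending, unique, > 0.
    pixel_pitch : float, micrometres per pixel.
    matrices : (n_wl, H, W, 4, 4) float array; invalid pixels hold NaN.
    validity : (n_wl, H, W) bool array; False marks pixels where no matrix
        was derived.  Invalid pixels are excluded from every statistic.
    physicality : optional (n_wl, H, W) bool array; True flags pixels whose
        (noisy) matrix violates passivity beyond the documented bound.  The
        matrices are flagged, never repaired.
    meta : free-form metadata (angle convention, corrected flag, seed, log).
    """

    wavelengths: np.ndarray
    pixel_pitch: float
    matrices: np.ndarray
    validity: np.ndarray
    physicality: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise InvalidArgumentError("wavelengths must be a non-empty 1-D list")
        if np.any(self.wavelengths <= 0):
            raise InvalidArgumentError("wavelengths must be positive")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly ascending and unique")
        n = self.wavelengths.size
        if self.matrices.ndim != 5 or self.matrices.shape[0] != n or self.matrices.shape[-2:] != (4, 4):
            raise InvalidArgumentError("matrices must have shape (n_wl, H, W, 4, 4)")
        if self.validity.shape != self.matrices.shape[:3]:
            raise InvalidArgumentError("validity must have shape (n_wl, H, W)")
        if self.pixel_pitch <= 0:
            raise InvalidArgumentError("pixel_pitch must be positive")
        self.meta.setdefault("angle_convention", ANGLE_CONVENTION)
        self.meta.setdefault("corrected", False)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.matrices.shape[1:3]

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths.size)

    def plane(self, index: int) -> np.ndarray:
        """(H, W, 4, 4) matrices at wavelength ``index``."""
        return self.matrices[index]

    def copy(self) -> "MuellerImageStack":
        return MuellerImageStack(
            wavelengths=self.wavelengths.copy(),
            pixel_pitch=self.pixel_pitch,
            matrices=self.matrices.copy(),
            validity=self.validity.copy(),
            physicality=None if self.physicality is None else self.physicality.copy(),
            meta=dict(self.meta),
        )
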