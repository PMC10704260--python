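"""Synthetic multi-wavelength Mueller stacks of birefringent fiber phantoms.

Scenes emulate the bench phantoms used to probe backscattering polarimetry:
plastic fibers (fiber-optic cable, synthetic hair, monofilament thread)
secured on a dark, depolarizing background and arranged as crossing,
inclined, cylinder-wrapped or in-plane-looping fibers, imaged at five
visible wavelengths.  Every pixel's Mueller matrix is composed as

    M = M_background_depolarizer . M_retarder(delta, axis) [. M_diattenuator]

with delta from the tilted-uniaxial forward model at the pixel's inclination
and wavelength, and the axis tied to the local fiber tangent: parallel for
positive birefringence, perpendicular for negative (the white-matter /
polystyrene case).  Full per-pixel ground truth is recorded before noise.

Default study conditions (documented in docs/methods.md): pixel pitch 10 um
(the emulated instrument's resolution), fiber-optic diameter 290 um and
synthetic-hair diameter 60 um, polystyrene-like indices nO = 1.59,
nE = 1.57 over a 10 um path, wavelengths {405, 442, 473, 532, 632} nm and
Mueller-element noise rising with wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._exceptions import ConfigError, InvalidArgumentError, OutOfBoundsError
from .forward import UniaxialMedium, tilted_retardance
from .mueller import (
    DEFAULT_WAVELENGTHS,
    MuellerImageStack,
    make_depolarizer,
    make_linear_diattenuator,
    make_linear_retarder,
)

#: Default pixel pitch, um per px.
DEFAULT_PITCH = 10.0
#: Measured phantom fiber diameters, um.
FIBER_OPTIC_DIAMETER = 290.0
SYNTHETIC_HAIR_DIAMETER = 60.0
MONOFILAMENT_DIAMETER = 63.0
#: Polystyrene-like uniaxial medium (negative birefringence) over a 10 um path.
DEFAULT_MEDIUM = UniaxialMedium(nO=1.59, nE=1.57, L=10.0)
#: Per-wavelength Mueller-element noise sigma, ascending with wavelength.
DEFAULT_NOISE_SIGMAS = (0.005, 0.006, 0.007, 0.009, 0.012)
#: Background depolarizer coefficients (dark foil: strong depolarization).
DEFAULT_BACKGROUND = (0.2, 0.2, 0.2)
#: Relative passivity violation beyond which a noisy pixel is flagged.
PHYSICALITY_BOUND = 0.05

PRESET_NAMES = (
    "crossing",
    "inclined_series",
    "cylinder_wrap",
    "inplane_loop",
    "rotation_series",
)


@dataclass
class FiberSpec:
    """One phantom fiber: geometry, medium and optical conventions.

    ``inclination_profile`` gives the out-of-plane inclination (degrees, in
    [0, 90]) versus arc length s (um): a constant, ("ramp", start, end),
    ("cylinder", radius_um) for arcsin(s / r) wrap geometry, or a callable.
    ``birefringence_sign`` fixes the retardance-axis convention: positive ->
    axis parallel to the tangent, negative -> perpendicular.
    """

    centerline: np.ndarray
    diameter: float
    medium: UniaxialMedium = DEFAULT_MEDIUM
    birefringence_sign: str = "negative"
    inclination_profile: float | tuple | Callable = 0.0
    z_order: int = 0
    diattenuation: tuple[float, bool] | None = None

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2 or self.centerline.shape[0] < 2:
            raise InvalidArgumentError("centerline must be an (n>=2, 2) polyline in (x, y) px")
        if self.diameter <= 0:
            raise InvalidArgumentError("diameter must be positive (um)")
        if self.birefringence_sign not in ("positive", "negative"):
            raise InvalidArgumentError("birefringence_sign must be 'positive' or 'negative'")

    def inclination_at(self, s_um: np.ndarray) -> np.ndarray:
        prof = self.inclination_profile
        if callable(prof):
            out = np.asarray(prof(s_um), dtype=float)
        elif isinstance(prof, (int, float)):
            out = np.full_like(np.asarray(s_um, float), float(prof))
        elif isinstance(prof, tuple) and prof[0] == "ramp":
            _, start, end = prof
            s = np.asarray(s_um, float)
            span = s.max() - s.min() if s.size else 1.0
            t = (s - s.min()) / (span if span > 0 else 1.0)
            out = start + t * (end - start)
        elif isinstance(prof, tuple) and prof[0] == "cylinder":
            radius = float(prof[1])
            ratio = np.clip(np.asarray(s_um, float) / radius, -1.0, 1.0)
            out = np.abs(np.degrees(np.arcsin(ratio)))
        else:
            raise InvalidArgumentError(f"unrecognized inclination profile {prof!r}")
        if np.any(out < -1e-9) or np.any(out > 90 + 1e-9):
            raise InvalidArgumentError("inclination profile leaves [0, 90] degrees")
        return np.clip(out, 0.0, 90.0)


@dataclass
class PhantomScene:
    """A full scene: fibers over a depolarizing background, plus imaging setup."""

    fibers: Sequence[FiberSpec]
    size: tuple[int, int] = (96, 96)
    pixel_pitch: float = DEFAULT_PITCH
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS
    background: tuple[float, float, float] = DEFAULT_BACKGROUND
    overlap_mode: str | None = None
    noise: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        zs = [f.z_order for f in self.fibers]
        if len(set(zs)) != len(zs):
            raise InvalidArgumentError("fiber z_order values must be unique within a scene")
        if self.overlap_mode not in (None, "top", "average"):
            raise InvalidArgumentError("overlap_mode must be 'top', 'average' or None")


@dataclass
class GroundTruth:
    """Per-pixel truth recorded before noise.

    ``fiber_id`` is -1 on background; ``axis_angle`` already folds in the
    birefringence-sign convention.  ``retardance`` has shape (n_wl, H, W) and
    agrees with the forward model at every fiber pixel; background pixels
    hold NaN in the continuous fields.
    """

    fiber_id: np.ndarray
    axis_angle: np.ndarray
    inclination: np.ndarray
    retardance: np.ndarray
    diattenuation: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_WAVELENGTHS, float))


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _polyline_fields(vertices: np.ndarray, H: int, W: int):
    """Per-pixel distance to the polyline, nearest-segment tangent angle and
    arc position, vectorized over pixels x segments."""
    cols, rows = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    P = np.stack([cols.ravel(), rows.ravel()], axis=1)          # (N, 2), (x, y)
    seg0 = vertices[:-1]
    dseg = np.diff(vertices, axis=0)
    seg_len = np.hypot(dseg[:, 0], dseg[:, 1])
    keep = seg_len > 0
    seg0, dseg, seg_len = seg0[keep], dseg[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]

    rel = P[:, None, :] - seg0[None, :, :]                       # (N, K, 2)
    t = np.clip(
        (rel * dseg[None, :, :]).sum(-1) / (seg_len**2)[None, :], 0.0, 1.0
    )
    proj = seg0[None, :, :] + t[..., None] * dseg[None, :, :]
    d2 = ((P[:, None, :] - proj) ** 2).sum(-1)
    nearest = np.argmin(d2, axis=1)
    ar = np.arange(P.shape[0])
    dist = np.sqrt(d2[ar, nearest]).reshape(H, W)
    tangent = (
        np.degrees(np.arctan2(dseg[nearest, 1], dseg[nearest, 0])) % 180.0
    ).reshape(H, W)
    arc = (cum[nearest] + t[ar, nearest] * seg_len[nearest]).reshape(H, W)
    return dist, tangent, arc


def render_fiber_geometry(
    spec: FiberSpec, size: tuple[int, int], pixel_pitch: float = DEFAULT_PITCH
):
    """Rasterize a fiber: footprint mask, tangent angle and inclination maps.

    The footprint is the centerline dilated to the fiber diameter; tangent
    angles come from the nearest centerline segment, inclination from the
    fiber's profile evaluated at the nearest arc-length position (um).
    Raises OutOfBoundsError when the dilated centerline leaves the frame.
    """
    H, W = size
    r_px = 0.5 * spec.diameter / pixel_pitch
    v = spec.centerline
    if (
        np.any(v[:, 0] < r_px)
        or np.any(v[:, 0] > W - 1 - r_px)
        or np.any(v[:, 1] < r_px)
        or np.any(v[:, 1] > H - 1 - r_px)
    ):
        raise OutOfBoundsError("centerline (dilated by diameter/2) exits the image")
    dist, tangent, arc = _polyline_fields(v, H, W)
    footprint = dist <= r_px
    inclination = spec.inclination_at(arc * pixel_pitch)
    return footprint, tangent, inclination


# --------------------------------------------------------------------------
# scene -> Mueller stack
# --------------------------------------------------------------------------

def _fiber_pixel_matrices(
    spec: FiberSpec,
    tangent: np.ndarray,
    inclination: np.ndarray,
    wavelengths: np.ndarray,
    background: np.ndarray,
):
    """Single-fiber Mueller matrices and truth fields on the footprint pixels."""
    axis = tangent if spec.birefringence_sign == "positive" else (tangent + 90.0) % 180.0
    n_wl = wavelengths.size
    mats = np.empty((n_wl,) + tangent.shape + (4, 4))
    delta = np.empty((n_wl,) + tangent.shape)
    for k, wl in enumerate(wavelengths):
        delta[k] = tilted_retardance(spec.medium, inclination, float(wl))
        M = make_linear_retarder(delta[k], axis)
        if spec.diattenuation is not None:
            d, follows = spec.diattenuation
            d_axis = tangent if follows else axis
            M = M @ make_linear_diattenuator(np.full_like(tangent, d), d_axis)
        mats[k] = background @ M
    d_truth = (
        np.full_like(tangent, spec.diattenuation[0]) if spec.diattenuation else np.zeros_like(tangent)
    )
    return mats, axis, delta, d_truth


def scene_to_mueller(scene: PhantomScene) -> tuple[MuellerImageStack, GroundTruth]:
    """Render a scene into a Mueller image stack with per-pixel ground truth.

    Overlap pixels take the top fiber's matrix (``overlap_mode='top'``) or the
    element-wise mean of the covering single-fiber matrices (``'average'``,
    the bulk-tissue emulation).  Truth at overlap pixels records the top
    fiber.  Noise, if configured, is applied after truth is recorded.
    """
    H, W = scene.size
    wavelengths = np.asarray(scene.wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise InvalidArgumentError("scene has no wavelengths")
    bg = make_depolarizer(*scene.background)
    M = np.broadcast_to(bg, (wavelengths.size, H, W, 4, 4)).copy()

    fiber_id = np.full((H, W), -1, dtype=int)
    axis_map = np.full((H, W), np.nan)
    incl_map = np.full((H, W), np.nan)
    ret_map = np.full((wavelengths.size, H, W), np.nan)
    diatt_map = np.full((H, W), np.nan)
    zbuf = np.full((H, W), -np.inf)
    cover = np.zeros((H, W), dtype=int)
    accum = np.zeros_like(M)

    for idx, spec in enumerate(scene.fibers):
        footprint, tangent, inclination = render_fiber_geometry(
            spec, scene.size, scene.pixel_pitch
        )
        mats, axis, delta, d_truth = _fiber_pixel_matrices(
            spec, tangent, inclination, wavelengths, bg
        )
        f = footprint
        cover += f
        accum[:, f] += mats[:, f]
        on_top = f & (spec.z_order > zbuf)
        zbuf[on_top] = spec.z_order
        # truth always records the topmost fiber
        fiber_id[on_top] = idx
        axis_map[on_top] = axis[on_top]
        incl_map[on_top] = inclination[on_top]
        ret_map[:, on_top] = delta[:, on_top]
        diatt_map[on_top] = d_truth[on_top]
        if scene.overlap_mode != "average":
            M[:, on_top] = mats[:, on_top]

    overlap = cover > 1
    if np.any(overlap) and scene.overlap_mode is None:
        raise ConfigError("fibers overlap but overlap_mode is unset")
    if scene.overlap_mode == "average":
        covered = cover > 0
        M[:, covered] = accum[:, covered] / cover[covered][None, :, None, None]

    validity = np.ones((wavelengths.size, H, W), dtype=bool)
    stack = MuellerImageStack(
        wavelengths=wavelengths,
        pixel_pitch=scene.pixel_pitch,
        matrices=M,
        validity=validity,
        meta={
            "seed": scene.seed,
            "overlap_mode": scene.overlap_mode,
            "background": tuple(scene.background),
        },
    )
    truth = GroundTruth(
        fiber_id=fiber_id,
        axis_angle=axis_map,
        inclination=incl_map,
        retardance=ret_map,
        diattenuation=diatt_map,
        wavelengths=wavelengths,
    )
    if scene.noise is not None and np.any(np.asarray(scene.noise) > 0):
        stack = add_noise(stack, scene.noise, scene.seed)
    return stack, truth


def add_noise(
    stack: MuellerImageStack, sigma_per_wavelength: Sequence[float], seed: int
) -> MuellerImageStack:
    """Add i.i.d. Gaussian noise to every Mueller element, scaled by the pixel m00.

    Deterministic under a fixed seed.  Noisy matrices violating passivity
    beyond PHYSICALITY_BOUND (relative) are flagged in ``physicality`` — never
    repaired.
    """
    sigmas = np.asarray(sigma_per_wavelength, dtype=float)
    if sigmas.shape != (stack.n_wavelengths,):
        raise InvalidArgumentError("sigma list length must match the number of wavelengths")
    if np.any(sigmas < 0):
        raise InvalidArgumentError("noise sigmas must be non-negative")
    out = stack.copy()
    if np.all(sigmas == 0):
        return out
    rng = np.random.default_rng(seed)
    m00 = out.matrices[..., 0, 0]
    noise = rng.standard_normal(out.matrices.shape)
    noise *= sigmas[:, None, None, None, None] * np.abs(m00)[..., None, None]
    out.matrices = out.matrices + noise
    new_m00 = out.matrices[..., 0, 0]
    bad = (new_m00 <= 0) | np.any(
        np.abs(out.matrices) > np.abs(new_m00)[..., None, None] * (1 + PHYSICALITY_BOUND),
        axis=(-2, -1),
    )
    out.physicality = bad
    out.meta["noise_sigmas"] = [float(s) for s in sigmas]
    out.meta["seed"] = int(seed)
    return out


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _line_through_center(angle_deg: float, size, margin: float):
    """A straight centerline through the image center at ``angle_deg``."""
    H, W = size
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    theta = np.radians(angle_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    half = min(W, H) / 2.0 - margin
    return np.array([[cx - half * ux, cy - half * uy], [cx + half * ux, cy + half * uy]])


def preset_phantom(name: str, **params):
    """Ready-made scenes mirroring the bench experiment series.

    crossing           two straight fibers at configurable angles, one on top;
    inclined_series    one scene per constant inclination angle;
    cylinder_wrap      a fiber draped over a cylinder (inclination ramp);
    inplane_loop       a looping in-plane fiber;
    rotation_series    the same fiber re-imaged at each stage angle.

    Series presets return a list of (parameter, scene) pairs; the others a
    single PhantomScene.
    """
    if name not in PRESET_NAMES:
        raise InvalidArgumentError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    size = tuple(params.pop("size", (96, 96)))
    pitch = float(params.pop("pixel_pitch", DEFAULT_PITCH))
    wavelengths = tuple(params.pop("wavelengths", DEFAULT_WAVELENGTHS))
    medium = params.pop("medium", DEFAULT_MEDIUM)
    sign = params.pop("birefringence_sign", "negative")
    diameter = float(params.pop("diameter", FIBER_OPTIC_DIAMETER))
    noise = params.pop("noise", None)
    seed = int(params.pop("seed", 0))
    margin = diameter / pitch / 2.0 + 1.0
    common = dict(size=size, pixel_pitch=pitch, wavelengths=wavelengths, noise=noise, seed=seed)

    if name == "crossing":
        a1 = float(params.pop("angle_bottom", 60.0))
        a2 = float(params.pop("angle_top", 90.0))
        mode = params.pop("overlap_mode", "top")
        _reject_extra(params)
        fibers = [
            FiberSpec(_line_through_center(a1, size, margin), diameter, medium, sign, 0.0, z_order=0),
            FiberSpec(_line_through_center(a2, size, margin), diameter, medium, sign, 0.0, z_order=1),
        ]
        return PhantomScene(fibers=fibers, overlap_mode=mode, **common)

    if name == "inclined_series":
        inclinations = params.pop("inclinations", (0.0, 10.0, 20.0, 30.0, 40.0, 50.0))
        _reject_extra(params)
        scenes = []
        for inc in inclinations:
            fiber = FiberSpec(
                _line_through_center(0.0, size, margin), diameter, medium, sign,
                float(inc), z_order=0,
            )
            scenes.append((float(inc), PhantomScene(fibers=[fiber], **common)))
        return scenes

    if name == "cylinder_wrap":
        radius_um = float(params.pop("radius_um", 14200.0))
        _reject_extra(params)
        fiber = FiberSpec(
            _line_through_center(0.0, size, margin), diameter, medium, sign,
            ("cylinder", radius_um), z_order=0,
        )
        return PhantomScene(fibers=[fiber], **common)

    if name == "inplane_loop":
        loop_diameter = float(params.pop("fiber_diameter", SYNTHETIC_HAIR_DIAMETER))
        loop_sign = params.pop("loop_sign", "positive")
        radius_px = float(params.pop("radius_px", min(size) / 2.0 - loop_diameter / pitch - 3.0))
        _reject_extra(params)
        H, W = size
        cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
        t = np.linspace(0.0, 2.0 * np.pi, 181)
        ring = np.stack([cx + radius_px * np.cos(t), cy + radius_px * np.sin(t)], axis=1)
        fiber = FiberSpec(ring, loop_diameter, medium, loop_sign, 0.0, z_order=0)
        return PhantomScene(fibers=[fiber], **common)

    # rotation_series
    stage_angles = params.pop("stage_angles", tuple(np.arange(0.0, 180.0, 12.0)))
    base_angle = float(params.pop("base_angle", 0.0))
    inclination = float(params.pop("inclination", 30.0))
    _reject_extra(params)
    scenes = []
    for phi in stage_angles:
        fiber = FiberSpec(
            _line_through_center((base_angle + phi) % 180.0, size, margin),
            diameter, medium, sign, inclination, z_order=0,
        )
        scenes.append((float(phi), PhantomScene(fibers=[fiber], **common)))
    return scenes


def _reject_extra(params: dict) -> None:
    if params:
        raise InvalidArgumentError(f"unrecognized preset parameters: {sorted(params)}")
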