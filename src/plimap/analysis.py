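"""ROI analyses of polarization-property maps.

Covers the post-decomposition toolbox: masked Gaussian smoothing (angle maps
handled in doubled-angle space to respect the 180-deg period), normalized
angular distributions ("radial plots"), profiles averaged transverse to a
path with ordinary least-squares trend fits, and the rotation-series
analysis (co-registration by known stage angle, axial sinusoid on retardance,
line on retardance angle).

Axial circular statistics: orientations are doubled before averaging, so the
mean of {30 deg, 150 deg} is 0 deg, not 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

from ._exceptions import (
    EmptyROIError,
    InsufficientDataError,
    InvalidArgumentError,
    OutOfBoundsError,
)
from .decomposition import PolarizationMaps
from .unwrap import axial_difference


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ROIMask:
    """Boolean region-of-interest mask with a free-text label."""

    flags: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.flags))


@dataclass
class AngularHistogram:
    """Normalized axial-angle distribution over [0, 180).

    Heights are scaled so the modal bin is exactly 1; ``dominant_angle`` is
    the center of the modal bin (ties resolved by the axial circular mean of
    the tied bin centers).
    """

    bin_edges: np.ndarray
    heights: np.ndarray
    dominant_angle: float
    n_pixels: int


@dataclass
class PathProfile:
    """Map values averaged transverse to a path, one value per arc station."""

    stations: np.ndarray          # arc-length positions, um, strictly increasing
    values: np.ndarray            # NaN where all transverse pixels were invalid
    transverse_width: float       # um


@dataclass
class LinearFit:
    slope: float                  # map units per um
    intercept: float
    r_squared: float
    slope_stderr: float
    n: int


@dataclass
class RotationSeries:
    """Per-ROI mean retardance and circular-mean retardance angle vs stage angle."""

    orientations: np.ndarray      # unique stage angles, degrees
    mean_retardance: Mapping[str, np.ndarray]
    mean_angle: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        if np.unique(self.orientations).size != self.orientations.size:
            raise InvalidArgumentError("orientations must be unique")


@dataclass
class RotationFit:
    """Axial sinusoid fit a*cos(2(phi - phi0)) + c on retardance, line on angle."""

    amplitude: float | None
    phase_deg: float | None
    offset: float | None
    angle_slope: float
    angle_intercept: float
    angle_r_squared: float


# --------------------------------------------------------------------------
# axial circular statistics
# --------------------------------------------------------------------------

def axial_mean(angles, weights=None) -> float:
    """Circular mean of axial data (180-deg period), in [0, 180)."""
    a = np.radians(2.0 * np.asarray(angles, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(a) & np.isfinite(w)
    if not np.any(ok):
        return float("nan")
    c = float(np.sum(w[ok] * np.cos(a[ok])))
    s = float(np.sum(w[ok] * np.sin(a[ok])))
    out = float(np.degrees(0.5 * np.arctan2(s, c)) % 180.0)
    return 0.0 if out >= 180.0 else out  # -0.0 % 180 folds to 180.0


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def _masked_gaussian(values: np.ndarray, weight: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized masked Gaussian convolution; 'reflect' keeps the operator
    symmetric (hence mean-preserving on a fully valid frame)."""
    num = ndimage.gaussian_filter(np.where(weight > 0, values, 0.0) * weight, sigma, mode="reflect")
    den = ndimage.gaussian_filter(weight.astype(float), sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 1e-12] = np.nan
    return out


def smooth_maps(maps: PolarizationMaps, sigma: float = 10.0) -> PolarizationMaps:
    """Gaussian-smooth all maps; angles are smoothed in (cos 2t, sin 2t) space.

    Invalid pixels are excluded through normalized masked convolution and stay
    invalid; sigma = 0 returns an unchanged copy.
    """
    if sigma < 0:
        raise InvalidArgumentError("sigma must be non-negative")
    out = maps.copy()
    if sigma == 0:
        return out
    valid = maps.validity & np.isfinite(np.asarray(maps.retardance, float))
    w = valid.astype(float)
    for name in ("retardance", "diattenuation", "depolarization"):
        sm = _masked_gaussian(np.asarray(getattr(maps, name), float), w, sigma)
        setattr(out, name, np.where(valid, sm, np.nan))
    for name in ("retardance_angle", "diattenuation_angle"):
        ang = np.asarray(getattr(maps, name), float)
        defined = valid & np.isfinite(ang)
        wa = defined.astype(float)
        t = np.radians(2.0 * np.where(defined, ang, 0.0))
        cbar = _masked_gaussian(np.cos(t), wa, sigma)
        sbar = _masked_gaussian(np.sin(t), wa, sigma)
        sm = np.degrees(0.5 * np.arctan2(sbar, cbar)) % 180.0
        setattr(out, name, np.where(defined, sm, np.nan))
    out.meta["smoothing_sigma_px"] = sigma
    return out


# --------------------------------------------------------------------------
# angular distribution (radial plots)
# --------------------------------------------------------------------------

def angular_distribution(
    angle_map,
    mask: ROIMask,
    weights_map=None,
    n_bins: int = 36,
) -> AngularHistogram:
    """Histogram of axial angles inside an ROI, normalized to unit maximum.

    ``weights_map`` optionally weights each pixel (e.g. by retardance, the
    "scaled by retardance" radial plots); the dominant angle is the modal bin
    center, ties resolved by the axial circular mean of the tied centers.
    """
    if n_bins < 4:
        raise InvalidArgumentError("n_bins must be at least 4")
    angle = np.asarray(angle_map, dtype=float)
    if mask.flags.shape != angle.shape:
        raise InvalidArgumentError("mask shape does not match angle map")
    sel = mask.flags & np.isfinite(angle)
    if weights_map is not None:
        wmap = np.asarray(weights_map, dtype=float)
        sel &= np.isfinite(wmap)
    if not np.any(sel):
        raise EmptyROIError(f"ROI {mask.label!r} selects no valid angle pixels")
    vals = angle[sel] % 180.0
    vals[vals >= 180.0] = 0.0
    w = None if weights_map is None else np.asarray(weights_map, float)[sel]
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    heights, _ = np.histogram(vals, bins=edges, weights=w)
    heights = heights.astype(float)
    hmax = heights.max()
    if hmax <= 0:
        raise EmptyROIError("all histogram weights are zero")
    heights /= hmax
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = np.flatnonzero(np.isclose(heights, 1.0, atol=1e-12))
    dominant = float(centers[modal[0]]) if modal.size == 1 else axial_mean(centers[modal])
    return AngularHistogram(
        bin_edges=edges,
        heights=heights,
        dominant_angle=dominant,
        n_pixels=int(np.count_nonzero(sel)),
    )


# --------------------------------------------------------------------------
# path profiles and linear fits
# --------------------------------------------------------------------------

def _resample_polyline(path: np.ndarray, step: float = 1.0):
    """Stations every ``step`` px along a polyline; returns points, tangents, arc."""
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        seg = seg[seg_len > 0]
        path = np.concatenate([path[:1], path[1:][seg_len > 0]])
        seg_len = seg_len[seg_len > 0]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, total + 0.5 * step, step)
    s[-1] = min(s[-1], total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    t = (s - cum[idx]) / seg_len[idx]
    pts = path[idx] + seg[idx] * t[:, None]
    tans = seg[idx] / seg_len[idx, None]
    return pts, tans, s


def profile_along_path(
    map2d,
    path,
    transverse_width: float,
    pixel_pitch: float = 1.0,
    validity=None,
) -> PathProfile:
    """Mean map value per 1-px arc station, averaged over +/- width/2 transverse.

    ``path`` is an ordered polyline in (x, y) pixel coordinates with at least
    two vertices and must stay inside the image; ``transverse_width`` and the
    returned stations are in micrometres (``pixel_pitch`` um per px).
    Stations whose transverse pixels are all invalid hold NaN.
    """
    arr = np.asarray(map2d, dtype=float)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise InvalidArgumentError("path must be an (n>=2, 2) polyline in (x, y)")
    H, W = arr.shape
    if np.any(path[:, 0] < 0) or np.any(path[:, 0] > W - 1) or np.any(
        path[:, 1] < 0
    ) or np.any(path[:, 1] > H - 1):
        raise OutOfBoundsError("path exits the image frame")
    valid = np.isfinite(arr) if validity is None else (np.asarray(validity, bool) & np.isfinite(arr))

    pts, tans, s_px = _resample_polyline(path)
    normals = np.stack([-tans[:, 1], tans[:, 0]], axis=1)
    half_px = 0.5 * transverse_width / pixel_pitch
    offsets = np.arange(-np.floor(half_px), np.floor(half_px) + 0.5, 1.0)
    if offsets.size == 0:
        offsets = np.array([0.0])
    sample = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = sample[..., 0], sample[..., 1]
    inside = (xs >= 0) & (xs <= W - 1) & (ys >= 0) & (ys <= H - 1)
    coords = np.stack([ys.ravel(), xs.ravel()])
    v = ndimage.map_coordinates(np.where(valid, arr, 0.0), coords, order=1, mode="nearest")
    w = ndimage.map_coordinates(valid.astype(float), coords, order=1, mode="nearest")
    v = v.reshape(xs.shape)
    w = (w.reshape(xs.shape) * inside)
    # demand essentially-valid interpolation support to avoid edge bleed
    w = np.where(w > 0.999, w, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (v * w).sum(axis=1) / wsum
    means[wsum <= 0] = np.nan
    return PathProfile(
        stations=s_px * pixel_pitch,
        values=means,
        transverse_width=float(transverse_width),
    )


def linear_fit_profile(profile: PathProfile) -> LinearFit:
    """Ordinary least-squares line through the valid stations of a profile."""
    x = np.asarray(profile.stations, dtype=float)
    y = np.asarray(profile.values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if np.count_nonzero(ok) < 2:
        raise InsufficientDataError("need at least 2 valid stations for a line fit")
    if np.count_nonzero(ok) == 2 or np.ptp(y[ok]) == 0:
        # degenerate-variance cases linregress handles awkwardly
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        resid = y[ok] - (slope * x[ok] + intercept)
        ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return LinearFit(float(slope), float(intercept), r2, float("nan"), int(ok.sum()))
    fit = linregress(x[ok], y[ok])
    return LinearFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_stderr=float(fit.stderr),
        n=int(np.count_nonzero(ok)),
    )


# --------------------------------------------------------------------------
# rotation series
# --------------------------------------------------------------------------

def _rotate_plane(arr: np.ndarray, phi_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate image content by ``-phi_deg`` about ``center`` = (x, y) px,
    counterclockwise positive in the package's axis convention (y up),
    bilinear interpolation, NaN outside the source frame."""
    phi = np.radians(phi_deg)
    # array rows run opposite to the convention's y axis: flip the angle sign
    c, s = np.cos(-phi), np.sin(-phi)
    cx, cy = center
    # inverse map: output (row, col) -> input coordinates
    mat = np.array([[c, -s], [s, c]])  # acts on (row, col) offsets
    offset = np.array([cy, cx]) - mat @ np.array([cy, cx])
    filled = np.where(np.isfinite(arr), arr, 0.0)
    ok = np.isfinite(arr).astype(float)
    out = ndimage.affine_transform(filled, mat, offset=offset, order=1, mode="constant", cval=0.0)
    w = ndimage.affine_transform(ok, mat, offset=offset, order=1, mode="constant", cval=0.0)
    out = np.where(w > 0.999, out / np.where(w > 0, w, 1.0), np.nan)
    return out


def register_rotation(
    maps: PolarizationMaps, stage_angle: float, center: tuple[float, float] | None = None
) -> PolarizationMaps:
    """Co-register a stage-rotated acquisition back to the unrotated frame.

    Scalar maps are rigidly rotated by the known stage angle about ``center``
    (image center by default) with bilinear interpolation; angle maps are
    rotated spatially in doubled-angle space and their values shifted by
    -stage_angle (mod 180).  Out-of-frame regions become invalid.
    """
    if center is None:
        H, W = maps.shape
        center = ((W - 1) / 2.0, (H - 1) / 2.0)
    out = maps.copy()
    if stage_angle % 360.0 == 0.0:
        return out
    for name in ("retardance", "diattenuation", "depolarization"):
        setattr(out, name, _rotate_plane(np.asarray(getattr(maps, name), float), stage_angle, center))
    for name in ("retardance_angle", "diattenuation_angle"):
        ang = np.asarray(getattr(maps, name), float)
        t = np.radians(2.0 * ang)
        cbar = _rotate_plane(np.cos(t), stage_angle, center)
        sbar = _rotate_plane(np.sin(t), stage_angle, center)
        rot = np.degrees(0.5 * np.arctan2(sbar, cbar)) % 180.0
        setattr(out, name, (rot - stage_angle) % 180.0)
        undef = ~np.isfinite(cbar)
        getattr(out, name)[undef] = np.nan
    vw = _rotate_plane(maps.validity.astype(float), stage_angle, center)
    out.validity = np.isfinite(vw) & (vw > 0.5)
    out.meta["registered_stage_angle_deg"] = float(stage_angle)
    return out


def rotation_series_from_maps(
    maps_by_orientation: Sequence[tuple[float, PolarizationMaps]],
    rois: Mapping[str, ROIMask],
) -> RotationSeries:
    """Collect per-ROI mean retardance and circular-mean angle per stage angle."""
    orientations = np.array([phi for phi, _ in maps_by_orientation], dtype=float)
    ret: dict[str, list[float]] = {k: [] for k in rois}
    ang: dict[str, list[float]] = {k: [] for k in rois}
    for _, maps in maps_by_orientation:
        R = np.asarray(maps.retardance, float)
        A = np.asarray(maps.retardance_angle, float)
        for label, roi in rois.items():
            sel = roi.flags & maps.validity & np.isfinite(R)
            ret[label].append(float(np.mean(R[sel])) if np.any(sel) else float("nan"))
            sel_a = sel & np.isfinite(A)
            ang[label].append(axial_mean(A[sel_a]) if np.any(sel_a) else float("nan"))
    return RotationSeries(
        orientations=orientations,
        mean_retardance={k: np.array(v) for k, v in ret.items()},
        mean_angle={k: np.array(v) for k, v in ang.items()},
    )


def _unwrap_axial_sequence(angles: np.ndarray) -> np.ndarray:
    """Lift an axial angle sequence to a continuous line (steps in (-90, 90])."""
    out = np.array(angles, dtype=float)
    for i in range(1, out.size):
        out[i] = out[i - 1] + float(axial_difference(angles[i], out[i - 1]))
    return out


def rotation_series_analysis(series: RotationSeries) -> dict[str, RotationFit]:
    """Fit each ROI's retardance to an axial sinusoid and its angle to a line.

    Retardance means are fit to a*cos(2(phi - phi0)) + c (180-deg periodic)
    via a linear harmonic basis; this needs >= 4 orientations and is skipped
    (None fields) below that.  Angle means, lifted from their 180-deg wrap,
    are fit to a line whose slope is expected near 1; >= 2 orientations.
    """
    phi = series.orientations
    if phi.size < 2:
        raise InsufficientDataError("need at least 2 orientations")
    out: dict[str, RotationFit] = {}
    for label in series.mean_retardance:
        r = np.asarray(series.mean_retardance[label], float)
        a = np.asarray(series.mean_angle[label], float)
        ok_r = np.isfinite(r)
        amplitude = phase = offset = None
        if np.count_nonzero(ok_r) >= 4:
            x = np.radians(2.0 * phi[ok_r])
            basis = np.column_stack([np.cos(x), np.sin(x), np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(basis, r[ok_r], rcond=None)
            amplitude = float(np.hypot(coef[0], coef[1]))
            phase = float(np.degrees(0.5 * np.arctan2(coef[1], coef[0])) % 180.0)
            offset = float(coef[2])
        ok_a = np.isfinite(a)
        if np.count_nonzero(ok_a) < 2:
            raise InsufficientDataError(f"ROI {label!r}: need >= 2 valid angle means")
        lifted = _unwrap_axial_sequence(a[ok_a])
        x = phi[ok_a]
        if np.count_nonzero(ok_a) == 2:
            slope, intercept = np.polyfit(x, lifted, 1)
            r2 = 1.0
        else:
            fit = linregress(x, lifted)
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        out[label] = RotationFit(
            amplitude=amplitude,
            phase_deg=phase,
            offset=offset,
            angle_slope=float(slope),
            angle_intercept=float(intercept),
            angle_r_squared=float(r2),
        )
    return out
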