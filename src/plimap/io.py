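"""Container I/O and the pipeline orchestrator.

Stack container layout: one multi-page 32-bit float TIFF holding, per
wavelength, 16 planes ordered m00, m01, ..., m33 (row-major); invalid pixels
are NaN in all 16 planes.  Metadata (wavelengths, pixel pitch, angle
convention, corrected flag, seed, creation log) travels as JSON in the TIFF
image description.  Round trips are lossless at 32-bit precision.

Maps export: one 32-bit float TIFF per quantity per wavelength, a
tab-separated summary of per-region statistics, and a JSON sidecar naming
units, conventions and the NaN sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from ._exceptions import (
    ConfigError,
    ContainerError,
    EmptyROIError,
    InvalidArgumentError,
    MetadataError,
)
from .analysis import ROIMask, angular_distribution, smooth_maps
from .decomposition import PolarizationMaps, decompose_stack
from .mueller import ANGLE_CONVENTION, MuellerImageStack
from .phantoms import add_noise, preset_phantom, render_fiber_geometry, scene_to_mueller
from .unwrap import (
    BRANCH_AROUND_PI,
    BRANCH_AROUND_ZERO,
    WrapMask,
    detect_wrapped_regions,
    select_branch,
    unwrap_maps,
)

_MAP_QUANTITIES = (
    "retardance",
    "retardance_angle",
    "diattenuation",
    "diattenuation_angle",
    "depolarization",
)

_UNITS = {
    "retardance": "radians",
    "retardance_angle": "degrees [0,180)",
    "diattenuation": "dimensionless [0,1]",
    "diattenuation_angle": "degrees [0,180)",
    "depolarization": "dimensionless [0,1]",
}


# --------------------------------------------------------------------------
# stack container
# --------------------------------------------------------------------------

def write_stack(stack: MuellerImageStack, destination) -> Path:
    """Write a stack as a multi-page float32 TIFF with JSON metadata."""
    destination = Path(destination)
    n, (H, W) = stack.n_wavelengths, stack.shape
    planes = np.empty((n * 16, H, W), dtype=np.float32)
    for k in range(n):
        M = stack.matrices[k].copy()
        M[~stack.validity[k]] = np.nan
        planes[k * 16 : (k + 1) * 16] = (
            M.reshape(H, W, 16).transpose(2, 0, 1).astype(np.float32)
        )
    meta = {
        "format": "plimap-mueller-stack-v1",
        "wavelengths_nm": [float(w) for w in stack.wavelengths],
        "pixel_pitch_um": float(stack.pixel_pitch),
        "angle_convention": stack.meta.get("angle_convention", ANGLE_CONVENTION),
        "corrected": bool(stack.meta.get("corrected", False)),
        "seed": stack.meta.get("seed"),
        "log": stack.meta.get("log", []),
    }
    tifffile.imwrite(
        destination,
        planes,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )
    return destination


def read_stack(source) -> MuellerImageStack:
    """Read a stack container; validates plane layout and metadata."""
    source = Path(source)
    with tifffile.TiffFile(source) as tif:
        planes = tif.asarray()
        desc = tif.pages[0].description
    if planes.ndim == 2:
        planes = planes[None]
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError as exc:
        raise MetadataError(f"container metadata is not valid JSON: {exc}") from exc
    if "wavelengths_nm" not in meta or not meta["wavelengths_nm"]:
        raise MetadataError("container metadata is missing 'wavelengths_nm'")
    if "pixel_pitch_um" not in meta:
        raise MetadataError("container metadata is missing 'pixel_pitch_um'")
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    if planes.shape[0] % 16 != 0 or planes.shape[0] != 16 * wavelengths.size:
        raise ContainerError(
            f"expected {16 * wavelengths.size} planes (16 per wavelength), "
            f"found {planes.shape[0]}"
        )
    n = wavelengths.size
    H, W = planes.shape[1:]
    matrices = np.empty((n, H, W, 4, 4))
    for k in range(n):
        matrices[k] = (
            planes[k * 16 : (k + 1) * 16].astype(float).transpose(1, 2, 0).reshape(H, W, 4, 4)
        )
    validity = np.all(np.isfinite(matrices), axis=(-2, -1))
    return MuellerImageStack(
        wavelengths=wavelengths,
        pixel_pitch=float(meta["pixel_pitch_um"]),
        matrices=matrices,
        validity=validity,
        meta={
            "angle_convention": meta.get("angle_convention", ANGLE_CONVENTION),
            "corrected": bool(meta.get("corrected", False)),
            "seed": meta.get("seed"),
            "log": meta.get("log", []),
        },
    )


# --------------------------------------------------------------------------
# maps export / import
# --------------------------------------------------------------------------

def _map_filename(quantity: str, wavelength: float) -> str:
    return f"{quantity}_{wavelength:g}nm.tif"


def export_maps(
    maps_list,
    destination,
    regions: Mapping[str, ROIMask] | None = None,
    n_bins: int = 36,
) -> Path:
    """Export maps as per-quantity TIFFs plus a summary table and sidecar.

    ``maps_list`` is one PolarizationMaps or a list of them (one per
    wavelength).  NaN is the undefined/invalid sentinel, preserved verbatim
    and documented in the sidecar.
    """
    if isinstance(maps_list, PolarizationMaps):
        maps_list = [maps_list]
    if not maps_list:
        raise InvalidArgumentError("no maps to export")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    for maps in maps_list:
        for q in _MAP_QUANTITIES:
            arr = np.asarray(getattr(maps, q), dtype=np.float32)
            tifffile.imwrite(destination / _map_filename(q, maps.wavelength), arr)
    summary = summarize_maps(maps_list, regions=regions, n_bins=n_bins)
    summary.to_csv(destination / "summary.tsv", sep="\t", index=False, float_format="%.9g")
    sidecar = {
        "format": "plimap-maps-v1",
        "quantities": {q: _UNITS[q] for q in _MAP_QUANTITIES},
        "wavelengths_nm": [m.wavelength for m in maps_list],
        "angle_convention": maps_list[0].meta.get("angle_convention", ANGLE_CONVENTION),
        "corrected": [bool(m.corrected) for m in maps_list],
        "invalid_sentinel": "NaN (invalid pixel or undefined angle)",
        "pixel_pitch_um": maps_list[0].meta.get("pixel_pitch"),
    }
    (destination / "metadata.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return destination


def read_maps(source) -> list[PolarizationMaps]:
    """Re-import maps written by :func:`export_maps`."""
    source = Path(source)
    sidecar_path = source / "metadata.json"
    if not sidecar_path.exists():
        raise MetadataError(f"no metadata.json in {source}")
    sidecar = json.loads(sidecar_path.read_text())
    out = []
    for i, wl in enumerate(sidecar["wavelengths_nm"]):
        data = {
            q: tifffile.imread(source / _map_filename(q, wl)).astype(float)
            for q in _MAP_QUANTITIES
        }
        validity = np.isfinite(data["retardance"])
        out.append(
            PolarizationMaps(
                wavelength=float(wl),
                validity=validity,
                corrected=bool(sidecar.get("corrected", [False] * (i + 1))[i]),
                meta={
                    "angle_convention": sidecar.get("angle_convention", ANGLE_CONVENTION),
                    "pixel_pitch": sidecar.get("pixel_pitch_um"),
                },
                **data,
            )
        )
    return out


def summarize_maps(
    maps_list,
    regions: Mapping[str, ROIMask] | None = None,
    n_bins: int = 36,
) -> pd.DataFrame:
    """Per-region, per-wavelength statistics table.

    Columns: wavelength_nm, region, n_pixels, mean_retardance_rad,
    dominant_retardance_angle_deg, mean_diattenuation,
    dominant_diattenuation_angle_deg, mean_depolarization.
    """
    rows = []
    for maps in maps_list:
        valid = maps.validity & np.isfinite(np.asarray(maps.retardance, float))
        if regions is None:
            use_regions = {"all": ROIMask(valid, "all valid pixels")}
        else:
            use_regions = regions
        for label, roi in use_regions.items():
            sel = roi.flags & valid
            row = {
                "wavelength_nm": maps.wavelength,
                "region": label,
                "n_pixels": int(np.count_nonzero(sel)),
            }
            if np.any(sel):
                row["mean_retardance_rad"] = float(
                    np.mean(np.asarray(maps.retardance, float)[sel])
                )
                row["mean_diattenuation"] = float(
                    np.mean(np.asarray(maps.diattenuation, float)[sel])
                )
                row["mean_depolarization"] = float(
                    np.mean(np.asarray(maps.depolarization, float)[sel])
                )
                for q, col in (
                    ("retardance_angle", "dominant_retardance_angle_deg"),
                    ("diattenuation_angle", "dominant_diattenuation_angle_deg"),
                ):
                    try:
                        hist = angular_distribution(
                            np.asarray(getattr(maps, q), float), ROIMask(sel, label), n_bins=n_bins
                        )
                        row[col] = hist.dominant_angle
                    except EmptyROIError:
                        row[col] = float("nan")
            else:
                for col in (
                    "mean_retardance_rad",
                    "mean_diattenuation",
                    "mean_depolarization",
                    "dominant_retardance_angle_deg",
                    "dominant_diattenuation_angle_deg",
                ):
                    row[col] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mask image I/O (single-channel)
# --------------------------------------------------------------------------

def write_mask(mask: np.ndarray, destination) -> Path:
    """Write a boolean mask as a single-channel 8-bit image (0/255)."""
    destination = Path(destination)
    tifffile.imwrite(destination, (np.asarray(mask, bool) * np.uint8(255)))
    return destination


def read_mask(source) -> np.ndarray:
    """Read a single-channel mask image: nonzero means flagged."""
    arr = tifffile.imread(Path(source))
    if arr.ndim != 2:
        raise InvalidArgumentError("mask image must be single-channel")
    return arr > 0


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _require(config: Mapping, key: str, path: str):
    if key not in config:
        raise ConfigError(f"missing config field: {path}")
    return config[key]


def scene_regions(scene) -> dict[str, np.ndarray]:
    """Per-fiber, overlap and background masks for a rendered scene."""
    footprints = [
        render_fiber_geometry(f, scene.size, scene.pixel_pitch)[0] for f in scene.fibers
    ]
    cover = np.sum(footprints, axis=0) if footprints else np.zeros(scene.size, dtype=int)
    regions: dict[str, np.ndarray] = {}
    for i, f in enumerate(footprints):
        regions[f"fiber{i}"] = f
        regions[f"fiber{i}_only"] = f & (cover == 1)
    if len(footprints) > 1:
        regions["overlap"] = cover > 1
    regions["background"] = cover == 0
    return regions


def run_pipeline(config, base_dir=None) -> dict:
    """Run simulate/ingest -> decompose -> smooth -> unwrap -> analyze -> export.

    ``config`` is a mapping or a path to a YAML file.  Outputs are
    deterministic under a fixed seed; every stage appends its parameters to
    the run log.  Returns a dict with the output directory, the summary frame
    and the in-memory products.
    """
    if not isinstance(config, Mapping):
        cfg_path = Path(config)
        config = yaml.safe_load(cfg_path.read_text())
        base_dir = base_dir or cfg_path.parent
    base_dir = Path(base_dir or ".")
    if not isinstance(config, Mapping):
        raise ConfigError("config root must be a mapping")

    seed = int(config.get("seed", 0))
    out_dir = base_dir / str(_require(config, "output", "output"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = [{"stage": "config", "seed": seed}]

    # --- stage 1: obtain a stack ---------------------------------------
    truth = None
    scene = None
    if "scene" in config:
        scene_cfg = config["scene"]
        if "wavelengths" in scene_cfg and not scene_cfg["wavelengths"]:
            raise ConfigError("missing config field: scene.wavelengths")
        preset = _require(scene_cfg, "preset", "scene.preset")
        params = dict(scene_cfg.get("params", {}))
        if "wavelengths" in scene_cfg:
            params["wavelengths"] = scene_cfg["wavelengths"]
        params.setdefault("seed", seed)
        built = preset_phantom(preset, **params)
        if isinstance(built, list):
            raise ConfigError(
                "scene.preset: series presets are not supported by run_pipeline; "
                "use a single-scene preset"
            )
        scene = built
        stack, truth = scene_to_mueller(scene)
        log.append({"stage": "simulate", "preset": preset, "params": {
            k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in params.items()
        }})
    elif "input" in config:
        stack = read_stack(base_dir / str(config["input"]))
        log.append({"stage": "ingest", "input": str(config["input"])})
    else:
        raise ConfigError("missing config field: scene (or input)")

    if "noise" in config and config["noise"]:
        sigmas = _require(config["noise"], "sigmas", "noise.sigmas")
        stack = add_noise(stack, sigmas, seed)
        log.append({"stage": "noise", "sigmas": [float(s) for s in sigmas]})

    write_stack(stack, out_dir / "stack.tif")

    # --- stage 2: decompose --------------------------------------------
    maps_list = decompose_stack(stack)
    log.append({"stage": "decompose",
                "failures": stack.meta.get("decomposition_failures")})

    # --- stage 3: smooth -------------------------------------------------
    sigma = float(config.get("smoothing", {}).get("sigma", 0.0) or 0.0)
    if sigma > 0:
        maps_list = [smooth_maps(m, sigma) for m in maps_list]
    log.append({"stage": "smooth", "sigma_px": sigma})

    # --- stage 4: unwrap -------------------------------------------------
    unwrap_cfg = config.get("unwrap", {}) or {}
    policy = str(unwrap_cfg.get("policy", "off"))
    if policy not in ("off", "auto", BRANCH_AROUND_PI, BRANCH_AROUND_ZERO):
        raise ConfigError("invalid config field: unwrap.policy")
    if policy != "off":
        axis = int(unwrap_cfg.get("axis", 1))
        masks = [
            detect_wrapped_regions(np.asarray(m.retardance_angle, float), axis=axis)
            for m in maps_list
        ]
        if policy == "auto":
            tables = {}
            for branch in (BRANCH_AROUND_PI, BRANCH_AROUND_ZERO):
                entries = []
                for m, wmask in zip(maps_list, masks):
                    trial = unwrap_maps(
                        m, WrapMask(wmask.flags, branch, "candidate")
                    )
                    r = np.asarray(trial.retardance, float)
                    sel = trial.validity & np.isfinite(r)
                    entries.append(
                        (m.wavelength, float(np.mean(np.abs(r[sel]))) if np.any(sel) else float("nan"))
                    )
                tables[branch] = entries
            decision = select_branch(tables)
            branch = decision.branch
            log.append({"stage": "unwrap-branch", "branch": branch,
                        "ambiguous": decision.ambiguous,
                        "violations": decision.violations})
        else:
            branch = policy
            log.append({"stage": "unwrap-branch", "branch": branch, "ambiguous": False})
        if branch is not None:
            maps_list = [
                unwrap_maps(m, WrapMask(w.flags, branch, "pipeline"))
                for m, w in zip(maps_list, masks)
            ]
            log.append({"stage": "unwrap",
                        "flagged": [int(np.count_nonzero(w.flags)) for w in masks]})

    # --- stage 5: analyze + export ---------------------------------------
    regions = None
    if scene is not None:
        regions = {
            label: ROIMask(mask, label) for label, mask in scene_regions(scene).items()
        }
    n_bins = int(config.get("histogram_bins", 36))
    export_maps(maps_list, out_dir, regions=regions, n_bins=n_bins)
    summary = pd.read_csv(out_dir / "summary.tsv", sep="\t")
    log.append({"stage": "analyze", "regions": sorted(regions) if regions else ["all"]})

    (out_dir / "run_log.json").write_text(
        json.dumps(log, sort_keys=True, indent=1, default=repr)
    )
    return {
        "output": out_dir,
        "summary": summary,
        "maps": maps_list,
        "stack": stack,
        "truth": truth,
    }
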