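"""Tilted uniaxial-crystal retardance model.

A birefringent fiber is modeled as a uniaxial medium with ordinary index nO
and extraordinary index nE whose optic axis lies in the imaging plane when
untilted.  Tilting the axis out of plane by an inclination theta_i changes
the effective extraordinary index seen by the probing light,

    n_eff(theta_i) = nO nE / sqrt(nE^2 sin^2 theta_i + nO^2 cos^2 theta_i),

so the measured retardance over a path length L at vacuum wavelength lambda is

    delta(theta_i, lambda) = (2 pi L / lambda) |n_eff(theta_i) - nO|.

Only the magnitude is modeled (backscattering polarimeters are insensitive to
the retardance sign), so negative birefringence (nE < nO, the white-matter
and polystyrene-fiber case) enters through the axis convention downstream,
not through delta.  L is treated as independent of inclination and
wavelength; an optional per-wavelength multiplicative table on |n_eff - nO|
can represent polymer dispersion (order 10% across the visible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import InvalidArgumentError


@dataclass(frozen=True)
class UniaxialMedium:
    """Uniaxial medium: ordinary/extraordinary indices and path length (um).

    ``delta_n_scale`` optionally maps wavelength (nm) to a multiplicative
    dispersion factor on the birefringence; wavelengths absent from the table
    default to 1.
    """

    nO: float
    nE: float
    L: float
    delta_n_scale: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.nO > 0 and self.nE > 0 and self.L > 0):
            raise InvalidArgumentError("nO, nE and L must all be positive")

    @property
    def birefringence(self) -> float:
        """Delta n = nE - nO; negative for white matter and polystyrene fibers."""
        return self.nE - self.nO

    def dispersion_factor(self, wavelength: float) -> float:
        return float(self.delta_n_scale.get(float(wavelength), 1.0))


def _check_theta(theta_i: Any) -> np.ndarray:
    theta = np.asarray(theta_i, dtype=float)
    if not np.all(np.isfinite(theta)) or np.any(theta < 0) or np.any(theta > 90):
        raise InvalidArgumentError("inclination theta_i must lie in [0, 90] degrees")
    return theta


def effective_index(medium: UniaxialMedium, theta_i: Any) -> np.ndarray | float:
    """Effective extraordinary index at inclination ``theta_i`` (degrees).

    Equals nE at 0 deg (optic axis in plane) and nO at 90 deg (optic axis
    along the propagation direction); broadcasts over array input.
    """
    theta = np.radians(_check_theta(theta_i))
    nO, nE = medium.nO, medium.nE
    out = nO * nE / np.sqrt(nE**2 * np.sin(theta) ** 2 + nO**2 * np.cos(theta) ** 2)
    return out if out.ndim else float(out)


def tilted_retardance(
    medium: UniaxialMedium, theta_i: Any, wavelength: Any
) -> np.ndarray | float:
    """Retardance magnitude (radians) at inclination ``theta_i`` and ``wavelength`` (nm).

    delta = (2 pi L / lambda) |n_eff(theta_i) - nO| times the optional
    per-wavelength dispersion factor; strictly decreasing in theta_i for
    nE != nO and exactly 0 at 90 deg.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(~np.isfinite(wl)) or np.any(wl <= 0):
        raise InvalidArgumentError("wavelength must be positive")
    theta = _check_theta(theta_i)
    n_eff = np.asarray(effective_index(medium, theta))
    scale = np.vectorize(medium.dispersion_factor)(wl) if wl.ndim else medium.dispersion_factor(float(wl))
    L_nm = medium.L * 1e3  # um -> nm, so 2 pi L / lambda is dimensionless
    out = 2.0 * np.pi * L_nm / wl * np.abs(n_eff - medium.nO) * scale
    out = np.asarray(out)
    return out if out.ndim else float(out)


def retardance_curves(
    medium: UniaxialMedium,
    wavelengths: Iterable[float],
    thetas: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Tabulate delta(theta_i, lambda) for plotting or export.

    Returns a tidy frame with columns theta_deg, wavelength_nm,
    retardance_rad; ``thetas`` defaults to a 1-degree grid on [0, 90].
    """
    thetas = np.arange(0.0, 90.5, 1.0) if thetas is None else np.asarray(list(thetas), float)
    wls = np.asarray(list(wavelengths), dtype=float)
    rows = []
    for wl in wls:
        delta = tilted_retardance(medium, thetas, wl)
        rows.append(
            pd.DataFrame(
                {
                    "theta_deg": thetas,
                    "wavelength_nm": wl,
                    "retardance_rad": np.asarray(delta),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def export_curves(frame: pd.DataFrame, destination) -> None:
    """Write a retardance-curve table as tab-separated text with a unit header."""
    with open(destination, "w", encoding="utf-8") as fh:
        fh.write("# columns: theta_deg (inclination), wavelength_nm, retardance_rad\n")
        frame.to_csv(fh, sep="\t", index=False)
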