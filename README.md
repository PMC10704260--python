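# plimap

Analysis pipeline for **backscattering Mueller-matrix polarized-light imaging
(PLI)** of fibrous samples — birefringent fiber phantoms and, by analogy,
white-matter fiber tracts.  The package simulates multi-wavelength Mueller
image stacks of fiber scenes with full per-pixel ground truth, decomposes
them into polarization-property maps, corrects the retardance
phase-wrapping artifact, and quantifies how fiber geometry (crossing,
inclination, out-of-plane curvature, in-plane curvature, stage rotation)
shows up in those maps.

It is written for optics and biomedical-imaging researchers who want a
tested, reproducible reference for the analysis side of a backscattering
polarimeter: everything downstream of the calibrated per-pixel Mueller
matrix.

## The model

A fibrous, uniaxial medium with ordinary index $n_O$, extraordinary index
$n_E$ and path length $L$ imparts a retardance at vacuum wavelength
$\lambda$ of

$$\delta = \frac{2\pi \,\Delta n\, L}{\lambda}, \qquad \Delta n = n_E - n_O .$$

Tilting the optic axis out of the imaging plane by an inclination
$\theta_i$ changes the effective extraordinary index,

$$n_e(\theta_i) = \frac{n_O n_E}{\sqrt{n_E^2 \sin^2\theta_i + n_O^2 \cos^2\theta_i}},$$

so the measured (magnitude-only) retardance becomes

$$\delta(\theta_i, \lambda) = \frac{2\pi L}{\lambda}\,\bigl|\,n_e(\theta_i) - n_O\,\bigr| ,$$

which decreases monotonically with tilt and vanishes at
$\theta_i = 90^\circ$.  White matter and polystyrene fibers are *negatively*
birefringent ($n_E < n_O$), which makes the measured retardance axis run
perpendicular to the fiber.

Measured pixels are factored by the **Lu–Chipman polar decomposition**
$M = M_\Delta M_R M_D$ (depolarizer · retarder · diattenuator), from which
the maps are extracted: retardance $R = \cos^{-1}[\mathrm{tr}(M_R)/2 - 1]$,
its fast-axis angle, diattenuation $D$ and its axis, and depolarization
power $\Delta = 1 - |\mathrm{tr}(M_\Delta) - 1|/3$.  Because the inverse
cosine is confined to $[0,\pi]$, true retardance above $\pi$ wraps to
$2\pi - \delta$ and the recovered axis flips by exactly 90°; the
`plimap.unwrap` module detects the 90° axial discontinuities, corrects the
selected branch and resolves the branch from the expected decrease of
retardance with wavelength.

Radius of curvature of surface cross sections is estimated with the
SVD-based Taubin algebraic circle fit (`plimap.curvature`).

## Worked example

```python
import numpy as np
import plimap as pl
from plimap.io import scene_regions

# tilt-retardance curve of the default phantom medium
medium = pl.UniaxialMedium(nO=1.59, nE=1.57, L=10.0)
for theta in (0, 30, 60, 90):
    print(f"delta({theta:2d} deg, 532 nm) = "
          f"{pl.tilted_retardance(medium, theta, 532):.4f} rad")

# crossing-fiber phantom, top-overlap physics, noise-free
scene = pl.preset_phantom("crossing", overlap_mode="top",
                          wavelengths=(532,), size=(64, 64))
stack, truth = pl.scene_to_mueller(scene)
maps = pl.decompose_stack(stack)[0]
overlap = scene_regions(scene)["overlap"]
hist = pl.angular_distribution(maps.retardance_angle,
                               pl.ROIMask(overlap, "overlap"))
print(f"overlap dominant retardance angle = {hist.dominant_angle:.1f} deg "
      f"(top fiber runs at 90 deg)")

# Taubin circle fit of a short arc
fit = pl.taubin_circle_fit(np.c_[3 + 14.2*np.cos(np.linspace(0, 1, 30)),
                                 -2 + 14.2*np.sin(np.linspace(0, 1, 30))])
print(f"fitted radius of curvature = {fit.radius:.3f} mm "
      f"(rms residual {fit.rms_residual:.2e})")
```

Output:

```
delta( 0 deg, 532 nm) = 2.3621 rad
delta(30 deg, 532 nm) = 1.7799 rad
delta(60 deg, 532 nm) = 0.5990 rad
delta(90 deg, 532 nm) = 0.0000 rad
overlap dominant retardance angle = 2.5 deg (top fiber runs at 90 deg)
fitted radius of curvature = 14.200 mm (rms residual 1.59e-15)
```

The tilt curve shows the monotone loss of retardance as the fiber leaves the
imaging plane.  In the crossing region the *top* fiber dominates: its long
axis runs at 90°, and because the medium is negatively birefringent the
recovered retardance axis sits 90° away, in the histogram bin centered at
2.5° (bins are 5° wide).  The circle fit recovers the 14.2 mm radius from a
partial arc to machine precision.

There is also a CLI mirroring the pipeline stages:

```bash
plimap simulate --preset crossing --overlap-mode top --out stack.tif
plimap decompose stack.tif maps/
plimap analyze maps/
plimap curvature points.txt
plimap run config.yaml        # full simulate→decompose→unwrap→analyze run
```

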