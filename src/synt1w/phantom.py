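"""Quantitative-map phantoms with known ground-truth cord geometry.

A phantom is a tilted circular cylinder of "cord" tissue surrounded by a
cerebrospinal-fluid (CSF) annulus inside a background compartment, voxelized
onto a regular grid with partial-volume fractions obtained by regular
subvoxel sampling.  The generator returns the three quantitative maps plus
the analytic per-slice cross-sectional area, so segmentation and
angle-correction accuracy can be verified against ground truth.

Default tissue parameters are plausible 3 T values chosen for this package
(they are configurable and not tied to any particular cohort): the cord is
the brightest T1-weighted structure, CSF the darkest, and the background a
low-signal lumped extra-spinal compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .maps import QuantitativeMaps
from .signal import TissueVoxel

__all__ = [
    "PhantomSpec",
    "CordPhantom",
    "make_cord_phantom",
    "perturb_maps",
    "DEFAULT_TISSUES",
    "PD_CONTRAST_TISSUES",
]

DEFAULT_TISSUES: dict[str, TissueVoxel] = {
    "cord": TissueVoxel(PD=0.70, R1=1.00, R2star=30.0),
    "csf": TissueVoxel(PD=1.00, R1=0.25, R2star=1.5),
    "background": TissueVoxel(PD=0.40, R1=0.60, R2star=40.0),
}

# Geometry-validation tissue set: contrast carried by PD alone (equal R1 and
# R2*), so the synthesized intensity is exactly linear in the partial-volume
# cord fraction and a half-intensity threshold recovers the geometric
# boundary.  With R1-driven contrast (DEFAULT_TISSUES) the signal is concave
# in the mixing fraction and a half-intensity boundary sits outside the true
# edge — a real partial-volume bias, quantified in the package docs.
PD_CONTRAST_TISSUES: dict[str, TissueVoxel] = {
    "cord": TissueVoxel(PD=1.00, R1=0.80, R2star=25.0),
    "csf": TissueVoxel(PD=0.45, R1=0.80, R2star=25.0),
    "background": TissueVoxel(PD=0.45, R1=0.80, R2star=25.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and noise description of a cord phantom.

    ``cord_radius`` may be a scalar (straight cylinder) or a per-slice array
    to emulate radius variation along the cord.  ``tilt_deg`` tilts the cord
    axis away from the slice normal (about the first in-plane axis), so the
    in-plane cut is an ellipse of area ``pi r^2 / cos(tilt)``.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cord_radius: float | np.ndarray = 4.0
    csf_thickness: float = 3.0
    tilt_deg: float = 0.0
    tissue_params: dict[str, TissueVoxel] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    noise_sd: float = 0.0
    subsample: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        radii = np.atleast_1d(np.asarray(self.cord_radius, dtype=float))
        if np.any(radii <= 0):
            raise ValueError("cord_radius must be positive")
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError(f"tilt_deg must be in [0, 90), got {self.tilt_deg}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        missing = {"cord", "csf", "background"} - set(self.tissue_params)
        if missing:
            raise ValueError(f"tissue_params missing classes: {sorted(missing)}")


@dataclass
class CordPhantom:
    """A generated phantom: maps plus analytic ground truth."""

    maps: QuantitativeMaps
    true_csa_per_slice: np.ndarray  # in-plane elliptical cut area, mm^2
    true_csa_corrected: np.ndarray  # perpendicular (angle-corrected) area, mm^2
    cord_fraction: np.ndarray  # partial-volume cord fraction per voxel
    spec: PhantomSpec


def _slice_radii(spec: PhantomSpec) -> np.ndarray:
    nz = spec.grid_shape[2]
    radii = np.atleast_1d(np.asarray(spec.cord_radius, dtype=float))
    if radii.size == 1:
        return np.full(nz, radii[0])
    if radii.size != nz:
        raise ValueError(f"cord_radius array length {radii.size} != n slices {nz}")
    return radii


def make_cord_phantom(spec: PhantomSpec) -> CordPhantom:
    """Voxelize the phantom and return maps plus analytic ground truth.

    Partial-volume fractions use ``subsample**3`` regular subvoxel points per
    voxel, so the voxelized area converges to the analytic ellipse area as
    the subsampling is refined.  Independent Gaussian noise of SD
    ``noise_sd`` (same units as each map) is added per map.  Deterministic
    for a fixed ``(spec, seed)``.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_spacing
    radii = _slice_radii(spec)
    if np.any(radii < max(sx, sy)):
        warnings.warn("cord radius smaller than one voxel; expect severe digitization")

    tilt = np.radians(spec.tilt_deg)
    # Cord axis direction (unit) leaning in the y-z plane; passes through volume centre.
    axis = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    centre = np.array([(nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy, (nz - 1) / 2.0 * sz])

    k = spec.subsample
    offs = (np.arange(k) + 0.5) / k - 0.5  # subvoxel offsets in voxel units
    ox, oy, oz = np.meshgrid(offs * sx, offs * sy, offs * sz, indexing="ij")
    sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (k^3, 3)

    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    cord_frac = np.zeros(spec.grid_shape)
    csf_frac = np.zeros(spec.grid_shape)
    for iz in range(nz):
        r = radii[iz]
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        centres = np.stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, iz * sz)], axis=1
        )  # (nvox, 3)
        pts = centres[:, None, :] + sub[None, :, :]  # (nvox, k^3, 3)
        rel = pts - centre
        along = rel @ axis
        perp = rel - along[..., None] * axis
        d = np.linalg.norm(perp, axis=-1)
        cord_frac[:, :, iz] = (d <= r).mean(axis=1).reshape(nx, ny)
        csf_frac[:, :, iz] = (
            ((d > r) & (d <= r + spec.csf_thickness)).mean(axis=1).reshape(nx, ny)
        )
    bg_frac = 1.0 - cord_frac - csf_frac

    tp = spec.tissue_params
    def mix(attr: str) -> np.ndarray:
        return (
            cord_frac * getattr(tp["cord"], attr)
            + csf_frac * getattr(tp["csf"], attr)
            + bg_frac * getattr(tp["background"], attr)
        )

    pd_map, r1_map, r2s_map = mix("PD"), mix("R1"), mix("R2star")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pd_map = pd_map + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        r1_map = r1_map + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        r2s_map = r2s_map + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    affine = np.diag([sx, sy, sz, 1.0])
    maps = QuantitativeMaps(
        PD=pd_map,
        R1=r1_map,
        R2star=r2s_map,
        voxel_spacing=(sx, sy, sz),
        affine=affine,
        validity_mask=np.ones(spec.grid_shape, dtype=bool),
    )
    true_corr = np.pi * radii**2
    true_inplane = true_corr / np.cos(tilt)
    return CordPhantom(
        maps=maps,
        true_csa_per_slice=true_inplane,
        true_csa_corrected=true_corr,
        cord_fraction=cord_frac,
        spec=spec,
    )


def perturb_maps(
    maps: QuantitativeMaps,
    noise_sd: float | tuple[float, float, float],
    seed: int,
) -> QuantitativeMaps:
    """Additive Gaussian perturbation of the three maps (test-retest emulation).

    ``noise_sd`` is either one SD applied to each map or a per-map triple
    (PD, R1, R2*).  Zero SD returns an identical copy.  Deterministic per seed.
    """
    if np.isscalar(noise_sd):
        sds = (float(noise_sd),) * 3
    else:
        sds = tuple(float(s) for s in noise_sd)
    if any(s < 0 for s in sds):
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    arrays = []
    for arr, sd in zip((maps.PD, maps.R1, maps.R2star), sds):
        if sd == 0:
            arrays.append(arr.copy())
        else:
            arrays.append(arr + rng.normal(0.0, sd, arr.shape))
    return QuantitativeMaps(
        PD=arrays[0],
        R1=arrays[1],
        R2star=arrays[2],
        voxel_spacing=maps.voxel_spacing,
        affine=maps.affine.copy(),
        validity_mask=maps.validity_mask.copy(),
    )
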