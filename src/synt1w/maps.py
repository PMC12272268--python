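"""Container and NIfTI I/O for co-registered quantitative maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["QuantitativeMaps", "read_quantitative_maps", "write_quantitative_maps"]


@dataclass
class QuantitativeMaps:
    """Co-registered PD / R1 / R2* voxel volumes on a shared grid.

    ``PD`` is in arbitrary (or percent) units, ``R1`` and ``R2star`` in s^-1.
    ``validity_mask`` marks voxels whose three inputs are all finite and
    non-negative; invalid voxels synthesize to zero downstream.
    """

    PD: np.ndarray
    R1: np.ndarray
    R2star: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.PD = np.asarray(self.PD, dtype=float)
        self.R1 = np.asarray(self.R1, dtype=float)
        self.R2star = np.asarray(self.R2star, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not (self.PD.shape == self.R1.shape == self.R2star.shape):
            raise ValueError(
                f"map shapes differ: PD {self.PD.shape}, R1 {self.R1.shape}, "
                f"R2star {self.R2star.shape}"
            )
        if self.validity_mask is None:
            self.validity_mask = (
                np.isfinite(self.PD)
                & np.isfinite(self.R1)
                & np.isfinite(self.R2star)
                & (self.PD >= 0)
                & (self.R1 >= 0)
                & (self.R2star >= 0)
            )
        self.validate()

    def validate(self) -> None:
        if not (self.PD.shape == self.R1.shape == self.R2star.shape):
            raise ValueError(
                f"map shapes differ: PD {self.PD.shape}, R1 {self.R1.shape}, "
                f"R2star {self.R2star.shape}"
            )
        if self.PD.ndim != 3:
            raise ValueError(f"maps must be 3-D, got ndim={self.PD.ndim}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        if self.validity_mask.shape != self.PD.shape:
            raise ValueError("validity_mask shape differs from map shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.PD.shape

    def n_invalid(self) -> int:
        return int((~self.validity_mask).sum())


def _load(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return data, img.affine, tuple(float(z) for z in img.header.get_zooms()[:3])


def read_quantitative_maps(
    pd_path: str | Path | None = None,
    r1_path: str | Path | None = None,
    r2star_path: str | Path | None = None,
    stacked_path: str | Path | None = None,
    affine_tol: float = 1e-4,
) -> QuantitativeMaps:
    """Read PD/R1/R2* either from three 3-D NIfTI files or one 4-D file.

    The three volumes must share grid shape; affines must agree within
    ``affine_tol`` elementwise.  NaN voxels become invalid in the mask.
    """
    if stacked_path is not None:
        img = nib.load(str(stacked_path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4 or data.shape[3] != 3:
            raise ValueError(f"stacked maps must be 4-D with 3 volumes, got shape {data.shape}")
        pd_d, r1_d, r2s_d = data[..., 0], data[..., 1], data[..., 2]
        affine = img.affine
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        if pd_path is None or r1_path is None or r2star_path is None:
            raise ValueError("provide either stacked_path or all of pd/r1/r2star paths")
        pd_d, affine, spacing = _load(pd_path)
        r1_d, a1, s1 = _load(r1_path)
        r2s_d, a2, s2 = _load(r2star_path)
        if pd_d.shape != r1_d.shape or pd_d.shape != r2s_d.shape:
            raise ValueError(
                f"map grids differ: {pd_d.shape}, {r1_d.shape}, {r2s_d.shape}"
            )
        for other in (a1, a2):
            if np.max(np.abs(affine - other)) > affine_tol:
                raise ValueError("affines differ beyond tolerance between map files")
    return QuantitativeMaps(
        PD=pd_d, R1=r1_d, R2star=r2s_d, voxel_spacing=spacing, affine=affine
    )


def write_quantitative_maps(maps: QuantitativeMaps, out_dir: str | Path, stem: str = "maps") -> dict:
    """Write the three maps as ``<stem>_{pd,r1,r2star}.nii.gz``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, arr in (("pd", maps.PD), ("r1", maps.R1), ("r2star", maps.R2star)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), maps.affine)
        img.header.set_zooms(maps.voxel_spacing)
        p = out_dir / f"{stem}_{key}.nii.gz"
        nib.save(img, str(p))
        paths[key] = p
    return paths


def write_volume(
    data: np.ndarray,
    affine: np.ndarray,
    voxel_spacing,
    path: str | Path,
    scale_int16: bool = False,
) -> Path:
    """Write a synthesized volume as NIfTI, optionally min-max scaled to int16."""
    arr = np.asarray(data, dtype=float)
    if scale_int16:
        lo, hi = float(arr.min()), float(arr.max())
        if hi > lo:
            arr = (arr - lo) / (hi - lo) * 32767.0
        arr = arr.astype(np.int16)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    img.header.set_zooms(tuple(voxel_spacing))
    nib.save(img, str(path))
    return Path(path)
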