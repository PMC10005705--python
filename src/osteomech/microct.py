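"""Calibrated micro-CT morphometry of long-bone volumes.

Scanner attenuation is converted to hydroxyapatite-equivalent density
(mgHA/cm^3) by an ordinary-least-squares line through calibration-phantom
readings of known density.  On the calibrated, thresholded volume the
module computes regional morphometry: the volume of interest below the
growth plate is split into equal axial blocks (proximal block 1 to distal
block 7 by default) and each transverse section into antero-posterior (AP)
and medio-lateral (ML) sectors about the section centroid, reporting BMD
(g/cm^3), BMC (g) and bone-volume fraction BV/TV per region.  Cortical
inner/outer diameters are estimated from cross-sections as
equivalent-circle diameters of the filled periosteal and medullary areas.

Axis convention: arrays are indexed (axial, AP, ML), voxel indices are
0-based, and world coordinates are voxel-centre millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "CalibrationCurve",
    "RegionalMorphometry",
    "calibrate",
    "segment_bone",
    "regional_morphometry",
    "estimate_diameters",
    "area_fraction",
]

#: Default bone segmentation threshold, mgHA/cm^3.
DEFAULT_THRESHOLD = 400.0


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D density or attenuation grid with physical spacing.

    values are attenuation (arbitrary units, ``calibrated=False``) or
    mineral density in mgHA/cm^3 (``calibrated=True``); spacing is mm per
    axis in (axial, AP, ML) order.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    calibrated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("values must be a non-empty 3-D grid")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine attenuation-to-density map fitted on phantom readings."""

    slope: float  # mgHA/cm^3 per attenuation unit
    intercept: float  # mgHA/cm^3
    r_squared: float
    phantom_table: pd.DataFrame  # density_mgHA_cm3, mean_attenuation

    def __call__(self, attenuation: np.ndarray | float) -> np.ndarray | float:
        return self.slope * attenuation + self.intercept


@dataclass
class RegionalMorphometry:
    """Block-by-sector mineral morphometry plus whole-bone summaries.

    ``per_region`` columns: block (1 = proximal), sector, bmd_g_cm3,
    bmc_g, bvtv.  Blocks with no bone voxels report missing (NaN) BMD
    rather than zero, so group means are not biased downward.
    """

    per_region: pd.DataFrame
    per_block: pd.DataFrame
    whole: dict[str, float]
    n_blocks: int
    sector_mode: str


def calibrate(
    volume: VoxelVolume, phantom_readings: pd.DataFrame
) -> tuple[CalibrationCurve, VoxelVolume]:
    """Fit the density calibration line and map a volume through it.

    ``phantom_readings`` needs columns ``density_mgHA_cm3`` and
    ``mean_attenuation`` with at least two distinct densities.  The OLS
    line regresses known density on measured attenuation; mapped densities
    below zero are clipped to zero (their count is recorded on the
    returned volume's calibration table attributes).
    """
    dens = np.asarray(phantom_readings["density_mgHA_cm3"], dtype=float)
    att = np.asarray(phantom_readings["mean_attenuation"], dtype=float)
    if np.unique(dens).size < 2:
        raise ValueError("at least two distinct phantom densities are required")
    if np.ptp(att) == 0:
        raise ValueError("identical phantom attenuations: degenerate calibration fit")
    slope, intercept = np.polyfit(att, dens, 1)
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    pred = slope * att + intercept
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - float(np.sum((dens - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    curve = CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        phantom_table=phantom_readings.copy(),
    )
    mapped = curve(volume.values)
    n_clipped = int(np.count_nonzero(mapped < 0))
    if n_clipped:
        mapped = np.clip(mapped, 0.0, None)
    calibrated = VoxelVolume(values=mapped, spacing=volume.spacing, calibrated=True)
    object.__setattr__(calibrated, "n_clipped", n_clipped)
    return curve, calibrated


def segment_bone(
    volume: VoxelVolume, threshold: float = DEFAULT_THRESHOLD
) -> tuple[np.ndarray, float]:
    """Threshold a calibrated volume into a bone mask.

    Returns the boolean mask (``values >= threshold``) and the masked
    fraction of the grid.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not volume.calibrated:
        raise ValueError("segment_bone requires a calibrated volume")
    mask = volume.values >= threshold
    return mask, float(mask.mean())


def _sector_labels(
    shape: tuple[int, int], centroid: tuple[float, float], mode: str
) -> np.ndarray:
    """Label each in-plane voxel by sector about the centroid.

    halves: the plane is partitioned into an AP wedge pair (voxels whose
    offset from the centroid is predominantly along the AP axis) and an ML
    wedge pair, i.e. two orthogonal 90-degree double-wedges.  quadrants:
    the four wedges A, P, M, L separately.
    """
    ap = np.arange(shape[0])[:, None] - centroid[0]
    ml = np.arange(shape[1])[None, :] - centroid[1]
    ap = np.broadcast_to(ap, shape)
    ml = np.broadcast_to(ml, shape)
    ap_dominant = np.abs(ap) >= np.abs(ml)
    if mode == "halves":
        return np.where(ap_dominant, 0, 1)  # 0 = AP, 1 = ML
    if mode == "quadrants":
        lab = np.empty(shape, dtype=int)
        lab[ap_dominant & (ap < 0)] = 0  # anterior
        lab[ap_dominant & (ap >= 0)] = 1  # posterior
        lab[~ap_dominant & (ml < 0)] = 2  # medial
        lab[~ap_dominant & (ml >= 0)] = 3  # lateral
        return lab
    raise ValueError(f"unknown sector_mode {mode!r}")


_SECTOR_NAMES = {"halves": ["AP", "ML"], "quadrants": ["A", "P", "M", "L"]}


def regional_morphometry(
    volume: VoxelVolume,
    mask: np.ndarray,
    growth_plate_index: int = 0,
    n_blocks: int = 7,
    sector_mode: str = "halves",
    voi_fraction: float = 0.8,
) -> RegionalMorphometry:
    """Block-by-sector BMD, BMC and BV/TV below the growth plate.

    The VOI starts at ``growth_plate_index`` (a user-supplied axial plane;
    automatic growth-plate detection is out of scope) and spans
    ``voi_fraction`` of the remaining axial length, split into
    ``n_blocks`` equal axial blocks numbered proximal (1) to distal.
    Within each transverse plane, sectors are assigned about the section
    centroid of the bone mask (grid centre when a plane is empty).

    BMC sums density * voxel volume over bone voxels (reported in g),
    BMD = BMC / bone volume (g/cm^3), BV/TV = bone voxels / VOI voxels.
    Sector masses partition block masses exactly.
    """
    if not volume.calibrated:
        raise ValueError("regional morphometry requires a calibrated volume")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.values.shape:
        raise ValueError("mask and volume must be congruent")
    nz = volume.values.shape[0]
    if not 0 <= growth_plate_index < nz:
        raise ValueError("growth-plate plane outside the volume")
    voi_len = int(round(voi_fraction * (nz - growth_plate_index)))
    if voi_len < n_blocks:
        raise ValueError("VOI too short for the requested number of blocks")
    voi = slice(growth_plate_index, growth_plate_index + voi_len)
    vv = volume.voxel_volume_mm3
    names = _SECTOR_NAMES[sector_mode]
    block_slices = np.array_split(np.arange(voi.start, voi.stop), n_blocks)
    rows = []
    for b, zidx in enumerate(block_slices, start=1):
        bmc = dict.fromkeys(names, 0.0)
        bv = dict.fromkeys(names, 0.0)
        tv = dict.fromkeys(names, 0.0)
        for z in zidx:
            plane_mask = mask[z]
            plane_dens = volume.values[z]
            if plane_mask.any():
                com = ndimage.center_of_mass(plane_mask)
            else:
                com = ((plane_mask.shape[0] - 1) / 2, (plane_mask.shape[1] - 1) / 2)
            labels = _sector_labels(plane_mask.shape, com, sector_mode)
            for s, name in enumerate(names):
                sel = labels == s
                tv[name] += float(np.count_nonzero(sel)) * vv
                bone = sel & plane_mask
                bv[name] += float(np.count_nonzero(bone)) * vv
                bmc[name] += float(plane_dens[bone].sum()) * vv * 1e-6  # g
        for name in names:
            bv_cm3 = bv[name] * 1e-3
            rows.append(
                {
                    "block": b,
                    "sector": name,
                    "bmc_g": bmc[name],
                    "bvtv": bv[name] / tv[name] if tv[name] > 0 else np.nan,
                    "bmd_g_cm3": bmc[name] / bv_cm3 if bv_cm3 > 0 else np.nan,
                    "bv_mm3": bv[name],
                    "tv_mm3": tv[name],
                }
            )
    per_region = pd.DataFrame(rows)
    per_block = (
        per_region.groupby("block", as_index=False)
        .agg(bmc_g=("bmc_g", "sum"), bv_mm3=("bv_mm3", "sum"), tv_mm3=("tv_mm3", "sum"))
        .assign(
            bvtv=lambda t: t.bv_mm3 / t.tv_mm3,
            bmd_g_cm3=lambda t: np.where(
                t.bv_mm3 > 0, t.bmc_g / (t.bv_mm3 * 1e-3), np.nan
            ),
        )
    )
    total_bv = float(per_block.bv_mm3.sum())
    whole = {
        "bmc_g": float(per_block.bmc_g.sum()),
        "bmd_g_cm3": float(per_block.bmc_g.sum()) / (total_bv * 1e-3)
        if total_bv > 0
        else float("nan"),
        "bvtv": total_bv / float(per_block.tv_mm3.sum()),
        "bmd_min": float(per_block.bmd_g_cm3.min()),
        "bmd_max": float(per_block.bmd_g_cm3.max()),
        "bvtv_min": float(per_block.bvtv.min()),
        "bvtv_max": float(per_block.bvtv.max()),
    }
    return RegionalMorphometry(
        per_region=per_region,
        per_block=per_block,
        whole=whole,
        n_blocks=n_blocks,
        sector_mode=sector_mode,
    )


def estimate_diameters(
    mask: np.ndarray, axial_positions: list[int], spacing: float
) -> list[tuple[float, float, bool]]:
    """Equivalent-circle outer/inner diameters at given cross-sections.

    Per section the periosteal area is the hole-filled bone mask and the
    medullary area the filled region minus bone; do = 2 sqrt(A/pi) of
    each.  Returns (do, di, has_cavity) in mm per position; a non-annular
    section reports di = 0 with ``has_cavity=False``.
    """
    mask = np.asarray(mask, dtype=bool)
    out = []
    for z in axial_positions:
        section = mask[z]
        if not section.any():
            raise ValueError(f"axial position {z} does not intersect the mask")
        filled = ndimage.binary_fill_holes(section)
        a_outer = float(np.count_nonzero(filled)) * spacing**2
        a_med = float(np.count_nonzero(filled & ~section)) * spacing**2
        do = 2.0 * math.sqrt(a_outer / math.pi)
        di = 2.0 * math.sqrt(a_med / math.pi)
        out.append((do, di, a_med > 0))
    return out


def area_fraction(
    image: np.ndarray,
    rois: list[tuple[int, int, int, int]],
    threshold: float,
) -> float:
    """Mean percent area at or above threshold over rectangular ROIs.

    ROIs are (row, col, height, width) in pixels; emulates counting the
    stained trabecular-bone fraction in randomly placed microscope fields.
    """
    image = np.asarray(image, dtype=float)
    if not rois:
        raise ValueError("at least one ROI is required")
    fractions = []
    for r0, c0, h, w in rois:
        if h <= 0 or w <= 0:
            raise ValueError("empty ROI")
        if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
            raise ValueError("ROI outside image bounds")
        patch = image[r0 : r0 + h, c0 : c0 + w]
        fractions.append(np.count_nonzero(patch >= threshold) / patch.size)
    return 100.0 * float(np.mean(fractions))
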