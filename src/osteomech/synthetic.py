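"""Synthetic measurement generators with known ground truth.

Every input the analysis stages consume can be generated here with planted
parameters, so each stage is verifiable by round-trip recovery without
original specimens:

* sinusoidal DMA traces from a standard-linear-solid (SLS) material,
* elastoplastic three-point-bending load-displacement curves with pop-in
  load drops,
* voxelized hollow-tube density phantoms with calibration inserts,
* longitudinal cohort tables (body weight, lean and fat mass),
* dietary omega-3/6/9 mass-fraction bookkeeping.

The SLS (three-parameter solid: a spring in parallel with a Maxwell arm)
has closed-form dynamic moduli

    E'(w)  = E_eq + (E_inst - E_eq) (w tau)^2 / (1 + (w tau)^2)
    E''(w) = (E_inst - E_eq) (w tau) / (1 + (w tau)^2)

which the DMA generator uses directly: the steady-state strain response to
sigma(t) = sigma_0 + sigma_a sin(wt) is sigma_0/E_eq + (sigma_a/|E*|)
sin(wt - delta) with delta = atan(E''/E').  Noise is Gaussian and additive
on the dependent channel only (strain for DMA, load for bending), so the
noise-free limit matches the closed forms exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bending import LoadDisplacementCurve, TubeGeometry, moment_of_inertia
from .dma import DMATrace
from .microct import VoxelVolume

__all__ = [
    "SLSParams",
    "DMAProtocol",
    "GeneratedDMATrace",
    "BendingGroundTruth",
    "PhantomSpec",
    "PhantomVolume",
    "CohortSpec",
    "GroupMeans",
    "sls_moduli",
    "generate_dma_trace",
    "generate_bending_curve",
    "expected_offset_yield",
    "generate_phantom_volume",
    "generate_cohort",
    "diet_omega_fractions",
    "OmegaFractions",
]

#: Default drive frequencies (Hz) of the dynamic sweep.
DEFAULT_FREQUENCIES = (0.05, 0.1, 1.0, 10.0)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# dynamic mechanical traces


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid material parameters.

    E_inst is the instantaneous (high-frequency) modulus, E_eq the
    equilibrium (low-frequency) modulus, tau the relaxation time; moduli
    in MPa, tau in s.  noise_sd is the standard deviation of additive
    Gaussian strain noise (dimensionless strain units).
    """

    E_inst: float
    E_eq: float
    tau: float
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.E_inst > self.E_eq > 0:
            raise ValueError("require E_inst > E_eq > 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class DMAProtocol:
    """Sinusoidal loading protocol of the frequency sweep.

    The default stress waveform has mean 0.75 MPa and amplitude 0.25 MPa,
    i.e. it oscillates between 0.5 and 1.0 MPa, staying below the elastic
    limit of a mouse tibia.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    stress_mean: float = 0.75  # MPa
    stress_amplitude: float = 0.25  # MPa
    n_cycles: int = 8
    samples_per_cycle: int = 64

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("all frequencies must be positive")
        if self.stress_amplitude <= 0:
            raise ValueError("stress amplitude must be positive")
        if self.samples_per_cycle < 16:
            raise ValueError("at least 16 samples per cycle are required")
        if self.n_cycles < 4:
            raise ValueError("at least 4 cycles are required (one is discarded)")


@dataclass(frozen=True)
class GeneratedDMATrace:
    """A synthetic trace together with its ground-truth moduli."""

    trace: DMATrace
    storage_modulus: float  # MPa
    loss_modulus: float  # MPa
    loss_tangent: float
    phase_lag: float  # rad
    strain_amplitude: float


def sls_moduli(params: SLSParams, frequency: float) -> tuple[float, float, float]:
    """Closed-form (E', E'', tan delta) of the SLS at a frequency in Hz."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    wt = 2.0 * math.pi * frequency * params.tau
    de = params.E_inst - params.E_eq
    e1 = params.E_eq + de * wt**2 / (1.0 + wt**2)
    e2 = de * wt / (1.0 + wt**2)
    return e1, e2, e2 / e1


def generate_dma_trace(
    params: SLSParams,
    protocol: DMAProtocol,
    frequency: float,
    seed: int | np.random.Generator | None = None,
) -> GeneratedDMATrace:
    """Steady-state sinusoidal trace of an SLS specimen at one frequency.

    The stress channel is exactly ``stress_mean + stress_amplitude *
    sin(2 pi f t)``; the strain channel is the SLS steady-state response
    plus Gaussian noise of sd ``params.noise_sd``.
    """
    if frequency not in protocol.frequencies:
        raise ValueError(f"frequency {frequency} Hz is not in the protocol")
    rng = _rng(params.seed if seed is None else seed)
    e1, e2, tand = sls_moduli(params, frequency)
    delta = math.atan2(e2, e1)
    e_star = math.hypot(e1, e2)
    n = protocol.n_cycles * protocol.samples_per_cycle
    t = np.arange(n) / (protocol.samples_per_cycle * frequency)
    w = 2.0 * math.pi * frequency
    stress = protocol.stress_mean + protocol.stress_amplitude * np.sin(w * t)
    eps_a = protocol.stress_amplitude / e_star
    strain = protocol.stress_mean / params.E_eq + eps_a * np.sin(w * t - delta)
    if params.noise_sd > 0:
        strain = strain + rng.normal(0.0, params.noise_sd, size=n)
    return GeneratedDMATrace(
        trace=DMATrace(time=t, stress=stress, strain=strain, frequency=frequency),
        storage_modulus=e1,
        loss_modulus=e2,
        loss_tangent=tand,
        phase_lag=delta,
        strain_amplitude=eps_a,
    )


# ---------------------------------------------------------------------------
# bending curves


@dataclass(frozen=True)
class BendingGroundTruth:
    """Planted parameters of a synthetic bending test.

    The elastic segment has slope ``48 E I / L^3`` (E in GPa converted to
    N/mm^2); beyond the yield load the slope is ``hardening_slope``; at
    each pop-in displacement the load instantaneously drops by the given
    fraction and then resumes along the hardening slope; the curve
    terminates with a drop to zero at ``fracture_displacement``.
    """

    E_true: float  # GPa
    geometry: TubeGeometry
    yield_load: float  # N
    hardening_slope: float  # N/mm
    fracture_displacement: float  # mm
    popin_events: tuple[tuple[float, float], ...] = ()  # (mm, drop fraction)
    span: float | None = None  # mm; defaults to geometry.span

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if self.yield_load <= 0:
            raise ValueError("yield_load must be positive")
        if self.hardening_slope < 0:
            raise ValueError("hardening_slope must be non-negative")
        if self.fracture_displacement <= self.yield_displacement:
            raise ValueError("fracture must occur beyond the yield displacement")
        for d, frac in self.popin_events:
            if not 0 < frac < 1:
                raise ValueError("pop-in drop fractions must lie in (0, 1)")
            if not 0 < d < self.fracture_displacement:
                raise ValueError("pop-in displacements must precede fracture")
        if self.span is not None and self.span != self.geometry.span:
            object.__setattr__(
                self, "geometry",
                TubeGeometry(
                    self.geometry.outer_radius, self.geometry.inner_radius,
                    span=self.span, tibial_length=self.geometry.tibial_length,
                ),
            )

    @property
    def elastic_slope(self) -> float:
        """Elastic load-displacement slope 48 E I / L^3 in N/mm."""
        e_mpa = self.E_true * 1000.0
        return 48.0 * e_mpa * moment_of_inertia(self.geometry) / self.geometry.span**3

    @property
    def yield_displacement(self) -> float:
        return self.yield_load / self.elastic_slope


def generate_bending_curve(
    truth: BendingGroundTruth,
    sampling_step: float = 0.005,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> LoadDisplacementCurve:
    """Sample a load-displacement curve from planted elastoplastic truth.

    The noise-free curve is exactly bilinear (elastic slope then hardening
    slope) with instantaneous pop-in drops between samples and a terminal
    drop to zero after ``fracture_displacement``.  Gaussian load noise of
    sd ``noise_sd`` (N) is clipped so the load stays non-negative.
    """
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    rng = _rng(seed)
    s = truth.elastic_slope
    d_y = truth.yield_displacement
    d = np.arange(0.0, truth.fracture_displacement + sampling_step / 2, sampling_step)
    popins = sorted(truth.popin_events)
    load = np.empty_like(d)
    current = 0.0
    next_pop = 0
    for i, di in enumerate(d):
        if i > 0:
            step = d[i] - d[i - 1]
            slope = s if di <= d_y else truth.hardening_slope
            # segment straddling the yield point: split the increment
            if d[i - 1] < d_y < di:
                current += s * (d_y - d[i - 1]) + truth.hardening_slope * (di - d_y)
            else:
                current += slope * step
            while next_pop < len(popins) and popins[next_pop][0] <= di:
                current *= 1.0 - popins[next_pop][1]
                next_pop += 1
        load[i] = current
    # terminal fracture: two post-failure samples at zero load
    d = np.concatenate([d, [d[-1] + sampling_step, d[-1] + 2 * sampling_step]])
    load = np.concatenate([load, [0.0, 0.0]])
    if noise_sd > 0:
        load = load + rng.normal(0.0, noise_sd, size=load.size)
    load = np.clip(load, 0.0, None)
    return LoadDisplacementCurve(displacement=d, load=load)


def expected_offset_yield(
    truth: BendingGroundTruth, offset: float = 0.015
) -> tuple[float, float] | None:
    """Analytic offset-yield point of the noise-free bilinear curve.

    The offset line ``S (d - offset)`` intersects the hardening branch at
    d = (F_y - h d_y + S offset) / (S - h); returns None when the
    intersection falls beyond the fracture displacement (pop-ins before
    the intersection are not accounted for).
    """
    s = truth.elastic_slope
    h = truth.hardening_slope
    if h >= s:
        return None
    d_y = truth.yield_displacement
    d_star = (truth.yield_load - h * d_y + s * offset) / (s - h)
    if d_star > truth.fracture_displacement:
        return None
    return d_star, s * (d_star - offset)


# ---------------------------------------------------------------------------
# voxel phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """A hollow-tube density phantom with calibration inserts.

    Radius profiles are per-axial-slice arrays (mm); ``density`` is either
    a scalar (uniform mineral density, mgHA/cm^3) or a per-slice array.
    The attenuation map is affine: attenuation = slope * density +
    intercept (arbitrary units).  Calibration inserts are synthesized as
    separate uniform sub-volumes, mirroring phantoms scanned alongside the
    specimen.
    """

    outer_radius_profile: np.ndarray  # mm per axial slice
    inner_radius_profile: np.ndarray
    density: float | np.ndarray = 800.0  # mgHA/cm^3
    voxel_spacing: float = 0.010  # mm, isotropic
    calibration_densities: tuple[float, ...] = (0.0, 50.0, 200.0, 800.0, 1200.0)
    attenuation_slope: float = 1.0  # a.u. per mgHA/cm^3
    attenuation_intercept: float = 0.0  # a.u.
    noise_sd: float = 0.0  # a.u., additive attenuation noise
    margin: float = 0.05  # mm of background around the tube
    max_voxels: int = 20_000_000

    def __post_init__(self) -> None:
        ro = np.atleast_1d(np.asarray(self.outer_radius_profile, dtype=float))
        ri = np.atleast_1d(np.asarray(self.inner_radius_profile, dtype=float))
        object.__setattr__(self, "outer_radius_profile", ro)
        object.__setattr__(self, "inner_radius_profile", ri)
        if ro.shape != ri.shape:
            raise ValueError("radius profiles must have equal length")
        if np.any(ri < 0) or np.any(ri >= ro):
            raise ValueError("require 0 <= inner < outer radius everywhere")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if 0.0 not in self.calibration_densities:
            raise ValueError("calibration densities must include 0")
        dens = np.asarray(self.density, dtype=float)
        if dens.ndim == 1 and dens.shape != ro.shape:
            raise ValueError("per-slice density must match the radius profiles")

    @property
    def n_slices(self) -> int:
        return int(self.outer_radius_profile.size)

    @property
    def length(self) -> float:
        """Axial extent in mm."""
        return self.n_slices * self.voxel_spacing

    def density_profile(self) -> np.ndarray:
        dens = np.asarray(self.density, dtype=float)
        if dens.ndim == 0:
            return np.full(self.n_slices, float(dens))
        return dens


@dataclass
class PhantomVolume:
    """Generated phantom: raw attenuation volume, inserts, and ground truth."""

    volume: VoxelVolume  # raw attenuation, uncalibrated
    insert_attenuation: dict[float, np.ndarray]  # density -> insert sub-volume
    phantom_readings: pd.DataFrame  # columns: density_mgHA_cm3, mean_attenuation
    bone_mask_true: np.ndarray  # exact bone voxels (noise-free membership)
    truth_per_block: pd.DataFrame  # analytic block BV/TV, BMC (g), BMD (g/cm^3)
    truth_whole: dict[str, float]


def _analytic_block_truth(spec: PhantomSpec, n_blocks: int, tv_area_mm2: float) -> pd.DataFrame:
    """Block-wise ground truth integrated from the radius profiles."""
    ro = spec.outer_radius_profile
    ri = spec.inner_radius_profile
    dens = spec.density_profile()
    slice_area = math.pi * (ro**2 - ri**2)  # mm^2 of bone per slice
    h = spec.voxel_spacing
    rows = []
    for b, idx in enumerate(np.array_split(np.arange(spec.n_slices), n_blocks)):
        bv = float(np.sum(slice_area[idx])) * h  # mm^3
        tv = tv_area_mm2 * h * idx.size
        bmc_g = float(np.sum(dens[idx] * slice_area[idx])) * h * 1e-6  # g
        bmd = bmc_g / (bv * 1e-3) if bv > 0 else np.nan  # g/cm^3
        rows.append({"block": b + 1, "bvtv": bv / tv, "bmc_g": bmc_g, "bmd_g_cm3": bmd})
    return pd.DataFrame(rows)


def generate_phantom_volume(
    spec: PhantomSpec,
    seed: int | np.random.Generator | None = None,
    n_blocks: int = 7,
    insert_shape: tuple[int, int, int] = (8, 8, 8),
) -> PhantomVolume:
    """Voxelize a hollow-tube phantom and its calibration inserts.

    Voxels whose centres fall between the inner and outer radius carry the
    slice density mapped through the affine attenuation map; everything
    else is background (density 0).  Gaussian attenuation noise of sd
    ``spec.noise_sd`` is added to the tube volume and the inserts alike.
    Analytic per-block ground truth (BV/TV, BMC, BMD) is integrated
    directly from the radius profiles.
    """
    rng = _rng(seed)
    n_blocks = min(n_blocks, spec.n_slices)
    h = spec.voxel_spacing
    half_extent = float(spec.outer_radius_profile.max()) + spec.margin
    n_xy = 2 * int(math.ceil(half_extent / h)) + 1
    n_vox = spec.n_slices * n_xy * n_xy
    if n_vox > spec.max_voxels:
        raise ValueError(
            f"volume of {n_vox} voxels exceeds the budget of {spec.max_voxels}; "
            "coarsen voxel_spacing or shorten the profiles"
        )
    coords = (np.arange(n_xy) - (n_xy - 1) / 2) * h  # voxel centres, mm
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    r2 = xx**2 + yy**2
    dens = spec.density_profile()
    values = np.empty((spec.n_slices, n_xy, n_xy))
    mask = np.empty((spec.n_slices, n_xy, n_xy), dtype=bool)
    for k in range(spec.n_slices):
        ring = (r2 >= spec.inner_radius_profile[k] ** 2) & (
            r2 < spec.outer_radius_profile[k] ** 2
        )
        mask[k] = ring
        values[k] = np.where(ring, dens[k], 0.0)
    atten = spec.attenuation_slope * values + spec.attenuation_intercept
    if spec.noise_sd > 0:
        atten = atten + rng.normal(0.0, spec.noise_sd, size=atten.shape)
    inserts: dict[float, np.ndarray] = {}
    readings = []
    for d in spec.calibration_densities:
        block = np.full(insert_shape, spec.attenuation_slope * d + spec.attenuation_intercept)
        if spec.noise_sd > 0:
            block = block + rng.normal(0.0, spec.noise_sd, size=insert_shape)
        inserts[float(d)] = block
        readings.append(
            {"density_mgHA_cm3": float(d), "mean_attenuation": float(block.mean())}
        )
    tv_area = (n_xy * h) ** 2
    truth = _analytic_block_truth(spec, n_blocks, tv_area)
    whole = {
        "bmc_g": float(truth["bmc_g"].sum()),
        "bvtv": float(
            np.average(truth["bvtv"], weights=[1.0] * len(truth))
        ),
        "bmd_g_cm3": float(truth["bmc_g"].sum())
        / max(float(np.sum(math.pi * (spec.outer_radius_profile**2 - spec.inner_radius_profile**2)) * h * 1e-3), 1e-300),
    }
    return PhantomVolume(
        volume=VoxelVolume(values=atten, spacing=(h, h, h), calibrated=False),
        insert_attenuation=inserts,
        phantom_readings=pd.DataFrame(readings),
        bone_mask_true=mask,
        truth_per_block=truth,
        truth_whole=whole,
    )


# ---------------------------------------------------------------------------
# cohort tables


@dataclass(frozen=True)
class GroupMeans:
    """Endpoint group means (g) driving the linear trajectories."""

    start_weight: float
    final_weight: float
    start_lean: float
    final_lean: float
    start_fat: float
    final_fat: float

    def __post_init__(self) -> None:
        for v in (
            self.start_weight, self.final_weight, self.start_lean,
            self.final_lean, self.start_fat, self.final_fat,
        ):
            if v < 0:
                raise ValueError("masses must be non-negative")
        if self.start_weight <= 0 or self.final_weight <= 0:
            raise ValueError("body weights must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: per-group endpoint means, dispersion, and size."""

    group_means: dict[str, GroupMeans]
    weekly_noise_sd: float = 0.0  # g, on every channel
    n_per_group: int = 6
    n_weeks: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("at least 2 animals per group are required")
        if self.weekly_noise_sd < 0:
            raise ValueError("weekly_noise_sd must be non-negative")
        if self.n_weeks < 1:
            raise ValueError("at least one study week is required")


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Tidy longitudinal cohort table.

    Columns: animal_id, group, week (0 = start of the study period),
    body_weight_g, lean_g, fat_g.  Each animal's trajectory interpolates
    the group endpoint means linearly with iid Gaussian noise per
    animal-week; lean + fat never exceeds total weight (both are rescaled
    when noise pushes them over).  Deterministic under a fixed seed.
    """
    rng = _rng(spec.seed if seed is None else seed)
    frac = np.arange(spec.n_weeks + 1) / spec.n_weeks
    rows = []
    for group in sorted(spec.group_means):
        gm = spec.group_means[group]
        bw_mean = gm.start_weight + frac * (gm.final_weight - gm.start_weight)
        lean_mean = gm.start_lean + frac * (gm.final_lean - gm.start_lean)
        fat_mean = gm.start_fat + frac * (gm.final_fat - gm.start_fat)
        for a in range(spec.n_per_group):
            animal = f"{group}_{a + 1:02d}"
            noise = (
                rng.normal(0.0, spec.weekly_noise_sd, size=(3, spec.n_weeks + 1))
                if spec.weekly_noise_sd > 0
                else np.zeros((3, spec.n_weeks + 1))
            )
            bw = np.maximum(bw_mean + noise[0], 0.1)
            lean = np.maximum(lean_mean + noise[1], 0.0)
            fat = np.maximum(fat_mean + noise[2], 0.0)
            soft = lean + fat
            over = soft > bw
            scale = np.where(over, bw / np.maximum(soft, 1e-12), 1.0)
            lean, fat = lean * scale, fat * scale
            for w in range(spec.n_weeks + 1):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "week": w,
                        "body_weight_g": bw[w],
                        "lean_g": lean[w],
                        "fat_g": fat[w],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diet composition


@dataclass(frozen=True)
class OmegaFractions:
    """Mass-weighted omega-3/6/9 percentages of total fat, with intervals."""

    omega3: float
    omega6: float
    omega9: float
    omega3_interval: tuple[float, float]
    omega6_interval: tuple[float, float]
    omega9_interval: tuple[float, float]

    def as_tuple(self) -> tuple[float, float, float]:
        return self.omega3, self.omega6, self.omega9


def _as_interval(x: float | tuple[float, float]) -> tuple[float, float]:
    if isinstance(x, tuple):
        lo, hi = float(x[0]), float(x[1])
    else:
        lo = hi = float(x)
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"composition fraction out of [0, 1]: {x}")
    return lo, hi


def diet_omega_fractions(
    fat_ingredients: list[
        tuple[float, tuple[float | tuple[float, float], ...]]
    ],
) -> OmegaFractions:
    """Omega-3/6/9 percentages of a fat blend.

    ``fat_ingredients`` holds (mass in g, (w3, w6, w9)) entries where each
    composition component is a fraction in [0, 1] or a (low, high) range
    (published oil compositions are often ranges).  Point estimates use
    range midpoints; intervals propagate the ranges.  The three point
    estimates always sum to at most 100 %.
    """
    if not fat_ingredients:
        raise ValueError("at least one fat ingredient is required")
    total = 0.0
    lo = np.zeros(3)
    hi = np.zeros(3)
    mid = np.zeros(3)
    for mass, comp in fat_ingredients:
        if mass <= 0:
            raise ValueError("ingredient masses must be positive")
        if len(comp) != 3:
            raise ValueError("composition must be an (w3, w6, w9) triple")
        total += mass
        for k, c in enumerate(comp):
            a, b = _as_interval(c)
            lo[k] += mass * a
            hi[k] += mass * b
            mid[k] += mass * 0.5 * (a + b)
    pct = 100.0 * mid / total
    ints = [(100.0 * lo[k] / total, 100.0 * hi[k] / total) for k in range(3)]
    return OmegaFractions(
        omega3=float(pct[0]),
        omega6=float(pct[1]),
        omega9=float(pct[2]),
        omega3_interval=ints[0],
        omega6_interval=ints[1],
        omega9_interval=ints[2],
    )
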