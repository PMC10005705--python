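"""Three-point-bending analysis of whole-bone load-displacement curves.

The tibial midshaft is idealized as a circular tube loaded at the midpoint
of a span ``L``.  Under that beam model the standard relations are

    sigma = F * L * c_o / (4 * I)          (outer-fibre bending stress)
    E     = (F/d) * L^3 / (48 * I)         (elastic modulus from stiffness)
    I     = pi/4 * (c_o^4 - c_i^4)         (second moment of a circular tube)
    A     = pi * (c_o^2 - c_i^2)           (annulus cross-sectional area)

with ``c_o``/``c_i`` the outer/inner midshaft radii.  Units are mm, N and
MPa throughout; the modulus is reported in GPa.

The yield point is located with the offset method: a line parallel to the
initial linear portion of the load-displacement curve, shifted 0.015 mm
along the displacement axis, intersected with the measured curve.  The
post-yield displacement (PYD, a ductility measure) is the displacement from
the yield point to the fracture point.  Sudden partial load drops before
fracture ("pop-in" events, attributed to microcrack growth) are detected by
a relative-drop threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TubeGeometry",
    "LoadDisplacementCurve",
    "BendingResult",
    "BodySize",
    "PopinEvent",
    "moment_of_inertia",
    "cross_sectional_area",
    "stress_at",
    "linear_slope",
    "elastic_modulus",
    "find_yield",
    "key_points",
    "detect_popins",
    "normalize_by_body_size",
    "inner_radius_from_ratio",
    "analyze_curve",
]

#: Displacement offset (mm) for the offset-yield construction.
DEFAULT_YIELD_OFFSET_MM = 0.015

#: Terminal load drop below this fraction of the ultimate load marks fracture.
DEFAULT_FRACTURE_FRACTION = 0.10

#: Relative load drop between successive samples that counts as a pop-in.
DEFAULT_POPIN_THRESHOLD = 0.05


@dataclass(frozen=True)
class TubeGeometry:
    """Idealized circular cross-section of a long-bone midshaft.

    Parameters
    ----------
    outer_radius, inner_radius
        Midshaft radii ``c_o`` and ``c_i`` in mm; ``0 <= c_i < c_o``.
    span
        Distance between the support bars in mm.
    tibial_length
        Whole-bone length in mm (optional; used for body-size scaling).
    """

    outer_radius: float
    inner_radius: float = 0.0
    span: float = 6.0
    tibial_length: float | None = None

    def __post_init__(self) -> None:
        if not self.outer_radius > 0:
            raise ValueError("outer radius must be positive")
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError(
                f"inner radius must satisfy 0 <= ci < co, got "
                f"ci={self.inner_radius}, co={self.outer_radius}"
            )
        if not self.span > 0:
            raise ValueError("span must be positive")


@dataclass(frozen=True)
class LoadDisplacementCurve:
    """A sampled bending record: displacement (mm) vs load (N)."""

    displacement: np.ndarray
    load: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "load", f)
        if d.ndim != 1 or f.shape != d.shape:
            raise ValueError("displacement and load must be 1-D arrays of equal length")
        if d.size < 10:
            raise ValueError("curve must have at least 10 samples")
        if not np.all(np.diff(d) > 0):
            raise ValueError("displacement must be strictly increasing")

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class PopinEvent:
    """A sudden partial load drop between successive samples."""

    displacement: float  # mm, position of the sample after the drop
    drop: float  # N, magnitude of the load decrease
    fraction: float  # drop relative to the pre-drop load


@dataclass
class BendingResult:
    """Structural and material outputs of one bending test."""

    yield_stress: float  # MPa
    ultimate_stress: float  # MPa
    fracture_stress: float  # MPa
    elastic_modulus: float  # GPa
    pyd: float  # mm
    area: float  # mm^2
    moment_of_inertia: float  # mm^4
    yield_point: tuple[float, float]  # (mm, N)
    ultimate_point: tuple[float, float]
    fracture_point: tuple[float, float]
    stiffness: float  # N/mm, slope of the linear region
    fit_r_squared: float
    popin_events: list[PopinEvent] = field(default_factory=list)
    yield_detected: bool = True
    fracture_flagged: bool = False
    normalized: bool = False
    normalization_factor: float | None = None


@dataclass(frozen=True)
class BodySize:
    """Body-size covariate: strength is scaled by body_weight/tibial_length."""

    body_weight: float  # g
    tibial_length: float  # mm

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.tibial_length <= 0:
            raise ValueError("body weight and tibial length must be positive")

    @property
    def factor(self) -> float:
        return self.body_weight / self.tibial_length


def moment_of_inertia(geometry: TubeGeometry) -> float:
    """Second moment of area ``pi/4 (co^4 - ci^4)`` of a circular tube, mm^4."""
    co, ci = geometry.outer_radius, geometry.inner_radius
    return math.pi / 4.0 * (co**4 - ci**4)


def cross_sectional_area(geometry: TubeGeometry) -> float:
    """Annulus area ``pi (co^2 - ci^2)`` = ``pi/4 (do^2 - di^2)``, mm^2."""
    co, ci = geometry.outer_radius, geometry.inner_radius
    return math.pi * (co**2 - ci**2)


def stress_at(load: float, geometry: TubeGeometry) -> float:
    """Outer-fibre bending stress ``F L co / (4 I)`` at midspan, MPa.

    With load in N and lengths in mm the expression is already in
    N/mm^2 = MPa, so no unit conversion is needed.
    """
    if load < 0:
        raise ValueError("load must be non-negative")
    return load * geometry.span * geometry.outer_radius / (4.0 * moment_of_inertia(geometry))


def _rise_region(curve: LoadDisplacementCurve, fit_window: float) -> slice:
    """Index range of the initial linear region.

    The region is the ``fit_window`` central fraction of the rise to half
    the maximum load, which excludes both the toe-in at contact and the
    plastic region near the peak.
    """
    load = curve.load
    half = 0.5 * float(load.max())
    above = np.nonzero(load >= half)[0]
    end = int(above[0]) if above.size else len(load) - 1
    end = max(end, 3)
    lo = int(round(end * 0.5 * (1.0 - fit_window)))
    hi = int(round(end * (0.5 * (1.0 - fit_window) + fit_window)))
    hi = max(hi, lo + 3)
    return slice(lo, min(hi + 1, len(load)))


def linear_slope(
    curve: LoadDisplacementCurve, fit_window: float = 0.6
) -> tuple[float, float]:
    """Least-squares slope (N/mm) of the initial linear region, with R^2.

    ``fit_window`` is the fraction of the rise to half-maximum load kept
    for the fit, centred within that rise (the default 0.6 keeps the
    20-80 % segment).
    """
    if not 0 < fit_window <= 1:
        raise ValueError("fit_window must lie in (0, 1]")
    sel = _rise_region(curve, fit_window)
    d = curve.displacement[sel]
    f = curve.load[sel]
    if d.size < 3:
        raise ValueError("fewer than 3 samples in the linear-fit window")
    slope, intercept = np.polyfit(d, f, 1)
    resid = f - (slope * d + intercept)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def elastic_modulus(slope: float, geometry: TubeGeometry) -> float:
    """Elastic modulus ``(F/d) L^3 / (48 I)`` in GPa.

    ``slope`` is the load-displacement stiffness in N/mm; N/mm * mm^3 / mm^4
    = MPa, divided by 1000 for GPa.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    e_mpa = slope * geometry.span**3 / (48.0 * moment_of_inertia(geometry))
    return e_mpa / 1000.0


def find_yield(
    curve: LoadDisplacementCurve,
    slope: float,
    offset: float = DEFAULT_YIELD_OFFSET_MM,
    end_index: int | None = None,
) -> tuple[float, float] | None:
    """Offset-yield point: first crossing of ``load = slope*(d - offset)``.

    The offset line runs parallel to the linear portion of the curve,
    shifted ``offset`` mm along the displacement axis.  The crossing is
    linearly interpolated between samples.  Returns ``None`` when the
    curve never falls onto the offset line before ``end_index``
    (e.g. a purely linear record).
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if slope <= 0:
        raise ValueError("slope must be positive")
    d = curve.displacement
    f = curve.load
    stop = len(d) if end_index is None else end_index + 1
    # g > 0 while the curve lies above the offset line
    g = f[:stop] - slope * (d[:stop] - offset)
    sign_change = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0]
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    t = g[i] / (g[i] - g[i + 1])
    dy = d[i] + t * (d[i + 1] - d[i])
    fy = f[i] + t * (f[i + 1] - f[i])
    return float(dy), float(fy)


def key_points(
    curve: LoadDisplacementCurve,
    fracture_fraction: float = DEFAULT_FRACTURE_FRACTION,
) -> tuple[tuple[float, float], tuple[float, float], bool]:
    """Ultimate and fracture points of a test run to failure.

    The ultimate point is the global load maximum.  The fracture point is
    the last sample before the terminal drop below ``fracture_fraction``
    of the ultimate load; when the record never drops (test stopped before
    failure) the last sample is returned and flagged.

    Returns ``(ultimate, fracture, flagged)`` with points as (mm, N).
    """
    d, f = curve.displacement, curve.load
    i_ult = int(np.argmax(f))
    ultimate = (float(d[i_ult]), float(f[i_ult]))
    floor = fracture_fraction * f[i_ult]
    below = np.nonzero(f[i_ult:] < floor)[0]
    if below.size == 0:
        return ultimate, (float(d[-1]), float(f[-1])), True
    i_frac = i_ult + int(below[0]) - 1
    return ultimate, (float(d[i_frac]), float(f[i_frac])), False


def detect_popins(
    curve: LoadDisplacementCurve,
    drop_fraction: float = DEFAULT_POPIN_THRESHOLD,
) -> list[PopinEvent]:
    """Pop-in events: relative load drops exceeding ``drop_fraction``.

    An event is recorded where the load decreases between successive
    samples by more than ``drop_fraction`` of the pre-drop load.  The
    terminal fracture drop (at or beyond the fracture point) is excluded.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must lie in (0, 1)")
    d, f = curve.displacement, curve.load
    _, (d_frac, _), _ = key_points(curve)
    events: list[PopinEvent] = []
    for i in range(len(f) - 1):
        if d[i + 1] > d_frac:
            break
        if f[i] <= 0:
            continue
        drop = f[i] - f[i + 1]
        if drop > drop_fraction * f[i]:
            events.append(
                PopinEvent(
                    displacement=float(d[i + 1]),
                    drop=float(drop),
                    fraction=float(drop / f[i]),
                )
            )
    return events


def normalize_by_body_size(result: BendingResult, body: BodySize) -> BendingResult:
    """Scale strength outputs by the body-weight-to-tibial-length ratio.

    All four strength/stiffness parameters (yield, ultimate and fracture
    stress, and the elastic modulus) are divided by
    ``body_weight / tibial_length``; the factor is recorded so the raw
    values can be restored exactly.
    """
    if result.normalized:
        raise ValueError("result is already body-size normalized")
    k = body.factor
    return replace(
        result,
        yield_stress=result.yield_stress / k,
        ultimate_stress=result.ultimate_stress / k,
        fracture_stress=result.fracture_stress / k,
        elastic_modulus=result.elastic_modulus / k,
        normalized=True,
        normalization_factor=k,
    )


def inner_radius_from_ratio(
    outer_radius: float, ratio_samples: list[tuple[float, float]]
) -> float:
    """Inner radius from the mean inner-to-outer diameter ratio.

    ``ratio_samples`` holds (inner diameter, outer diameter) pairs measured
    on cross-sections of a scanned specimen; the mean of the per-section
    ratios (not the ratio of means) scales ``outer_radius``.
    """
    if not ratio_samples:
        raise ValueError("at least one (di, do) pair is required")
    ratios = []
    for di, do in ratio_samples:
        if not 0 <= di < do:
            raise ValueError(f"require 0 <= di < do, got di={di}, do={do}")
        ratios.append(di / do)
    return outer_radius * float(np.mean(ratios))


def analyze_curve(
    curve: LoadDisplacementCurve,
    geometry: TubeGeometry,
    body: BodySize | None = None,
    *,
    fit_window: float = 0.6,
    offset: float = DEFAULT_YIELD_OFFSET_MM,
    fracture_fraction: float = DEFAULT_FRACTURE_FRACTION,
    popin_threshold: float = DEFAULT_POPIN_THRESHOLD,
) -> BendingResult:
    """Full analysis of one bending record.

    Fits the linear region, locates the offset-yield, ultimate and
    fracture points, converts loads to outer-fibre stresses, detects
    pop-ins, and optionally normalizes strength outputs by body size.
    When no yield is detected the ultimate point stands in for it (flagged
    via ``yield_detected=False``).
    """
    slope, r2 = linear_slope(curve, fit_window)
    ultimate, fracture, frac_flagged = key_points(curve, fracture_fraction)
    i_frac = int(np.searchsorted(curve.displacement, fracture[0]))
    yp = find_yield(curve, slope, offset, end_index=i_frac)
    yield_detected = yp is not None
    if yp is None:
        yp = ultimate
    pyd = max(fracture[0] - yp[0], 0.0)
    result = BendingResult(
        yield_stress=stress_at(yp[1], geometry),
        ultimate_stress=stress_at(ultimate[1], geometry),
        fracture_stress=stress_at(fracture[1], geometry),
        elastic_modulus=elastic_modulus(slope, geometry),
        pyd=pyd,
        area=cross_sectional_area(geometry),
        moment_of_inertia=moment_of_inertia(geometry),
        yield_point=yp,
        ultimate_point=ultimate,
        fracture_point=fracture,
        stiffness=slope,
        fit_r_squared=r2,
        popin_events=detect_popins(curve, popin_threshold),
        yield_detected=yield_detected,
        fracture_flagged=frac_flagged,
    )
    if body is not None:
        result = normalize_by_body_size(result, body)
    return result
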