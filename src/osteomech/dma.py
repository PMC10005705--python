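"""Dynamic mechanical analysis: storage/loss moduli from sinusoidal traces.

A specimen driven by a sinusoidal stress sigma(t) = sigma_0 + sigma_a
sin(2 pi f t) responds, in steady state, with a sinusoidal strain lagging
the stress by the phase angle delta.  The complex-modulus decomposition

    |E*|  = sigma_a / eps_a
    E'    = |E*| cos(delta)     (storage modulus, elastic energy storage)
    E''   = |E*| sin(delta)     (loss modulus, viscous dissipation)
    tan delta = E'' / E'        (damping capacity)

is evaluated per drive frequency; a sweep over frequencies yields the
viscoelastic spectrum.  Amplitudes and phases are extracted by linear
least squares against quadrature sinusoids at the known drive frequency,
which stays stable on the short records a 0.05 Hz test allows (an FFT
peak-pick would not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DMATrace",
    "SinusoidFit",
    "ViscoelasticSpectrum",
    "fit_sinusoid",
    "viscoelastic_moduli",
    "frequency_sweep",
    "hysteresis_energy",
    "fit_sls_spectrum",
]


@dataclass(frozen=True)
class DMATrace:
    """One steady-state record at a single drive frequency.

    time in s (uniformly sampled), stress in MPa, strain dimensionless;
    at least 3 full cycles are required for a stable phase estimate.
    """

    time: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    frequency: float  # Hz

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        e = np.asarray(self.strain, dtype=float)
        for name, arr in (("time", t), ("stress", s), ("strain", e)):
            if arr.ndim != 1 or arr.shape != t.shape:
                raise ValueError(f"{name} must be a 1-D array matching time")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stress", s)
        object.__setattr__(self, "strain", e)
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time must be uniformly sampled")
        span = t[-1] - t[0] if t.size else 0.0
        if span * self.frequency < 3.0 - 1e-9:
            raise ValueError("trace must cover at least 3 full cycles")


@dataclass(frozen=True)
class SinusoidFit:
    amplitude: float
    phase: float  # rad, of a + amp*sin(2 pi f t + phase)
    offset: float
    residual_se: float


@dataclass
class ViscoelasticSpectrum:
    """E', E'' and tan(delta) per frequency, ordered by frequency."""

    frequency: list[float]
    storage_modulus: list[float]  # MPa
    loss_modulus: list[float]  # MPa
    loss_tangent: list[float]
    phase_lag: list[float] = field(default_factory=list)  # rad
    strain_amplitude: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frequency)

    def loss_vs_storage(self) -> list[tuple[float, float]]:
        """(E', E'') pairs for a loss-versus-storage scatter."""
        return list(zip(self.storage_modulus, self.loss_modulus))


def fit_sinusoid(
    signal: np.ndarray, time: np.ndarray, frequency: float
) -> SinusoidFit:
    """Least-squares fit of ``a + b sin(wt) + c cos(wt)`` at a known frequency.

    The model is linear in (a, b, c), so the minimum is unique; amplitude
    is sqrt(b^2+c^2) and phase atan2(c, b), i.e. the signal is represented
    as ``a + amplitude * sin(wt + phase)``.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if signal.size < 6:
        raise ValueError("at least 6 samples are required")
    w = 2.0 * np.pi * frequency
    design = np.column_stack(
        [np.ones_like(time), np.sin(w * time), np.cos(w * time)]
    )
    coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
    a, b, c = coef
    resid = signal - design @ coef
    dof = max(signal.size - 3, 1)
    return SinusoidFit(
        amplitude=float(np.hypot(b, c)),
        phase=float(np.arctan2(c, b)),
        offset=float(a),
        residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def _discard_first_cycle(trace: DMATrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # the start-up transient of a relaxing specimen decays over ~tau and
    # contaminates the phase estimate; one full cycle is dropped
    t0 = trace.time[0] + 1.0 / trace.frequency
    keep = trace.time >= t0 - 1e-12
    return trace.time[keep], trace.stress[keep], trace.strain[keep]


def viscoelastic_moduli(trace: DMATrace) -> tuple[float, float, float]:
    """(E', E'', tan delta) of one trace, moduli in the stress units.

    The phase lag delta = phase(stress) - phase(strain) is wrapped to
    [0, pi/2]: physical dissipation cannot be negative.  A strain
    amplitude indistinguishable from zero signals an unmeasurable
    specimen.
    """
    t, stress, strain = _discard_first_cycle(trace)
    fs = fit_sinusoid(stress, t, trace.frequency)
    fe = fit_sinusoid(strain, t, trace.frequency)
    if fe.amplitude <= 1e-12 * max(fs.amplitude, 1.0):
        raise ValueError("strain amplitude is ~0: unmeasurable specimen")
    delta = fs.phase - fe.phase
    delta = (delta + np.pi) % (2.0 * np.pi) - np.pi  # principal value
    delta = min(max(delta, 0.0), np.pi / 2.0)
    e_star = fs.amplitude / fe.amplitude
    e_storage = e_star * np.cos(delta)
    e_loss = e_star * np.sin(delta)
    return float(e_storage), float(e_loss), float(e_loss / e_storage)


def frequency_sweep(traces: list[DMATrace]) -> ViscoelasticSpectrum:
    """Viscoelastic spectrum over a set of single-frequency traces."""
    if not traces:
        raise ValueError("at least one trace is required")
    freqs = [tr.frequency for tr in traces]
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate frequencies in sweep")
    spectrum = ViscoelasticSpectrum([], [], [], [], [], [])
    for tr in sorted(traces, key=lambda tr: tr.frequency):
        e1, e2, tand = viscoelastic_moduli(tr)
        t, _, strain = _discard_first_cycle(tr)
        fe = fit_sinusoid(strain, t, tr.frequency)
        spectrum.frequency.append(tr.frequency)
        spectrum.storage_modulus.append(e1)
        spectrum.loss_modulus.append(e2)
        spectrum.loss_tangent.append(tand)
        spectrum.phase_lag.append(float(np.arctan2(e2, e1)))
        spectrum.strain_amplitude.append(fe.amplitude)
    return spectrum


def hysteresis_energy(trace: DMATrace) -> float:
    """Energy dissipated per cycle from the stress-strain hysteresis loop.

    Trapezoidal integration of the loop area over the whole-cycle portion
    of the record, averaged per cycle.  For a linear viscoelastic material
    this equals pi * E'' * eps_a^2, which serves as an identity check on
    the fitted loss modulus.
    """
    t, stress, strain = _discard_first_cycle(trace)
    n_cycles = np.floor((t[-1] - t[0]) * trace.frequency + 1e-9)
    if n_cycles < 1:
        raise ValueError("less than one full cycle after transient removal")
    t_end = t[0] + n_cycles / trace.frequency
    keep = t <= t_end + 1e-12
    # closed-loop integral of sigma d(eps)
    area = float(np.trapezoid(stress[keep], strain[keep]))
    return abs(area) / n_cycles


def fit_sls_spectrum(
    spectrum: ViscoelasticSpectrum, initial: tuple[float, float, float] | None = None
) -> tuple[float, float, float]:
    """Least-squares standard-linear-solid parameters from a spectrum.

    Fits (E_inst, E_eq, tau) of the three-parameter solid, whose moduli are
    E'(w) = E_eq + (E_inst - E_eq) (w tau)^2 / (1 + (w tau)^2) and
    E''(w) = (E_inst - E_eq) (w tau) / (1 + (w tau)^2), jointly to the
    measured E' and E''.
    """
    from scipy.optimize import least_squares

    w = 2.0 * np.pi * np.asarray(spectrum.frequency)
    e1 = np.asarray(spectrum.storage_modulus)
    e2 = np.asarray(spectrum.loss_modulus)
    if initial is None:
        initial = (float(e1.max()), float(e1.min()), float(1.0 / w[len(w) // 2]))

    def resid(p: np.ndarray) -> np.ndarray:
        e_inst, e_eq, tau = p
        wt = w * tau
        pred1 = e_eq + (e_inst - e_eq) * wt**2 / (1 + wt**2)
        pred2 = (e_inst - e_eq) * wt / (1 + wt**2)
        return np.concatenate([pred1 - e1, pred2 - e2])

    sol = least_squares(
        resid, x0=np.asarray(initial, dtype=float),
        bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
    )
    e_inst, e_eq, tau = sol.x
    return float(e_inst), float(e_eq), float(tau)
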