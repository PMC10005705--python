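"""Dynamic mechanical analysis of a viscoelastic tibia model.

Simulates the four-frequency sweep (0.05, 0.1, 1, 10 Hz) of a
standard-linear-solid specimen under a 0.25 MPa stress sinusoid and
extracts storage modulus E', loss modulus E'' and loss tangent from the
traces, comparing against the closed-form ground truth.
"""

from osteomech.dma import frequency_sweep
from osteomech.synthetic import DMAProtocol, SLSParams, generate_dma_trace, sls_moduli

params = SLSParams(E_inst=2.47, E_eq=1.59, tau=1.37, noise_sd=1e-4)
protocol = DMAProtocol()  # stress 0.75 +/- 0.25 MPa

traces = [
    generate_dma_trace(params, protocol, f, seed=i).trace
    for i, f in enumerate(protocol.frequencies)
]
spectrum = frequency_sweep(traces)

print(f"{'f (Hz)':>8} {'E_fit':>7} {'E_true':>7} {'E__fit':>7} {'tan_d':>6}")
for f, e1, e2, tand in zip(
    spectrum.frequency, spectrum.storage_modulus,
    spectrum.loss_modulus, spectrum.loss_tangent,
):
    e1_true, _, _ = sls_moduli(params, f)
    print(f"{f:8.2f} {e1:7.3f} {e1_true:7.3f} {e2:7.3f} {tand:6.3f}")
# E' rises with frequency (the material stiffens as the viscous arm locks
# up); E'' peaks near omega*tau = 1; the fitted values track the closed
# form to within the planted noise.
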