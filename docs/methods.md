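# Methods

This note documents the models, numerical choices and limitations behind
`osteomech`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Beam model of the bending test

The midshaft is treated as a straight, homogeneous circular tube in
Euler-Bernoulli bending over a 6 mm span. Outer-fibre stress
σ = F L c_o / (4 I), stiffness-to-modulus conversion
E = (F/d) L³ / (48 I), second moment I = π/4 (c_o⁴ − c_i⁴), and annulus
area A = π (c_o² − c_i²). Units are mm, N, MPa (N/mm²) throughout; E is
reported in GPa. Shear deformation, non-circularity and longitudinal
taper are ignored — the usual idealization for mouse tibiae, and the one
the area/moment reference values assume.

The inner radius of a specimen that was tested to destruction is
recovered from scanned litter-mates as c_o × mean(d_i/d_o) over several
cross-sections. The mean of per-section ratios is used, not the ratio of
means; the two differ on heterogeneous sections and the former is the
estimator matching the per-section measurement protocol.

### Yield, fracture, pop-ins

* **Linear region.** Published protocols rarely state how the "initial
  linear portion" is delimited, so the choice is exposed. Default: the central 60% of the
  rise to half-maximum load (i.e. the 20–80% segment), which excludes
  both the toe-in at contact and early plasticity. The window is a
  parameter; fits report R², and curves with R² < 0.99 deserve manual
  review.
* **Offset yield.** The yield point is the first crossing of the curve
  with load = S·(d − 0.015 mm), S the fitted slope, linearly interpolated
  between samples. The offset is applied on the displacement axis of the
  load-displacement plot (not on a strain axis). A purely linear record
  has no crossing and is reported as "no yield detected".
* **Key points.** Ultimate = global load maximum. Fracture = last sample
  before the terminal drop below 10% of ultimate load (configurable); a
  record that never drops is censored: the last sample is used and
  flagged. PYD = d_fracture − d_yield.
* **Pop-ins.** A pop-in is a between-sample load drop exceeding 5% of the
  pre-drop load (configurable), excluding the terminal fracture drop.
  The threshold trades sensitivity against load-cell noise; 5% sits well
  above the default synthetic noise (0.1 N on ~10 N signals).
* **Body-size normalization.** All four strength/stiffness outputs (σ_y,
  σ_u, σ_f, E) are divided by body_weight/tibial_length when a body size
  is supplied. Division (rather than regressing the covariate out) is the
  simple, transparent choice; the factor is recorded and exactly
  invertible, and raw values always remain available. Double
  normalization is rejected.

## Viscoelasticity

The dynamic stage assumes steady-state linear viscoelasticity: strain
responds to a stress sinusoid at the drive frequency with amplitude ratio
|E*| and lag δ. Amplitude and phase are extracted by least squares
against sin/cos at the *known* drive frequency — the model is linear in
its parameters, so the fit is unique and stable on the short records a
0.05 Hz test permits, where FFT peak-picking is not. The first cycle of
every trace is discarded before fitting because a relaxing specimen's
start-up transient (decaying over ~τ) contaminates the phase. δ is
clamped to [0, π/2]: physical dissipation cannot be negative, and small
negative noise-driven estimates are truncated to zero.

The synthetic material is the standard linear solid (spring E_eq in
parallel with a Maxwell arm), with

    E′(ω) = E_eq + ΔE (ωτ)²/(1+(ωτ)²),   E″(ω) = ΔE (ωτ)/(1+(ωτ)²),

ΔE = E_inst − E_eq. E″ peaks at ωτ = 1 with value ΔE/2; E′ runs from
E_eq (ω→0) to E_inst (ω→∞). Energy dissipated per cycle equals
π E″ ε_a², which the test suite verifies against trapezoidal integration
of the hysteresis loop. The default stress waveform is 0.75 ± 0.25 MPa
(mean ± amplitude): a 0.25 MPa amplitude spanning a 0.5 MPa min-to-max
range; both numbers are configurable. Each frequency is simulated as an
independent steady-state trace; the 60-minute isothermal dwell of a real
instrument is not modeled in time.

Per-group default SLS parameters in the pipeline (e.g. OVX:
E_inst = 2.47 MPa, E_eq = 1.59 MPa, τ = 1.37 s) were obtained by a
one-time least-squares fit of the SLS storage modulus to the reported
four-frequency group sweeps and then frozen. A single relaxation time
cannot reproduce a real bone's broad relaxation spectrum, so these
defaults reproduce the monotone E′(f) trend and the modulus scale, not
every printed point — they are study conditions, not fit targets.

## Micro-CT

* **Calibration.** Density = slope·attenuation + intercept by OLS through
  the five phantom readings (0, 50, 200, 800, 1200 mgHA/cm³). With exact
  affine attenuation the fit inverts the map exactly (R² = 1); mapped
  densities below zero are clipped to zero with a recorded count.
  Degenerate phantom tables (fewer than two distinct densities, or
  identical attenuations) are rejected.
* **Segmentation.** Global threshold, default 400 mgHA/cm³ — roughly
  midway between marrow-equivalent background and cortical bone in the
  synthetic phantoms. No protocol value exists to inherit, so the
  threshold is prominent in every API signature.
* **Regions.** The VOI starts at a user-supplied growth-plate plane
  (automatic detection is out of scope) and spans 80% of the remaining
  axial length, split into 7 equal axial blocks numbered proximal →
  distal. Sectors are assigned per transverse plane about the bone-mask
  centroid: the AP sector is the pair of 90° wedges whose offset from the
  centroid is predominantly antero-posterior, ML the orthogonal pair.
  This double-wedge partition makes AP + ML masses sum exactly to block
  mass (a tested invariant); a four-wedge quadrant mode (A/P/M/L) is
  available where finer laterality is wanted. Empty regions report
  missing (NaN), never zero, so downstream group means are not biased.
* **Units.** BMC in g (density mgHA/cm³ × voxel mm³ × 10⁻⁶), BMD in
  g/cm³, BV/TV dimensionless in [0, 1].
* **Diameters.** Per cross-section, the periosteal area is the hole-filled
  bone mask and the medullary area the fill minus the bone; equivalent
  circle diameters d = 2√(A/π). Non-annular sections report d_i = 0 with
  a flag.

## Exact statistics

U is computed from mid-rank sums. The null distribution is enumerated
over all C(n1+n2, n1) assignments of the pooled observations (ties
included via the observed multiset) whenever that count fits a budget
(default 200 000, covering 7 + 7 and beyond); otherwise the tie-corrected
normal approximation with continuity correction is used and labelled as
such. Two-sided p doubles the smaller tail, capped at 1 — the convention
of the major commercial packages — giving the attainable sequence 2/924,
4/924, 8/924 (0.002, 0.004, 0.009 at three decimals) at n = 6 + 6. The
enumerated distribution is cached on the rank multiset, which makes
repeated tests at the same sizes (the longitudinal report, null
simulations) cheap. Post hoc pairwise tests after Kruskal-Wallis are
unadjusted by default, matching the printed-table convention the package
emulates; Bonferroni/Holm correction is a caller-side choice. Reported
tables round p to 3 decimals; full precision is retained in objects and
JSON.

## Synthetic-data generator

The generator emulates the *measurement protocols*, not the biology:

* **DMA traces**: exact stress sinusoid; SLS closed-form steady-state
  strain plus additive Gaussian strain noise. Noise enters the dependent
  channel only, so noise-free traces match the closed forms to machine
  precision and every oracle test is exact.
* **Bending curves**: bilinear elastic/hardening construction with
  instantaneous pop-in drops between samples and a terminal drop to
  zero; additive Gaussian load noise, clipped at zero. The noise-free
  elastic slope is exactly 48 E I / L³ by construction. Pop-ins are
  modeled as vertical drops — the simplest shape consistent with
  observed records.
* **Phantoms**: voxel-centre membership between the radius profiles;
  affine attenuation map plus Gaussian noise; calibration inserts
  synthesized as separate labeled sub-volumes (as phantoms are scanned in
  practice, and so their ground truth is trivially exact). Default
  spacing 10 μm — slightly coarser than a real scanner's 7–9 μm to keep
  desk-scale volumes small; spacing is a parameter, and a voxel budget
  guard rejects accidental huge grids. Analytic per-block ground truth is
  integrated from the radius profiles; voxel sums converge to it as
  spacing shrinks (tested at 2%).
* **Cohorts**: per-animal weekly masses interpolate group endpoint means
  linearly with iid Gaussian noise; lean + fat is rescaled onto total
  weight when noise pushes it over. Default endpoint means are the
  three-group 12-week study conditions (control 18.92 → 28.05 g, OVX
  25.41 → 45.09 g, OVX+E2 20.96 → 27.32 g; week-12 lean/fat from the
  reported composition endpoints, week-0 lean/fat set to plausible values
  for 10-week-old C57BL/6J females since starting composition was not
  printed per group). Weekly noise sd defaults to 1 g, consistent with
  the reported standard errors (~0.3–1.1 g at n = 6).
* **Diet**: mass-weighted omega-3/6/9 percentages with interval
  propagation for range-valued ingredient compositions (point estimates
  use midpoints).

What the generator does **not** emulate: scanner physics beyond the
affine map (no beam hardening, PSF, or reconstruction artifacts), bone
heterogeneity and anisotropy, trabecular microarchitecture, estrogen
physiology or any metabolic mechanism — group differences are planted
phenomenologically. Passing round-trip tests therefore demonstrates that
the *analysis* stages are correct and self-consistent, not that they are
robust to every artifact of real instruments.

## Pipeline and reproducibility

A single run seed fans out to per-stage child seeds through
`SeedSequence(seed, spawn_key=(stage, item))`, a counter-based scheme:
adding a stage never perturbs earlier streams, and per-specimen streams
are independent. All pipeline outputs are plain text (CSV/JSON) for
diffability; figures are render-only and never feed back into any
computation. Provenance (seed, config hash, package versions) is written
alongside every run; determinism is tested by hashing the output tree of
two identical runs.

Default problem sizes (n = 6 per group, 12 weeks, 1.4 mm phantom shafts
at 10 μm, 8-cycle DMA records at 64 samples/cycle) were chosen so a full
study runs in seconds on a laptop while keeping every voxel/enumeration
oracle inside its stated tolerance.

## Known limitations

* The circular-tube idealization biases I and A for markedly elliptical
  midshafts; no finite-element or true-geometry option is provided.
* The offset-yield point on a noise-free bilinear curve sits slightly
  beyond the planted kink (by offset·S/(S−h) along the displacement
  axis); tests compare against the analytic intersection, and users
  comparing to kink-based definitions should expect that shift.
* Whether body-size adjustment should divide or regress out the covariate
  is a genuine methodological fork; division is implemented and flagged
  for sensitivity analysis via the retained raw values.
* Exact p-values with heavy ties can disagree with software that uses
  asymptotic tie corrections; the enumeration here is the ground truth
  for its own convention (smaller-tail doubling).
* The sector partition is a schematic-faithful double-wedge split; real
  anatomical AP/ML boundaries are not sharply defined, which is why the
  quadrant mode exists.
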