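# Methods

## Scope and data model

`myoflow` quantifies myocardial blood flow (MBF) from first-pass
contrast-enhanced CMR curves. The unit of data is a
`DynamicCurve`: a time-stamped trace for one AHA segment (1–16) or
for the arterial input function (AIF), in signal or concentration
units, belonging to a stress or rest phase of one subject. The
pipeline assumes curves have already been extracted from images
(contouring, segmentation and motion handling are out of scope) and
that each subject carries per-vessel invasive angiography labels
(percent stenosis, optionally fractional flow reserve, FFR).

Obstructive disease ("Group 2") is defined per vessel as stenosis
≥ 70 %, or stenosis ≥ 50 % with FFR ≤ 0.80; a patient is Group 2 when
any vessel is. Stenosis in [50, 70) % without an FFR measurement is
deliberately an error rather than a silent default, because the rule
is not evaluable there.

## Signal to concentration

Saturation-recovery prepared acquisitions make the frame signal a
function of the momentary longitudinal relaxation rate R1(t). The
default model is the pure saturation-recovery exponential

    S(t) = S0 · (1 − exp(−TD · R1(t))),

inverted against the mean of the first `n_baseline_frames`
(default 5) pre-contrast frames, followed by the linear relaxivity
model C(t) = (R1(t) − R1(0)) / r1. An alternative spoiled
gradient-echo readout model including flip angle and TR is selectable
(`SequenceParams.readout = "spgr"`); both are exactly invertible, and
the choice is recorded in the configuration. The readout-pulse
perturbation neglected by the default model is small at the short TR
used here and does not affect the package's synthetic round trips,
which use matching forward and inverse models by construction.

Defaults: TD = 0.1 s (preparation delay to central k-space),
r1 = 5.0 L·mmol⁻¹·s⁻¹ (typical gadobutrol at 3 T), baseline T1 1.2 s
for myocardium and 1.7 s for blood. All are configuration, not
hard-coded truth. Signals beyond the model's dynamic range raise a
saturation error naming the offending frame; negative concentrations
from baseline noise are retained and counted in the QC log, with
clipping available but off by default.

## Kinetic models

Tissue concentration is modelled as discrete convolution of the AIF
with an impulse response, `C_t = (h ⊛ C_a) · dt`, with the AIF
shifted by a candidate bolus-arrival delay. All internal computation
is in seconds; flows and PS are exposed in mL/min/mL with explicit
×60 conversion at the module boundary.

**Fermi.** `h(t) = A / (1 + exp(k (t − τ₀)))` for t ≥ 0. MBF is the
impulse-response value at contrast onset, `A / (1 + e^{−k τ₀})`. This
empirical logistic decays to zero and cannot represent tracer that
has left the vasculature.

**Distributed parameter (DP).** The one-barrier two-region axially
distributed model of capillary–interstitium exchange. Its transport
operator in the Laplace domain is

    h̃(s) = exp(−Tc s) · exp(−(PS/F) · s/(s + k₂)),
    Tc = v_p/F,   k₂ = PS/v_e,

and the residue function follows as R̃(s) = (1 − h̃(s))/s. The model
yields flow F, vascular and interstitial volume fractions v_p and
v_e, permeability–surface-area product PS, and the derived extraction
fraction E = 1 − e^{−PS/F}, distribution volume v_d = v_p + v_e
(whose ratio to flow equals the residue's area, ∫R dt = v_d/F) and
capillary transit time Tc.

### Evaluating the DP residue

Two independent evaluators are implemented:

1. **Exact time-domain form** (`dp_residue_analytic`): the transport
   operator inverts to a throughput spike at Tc plus a modified-Bessel
   tail, `e^{−PS/F}[δ(τ) + e^{−k₂τ}√(c/τ) I₁(2√(cτ))]` with
   c = PS·k₂/F, whose cumulative is a Marcum Q-function:
   `R(Tc + τ) = 1 − Q₁(√(2k₂τ), √(2·PS/F))`, evaluated through the
   noncentral chi-square CDF (`scipy.special.chndtr`) — exact, smooth
   in the parameters, and fast. The v_e → 0 limit with PS > 0 is
   clamped to the plug-flow limit.
2. **Numerical Laplace inversion** (`dp_residue_time`): the de
   Hoog–Knight–Stokes quotient-difference algorithm, vectorised over
   time and evaluated in logarithmic time blocks so small times keep
   full accuracy. Inverted samples are clipped to [0, 1] with the
   clipping magnitude logged (Gibbs overshoot is confined to the
   transit-time discontinuity).

The closed form is exact (no ringing at the jump) and roughly an
order of magnitude cheaper, so it drives the fitting loop; the
Laplace route cross-checks it, and both are validated against the
plug-flow (PS = 0) step, the closed-form area v_d/F, and an
independent arbitrary-precision inversion in the tests. The inversion
routine targets decaying residue-type originals; undamped oscillatory
transforms are outside its scope.

When the residue is *sampled for discrete convolution*, its
plug-flow step is replaced by the fraction of each grid cell it
covers. Pointwise sampling would make the model curve jump whenever
the transit time crosses a sample instant — a χ² surface full of
spurious micro-minima that demonstrably traps the optimiser — while
cell-averaged sampling varies continuously (piecewise linearly) with
the parameters and is the more faithful quadrature of the underlying
integral.

### Fitting

For each delay in {0, Δt, …, 6Δt} (Δt = frame interval) the model
parameters minimise the unweighted sum of squared residuals (χ², mM²)
by bounded trust-region least squares, from a fixed seeded set of
five starting points; the delay with minimal χ² wins, with ties going
to the smaller delay. A numerically perfect fit short-circuits the
remaining starts. Bounds:
F ∈ [0.01, 10] mL/min/mL, v_p ∈ [0.001, 0.3], v_e ∈ [0, 0.6],
PS ∈ [0, 5] mL/min/mL; Fermi A ∈ [0.01, 20], k ∈ [0, 5] s⁻¹,
τ₀ ∈ [0, 30] s. A flat tissue curve is reported at the lower flow
bound with a `degenerate` flag instead of being optimised.

χ² is unweighted because per-frame noise variances are not available
at this stage of the pipeline; a noise-weighted variant would only
rescale the objective under the homoscedastic concentration noise the
generator produces.

## Aggregation

Segment MBF estimates roll up by arithmetic mean over the standard
territory assignment LAD {1,2,7,8,13,14}, RCA {3,4,9,10,15},
LCX {5,6,11,12,16} (a configurable table, since true vascular
territories misregister against the 16-segment convention). MPR is
computed per segment as stress/rest (rest below 0.05 mL/min/mL raises
a degenerate-rest error), then averaged; MPR₂ is the mean of the two
lowest segment MPRs in the territory. Patient-level scores default to
the minimum (most ischaemic) territory — a prospective score cannot
condition on angiography — with mean and mean-over-diseased
alternatives available for evaluation.

## Diagnostics

ROC analysis enumerates thresholds at midpoints between consecutive
distinct scores (plus ±∞), so the trapezoidal AUC equals the
Mann–Whitney pair statistic with ties counted one half — asserted
exactly in the tests by brute-force pair counting. Lower
perfusion indicates disease; the machinery stays direction-agnostic
by negating scores internally and mapping thresholds back. The
operating point maximises Youden's J with ties resolved toward higher
sensitivity, then the lower threshold. AUC variance and the
comparison of the two models' correlated ROC curves use DeLong
placement values; proportion intervals are Wilson score intervals
(the underlying study does not name its method; Wilson behaves well
at the small denominators involved); group comparisons use Welch's
t-test; observer agreement uses Cohen's kappa with its asymptotic
interval; inter-model agreement uses Bland–Altman bias ± 1.96 SD.
Per-vessel analyses treat vessels as independent units, ignoring
within-patient clustering, mirroring the evaluation being reproduced;
no multiplicity correction is applied, likewise.

## Synthetic cohort

The generator emulates the study conditions the package is evaluated
under:

* **Grid**: 50 frames at 1 s spacing — one saturation-recovery image
  per cardiac cycle at a typical heart rate.
* **AIF**: a peak-normalised gamma variate (peak 4 mM, onset 10 s,
  time-to-peak 6 s, shape α = 3) resembling a single-bolus first pass
  at 0.05 mmol/kg; optional recirculation bump and an optional
  saturating soft-clip (`cap · tanh(C/cap)`) emulating blood-pool
  signal saturation. Both options are off by default because their
  true severity in vivo is unknown.
* **Cohort structure**: 8 patients without and 16 with obstructive
  disease; diseased patients carry 1, 2 or 3 diseased vessels with
  probabilities 10/16, 2/16, 4/16 — matching the published cohort
  composition (46 vs 26 vessels).
* **Haemodynamics**: territory-level true stress MBF drawn from the
  published per-patient DP-model group distributions (Group 1
  2.53 ± 0.37, Group 2 1.41 ± 0.46 mL/min/mL, truncated above
  0.1); rest MBF = stress / MPR with MPR drawn likewise
  (2.26 ± 0.61 / 1.21 ± 0.39), so simulated reserve distributions
  match by construction. Per-segment multiplicative jitter (SD 5 %)
  perturbs territory flow.
* **Microvasculature**: v_p = 0.08, v_e = 0.25, PS = 1.0 mL/min/mL —
  physiologically typical values treated as configuration, not truth.
* **Noise**: additive Gaussian in the concentration domain,
  SD 0.03 mM. Bolus-arrival delays of 0–2 frames are drawn per
  segment.
* **Labels**: diseased vessels draw stenosis/FFR combinations that
  satisfy the obstructive rule; healthy vessels draw combinations
  that fail it — verified property-wise in the tests.

What the generator does **not** emulate: image-domain effects (dark
rim, motion, partial volume), physiological AIF variability between
subjects, tissue signal saturation, within-patient correlation of
territory flows beyond the shared AIF, and — most importantly — any
departure of real myocardium from the DP model itself. Passing tests
therefore demonstrate correctness of the machinery under a DP world,
not fidelity of either kinetic model to real tissue.

### Known limitation: inter-model bias direction

On real patient data the Fermi model reports systematically *higher*
MBF than DP (a published mean difference of +0.55 mL/min/mL at
stress). On this package's DP-generated cohort the direction
reverses: the extravasation tail of a DP curve dominates the
unweighted χ², and the best-fitting Fermi logistic lowers its onset
value, giving a *negative* median Fermi-minus-DP difference. The
effect is robust to adding AIF saturation (which inflates the DP fit
at least as much), recirculation, and first-pass window truncation.
This is a structural property of fitting a mismatched empirical model
to data generated by the richer model — the real-data bias arises
from mechanisms (true tissue kinetics, measured-AIF distortion) the
generator does not reproduce — and the corresponding acceptance
check is expected to fail on the synthetic cohort. The same applies
to one operating threshold (the per-patient Fermi MBF cut, published
2.60): its binormal reconstruction converges to ≈ 2.51 because an
empirical Youden argmax on 24 patients is highly discrete, and no
generator setting consistent with the published summary statistics
moves it.

## Reproducibility

Every stochastic component draws from `numpy` Generators seeded from
the configuration; a fixed seed reproduces cohorts, fits, reports and
QC logs byte for byte. Reports embed the seed and a SHA-256 hash of
the canonical configuration. The acceptance script reconstructs each
published ROC area from 200 000 simulated scores per group (binormal
sampling from the published group means/SDs), a scale at which the
Monte-Carlo error of the AUC is ≈ 10⁻³.
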