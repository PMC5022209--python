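# myoflow

Quantitative myocardial perfusion from first-pass contrast-enhanced
cardiovascular MR (CMR) curves: signal-to-gadolinium conversion,
myocardial blood flow (MBF) estimation by **Fermi** and
**distributed-parameter (DP)** deconvolution, aggregation over the AHA
16-segment model to coronary territories and patients, and
diagnostic-performance evaluation against invasive angiography.

It is aimed at perfusion-CMR researchers who start from segmented
signal-intensity–time curves (arterial input plus 16 myocardial
segments per phase) and want absolute MBF (mL/min/mL), myocardial
perfusion reserve (MPR = stress/rest MBF), the two-lowest-segment
reserve MPR₂, and ROC-based operating thresholds for detecting
obstructive coronary artery disease (stenosis ≥ 70 %, or ≥ 50 % with
fractional flow reserve ≤ 0.80). Because no public dataset of this
kind exists, a synthetic-cohort generator with known ground-truth
kinetics stands in for patient data end to end.

## The models

The measured tissue concentration is modelled as a convolution with
the arterial input function (AIF):

```
C_t(t) = (h ⊛ C_a)(t - τ_d),     τ_d ∈ {0, Δt, …, 6 Δt}
```

where the bolus-arrival delay τ_d is chosen by grid search for the
best χ² fit. Two impulse responses are implemented:

* **Fermi** (empirical): `h(t) = A / (1 + exp(k (t − τ₀)))`, with
  MBF read off as the impulse response at contrast onset,
  `h(0) = A / (1 + e^{−k τ₀})`.
* **Distributed parameter** (1-barrier 2-region axially distributed
  exchange): `h(t) = F · R(t)` with the residue function defined in
  the Laplace domain by

  ```
  R̃(s) = (1 − e^{−Tc s} e^{−(PS/F)·s/(s + PS/v_e)}) / s,
  Tc = v_p / F
  ```

  over flow `F`, vascular volume `v_p`, interstitial volume `v_e`,
  and permeability–surface-area product `PS`, giving the derived
  extraction fraction `E = 1 − e^{−PS/F}`, distribution volume
  `v_d = v_p + v_e` and capillary transit time `Tc`. The residue is
  evaluated both by its exact time-domain form (a Marcum-Q /
  noncentral-χ² expression of the modified-Bessel outflow tail) and
  by accuracy-controlled numerical Laplace inversion (de Hoog), each
  validating the other.

Signal curves are converted to concentration by inverting the
saturation-recovery signal model `S ∝ 1 − e^{−TD·R1(t)}` against the
pre-contrast baseline and applying the linear relaxivity model
`C = ΔR1 / r1`.

## Worked example

```python
import numpy as np
from myoflow import (AIFParams, DPParams, gamma_variate_aif,
                     simulate_tissue_curve, fit_model, derive_microvascular)

times = np.arange(50.0)                        # 50 frames, 1 s apart
aif = gamma_variate_aif(AIFParams(), times)    # first-pass arterial input

truth = DPParams(flow=1.5, v_p=0.08, v_e=0.25, ps=1.0, tau_d=2.0)
tissue = simulate_tissue_curve(aif, truth, dt=1.0, noise_sd=0.02, seed=7)

for model in ("dp", "fermi"):
    fit = fit_model(aif, tissue, model)
    print(f"{model:5s}  MBF = {fit.mbf:.2f} mL/min/mL   "
          f"delay = {fit.delay:.0f} s   chi2 = {fit.chi2:.2e}")

micro = derive_microvascular(fit_model(aif, tissue, "dp").params)
print(f"extraction fraction E = {micro.extraction_fraction:.2f}, "
      f"v_d = {micro.v_d:.2f} mL/mL, Tc = {micro.transit_time:.1f} s")
```

prints

```
dp     MBF = 1.31 mL/min/mL   delay = 2 s   chi2 = 1.27e-02
fermi  MBF = 0.98 mL/min/mL   delay = 1 s   chi2 = 2.83e-02
extraction fraction E = 0.51, v_d = 0.33 mL/mL, Tc = 3.9 s
```

The DP fit recovers the true bolus delay (2 s) and lands near the
true flow of 1.5 mL/min/mL despite concentration noise; the Fermi
logistic, which cannot represent the extravasation tail of a
DP-generated curve, settles lower. χ² is the sum of squared residuals
in mM².

A full cohort run — simulate, convert, fit both models on all 16
segments in both phases, aggregate to territories and patients, and
evaluate ROC/Youden/DeLong statistics — is one command:

```sh
myoflow run -o out --seed 1      # writes curves/fits/vessels/patients/report
```

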