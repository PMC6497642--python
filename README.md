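# ebusplan

Cisplatin pharmacodynamics and injection-site planning for endobronchial
ultrasound-guided transbronchial needle injection (EBUS-TBNI) of lung
tumors.

Direct intratumoral injection of cisplatin is an emerging salvage therapy
for peribronchial lung cancer, but where to inject, at how many sites, and
at what dose is decided empirically. `ebusplan` implements a
reaction–diffusion/compartmental model of intratumoral cisplatin transport
and uses it to plan injections:

- **Analytic concentration fields.** A dose `m` injected at a point spreads
  as a 3D heat kernel with first-order loss `k = k_i + k_f` (uptake into
  cells + clearance into the vasculature). The accumulated intracellular
  concentration has a closed form, and its long-time limit is a screened
  Coulomb (Yukawa) field, `phi_i(r,∞) = k_i m e^{-r/ell}/(4 pi D r)` with
  screening length `ell = sqrt(D/k)` ≈ 1 mm — the quantity compared against
  a lethal threshold `phi_t`.
- **Blood-curve calibration.** The systemic compartment yields a
  biexponential blood concentration; fitting it to timed blood draws
  estimates `k_i + k_f` and the volume of distribution `V_f`.
- **Injection planning.** A genetic algorithm places N sites in a voxelized
  tumor mask to maximise the minimum asymptotic intracellular concentration;
  linearity in dose then gives the minimal total dose `M_min` that brings
  the whole tumor above `phi_t`, plus kill-fraction curves and ±10%
  parameter sensitivities.
- **Finite-difference oracle.** An explicit solver for the unsimplified
  PDE/compartment system validates every closed form and quantifies the
  sink and free-boundary approximations.
- **Synthetic data.** Generators for study-condition blood series (five
  8 mg injections; draws at 5–120 min; lognormal assay noise) and
  sphere/ellipsoid tumor masks, so the whole pipeline is testable offline.

## Worked example

```python
import ebusplan as eb

params = eb.ModelParameters.patient_fitted()

# calibrate against a (synthetic, noiseless) blood series
series, tumor = eb.generate_default_patient_like_case(seed=0)
fit = eb.fit_blood_model(series, params)
print(f"k_i+k_f = {fit.k_sum:.3e} 1/s, V_f = {fit.V_f/1e3:.1f} L, "
      f"k_f = {fit.k_f_derived:.3e} 1/s")

# plan 1..5 injections on the 40 mL tumor mask
plans = eb.optimize_placement_series(tumor, 5, params, eb.GAConfig(seed=17))
for n, res in plans.items():
    print(f"N={n}: minimal dose {res.M_min:.3g} mg")
```

Output:

```
k_i+k_f = 2.510e-04 1/s, V_f = 12.2 L, k_f = 1.460e-04 1/s
N=1: minimal dose 3.8e+04 mg
N=2: minimal dose 19.3 mg
N=3: minimal dose 8.44 mg
N=4: minimal dose 6.7 mg
N=5: minimal dose 2.67 mg
```

The fitted loss rate 2.51e-4 1/s splits, given the literature uptake rate
`k_i` = 1.05e-4 1/s, into a vascular clearance `k_f` = 1.46e-4 1/s; the
volume of distribution is about the extracellular fluid volume of an adult.
The minimal dose at threshold `phi_t` = 5e-8 mg/mL falls by roughly four
orders of magnitude between one central injection and five optimally spread
ones: a single site must overcome ~28 screening lengths of exponential decay
to reach the far end of the elongated tumor, while five sites cut the
worst-case distance to ~14.

A command-line interface wraps the same functionality:

```sh
ebusplan simulate --out-blood blood.csv --out-mask tumor.nii.gz --seed 7
ebusplan fit --blood blood.csv
ebusplan plan --mask tumor.nii.gz --n-sites 5 --seed 17 --out plan.json
ebusplan killcurve --plan plan.json --mask tumor.nii.gz --dose-mg 40
ebusplan sensitivity --plan plan.json --mask tumor.nii.gz --delta 0.10
```

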