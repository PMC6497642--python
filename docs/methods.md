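# Methods

## Model

A peribronchial tumor is treated as two topographically coincident
compartments — extracellular space (volume fraction `alpha_e`) and
intracellular space (`alpha_i`, with `alpha_e + alpha_i = 1`) — coupled to a
single well-mixed systemic fluid compartment of volume `V_f`. Cisplatin
injected into the extracellular space diffuses with coefficient `D`
(homogeneous, isotropic) and is lost by first-order transfer into cells
(rate `k_i`; binding to DNA is taken as irreversible, so the intracellular
space is a sink) and into the vasculature (rate `k_f`). The fluid
compartment clears renally at `k_r`. Treating the fluid space as a pure sink
for the intratumoral problem (justified because blood concentrations stay
orders of magnitude below early intratumoral ones), the extracellular field
obeys a diffusion equation with uniform first-order loss `k = k_i + k_f`,
whose free-space Green's function is a decayed heat kernel:

    phi_e(r, t) = sum_j m_j e^{-k t} (4 pi D t)^{-3/2} exp(-|r - r_j|^2 / 4Dt)

for point doses `m_j` at sites `r_j` (superposition; all fields are linear
in dose). The intracellular concentration is the uptake integral
`phi_i = k_i ∫_0^t phi_e dτ`, evaluated in closed form with complementary
error functions of `alpha = |r - r_j| / sqrt(4Dτ)` and `beta = sqrt(kτ)`;
its `t → ∞` limit is a screened-Coulomb (Yukawa) superposition

    phi_i(r, ∞) = sum_j k_i m_j exp(-|r - r_j| / ell) / (4 pi D |r - r_j|),

with screening length `ell = sqrt(D / k)` ≈ 0.099 cm at the calibrated
rates. This asymptote is the cytotoxicity surrogate: a tumor voxel counts as
killed when it meets or exceeds the lethal threshold `phi_t`.

The fluid compartment integrates the tumor outflow, giving a biexponential
blood curve per site, `(k/(k - k_r)) (m_j / V_f)(e^{-k_r t} - e^{-k t})`,
with the confluent limit `m_j k t e^{-k t} / V_f` substituted when
`|k - k_r| < 1e-12` 1/s.

### Normalization

The mass-conserving heat-kernel prefactor `(4 pi D t)^{-3/2}` is the
default: it makes the spatially integrated extracellular mass exactly
`M e^{-k t}`, which the blood-curve derivation relies on. A
`normalization="literature"` mode multiplies every spatial field by
`4 pi`, reproducing an alternative prefactor convention found in the
literature for the same kernel family; placement optima, kill fractions and
dose *ratios* are invariant to this global constant (it rescales `M_min`
only). Similarly, the closed-form uptake integral carries a `+` sign between
its two erfc terms — the sign required for the expression to equal the
quadrature of `k_i phi_e` and to converge to the Yukawa asymptote.

## Parameters

| Parameter | Meaning | Default | Origin |
|---|---|---|---|
| `D` | diffusion coefficient | 2.47e-6 cm^2/s | power law `1.778e-4 MW^-0.75` at MW = 300 Da |
| `k_i` | cellular uptake rate | 1.05e-4 1/s | literature value for carcinoma lines |
| `k_f` | vascular clearance rate | 1.46e-4 1/s | fitted `k_i + k_f` minus literature `k_i` |
| `k_r` | renal clearance rate | ln2/1800 s ≈ 3.85e-4 1/s | 30 min biological half-life |
| `V_f` | volume of distribution | 12.2 L (12200 cm^3) | blood-curve fit |
| `alpha_i` | intracellular fraction | 0.1 | order-of-magnitude choice consistent with `alpha_e >> alpha_i` |
| `phi_t` | lethal threshold | 5e-8 mg/mL | free parameter of the planning problem; never hard-coded |
| `k'_f` | fluid→tumor return | 0 | sink approximation; only the FD oracle exercises nonzero values |

Internal units are mg, cm, s; concentrations mg/cm^3 (≡ mg/mL). Config
files may specify `V_f_L` in litres (converted ×1000) and `MW` instead of
`D`.

## Calibration

Two parameters are identifiable from a timed blood series: `k_sum = k_i +
k_f` and `V_f`. `k_r` is fixed from the half-life. The cost is the
unweighted root-sum-of-squares residual; it is minimised by multi-start
(default 16) Levenberg–Marquardt in log-parameter space (positivity without
constraints, and the two parameters differ by seven orders of magnitude in
natural units), with seeded log-uniform starts over `k_sum ∈ [1e-6, 1e-2]`
1/s, `V_f ∈ [1e2, 1e6]` cm^3. `r^2 = 1 - SS_res/SS_tot` about the sample
mean. Injections are treated as simultaneous at the time of the final
injection (matching the blood-draw clock); optional per-site time offsets
shift each site's kernels.

## Geometry

Tumors are binary voxel masks with physical spacing (0-based indices,
voxel-centre world coordinates, `world = origin + index * spacing`). NIfTI
headers carry mm and are converted to cm on load/save. Synthetic spheres and
ellipsoids are voxelized at 0.1 cm spacing by default — about one screening
length, so the field minimum between sites is resolved — and require at
least 10 voxels across the smallest axis. The default evaluation domain is
every foreground voxel centre.

## Planning

The objective is max–min coverage: maximise the minimum of `phi_i(r, ∞)`
over tumor voxels with the total dose split equally between `N` sites. By
linearity the minimal total dose then follows from any reference dose:
`M_min = M_ref * phi_t / field_min`. All field minimisation happens in log
space (screening exponents reach e^-28 across the elongated 40 cm^3
fixture), and `M_min` is assembled from logs so underflow cannot corrupt the
scaling.

The optimiser is a real-coded genetic algorithm: population 60, tournament
selection (size 3), blend crossover (alpha 0.5, rate 0.9), Gaussian mutation
with sigma decaying from 10% to 0.5% of the bounding-box diagonal, elitism
2, up to 300 generations with a 50-generation stall rule; candidates outside
the mask are projected to the nearest interior voxel centre. Three details
matter in practice:

- **Fitness grid.** During evolution fitness is evaluated on all
  boundary-shell voxels plus a stride-2 interior sample. The minimum of a
  screened-Coulomb field binds on or near the surface; subsampling the shell
  lets the optimiser exploit unmonitored voxels. The returned optimum is
  always re-scored on the full voxel grid.
- **Seeding.** The initial population mixes k-means++ cluster centres,
  greedy farthest-point (k-center) covers and random voxel draws.
  `optimize_placement_series` additionally warm-starts each `N` from the
  best `N-1` placement plus a site at its worst-covered point, a
  near-duplicate of an existing site (equal-split dose stacking — the `N=4`
  optimum on the ellipsoid genuinely stacks two sites at the centre), and an
  even arrangement along the tumor's principal axis. This makes `M_min(N)`
  non-increasing in `N` in practice.
- **Polish.** A Nelder–Mead refinement of the GA optimum (the max–min
  landscape is piecewise smooth) typically improves the field minimum by a
  further 30–60% in log terms.

Kill curves report the percentage of voxels with `phi_i(∞) >= phi_t`; ties
count as killed, detected with a 1e-12 log-scale tolerance so that the
`M_min` rescaling round-trip cannot lose the binding voxel to float
rounding. A voxel whose centre hosts an injection site is scored at the
half-voxel distance rather than the 1/r singularity. Sensitivity analysis
perturbs `D`, `k_i`, `k_f` by ±10% at fixed sites and dose and reports the
percentage change of the field minimum (equivalently, of the largest
threshold still achieving complete kill). Faster diffusion raises it;
faster uptake or vascular clearance lowers it; all magnitudes shrink as
sites are added.

### Geometry dependence of the multi-site benefit

The dose reduction from multiple injections is controlled by how much extra
sites shrink the worst-case site-to-voxel distance, in units of `ell`. On a
*sphere*, covering with 5 balls reduces the covering radius only ~11–15%,
so the 1→5-site dose ratio is bounded near ~5× whatever the optimiser does.
On the elongated patient-like ellipsoid (40 cm^3, aspect 1.5:1:1) the ratio
exceeds 10^4 — a >3-orders-of-magnitude reduction. Multi-site gains are a
property of elongated geometry, not of the optimiser.

## Finite-difference oracle

An explicit forward-Euler solver with a 7-point Laplacian (chosen for
auditability) integrates the *unsimplified* system — including the fluid
compartment and an optional fluid→tumor return rate `k'_f` — and validates
every closed form. Time step `0.9 h^2 / 6D`; free-space boundaries are
emulated by absorbing edges on a padded box, no-flux by masked face fluxes
(mirrored ghost cells). The point source is one voxel's worth of dose;
comparisons exclude a small radius around the source where this
approximation is worst. Numerical notes discovered en route:

- Grids must have odd extents so the origin-centred source lies on a voxel
  centre; on even grids the half-voxel source offset produces an
  `O(r h / 2Dt)` spurious relative error in the Gaussian tails.
- The nominally fourth-order step `mu = D dt/h^2 = 1/6` is unusable from a
  delta initial condition: the checkerboard mode is then marginally stable
  and never decays.
- The uptake integral is accumulated trapezoidally; with rectangle
  accumulation the intracellular comparison misses 1% at practical step
  sizes.
- Agreement achieved: extracellular field within 1% of the analytic kernel
  (h = 0.01 cm, 63^3, t = 600 s, 2.5 voxels < r < 0.105 cm), intracellular
  within 1% (h = 0.005 cm, 95^3, t = 3600 s, 0.03 < r < 0.10 cm), global
  mass audit (tissue + intracellular + fluid + cleared vs injected) within
  0.5% throughout, and sink-approximation error growing monotonically with
  `k'_f`.

## Synthetic data

The generator emulates the calibration study conditions: five simultaneous
8 mg injections (40 mg total), venous draws at 5, 15, 30, 60 and 120 min,
true `k_sum = 2.51e-4` 1/s and `V_f = 12.2` L, and a 40 cm^3 ellipsoidal
tumor (aspect 1.5:1:1, mimicking an elongated paratracheal mass).
Measurement error is multiplicative lognormal with unit mean and a default
5% coefficient of variation — concentration assays err proportionally — and
is deterministic given a seed. What the generator does **not** emulate:
staggered injection timing within the procedure, assay detection limits,
inter-patient variability, spatially heterogeneous or anisotropic tissue,
and tumors with irregular (non-ellipsoidal) boundaries. Tests passing on
these synthetics therefore demonstrate internal consistency of the model
and estimator, not clinical validity on real tumors.

## Problem sizes and runtimes

Default verification sizes were chosen at desk scale: 63^3–95^3 oracle
grids, a 40 cm^3 tumor at 0.1 cm spacing (~40 000 voxels), 200 replicate
noisy fits, and one GA series N = 1..6 (about 1.5 min). The whole test
suite runs in a few minutes on one core.

## Known limitations

- Homogeneous, isotropic `D`, `k_i`, `k_f`; no saturation, efflux or
  explicit DNA-binding kinetics beyond the irreversible-sink assumption.
- The tumor boundary is ignored by the analytic fields (free-space
  solution); the oracle's no-flux mode quantifies the effect on retained
  mass (<5% at `t = 1/k` for a centred source).
- Threshold cytotoxicity only; AUC, peak-concentration and exposure-time
  models are out of scope.
- Single-series calibration (one patient); no population PK.
- Needle-trajectory and bronchoscopic-reachability constraints are not
  modelled; sites are free within the tumor.
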