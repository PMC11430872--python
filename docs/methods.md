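# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `rwdry`.

## Moisture ratio and thin-layer models

A drying run is a time/mass series with a known bone-dry mass. Dry-basis
moisture is Xₜ = (mₜ − m_dry)/m_dry and the moisture ratio is
MR = (Xₜ − Xₑ)/(X₀ − Xₑ). The equilibrium moisture Xₑ defaults to 0: thin
leaves in an RW dryer run essentially to bone dryness and the equilibrium
value is rarely measured; it is configurable per run. MR is invariant
under uniform mass rescaling, and MR(0) = 1 by construction.

Six empirical thin-layer models are fitted to MR(t) by trust-region
nonlinear least squares (`scipy.optimize.least_squares`), with:

- box bounds k, k₀ ∈ (0, 10] min⁻¹, n ∈ (0, 5], a, b, c ∈ [−5, 5];
- five seeded starts per fit, the first from a log-linearisation of the
  Newton model (slope of ln MR vs t over points with MR > 0); for the
  two-term model an additional start at the Henderson–Pabis embedding
  (c = 0) preserves the nested-model SSE ordering
  SSE(two-term) ≤ SSE(Henderson–Pabis) ≤ SSE(Newton);
- SSE-change tolerance 10⁻¹⁰; the convergence flag reports the optimizer's
  own status, never a fabricated success.

Goodness of fit is MSE = (1/N)Σ(pre − exp)² and the standard coefficient
of determination R² = 1 − SS_res/SS_tot (undefined, and flagged NaN, for
zero-variance observations). Ranking is by descending R², ties by
ascending MSE, then by fewer parameters; non-converged fits sort last.
Observed MR ≤ 0 (possible under noise) is excluded from log-based
initialisation but retained in the SSE.

`drying_time_to_target` inverts a fitted curve by geometric bracketing plus
bisection (tolerance 10⁻⁹ min); for Page/Newton the closed form
t = (−ln MR/k)^(1/n) cross-checks it in the tests. Models that never reach
the target (e.g. an upward-turning Wang–Singh parabola) fail explicitly.

## Diffusivity and activation energy

Only the first-term long-time asymptote of the Fick slab solution is used
(no multi-term series, no moisture-dependent diffusivity, no shrinkage).
The regression of ln MR on time uses seconds internally — D_eff is always
in m²/s — with a free intercept, since the slab solution predicts
intercept ln(8/π²) ≈ −0.21, not 0. Points with MR ≤ 0.05 are dropped by
default (`mr_floor`): the logarithm amplifies noise near zero.

The slab half-thickness defaults to L = 1.5×10⁻⁴ m (a 0.3 mm leaf) and is
prominently configurable. Absolute D_eff scales with L²; the activation
energy is independent of L because L only shifts the Arrhenius intercept.

The Arrhenius stage regresses ln D_eff on 1/(T + 273.15) over at least
three distinct temperatures; Eₐ = −slope·R with R = 8.314 J/(mol·K), and
D₀ = exp(intercept). The negative-exponent convention
D_eff = D₀ exp(−Eₐ/RT) is used throughout — it is the only convention
under which a positive activation energy produces diffusivities that grow
with temperature. An exactly flat set of diffusivities returns Eₐ = 0
with D₀ equal to the common value.

## Thermodynamics

ΔH = Eₐ − RT, ΔS = R[ln D₀ − ln(k_B/h) − ln T], ΔG = ΔH − TΔS, evaluated
at the observed temperatures only (no interpolation), reported in kJ/mol
and kJ/(mol·K). "k_B/h" is the Boltzmann/Planck ratio of standard
transition-state theory (CODATA constants, overridable only through an
explicit constants object). ΔG = ΔH − TΔS holds to machine precision by
construction. Reference ΔG values recomputed from tabulated ΔH/ΔS agree
within 0.1% per row — the tabulated inputs carry 4-significant-digit
rounding, which propagates up to ~0.05% into ΔG.

## Energy and emissions

Water removed follows the wet-basis mass balance
m_w = m₀(M₀ − M_f)/(100 − M_f) (fixed dry matter). SEC divides metered
kWh by kg water removed. The 0.871 divisor in SEC_real is treated as a
combined plant/transmission efficiency and is configurable. Emission
intensity is SEC_real × EF × (1 − ER/100) with EF in g/kWh converted to
kg/kWh; defaults EF_CO₂ = 622, EF_NOₓ = 3.78 (fossil-fuel combined-cycle
plant) and ER = 0. ER is exposed because reported absolute CO₂ columns in
the literature are not always consistent with ER = 0; the package's
percent-change summaries (the robust quantities) do not depend on it.
Percent change uses the drop convention 100(ref − new)/ref, so a positive
number is a decrease.

## Quality metrics

ΔE is the Euclidean CIELAB distance to the fresh reference and Chroma is
√(a*² + b*²) — no CIEDE2000, no hue angle. Both are computed per
replicate and then averaged in the pipeline; computing them on group means
is also possible and gives slightly different ΔE whenever replicates are
spread (Jensen's inequality), which is why published ΔE columns often
disagree with what the printed group means imply. DPPH activity above
100% or below 0% is reported as-is with a warning, never silently
clipped. Panel summaries use the sample SD (ddof = 1; 0 for singletons).

## Synthetic-data generator

The generator emulates the study conditions, not the dryer physics: the
curve shape is phenomenological (Page form), not a heat/mass-transfer
simulation of the Mylar film or the water bath. Defaults, chosen once to
mirror a bench mint RW campaign:

| parameter | default | why |
|---|---|---|
| temperatures | 50–90 °C step 10 | the five study levels |
| replicates | 3 | reported SDs imply triplicates |
| sampling interval | 5 min | the study's weighing cadence |
| initial moisture | 80% w.b. | measured fresh-leaf moisture |
| sample mass | 50 g | bench-scale single-layer charge |
| Page n | 1.1 | slight super-exponential decay typical of leaves |
| k_ref | 0.0116 min⁻ⁿ at 50 °C | gives ≈156 min drying time at 50 °C |
| Eₐ (simulated) | 27 kJ/mol | reproduces the ≈156→57 min span over 50→90 °C |
| MR stop | 0.05 | runs end near bone-dry |
| noise SD on MR | 0.005 | replicate scatter consistent with reported SDs |
| mean power | 0.09 kW | yields SEC ≈ 5.7 kWh/kg at 50 °C for a 50 g charge |

Replicate noise is additive Gaussian on MR (clipped to [0, 1]), the
simplest model consistent with mean ± SD summaries; the t = 0 sample is
noise-free so MR(0) = 1 exactly. Masses are back-computed from MR and the
bone-dry mass. A run ends at the first sample whose noiseless MR is at or
below the stop value; a hard cap of 10 000 samples guarantees termination
with an explicit error. Energy is constant mean power with seeded
per-interval jitter (increments floored at zero, so cumulative kWh is
non-decreasing). Quality/color panels are Gaussian draws around
configurable per-temperature means ± SD; rehydration curves are monotone
saturating three-phase shapes reaching the configured plateau.

Seeding: run-level streams derive from (master seed, temperature index,
replicate index), so adding replicates never perturbs existing runs, and
the pipeline fans a single global seed out to stages by a stable hash of
the stage name. Fixed seed ⇒ byte-identical CSV output.

What passing tests on synthetic data do **not** show: real leaves shrink,
their diffusivity is moisture-dependent, dryer power is not stationary,
and quality metrics correlate across assays — none of which the generator
reproduces. Synthetic-data results validate the estimation machinery, not
the biology.

## Neural network

The MLP is written from scratch (the trainer is the point, not a wrapper):
explicit flat parameter vector, seeded uniform(−0.5, 0.5) initialisation,
analytic per-sample Jacobian by backpropagation (tested against central
finite differences at 10⁻⁶). Inputs are affinely scaled to [−1, 1] per
feature from the training partition; the scaling is stored with the model
and serialised with it (JSON).

Training is Levenberg–Marquardt: solve (JᵀJ + λI)δ = −Jᵀr, accept when
the training SSE drops (λ ÷ 10), otherwise reject (λ × 10, cap 10¹⁰ then
clean stop). λ starts at 10⁻³. One epoch = one Jacobian evaluation.
Stopping: 1200-epoch cap, gradient-infinity-norm tolerance 10⁻¹²,
training MSE below 10⁻¹⁶ (machine precision for unit-scale MR), or
validation patience 6 — the best-validation weights are returned. The
70/15/15 split is seeded and stratified by temperature so every partition
covers all levels. A purelin-only network is affine end to end, so LM must
reach the ordinary-least-squares optimum of the equivalent design matrix;
this is asserted in the tests to 10⁻⁸ MSE.

The topology search grid covers single hidden layers of 2–15 tansig units
plus a tansig–logsig–purelin two-hidden-layer family, each candidate with
a fixed per-candidate seed, ranked by test MSE. Whether test/validation
partitions should be fixed across candidates is an open design point; the
default re-splits per candidate seed and reports the seed used.

## Reference tables and what is (not) reproducible

The shipped reference tables carry printed per-temperature summaries.
Desk-scale reproducible from them: the Arrhenius activation energy
(≈25.77 kJ/mol from the five diffusivities), ΔH via Eₐ − RT, the
ΔG = ΔH − TΔS identity, Chroma from a*/b* means, and all headline percent
changes. Not reproducible, by information content: absolute D_eff (the
source leaf thickness is unknown), absolute CO₂/NOₓ (unstated ER), the
per-run fit statistics and the reported ANN MSE (raw series undeposited),
and tabulated ΔS from any D₀ consistent with the Arrhenius fit under
standard constants — these are consumed as fixtures and checked by the
property suite instead (nested-model SSE dominance, exact parameter
recovery on noiseless data, Jacobian correctness, purelin ≡ OLS, ANN
R² ≥ 0.999 on a noiseless Page surface, ΔE metric axioms).

## Problem sizes

The test suite and the acceptance script run on synthetic campaigns of
5 temperatures × 1–3 replicates (≈20–35 samples per run), 100 random runs
for the dominance property, and single-topology network training on ~100
point surfaces; the whole suite completes in well under a minute on one
CPU.
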