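# Methods

## The connectance statistic

For a treatment cell with replicate plants *i* = 1…n and a fixed list of
variable pairs, each pair's Pearson correlation r (pairwise-complete across
replicates, n ≥ 3 required) is transformed to z = atanh(|r|) ≥ 0. Module
connectance is the unweighted mean of z over the module's pairs; global
connectance is the mean of the two module connectances — not the pooled mean
over all 15 module pairs. The distinction matters because the modules have
unequal sizes (9 vs 6): only the module-mean rule reproduces the published
global values from the published module values at printed precision, which
is how the aggregation rule was identified. The ETR–AmaxL linking pair is
reported separately and enters neither module nor the global mean, for the
same reason: including it in any average breaks the printed identities.

Significance of each r is computed from t = r√(n−2)/√(1−r²) with n−2
degrees of freedom (two-sided), and reported per pair; by default **all**
pairs enter the averages regardless of significance. The original
description of the method tests significance but never states an exclusion
rule, so filtering is offered only as an explicit non-default option
(`significance_alpha`, which zeroes pairs with p > α before averaging).
Pearson correlation is the default (the construction the statistic
originates from is Pearson-based); Spearman is available via
`method="spearman"`.

Degenerate inputs are errors, not NaNs: constant columns raise a
degenerate-input error naming the pair, fewer than 3 complete pairs raise an
insufficient-data error. |r| = 1 (common at n = 7 with derived variables) is
clamped to 1 − 10⁻¹² with a warning, keeping Cg finite (z ≈ 13.9) while
flagging the cell.

### Resampling inference

With the design's 7 replicates per cell, the sampling noise of a single z is
≈ 1/√(n−3) = 0.5 — comparable to the published treatment effects. Two tools
quantify this:

* **bootstrap_cg** — percentile CIs from resampling replicate rows with
  replacement (default 1000 draws, 95% level). Draws that produce a constant
  column are redrawn and counted. Requires complete rows.
* **permutation_test_cg** — p-value for |ΔCg_total| between two cells under
  random reassignment of the pooled replicates to groups of the original
  sizes, p = (1 + #{permuted ≥ observed})/(n_perm + 1). Calibration was
  checked by simulation: at α = 0.05 with n = 20 per group and 199
  permutations the type-I error over 1000 null pairs lies within [0.03,
  0.07] (see the acceptance tests).

Both are deterministic given their seed. Internally they use a fast
numpy-correlation path on the complete-case matrix; the per-pair path with
missing data is only used for point estimation.

## Leaf models

* **C3**: FvCB with Ac = Vcmax(Ci−Γ*)/(Ci+Kc(1+O/Ko)),
  Aj = J(Ci−Γ*)/(4Ci+8Γ*), A = min(Ac, Aj) − Rd. Kinetic constants are the
  standard 25 °C set (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹,
  Γ* = 42.75 µmol mol⁻¹, O = 210 mmol mol⁻¹), fixed: the target protocol
  measures at a single controlled cuvette temperature, so temperature
  response machinery would add unidentifiable freedom. The limiting-rate
  transition is a hard min; smoothing changes fitted Vcmax slightly and is
  deliberately not applied.
* **C4**: simplified enzyme-limited form, A = min(Vcmax,
  Vpmax·Ci/(Ci+Kp)[, J/6]) − Rd with Kp = 80 µmol mol⁻¹; saturates at far
  lower Ci than the C3 form. Photorespiration is modelled as 0.015·Vcmax
  (the CO2-concentrating mechanism suppresses oxygenation roughly 50-fold),
  landing in the observed C4 range (≈ 0.1–0.4 µmol m⁻² s⁻¹) against the C3
  rule Pr = Vcmax·Γ*/(Ci+Km) ≈ 2.5–4.
* **Light response**: non-rectangular hyperbola with parameters (Amax gross
  plateau, φ apparent quantum yield, θ convexity, Rd); A(0) = −Rd exactly;
  θ → 0 reduces to the rectangular hyperbola.
* **Fluorescence**: Fv/Fm = (Fm−Fo)/Fm, ΔF/Fm′ = (Fm′−Fs)/Fm′,
  qP = (Fm′−Fs)/(Fm′−Fo′), NPQ = Fm/Fm′−1,
  ETR = ΔF/Fm′·PPFD·f_PSII·absorptance with f_PSII = 0.5 and
  absorptance = 0.84 as explicit, overridable fields (both are
  species-dependent in practice). All outputs are invariant to rescaling the
  raw signals.
* **Stomatal limitation**: Ls = 100·(A(Ci=Ca) − A(Ci_op))/A(Ci=Ca).
  Supersaturation (negative Ls) is returned with a warning rather than
  clipped.
* **AES**: the alternative electron sink is implemented as
  (ETR/4)/(A+Rd) with the electron cost configurable, since published
  variants differ and the exact source formula is not recoverable.

### Curve fitting

`fit_aci` and `fit_light` use Levenberg–Marquardt least squares (lmfit) with
deterministic initialisation: φ and Rd from a straight line through the
three lowest-light points, Amax from the maximum observed A, Vcmax from the
sub-ambient-Ci points solved through the Rubisco-limited expression, J from
the high-Ci plateau. On noiseless model-generated curves both fits are
identity maps on the generating parameters to well under 1% (tested).
Non-convergence raises an error carrying solver diagnostics. AmaxCO2
("photosynthetic potential") is operationalised as the fitted model's
prediction at Ci = 2000 µmol mol⁻¹, a plateau read-out; no evaluation point
is canonical in the literature, so the choice is fixed and documented here.
Identifiability caveat: separating Rd from Vpmax in the C4 fit needs at
least two sub-saturation Ci points.

## The synthetic-data generators

**Tier 1 (exact)**: multivariate-normal draws with a user-specified target
correlation matrix (eigen square root; slightly indefinite matrices are
repaired by eigenvalue clipping plus unit-diagonal rescaling, with a
warning; a non-unit diagonal is rejected). This tier provides exact
population ground truth: for equicorrelated variables with correlation ρ
every module connectance converges to atanh(ρ).

**Tier 2 (mechanistic)**: each replicate plant draws parameters (Vcmax, J or
Vpmax, Rd, gs, effective PSII yield, Fv/Fm, NPQ, dry mass, leaf area) from
lognormal distributions (default CVs 0.02–0.20, chosen to match the spread
typical of replicate plants in controlled experiments). All parameters load
on a single latent "vigor" factor with per-parameter relative loadings
scaled by the scenario's `coupling` ∈ [0, 1]; a Gaussian latent factor was
chosen over copulas because it sets pairwise correlations with one
interpretable knob and makes the coupling–correlation monotonicity easy to
reason about. The operating point solves the supply–demand balance
Ci = Ca − 1.6·A(Ci)/gs by bracketing; transpiration is gs·VPD/P; the light
and CO2 curves come from the forward models above; fluorescence signals are
constructed to match the drawn parameter values (Fo′ by the standard
Fo/(Fv/Fm + Fo/Fm′) reconstruction) and passed through the fluorescence
operation. Independent multiplicative measurement noise (default 3%) is
added per reported variable — this is also what keeps the deterministic
ETR–ΔF/Fm′ relation from collapsing to |r| = 1.

By default the measured variables are derived through closed-form
evaluations of the same forward models that would generate the curves; with
`refit=True` each replicate's light and A/Ci curves are generated with noise
and refitted by least squares. The default skips the refit because on
model-generated curves the fit is the identity map (verified separately in
the fitting tests) and the statistical properties of the simulator are
needed at sample sizes where 2×n nonlinear fits per cell would dominate
runtime. Replicates whose draw fails (e.g. non-positive assimilation) are
regenerated and counted in `table.meta["n_regenerated"]`.

**Presets** encode the two factorial designs: parameter means per cell
follow the published treatment means (Vcmax 61–84 µmol m⁻² s⁻¹ for the C3
species, 10–27 for the C4; Rd, gs, fluorescence levels likewise), 7
replicates per cell, fixed per-cell seeds. Couplings rise with stress —
temperature: 0.70/0.82/0.92 (C3) and 0.65/0.58/0.90 (C4, reproducing the
observed dip at 30 °C); water: 0.80/0.96 (C3) and 0.65/0.90 (C4) — so the
population connectance increases with temperature and water deficit, the
qualitative published pattern, with a contrast large enough to be resolved
at inflated sample sizes (n ≈ 200). The presets are illustrative study
conditions, not reconstructions of the unpublished correlation matrices; at
the realistic n = 7 the built-in contrasts are (intentionally and
instructively) swamped by sampling noise.

What the simulator does **not** emulate: temperature dependence of kinetics,
mesophyll conductance, TPU limitation, instrument drift, non-Gaussian
outliers, or any between-plant structure beyond one latent factor.
Consequently, passing tests demonstrate that the pipeline measures what it
claims on data with known structure — not that real leaves have that
structure.

## Treatment comparisons and reports

One-way ANOVA (within species, across conditions — the reporting unit used
in the published mean tables) with Tukey HSD at α = 0.05 and a compact
letter display. Letters are assigned from the maximal cliques of the
non-significance graph (networkx), which guarantees the two defining
properties: groups sharing a letter are never significantly different, and
every non-significant pair shares a letter. A zero-variance group produces a
warning, not an error.

Percent changes use the reference-denominator convention (change relative to
the unstressed cell: 30 °C or 100% water) and half-up decimal rounding
(`round_half_up`, implemented over `decimal` to avoid binary-float
surprises). The published narrative claims that are recomputable from
printed cells are: +82% and +15% (global connectance, temperature run) and
−60/−31/−25% (dry mass). Two published claims do not recompute from any
printed cells (the respiration decomposition and the water-run dry-mass gain
percentages) and one printed global-connectance cell is inconsistent with
its own module values by one last digit; the demo report flags these rather
than reproducing them.

Report CSVs carry a header comment with a hash of the analysis-defining
config fields and the seed; the demo (`full_reproduction_demo`) interleaves
synthetic mean tables, connectance tables, percent changes, the published
aggregation check, and full per-pair detail (11 tables), deterministically
per seed.

## Problem sizes and numerical choices

Test and acceptance computations use: n = 10000 replicates for
distributional recovery (error of module connectance < 0.02 with
probability ≈ 0.997), n = 1000 null pairs × 199 permutations for
calibration, n = 200 per cell for the end-to-end direction check, n = 7 for
everything illustrating the realistic design. Tolerances: 10⁻¹² for the
z-transform identity, 1% for noiseless fit recovery, ±0.01 for the printed
aggregation identities. Ties in the permutation test are counted as extreme
(the +1 convention), making the test exact under the null.
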