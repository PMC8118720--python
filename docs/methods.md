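# Methods

This note documents the forward model behind the synthetic experiment,
the statistical procedures, the numerical choices, and what the package's
passing tests do and do not establish about real data.

## The experiment template

One *microcosm* is a sealed jar of sterilised, ground grassland litter
(default 5 g) inoculated with a single fungal isolate and wetted to a
fixed fraction of water holding capacity (WHC).  The default design is
fully factorial: 15 isolates plus one uninoculated control × 3 moisture
levels (4, 27, 50 % WHC) × 2 replicate jars = 96 microcosms, incubated
for several weeks and then destructively measured.  Raw measurements per
jar are: initial and final litter mass; hyphal lengths in 10 microscope
fields (2 filters × 5 fields) of a stained hexametaphosphate extract; and
fluorescence readings of 96-well enzyme assays (8 wells each for samples,
homogenate controls, substrate controls, standards, quench standards and
blanks) for four enzymes: cellobiohydrolase (CBH), β-glucosidase (BG),
β-xylosidase (BX) and N-acetyl-β-D-glucosaminidase (NAG).

## Forward model (synthetic data)

Each isolate carries a latent trivariate normal vector on log scale —
yield `Y`, acquisition `A`, stress tolerance `S` — with configurable
covariance (default: marginal SDs 0.5/0.5/1.0, no cross-correlation).
Optionally, rank-level fractions share latent variance within phylum,
class, order or family taxa without changing the marginal law; the
default puts all variance at the isolate level, i.e. the default
experiment represents null conditions (no trade-offs, no taxonomic
conservatism), and structure is injected explicitly where a study needs
it.

* **Moisture response.**  Expected total hyphal length is a Gaussian
  kernel over WHC, `L(w) = L_peak · exp(−(w − w_opt)²/2σ_w²)` with
  `L_peak = 250 m`, `σ_w = 0.18`, and an optimum
  `w_opt = 0.04 + 0.46·logistic(−S)` that moves monotonically from the
  wettest to the driest treatment as the stress latent grows.  Any
  unimodal kernel with a monotone optimum would do; the Gaussian makes
  the MAI provably monotone in `w_opt` (the derivative of a
  softmax-weighted mean is a positive variance term), which the
  forward–inverse rank test exploits.
* **Mass loss.**  `Δm = L / (250·e^Y)` g, capped at 90 % of the initial
  mass, so the isolate's true growth yield is `250·e^Y` m g⁻¹ wherever
  the cap does not bind (the cap binds in ≲0.2 % of draws at default
  settings).  Defaults give a median mass loss of ~1 g in 5 weeks — a
  realistic decomposition extent for grass litter — and hyphal
  lengths of order 50 m per gram litter.
* **Enzymes.**  True per-gram activity of enzyme *e* is
  `base_e · e^A · exp(c_e(w − 0.27))` with bases 50/200/60/100
  nmol h⁻¹ g⁻¹ for CBH/BG/BX/NAG and a log-linear moisture tilt
  (default: only NAG responds, c = 1.5).  All four enzymes share the
  acquisition latent, so enzyme–enzyme correlations are genuinely
  positive by construction — deliberate, as co-regulated exoenzyme
  suites are the empirically common case.
* **Plates and micrographs.**  Well fluorescence is constructed as the
  exact algebraic inverse of the activity equation (emission coefficient
  4000 fluorescence units nmol⁻¹, quench 0.8, blank 50, small homogenate
  and substrate backgrounds), and field lengths as the exact inverse of
  the microscopy scale-up; Gaussian well noise (SD 20), lognormal field
  noise (σ = 0.3), balance error (SD 0.02 g) and lognormal jar-level
  variability (CV 0.15 on growth and mass loss jointly, preserving
  yield; CV 0.15 on activity) are added on top.  With all noise at zero
  the trait derivation recovers every true quantity to floating point.
* **Seeding.**  One experiment seed drives fixed-key substreams per
  output table (latents, jars, microscopy, enzymes), so adding a table
  never perturbs earlier ones; the pipeline derives per-stage seeds from
  a single global seed.  Identical configurations and seeds give
  byte-identical CSVs.

What the generator does **not** emulate: plate spatial/edge effects,
substrate depletion, contamination, drying during incubation, or
image-analysis artefacts.  Within-isolate replicate variance in the
study is unknown (not reported), so the noise defaults are plausible
magnitudes, not estimates; calibration results below are statements
about these conditions, not about any particular laboratory.

## Trait derivation

* Total hyphal length per microcosm = per-gram microscopy length × litter
  mass **remaining** at harvest (configurable to initial mass; the mass
  basis cancels out of growth yield up to the explicit factor).
* Growth yield = total length / mass loss; non-positive mass loss yields
  an undefined-yield flag (NaN) and exclusion from yield analyses.
* Enzyme reduction: emission coefficient from the buffer standard, quench
  coefficient from the homogenate standard (clamped to (0, 1.5] with a
  QC warning; a fully quenched plate gives a missing activity), activity
  per gram from the standard fluorometric equation, then × mass remaining.
  Negative activities (possible for noisy near-zero plates) are counted
  and truncated to zero by default (`allow_negative_activity` keeps them).
* MAI per isolate uses replicate-mean total lengths per moisture level
  (pooled sums are a config option; identical for balanced data).
  Controls are excluded from all trait tables but summarised in the log.

## Pairwise trade-off tests

Fit on isolate × moisture replicate means (45 rows for the default
design).  The model for a response trait y and predictor trait x is

```
y_ij = β0 + β_w w_j + β_b x̄_i + β_d (x_ij − x̄_i) + u_ranks + u_isolate + ε_ij
```

with nested random intercepts at phylum/class/order/family (genus
optional) **plus isolate**, and the predictor split into its
between-isolate mean and within-isolate deviation.  The reported slope,
t and p belong to the between-isolate term `β_b`: a life-history
trade-off is a claim about isolates, and with repeated measures per
isolate a single undecomposed slope is statistically untrustworthy in
both directions — without the isolate intercept the test is
anticonservative (rows within an isolate are correlated), and with it a
single slope is shrunk toward zero whenever both traits carry independent
within-isolate measurement noise, which caps power well below what the
between-isolate signal supports.  Growth yield is rank-transformed
(average ranks) whenever it enters, as its raw values are strongly
right-skewed; ranking makes its regressions invariant to any strictly
increasing transform.

Variance components are estimated by REML with a small internal engine
(direct likelihood over the variance vector, L-BFGS-B on log scale,
multiple starts); inference on `β_b` uses the Kenward–Roger first-order
adjusted covariance with Satterthwaite denominator degrees of freedom
(numeric REML Hessian; df capped at the residual df, floor 1).  The
plug-in GLS standard error ignores the uncertainty of variance
components estimated from as few as 2–8 groups, and simulation shows it
is materially anticonservative here; the KR adjustment restores nominal
size.  Reported df are therefore estimates and can vary noticeably
between near-identical datasets; p-values are the stable quantity.

**Known limitation.**  When independent traits both carry *strong*
variance at a rank with very few levels (e.g. 2 phyla), their chance
alignment through that rank cannot be corrected by any within-dataset
procedure — the rank's variance component is unidentifiable from 2
levels, and simulations show residual anticonservatism (~0.08–0.10 at
nominal 0.05) no matter whether the rank enters as random, fixed, or via
simulation-based nulls.  This is a property of the design (15 isolates,
2 phyla), not of the implementation; with the default generator (no
taxonomic conservatism) and with moderate rank-level structure the test
is calibrated.  The error-calibration suite pins the type-I error of the
MAI–growth-yield test (the one pair that is exactly independent under
the null configuration) to [0.03, 0.07] at α = 0.05 and verifies ≥ 90 %
power against a latent yield–acquisition correlation of −0.9.

A caveat worth knowing when reading real output: standardising enzyme
activities by litter mass remaining couples them weakly to growth
(faster-growing isolates leave less litter), so activity–MAI and
activity–yield pairs are not exactly null even when the underlying
latents are independent.  This is a property of the standardisation
choice itself, which follows the original protocol.

## Taxonomic variance components

Per-rank nested variance components of an isolate-level trait are
estimated by ML (intercept-only mean), with a boundary-corrected LRT
(½χ²₀ + ½χ²₁) per rank.  Two share columns are reported: the joint-fit
share, and a *parsimonious* share after backward elimination of
components whose LRT p ≥ 0.05 (the `step`-style workflow standard for
mixed models).  The distinction matters: with 8 families nested in 4
orders, iid family effects produce chance between-order variance that an
unbiased joint fit must sometimes assign to the order component, so the
joint family share understates a pure family signal in a sizeable
fraction of datasets.  The recovery suite shows the parsimonious family
share exceeds 0.8, and the family LRT is significant, in ≥ 90 % of
simulations with all isolate variance injected at the family rank.  The
default taxonomy template nests taxa in balanced blocks (2 phyla / 3
classes / 4 orders / 8 families / 12 genera / 12 species for 15
isolates) precisely so that every order holds two families and the
family component stays identifiable.

## Redundancy analysis

Trait matrix: growth yield, total hyphal length, mass loss and the four
standardised activities, centred and (by default) unit-scaled, since the
columns mix m g⁻¹, g and nmol h⁻¹.  Constraints: numeric WHC plus
species indicator columns.  The implementation is direct linear algebra:
rank-revealing orthonormal basis of the centred constraints, projection,
eigendecomposition of the fitted cross-product on the (n − 1) scale —
verified to 1e-8 against a brute-force hat-matrix oracle and against
vegan's `rda` on a frozen instance.  Significance comes from a
permutation test of the pseudo-F, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`
(add-one convention, 999 permutations by default).  Classical RDA has no
random effects; the taxonomic hierarchy is honoured either by shuffling
rows only within a stratum (family by default) or by partialling
phylum/order/family indicator blocks out of both matrices (partial-RDA
mode).  Both are explicit approximations and are recorded in the result
notes.  Growth yield enters unranked here.

## Numerical and degenerate-input choices

* Variance components snapped to exact zero below a relative floor;
  residual variance floored at 1e-12 × Var(y) so exact deterministic
  relationships yield finite (enormous) t statistics instead of a
  singular solve.
* Negative KR-adjusted variances (possible when the numeric Hessian is
  near-singular) fall back to the plug-in variance.
* MAI normalises lengths before the weighted sum, so subnormal totals
  cannot underflow the numerator.
* ANOVA uses type-II sums of squares (equal to the classical balanced
  decomposition); a single-level factor is dropped with a warning, an
  unreplicated layout omits the interaction, and an all-constant response
  reports zero SS with undefined F.
* Eigenvalues are clipped at zero and sorted; quench clamps, invalid
  standards, negative activities, undefined yields and excluded controls
  are all counted in the derivation log and surfaced in the run manifest.

## Problem sizes used by the validation suites

The calibration suites run the full pipeline end-to-end: 1000 simulated
experiments for each type-I study (the RDA null uses 199 permutations
per dataset), 200 for the power and taxonomic-recovery studies, and 200
for the specificity study.  These sizes give Monte-Carlo standard errors
of ~0.007 on a 5 % rejection rate and ~0.02 on a 90 % detection rate,
sharp enough to distinguish nominal from broken calibration while
keeping the whole suite in the minutes range on a single CPU.
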