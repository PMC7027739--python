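# Methods

This note records the models, conventions and numerical choices behind
`microsoc`, in the order the pipeline applies them.

## Measurement conversions

**Respiration.** Headspace CO₂ accumulation is converted with the ideal
gas law.  With pressure in kPa and headspace volume in litres, kPa·L = J,
so the molar amount of headspace gas is n = p·V_hs/(R·T) directly; the
respired carbon is n × ΔCO₂(ppm) × 10⁻⁶ × 12.01 g/mol, expressed in µg,
divided by soil dry mass and scaled from the t-hour incubation to a
per-day rate by ×24/t.  We deliberately define the contract in these
dimensionally explicit terms rather than carrying opaque power-of-ten
factors: every rate in the package is in µg C g⁻¹ DW day⁻¹, and the
conversion is required (and tested) to agree with an independent stepwise
SI computation to <10⁻¹⁰ relative error.  For the standard 24-hr
incubation the hour→day factor is exactly 1, so the two plausible
readings of the time normalisation coincide.

**Growth.** New DNA is O_total × (at%_excess/100) × (100/at%_label) ×
(100/31.21), where 31.21% is the oxygen mass fraction of dsDNA and
at%_excess is the enrichment of the labeled sample over the mean of the
natural-abundance controls.  Negative excess — routine measurement noise
at low growth — is clamped to zero with a warning by default; `strict`
mode raises instead.  DNA production becomes biomass-C production through
the per-sample conversion factor f_DNA = C_mic/DNA content (both per g
DW), never a global constant.

**Derived quantities.** Uptake is the exact sum growth + respiration;
CUE = growth/uptake ∈ [0, 1) and is undefined (an error, never silently
zero) when both rates are zero.  Biomass-specific rates are reported in
ng C µg⁻¹ C_mic day⁻¹ (×1000 from the µg/µg ratio); turnover time is
1000/q_growth days, i.e. the reciprocal of the fraction of biomass renewed
per day.  Replicate samples are processed individually and aggregated to
plots by arithmetic mean.

## Stoichiometry

Fumigation extraction uses C_mic = (C_fum − C_unfum)/k_EC with k_EC = 0.45
applied by division, the standard extraction-efficiency convention.  The
amino-sugar partition subtracts bacterial glucosamine from total
glucosamine on a **molar** basis (1:1 with muramic acid in bacterial cell
walls, M_mur = 251.23, M_glcn = 179.17 g/mol) and then applies the
**mass-based** conversion factors 45 (muramic acid → bacterial necromass
C) and 9 (fungal glucosamine → fungal necromass C), reported in mg C g⁻¹
DW.  The molar-subtraction/mass-conversion split follows the protocol the
factors were derived for; both molar masses are configurable.

## Design statistics

**Block correction** recentres each block on the grand mean
(x − (block mean − grand mean)).  A literal "add the difference" would
double block effects rather than remove them; recentring is the only
reading under which corrected block means equal the grand mean and the
operation is idempotent, both of which are enforced by tests.

**Mixed models.** All inference uses ML (not REML) fits of a
random-intercept model per block, because likelihood-ratio tests between
nested fixed-effect structures require comparable likelihoods.  The
engine profiles the likelihood over the variance ratio θ = τ²/σ²
(Sherman–Morrison closed forms per block, one-dimensional bounded
optimisation, explicit θ = 0 boundary candidate) and is verified against
statsmodels `MixedLM` to ~10⁻⁵ in log-likelihood.  Wald t-statistics use
the small-sample rescaling n/(n−p) of the ML residual variance with
n−p degrees of freedom.  A constant response is returned as a degenerate
perfect fit with equal likelihood across nested models (LR = 0, p = 1)
instead of amplifying floating-point cancellation noise through the log
of a near-zero variance.

**Sequential LR scheme.** Per response: log PSR against the intercept-only
model; functional group richness added to the PSR model; each identity
flag (small herbs, tall herbs, grasses, legumes) added separately to the
PSR+PFGR model.  Each test has 1 df against χ²(1); the reversed order
(PFGR first) is available and leaves the identity tests unchanged.
Significance codes use ≤ thresholds (.1 †, .05 \*, .01 \*\*, .001 \*\*\*),
boundaries mapping to the stronger code.  No multiple-testing correction
is applied across responses, matching the analysis design this package
reproduces.

**Transforms.** Variables are linearised before modelling via a registry
(defaults: root C log, growth sqrt, biomass-specific growth and turnover
time log, F:B necromass ratio log; PSR always enters as log).  Only these
transforms are recoverable from the source analysis; others are
configurable and default to identity.

## Piecewise SEM

Each endogenous vertex of the DAG is fitted on its parents by the mixed
model above.  Standardized coefficients are raw coefficients ×
SD(cause)/SD(effect), with sample SDs on the transformed scale; binary
exogenous flags are standardized the same way for comparability.

**Directed separation.** The basis set contains one claim per non-adjacent
vertex pair, conditioning on the union of both vertices' parents; the
later vertex in (lexicographic) topological order is the regression
response.  This convention is validated exhaustively against graphical
d-separation on every DAG with ≤5 vertices.  Claim p-values combine into
Fisher's C = −2 Σ ln pᵢ ~ χ²(2k); p-values are floored at 10⁻¹⁶
(configurable) to keep C finite.  A saturated model reports C = 0 with
0 df as a perfect-fit sentinel.

**Information criteria.** AIC = C + 2K and AICc = C + 2K·n/(n−K−1), the
likelihood-free criteria of the d-separation framework.  K counts fixed-
effect coefficients plus intercepts across submodels; random-intercept
variances are not counted.  This is the dominant convention in the
piecewise framework but not the only one, so K is exposed on the results
object.  AICc raises when n ≤ K+1.

**Missing paths.** Claims rejected at the 5% level are reported as
candidate edges and never added automatically — whether a statistically
significant path is mechanistically meaningful is the analyst's call.

Indirect effects enumerate all directed paths of ≥2 edges between two
vertices and multiply the standardized coefficients along each; per-path
values and their sum are both returned.

## Synthetic-data generator

The generator is the package's verification instrument: it produces data
with exactly the statistical structure the analysis assumes.

* **Design**: 81 plots by default — PSR levels {1, 2, 4, 8, 16, 60} with
  replication (15, 16, 16, 16, 14, 4) — assigned round-robin to 4 blocks
  within each level; functional-group richness uniform on 1..min(PSR, 4)
  with exactly that many presence flags.
* **Causal system**: standardized log PSR drives each downstream vertex
  linearly with the configured path coefficients.  Defaults take the
  reported standardized effects PSR→growth = .25, PSR→biomass = .42,
  biomass→SOC = .68 directly; PSR→rootC = .40 was fixed once at a value
  typical of root-biomass responses in such gradients, which then pins
  rootC→growth = .15/.40 = .375 and rootC→biomass = .06/.40 = .15 from
  the reported indirect effects, and growth→biomass = .09/(.25+.15) =
  .225 from the indirect effect transmitted through both growth routes.
  growth→respiration = .35 reproduces a moderate positive coupling, and
  PSR→fungal necromass = .45 the strong necromass response.  Each vertex
  receives a per-block intercept (SD 0.15 on the standardized scale — a
  modest share of variance, ~2%) and residual noise sized from the
  implied covariance of its parents so total standardized variance is 1;
  an infeasible coefficient set raises before any data are drawn.
* **Scales**: standardized values are mapped to the published per-level
  summary (pooled means/SDs; bacterial necromass, absent from that table,
  uses 3.0 ± 0.45 mg C g⁻¹ DW, giving F:B ratios near 1.3–1.4).
  Variables with a registered transform are generated on that scale (log
  root C, sqrt growth) and back-transformed, keeping the system linear on
  the analysis scale — this is why standardized-coefficient recovery is
  unbiased.  Transformed-scale SDs come from the delta method.
  Positivity is enforced by redrawing residuals, never clipping, to avoid
  attenuating the coefficients.
* **Raw tables**: every measurement equation is inverted (headspace CO₂
  from respiration; isotopic excess and DNA content from growth and the
  target f_DNA = 50; fumigation pairs over a 140 µg C g⁻¹ baseline;
  amino-sugar concentrations from the necromass split), with incubation
  geometry 2 g soil, 24 hr, 295.15 K, 101.325 kPa, 20 ml headspace, 97 at%
  label, 0.2 at% natural abundance, 10 µg extract oxygen.  A latent value
  that would need more isotopic excess than the label can supply raises a
  configuration error.  The pipeline recovers all latent values to
  <10⁻⁹ relative error (observed: ~10⁻¹⁶).

What the generator does **not** emulate: realized (as opposed to sown)
species composition, soil-texture gradients, temporal dynamics,
measurement error in the instrument tables (raw values are exact
inversions), non-linear or threshold diversity effects, and correlated
residuals between vertices.  Passing tests therefore demonstrate that the
estimators are correct and calibrated under the assumed model, not that
the model is true of any real grassland.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to keep Monte-Carlo error well
inside the tested tolerances: coefficient recovery averages 200 replicates
at n = 200 (SE of the mean ≈ 0.005 per edge against a 0.05 band);
detection rates use 100 replicates at the design's own n = 81; Fisher's C
calibration uses 500 replicates (binomial SE ≈ 0.01 against the
[0.03, 0.08] band).  All randomness descends from one root seed through
named substreams (design / latent / tables), so identical configurations
produce byte-identical datasets.

## Known limitations

* The mixed-model engine supports exactly one random intercept — the
  design's block structure — not nested or crossed random effects.
* d-separation tests assume linear-Gaussian submodels; non-Gaussian
  responses would need generalized submodels the package does not fit.
* Variance–covariance SEM (RMSEA/SRMR fit indices, bidirectional edges)
  is out of scope; submodel residuals are exposed for external tools.
* The LR tests' χ²(1) reference is asymptotic; at n = 81 the empirical
  type-I error is ~5–6%, within the tested [3%, 8%] band but not exact.
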