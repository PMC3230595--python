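# Methods

## The model

The analysis treats species mean traits as the outcome of Brownian motion
on a rooted phylogeny: for tips *i*, *j*, `Cov(y_i, y_j) = σ² C_ij` where
`C_ij` is the summed branch length from the root to the most recent common
ancestor. All comparative machinery in the package — independent
contrasts, phylogenetic GLS, size correction — follows from this one
assumption. A star phylogeny (C = I) recovers conventional statistics as
a special case, which is exploited throughout for oracle tests.

## Branch lengths

Divergence times are unavailable for the composite topology, so lengths
are assigned from the topology alone:

| scheme   | node height rule                      | ultrametric |
|----------|---------------------------------------|-------------|
| constant | every branch = 1                      | no          |
| grafen   | (descendant tips − 1), root scaled to 1 | yes       |
| pagel    | depth = 1 + max(child depths), tips 0 | yes         |
| nee      | ln(descendant tips)                   | yes         |

Two conventions are fixed for reproducibility and are otherwise
inconsequential: Grafen heights are scaled so the root sits at height 1
(the rho = 1 case), and Nee heights use the natural log. Both choices
change **C** only by a global scale factor, which cancels in GLS
coefficient estimates and P values (σ̂² rescales inversely); a regression
test asserts this invariance. The default scheme is Nee, which passes the
contrast-standardization diagnostic for all analyzed traits on the
packaged data; the pipeline runs the diagnostic for all four schemes and
logs which pass rather than hard-coding the outcome.

Polytomies are resolved to zero-length bifurcations deterministically
(seed 0 recorded in the run log). A contrast node whose *both* child
branches have zero adjusted length is degenerate and raises; a single
zero branch merely passes its child's value through.

## Estimation choices

* **ML, not REML.** `lnL = −½[n ln(2πσ̂²) + ln|C| + n]` with
  `σ̂² = e'C⁻¹e/n`, so star and tree fits are compared on the same
  likelihood scale by `LRT = 2|Δ lnL|` against χ²₁(0.05) = 3.841. At or
  below the critical value the *phylogenetic* model is selected — species
  are never truly independent, so the tie goes to the tree.
* **Coefficient tests.** Standard errors use the small-sample correction
  `σ̂² n/(n−k) (X'C⁻¹X)⁻¹` with t on n−k df — equivalent to the usual
  unbiased-variance OLS t-test when C = I. This convention is isolated in
  `gls_fit` and verified against an independent OLS implementation.
* **Through-origin contrast correlation** uses df = (contrasts − 1),
  the standard convention of the contrasts literature.
* **t and χ² tails** are computed from the regularized incomplete
  beta/gamma functions; a separate high-accuracy distribution library is
  used as the oracle in tests only.
* **Degenerate inputs** fail loudly: non-positive-definite C and
  ill-conditioned designs raise (no silent ridging); a perfect fit
  (σ̂² = 0) raises rather than reporting an infinite likelihood. The
  regression grid records such cells as degenerate rows instead of
  crashing.

## Size correction and SDI

Each digit ratio is regressed on intercept + log10 SVL by GLS with the
tree covariance, separately per sex × limb (four regressions per limb
type), and the *raw* residuals `y − Xβ̂` are the size-corrected traits:
the slope is estimated phylogenetically but residuals stay on the trait
scale. The sexual dimorphism index shifts both residuals by +1 (making
them positive on these data) and takes m/f when male-biased, 2 − f/m when
female-biased; the index is continuous at equality and scale-free in the
shifted values. A shift that fails to make a residual positive raises
with the offending value.

## FDR family

The regression grid fits 8 traits × 5 substrates × 2 models = 80 cells,
but the FDR family defaults to the 60 hypotheses of the six derived
traits (size-corrected ratios per sex × limb, SDI per limb); the two SVL
rows are reported alongside but excluded from the family, matching the
stated 60-hypothesis design. `fdr_family="eight"` pools all 80 instead.
Q-values use the default lambda grid 0.00–0.90 (step 0.05) and B = 1000
bootstrap resamples with a fixed seed; with π₀ forced to 1 the output is
exactly Benjamini–Hochberg, which is the oracle identity used in tests.

## Species means, not individuals

Individual specimens are not available, so ratios are computed from
species-mean digit lengths (the ratio of mean logs rather than the mean
of individual ratios). The two differ at second order, roughly
`SE²/mean²` per species — with typical digit SE/mean below 5%, the error
on a ratio is well under 0.01 — and the package's paired t statistics and
correlations land within a few percent of individual-based values. This
approximation notice is logged on every fixture run.

## Synthetic data generator

The generator emulates the structure the analysis assumes: female log10
SVL evolves by Brownian motion (rate 0.01 per unit Nee branch length,
root 1.88 ≈ 76 mm) with a constant male offset (+0.043 log units,
matching the observed male bias); log10 digit lengths follow sex-specific
allometries centered on values estimated from the packaged tables, plus an
independent Brownian deviation per digit (rate 0.002); habitat is a
Dirichlet draw (concentration 15 on a dominant substrate) whose dominant
class switches along the tree under a low-rate Markov process (rate 0.5
per branch-length unit), so substrate use is phylogenetically clustered as
in real data — an i.i.d. option exists for null calibration; individuals
(default 10 per species × sex, ≈ the fixture median) are drawn
log-normally around species means with 10% CV and summarized exactly as
the real tables are (mean, SE of mm-scale values). The optional
ecological effect lengthens the female front-limb digit IV in proportion
to perch use, the pattern the analysis is designed to detect.

What the generator does **not** emulate: measurement error correlated
across digits within a specimen, unequal or tiny sample sizes (the real
tables go down to n = 3), left–right asymmetry, and any developmental or
hormonal mechanism. Passing tests on synthetic data therefore demonstrate
statistical correctness of the pipeline under its own model, not the
biological claims themselves.

## Problem sizes in tests

Monte-Carlo suites use the 25-tip study tree with 300–2000 replicates
(type-I error at 1000, contrast-variance checks at 400 × 24 contrasts,
covariance checks at 2000 draws on 3-tip trees), sizes at which binomial
or moment-based error bands are a few percent; each assertion's tolerance
is stated next to its replicate count in the test.

## Known limitations

* The composite topology is a transcription; within-genus resolutions
  carry the uncertainty documented in the fixture header. Quantities that
  depend on the tree (contrast correlations, PGLS coefficients,
  likelihoods) shift by a few percent under plausible alternative
  resolutions; conventional statistics are unaffected.
* Only the four arbitrary branch-length schemes are provided; no Pagel's
  λ, OU, or other covariance transforms.
* Regressions are univariate per substrate (the indices sum to one, so a
  joint design would be collinear by construction).
* No individual-level asymmetry analysis; only right-side measurements
  are represented in the species tables.
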