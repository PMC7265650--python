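# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that make runs bit-reproducible.

## Preprocessing

Quantified matrices pass through a fixed order: log2 transform →
detection filter → imputation.  Running stages out of order raises a
state error (imputation requires the log scale; feature selection
requires a fully observed matrix).

* **Detection filter.**  A feature is kept when its observed fraction is
  at least `min_fraction` (default 0.75), boundary inclusive — "at least
  75%" is read literally.
* **Imputation.**  Missing metabolite intensities are treated as
  left-censored (below the detection limit), so each missing entry of
  feature *f* is drawn from `Normal(mean_f − shift·sd_f, (width·sd_f)²)`
  with `shift = 1.8` and `width = 0.3` in units of the feature's observed
  standard deviation — the widely used downshifted-normal defaults for
  proteomics/metabolomics missing-not-at-random imputation.  Statistics
  are per feature; a per-sample variant is available via the function
  arguments.  Observed values are inputs, never targets: they are never
  altered.
* **Feature selection.**  For expression data the k most variable
  features (sample sd, default k = 2000) are retained; ties break to the
  lexicographically smaller feature id so runs are reproducible.
* Zeros in input TSVs are observed values by default; a
  `zero_as_missing` flag supports dialects that encode below-detection
  as 0.  No normalization beyond log2 is applied.

## Decomposable Gaussian graphical model

Data are modeled as multivariate Gaussian on the log2 scale.  Learning is
two-stage:

1. **Chow–Liu tree.**  Edge weights are the Gaussian mutual-information
   log-likelihood gains `−(n/2)·ln(1 − r²)`; Kruskal's algorithm with
   lexicographic tie-breaks yields the maximum-likelihood spanning tree.
   A disconnected candidate set yields a forest with a warning.
2. **Stepwise BIC forward selection.**  At each step, among the
   non-edges whose addition keeps the graph chordal, the edge with the
   largest strict BIC reduction is added; the search stops when no
   candidate reduces BIC.  The parameter count is `2p + |E|` (means,
   variances, one free covariance per edge); constants cancel in
   comparisons but are kept so traces are comparable across runs.

Two facts keep the inner loop exact and fast.  For a chordal graph G and
non-edge (u,v), **G+uv is chordal iff the common neighborhood
T = N(u)∩N(v) separates u from v** (if two members of T were non-adjacent
they would close a chordless 4-cycle through u and v, so T is complete;
a chordless u-v path avoiding T plus the new edge would be a chordless
cycle, and conversely).  T is then exactly the separator of the new
clique {u,v}∪T, so the likelihood gain is the local term
`−(n/2)·ln(1 − ρ²ᵤᵥ|T)`.  The test suite verifies both facts
independently: candidate sets against brute re-tests with an external
chordality check, and local gains against full decomposable-likelihood
refits (clique/separator sums) to 1e−8.

The stopping rule uses strict BIC decrease.  Greedy forward selection is
a local search: it provably matches an exhaustive per-step search (every
legal addition re-scored by a full-model BIC refit), which is what the
acceptance checks assert; it does not in general reach the global BIC
optimum over all reachable decomposable models, which can require
temporarily BIC-increasing steps.

MLE covariances (denominator n) are used throughout the likelihood
machinery; Pearson correlations are scale-invariant so the tree stage is
unaffected.  All tie-breaks — MCS vertex choice, Kruskal edge order,
candidate order, betweenness ties — are lexicographic on feature ids.

## Branches and functional node activities

The learned graphs are near-trees, so iterated removal of the
maximal-edge-betweenness edge (Girvan–Newman bisection, lexicographic
ties) cleanly isolates subtrees; the number of branches is a user
parameter because it is cohort-specific.  Each branch takes the most
frequent annotation label among its annotated members (ties flagged,
lexicographically resolved; unannotated branches excluded).  A branch's
per-sample activity is the mean of the member features **whose own
annotation matches the dominant label** — members with other labels are
excluded, since the activity is meant to track the node's main function;
averaging all members is available behind a flag.  Group comparison uses
the two-sided Mann–Whitney U test by default (activities are means of
log-scale data of unknown distribution; Welch's t is available), with
Benjamini–Hochberg adjustment across nodes.

## Expression-constrained FBA

The model is the standard constraint-based triple (S, bounds, objective)
with GPR rules and subsystem labels; flux units mmol·gDW⁻¹·h⁻¹, default
|bound| 1000 for unbounded reactions so score·bound stays finite.

* **GPR resolution.**  OR = sum (isozyme capacities add), AND = min
  (complexes limited by the scarcest subunit).  Unmeasured genes are
  dropped from their operator — absence of evidence is not zero
  expression; a `missing_policy="zero"` variant gives the stricter
  reading.  A fully unmeasured rule leaves its reaction unconstrained.
* **Max–min normalization** maps the sample's reaction scores to [0,1]
  within that sample (bounds inside one LP must be mutually comparable;
  normalizing per reaction across samples would not give that).  If all
  scores are equal the sample is uninformative and scores become 1
  (unconstrained), logged.
* **E-flux bounds.**  Scored reactions have both bounds scaled
  (reversible reactions shrink symmetrically; an upper-only variant is
  available).  Exchange reactions are exempt: GPRs do not gate the
  availability of the medium.
* **LP.**  Biomass is maximized by HiGHS linear programming; the default
  solution is parsimonious FBA (minimize Σ|v| at the fixed optimum via
  split variables), because plain FBA optima are degenerate and a "sum
  of fluxes" statistic is otherwise ill-defined.  Reported solutions
  satisfy S·v = 0 and the bounds to 1e−6.
* **Flux activities** are Σ|v| over each subsystem's reactions.
  Absolute values are used because signed sums of reversible fluxes
  cancel arbitrarily under orientation conventions; this is an
  interpretive choice, documented rather than claimed canonical.

## Survival signatures

* **Ranking.**  Each feature is dichotomized at its median and scored by
  the two-group log-rank test (hypergeometric variance with the
  (N−d)/(N−1) tie correction, p from χ²₁); features are ranked by
  ascending p.  A Cox-score ranking is available as an alternative.
* **Compound covariate predictor.**  The top-k features enter a risk
  score Σ wᵢ·zᵢ with wᵢ the univariate Cox coefficient (Efron tie
  handling, Newton–Raphson on the partial likelihood; non-convergent
  features are dropped for the next-ranked) and zᵢ standardized values.
  The cutoff is the training-score median — an a-priori 50:50 split.
  Negative weights are protective (higher abundance, better prognosis).
  This weighted-standardized-sum construction is a reconstruction of the
  classical compound-covariate method, not a bit-faithful port of any
  particular tool.
* **Validation.**  Leave-one-out cross-validation re-runs ranking,
  weighting and the cutoff on every fold — feature selection stays
  inside the loop, and the test suite demonstrates the inflation caused
  by leaking selection outside it.  The permutation p-value permutes
  survival records against samples, re-runs the *entire*
  cross-validation per permutation, and uses the add-one estimate
  `(1 + #{permuted ≥ observed})/(1 + n_perm)`, so p ≥ 1/(n_perm+1) and
  validity holds at finite n_perm; degenerate single-class CV groupings
  count as non-informative.  Default n_perm = 1000.
* **Independence check.**  A multivariate Cox model (lifelines) of
  event ~ risk class + clinical covariates (dummy-encoded, first level
  reference) reports whether the class retains significance; singular
  designs (constant or aliased terms) are rejected with the offending
  terms listed.

The log-rank statistic and univariate Cox fit are implemented directly in
numpy because the permutation test evaluates them hundreds of thousands
of times; both are validated in the tests against lifelines and against
the closed-form two-group exponential MLE.

## Synthetic data

The generator emulates the statistical structure of a two-group tumor
cohort (defaults: 67 samples split into two receptor-status-like groups,
pathway blocks of 8 features, equicorrelation 0.7 within blocks and 0
between, a +1 sd mean shift of flagged pathways in group 2, 15% missing,
censoring 30%):

* **Blocks.**  Features are multivariate normal on the log2 scale
  (centered at 10) with an equicorrelated block per pathway; the
  covariance is Cholesky-checked and non-positive-definite settings are
  rejected at configuration time.
* **Missingness** is probit-on-intensity left censoring:
  P(missing | z) = Φ((t − z)/s) with steepness s = 0.5 and threshold
  t = √(1+s²)·Φ⁻¹(rate), which hits the target marginal rate in closed
  form while making low-intensity values preferentially missing — the
  mechanism the downshifted-normal imputation assumes.  The 15% default
  rate is a free parameter of the simulation, not an empirical claim.
* **Survival** follows an exponential proportional-hazards model with
  linear predictor Σ βᵢ·zᵢ over planted features and a 50-month baseline
  median; censoring is independent uniform on [0, c] with c solved
  numerically so the expected censored fraction matches the target.  The
  default planted feature is protective (β = −1.5), mimicking a
  "glutamine-like" marker whose abundance predicts longer survival.
* **Toy metabolic model.**  Parallel linear pathways (per-pathway
  subsystems, random GPRs over synthetic genes) converge on a shared
  biomass precursor; redundancy matters, because max–min scoring always
  zeroes the lowest-expressed reaction and serial essential chains would
  make growth identically zero.  Uptake bound 10, internal bounds 8, so
  expression constraints actually bind.  The model ships as JSON and
  SBML L3/FBC, and construction verifies a strictly positive biomass
  optimum.

What the generator does **not** emulate: mass-spectrometry peak-level
artifacts (isotopes, adducts, batch drift), realistic inter-pathway
correlation structure, non-proportional hazards, or genome-scale model
complexity (loops, compartments, cofactor coupling).  Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on any real cohort.

## Pipeline and reproducibility

Multi-layer networks z-standardize each feature within its layer before
stacking; Pearson correlation is per-pair scale-free, but tree weights
compare across pairs, so the standardization is explicit and logged.
Layer tags are carried as node attributes so cross-layer mixing is
inspectable.  One top-level seed fans out to per-stage seeds through a
SHA-256 hash of (seed, stage), keeping stages independently
reproducible; every run directory contains a manifest with parameters
and SHA-256 checksums of all outputs, and re-running a config reproduces
the checksums bit-for-bit.

## Problem sizes used by the acceptance checks

Oracle-equivalence and chordality checks run on 5–7-variable problems
where exhaustive enumeration is feasible.  Structure recovery uses the
full stated conditions (5 blocks × 8 features, ρ = 0.8, n = 500, 20
runs).  The survival null calibration uses 50 seeds of a 36-sample,
10-feature cohort with 200 permutations (scaled down from the 1000
production default, which the permutation estimator supports without
modification); the planted-feature check uses 50 seeds at n = 200 with
50 features.  The imputation check draws 10⁴ values.

## Known limitations

* Greedy stepwise selection finds a local BIC optimum (see above); with
  independent blocks at n = 500 the BIC threshold admits occasional
  spurious cross-block edges near the tree bridges (measured at roughly
  0.5 per run), so block recovery is driven by the branch decomposition
  rather than perfect edge-level separation.
* The chordality-preserving candidate set is complete, which is exact
  but O(p²) per step; the implementation is comfortable to a few hundred
  features, not genome scale.
* Flux activities depend on the pFBA tie-breaking among optimal flux
  patterns; alternative optima with equal total |flux| are possible in
  degenerate models.
* The Cox Newton solver handles a single covariate; the multivariate
  independence check delegates to lifelines.
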