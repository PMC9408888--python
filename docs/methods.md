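# Methods

## Statistical model

The core estimator is single-response partial least squares (PLS1),
computed by NIPALS deflation. For autoscaled features X (n × p) and
autoscaled response y, each latent variable a extracts a unit-norm weight
vector wₐ ∝ Xₐᵀyₐ, scores tₐ = Xₐwₐ, X-loadings pₐ = Xₐᵀtₐ/‖tₐ‖², and a
response loading qₐ = yₐᵀtₐ/‖tₐ‖², after which X and y are deflated by the
rank-one contributions. The regression vector for A components is
b = W(PᵀW)⁻¹q. For a single response NIPALS and SIMPLS give identical
models, so no algorithm choice is exposed. When the residual covariance
Xₐᵀyₐ vanishes (e.g. the response is orthogonal to all features, or X has
lower rank than the requested component count), deflation stops early and
the remaining components contribute nothing; cross-validation curves carry
the last attainable prediction forward, which makes rank-deficiency ties
resolve toward fewer components.

PLS is the right tool here because the design is strongly p ≫ n
(150–400 correlated miRNAs against 20–23 samples), where ordinary least
squares is undefined and ridge-type shrinkage would not produce the
latent-variable structure that VIP scoring needs. With full components on
full-rank tall data PLS1 reproduces ordinary least squares exactly; the
test suite checks this against an independent normal-equations solve.

### Autoscaling

Every feature and the response are centered and scaled to unit sample
standard deviation (n−1 denominator). Scaling parameters are recomputed
inside each cross-validation training fold — the held-out sample never
influences the scaling — and predictions are back-transformed to response
units before the error is computed. Constant features are a hard error
naming the feature, since their scale is undefined.

### Model selection and significance

The number of latent variables minimizes the leave-one-out RMSECV over
1..max_components (default cap min(10, n−2, p); n−2 because each fold has
n−1 training samples). Ties resolve to the smaller count. Significance is
a permutation test: B response permutations (default 500, matching the
reference workflow configuration) each repeat the entire procedure,
including component re-selection — the conservative choice, since reusing
the observed component count would bias permuted errors upward — and
p = #{permuted RMSECV < observed}/B. This plain fraction can be exactly 0;
a (b+1)/(B+1) smoothed variant is available behind `smoothed=True`.

### VIP and recursive elimination

VIPⱼ = √(p · Σₐ SSYₐ wₐⱼ² / Σₐ SSYₐ) with SSYₐ = qₐ²‖tₐ‖² the response
variance captured by component a; Σⱼ VIPⱼ² = p holds to machine precision
and is asserted in tests. RFE drops exactly one feature per step (the
lowest VIP; ties eliminate the lexicographically later miRNA ID, making
runs deterministic), re-selecting the component count at every step. The
optimal subset is taken at a requested size (default 50, the reference
configuration) rather than at the global RMSECV minimum, because the
minimum of a noisy RMSECV-vs-size curve is unstable at these sample sizes;
the global-minimum rule (ties toward fewer features) is the fallback when
no size is given. Whether component counts should be re-selected or frozen
during elimination is genuinely open; re-selection was chosen for
consistency with how each subset would be used on its own.

### Exhaustive 2–3-miRNA models

All C(k,2) + C(k,3) subsets of the intersected panel are fitted, each with
its component count selected by LOOCV but capped at the subset size, and
ranked by RMSECV (ties by lexicographic ID tuple). Reported coefficients
are in response units per autoscaled intensity, with the response mean as
the implicit intercept: ŷ = ȳ + Σ Cᵢ·(autoscaled intensity)ᵢ. This
back-transformation convention is the package's own; it reproduces the
training fit to 1e−8 and is verified in tests.

## Clean-up and normalization

"Detected" means raw count ≥ 1 in a sample; the detection filter requires
⌈f·n⌉ detected samples, so f = 0.90 with n = 20 means "at least 18" and
f = 0.825 with n = 23 means "at least 19". The cross-matrix filter removes
miRNAs whose median raw count is *strictly* higher in serum than in liver
(equal medians are retained). Filters run on raw counts, per tissue first
and then jointly; the exact interleaving of per-tissue and joint filtering
is ambiguous in the workflow this reimplements, and the order implemented
here (per-tissue detection, then joint median filter) is documented as a
choice. Size factors are the median-of-ratios estimator over rows that are
strictly positive in every sample, computed per tissue — liver and serum
are never normalized jointly, since they are different matrices with
different depth structure. Factors are not re-centered afterward.

Correlation screening uses normalized values without log transform by
default (a log2(x+1) switch exists); alpha = 0.05 two-sided with **no
multiple-testing correction** — deliberate, matching the screening role of
this step, and worth remembering when interpreting the significant-count
outputs. PCA runs on autoscaled features, consistent with the PLS
convention; component signs are fixed by making each component's
largest-magnitude loading positive.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: an unpaired
liver cohort (n = 20, response = hepatic TG µg/mg protein) and a serum
cohort (n = 23, response = biopsy fat %), sharing one set of 154 mature
miRNAs. Counts are negative binomial with log link,
mean = sⱼ·exp(bᵢ + βᵢzⱼ), var = mean + α·mean²:

| parameter | default | meaning |
|---|---|---|
| n_mirna | 154 | features surviving upstream clean-up in the emulated study |
| n_informative | 25 | miRNAs driven by the latent steatosis variable |
| effect_size | 1.0 | log-fold change per SD of steatosis (1.5 ≈ strong) |
| opposite_trend_fraction | 0.8 | informative miRNAs whose serum sign is flipped vs liver |
| dispersion α | 0.3 | NB overdispersion typical of bulk small-RNA-seq |
| libsize_sigma | 0.3 | SD of log-normal size factors |
| baseline_logmean_range | (1.5, 8.0) | per-miRNA baseline natural-log mean (≈ 4–3000 counts) |
| steatosis_range | (0, 60) % fat | uniform latent phenotype |

Liver TG is an affine map of fat % (210 at 0 %, ≈1948 at 60 %, Gaussian
noise SD 50 µg/mg), spanning the 200–2000 µg/mg range reported for donor
livers. Serum baselines sit one natural-log unit below liver so that serum
medians are generally lower — without this, the cross-matrix median filter
would discard about half the features at random, which does not reflect
real liver/serum abundance structure. The uniform phenotype distribution
is a modeling choice; real cohorts are not characterized beyond summary
statistics. The generator does **not** emulate: read-level artifacts
(adapters, arm mis-assignment), miRNA–miRNA correlation beyond the shared
latent driver, batch structure, or heavy-tailed outlier samples. Passing
recovery tests therefore demonstrate correctness of the selection
machinery under a clean generative model, not expected sensitivity on real
sera.

Reproducibility: all randomness flows from one integer seed through
`numpy.random.SeedSequence` substreams (design, liver, serum, annotation —
and in the pipeline: cohort, per-arm permutation streams), so identical
configs give byte-identical outputs and the run manifest (config + seed +
SHA-256 of every output) suffices to reproduce a run.

## Biological penalty ranking

Evidence per panel miRNA: guide/passenger flag, liver and serum Pearson
r/p, predicted lipid-metabolism target-gene count (consumed as a
precomputed integer — target prediction itself is out of scope), and the
liver/serum mean-abundance ratio (liver-specific miRNAs such as miR-122-5p
sit at L/S ≈ 300–3000; low ratios suggest substantial non-hepatic
contribution). The combined score is an additive penalty (0 best): default
rules are passenger strand −2, each non-significant correlation (p ≥ 0.05)
−1, fewer than 5 lipid targets −1, L/S ratio below 5 (or undefined) −1.
No published weighting exists for combining these criteria, so the rule
set is configuration-driven (YAML) and the defaults are this package's
choice. Ranking is total and deterministic: penalty, then larger
min(|liver r|, |serum r|), then ID.

## Problem sizes and numerical choices

Validation runs use the study-scale conditions directly (154 miRNAs,
n = 20/23, 500 permutations, RFE to 1 feature, 10-replicate recovery
experiments); the full pipeline completes in ~20 s on one CPU, so no
scaled-down surrogate is needed. Degenerate inputs are errors, not
silent fixes: constant features/response, no all-positive normalization
reference row, infeasible component counts, empty ID intersections.
Floating-point output uses fixed formats (%.10g tables, %.17g phenotypes)
so byte-level determinism survives write/read round trips.

## Known limitations

* LOOCV-based selection with n ≈ 20 has high variance; the RMSECV of the
  selected subset is optimistically biased because the same folds guided
  elimination (no outer validation loop is implemented).
* The permutation p-value of the *selected* subset inherits selection
  bias; only the full-model permutation test is unbiased.
* Significance screening is uncorrected for multiplicity by design.
* The exhaustive search is limited to panels small enough to enumerate
  (~25 features); no heuristic search is provided.
* A fold in which a feature becomes constant makes LOOCV fail loudly;
  features that pass the detection filter rarely trigger this.
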