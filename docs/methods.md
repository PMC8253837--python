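# Methods

## Tumor fraction from segmented copy ratios (OTTER)

A plasma cfDNA sample with tumor fraction *t* is a mixture of diploid
normal genome (weight 1 − *t*) and tumor genome in which a segment may
carry an integer copy number *c*. The expected log2 copy ratio of such a
segment is

    E(t, c) = log2( (2 (1 − t) + t c) / 2 )

Given CBS segments with observed log2 ratios CR_i and bin counts l_i, the
estimator evaluates, for every candidate fraction *t* on a grid and every
copy state *c* in a small set, the squared distance d_{i,t,c} =
(CR_i − E(t, c))², assigns each segment its nearest state, accumulates
loss_t = Σ_i min_c d_{i,t,c} · l_i, and reports t̂ = argmin_t loss_t.

Assumptions: a diploid background (the c = 2 expectation is identically
zero at every purity, exact in floating point here because the argument
is computed as 1 + t (c − 2)/2); clonal integer copy states (no subclonal
mixtures); segment noise independent across segments with variance
shrinking in bin count (hence the l_i weighting).

### Parameters

| parameter | default | meaning |
|---|---|---|
| grid | 0.01 … 0.99 step 0.01 | candidate tumor fractions (dimensionless) |
| states | {0, 1, 2, 3, 4} | integer copy states scored per segment |
| min_bins | 100 | segments with fewer bins are discarded |
| excluded contigs | X, Y, M/MT (alias-aware) | sex chromosomes are copy-number confounded by patient sex; mitochondria excluded as a documented extension, toggleable |
| floor | −8 | value substituted when the log2 argument is ≤ 2^floor (c = 0 at high purity); keeps the loss finite |
| flat_tol | 1e−9 | loss-curve range below which `flat_loss` is flagged |

The grid excludes t = 0, so an all-diploid (flat) profile can never be
reported as zero tumor fraction; it is instead flagged `flat_loss` with
the estimate pinned at the smallest grid value. Callers must treat the
flag, not the number, as the signal.

### Ties, aliasing, degenerate inputs

Argmin ties over states resolve to the smaller copy state; ties over the
grid resolve to the smallest tumor fraction and set the `tie_broken`
flag. The smallest-t rule is deterministic and conservative. It also
documents a genuine identifiability limit: a profile whose only aberrant
segments are single gains (c = 3) at fraction t is fit *exactly* by
double gains (c = 4) at t/2, because 1 + t/2 = 1 + (t/2)·2·(1/2); the
estimator returns t/2 and flags the tie. Profiles containing at least
two distinct non-diploid states do not alias and are recovered exactly
in the noiseless case. An empty post-filter set is flagged
`no_segments`, never raised.

The estimator is an exhaustive grid minimization. An
expectation-maximization scheme over the same objective has the same
fixed points but requires initialization choices the objective itself
does not dictate; the exhaustive scan is exact on the grid, trivially
reproducible, and cheap (|T| × |C| × n_segments multiply-adds).

## VAF / ctFE consistency

A somatic variant in an unamplified region is expected at a VAF no
larger than the tumor fraction, so: VAF within the two-sided band
max(0.2 · ctFE, 0.02) of the ctFE → *within tolerance*; below the band →
*consistent*; above → *inconsistent*. The band is evaluated first, so
the three labels partition every (VAF, ctFE) pair, and VAF = ctFE is
within tolerance. The absolute 0.02 floor keeps the band meaningful at
small ctFE, where a pure relative band would collapse. Germline
variants (VAF tracks genotype, not purity) and variants in amplified
regions (VAF inflated by copy number) are excluded upstream of the
comparison; those flags are inputs, since calling them requires matched
normal sequencing.

## Dynamic filtering threshold

The required specificity follows from Bayes' theorem applied to the
odds form of the diagnostic-testing identity:

    specificity = 1 − pre_test_odds × sensitivity / post_test_odds

with post_test_odds = p/(1 − p) for a target post-test probability p,
and pre-test odds supplied per cancer cohort / gene / exon from
historical data (user input here; estimating them is out of scope). A
specificity outside (0, 1) means the prior cannot reach the target
posterior at any threshold and is reported as infeasible rather than
clamped.

The specificity is converted to a minimum alternate-read count under a
beta-binomial null for background errors, parameterized by mean error
rate e and overdispersion ρ (α = e(1 − ρ)/ρ, β = (1 − e)(1 − ρ)/ρ);
ρ = 0 degenerates to Binomial(depth, e). The threshold is the smallest
k with P(X ≥ k) ≤ 1 − specificity, found by binary search on the
monotone survival function (O(log depth) evaluations; a linear scan of
the full support is quadratic-cost in aggregate at panel depths). When
no k up to the full depth suffices, the sentinel depth + 1 is returned:
a shallow locus is a data property, not an error. Per-sequence-context
(e, ρ) pairs can be supplied; the mechanism is provided without default
values, which are assay-specific. The threshold is non-decreasing in
specificity, error rate and overdispersion, and the beta-binomial
threshold converges to the binomial one as ρ → 0.

## MSI calling

Per locus, three opaque metrics (normalized percent lower, mean lower,
mean log-likelihood) summarize the read-length distribution at a
microsatellite; computing them from reads is out of scope and they are
inputs. Features are standardized by the reference panel's per-feature
mean and SD (the three metrics are on different scales), and the
probability of instability is the unstable fraction among the k = 100
nearest reference loci in standardized Euclidean 3-space. Distance ties
at the k-th rank are broken by reference insertion order via a stable
sort, making the vote deterministic. A locus is unstable when its
probability exceeds 0.5 (the canonical KNN majority rule; the
sample-level rule is specified but the locus-level cut is a
documented choice here), and the sample is MSI-high when strictly more
than 50% of loci are unstable — exactly half is MSS.

## Synthetic data

The generators invert each analysis model so every stage can be tested
against known truth:

- **Segments** — log2 ratios drawn as E(t_true, c) + N(0, σ) per profile
  entry, σ on the log2 scale at the segment level. This emulates what
  the estimator consumes and nothing below it: no read-level coverage,
  no GC/mappability bias, no segmentation errors (breakpoint accuracy is
  the upstream tool's concern), no subclonal states. Passing recovery
  tests therefore demonstrates correctness of the estimator given
  correct segmentation, not robustness to segmentation artifacts.
- **Variants** — true somatic records with alt reads ~ Binomial(depth,
  VAF); null background sites ~ BetaBinomial(depth, e, ρ); depths from a
  negative binomial (mean 2000, dispersion 20 by default) emulating
  panel depth variation.
- **MSI panels** — two unit-variance Gaussian clouds in feature space.
  The `separation` parameter offsets *each feature* by that many
  within-class SDs, putting class centers √3 × separation apart in
  Euclidean distance; at separation 6 the per-locus Bayes error is
  ~10⁻⁷, so held-out classification is robustly perfect, while
  separation 0 gives chance level. (A center-to-center offset of 6 SDs
  would leave a ~1.3 × 10⁻³ overlap error — enough that "perfect
  accuracy over 1000 draws" would fail by chance alone — so the
  per-feature convention is the one under which the documented
  separation property is meaningful.)

Every generator takes an explicit seed and owns its
`numpy.random.Generator`; identical arguments give bitwise-identical
output, and generated tables round-trip through the package's own
readers.

## Numerical and I/O choices

- E(t, c) is computed as log2(1 + t(c − 2)/2) — algebraically equal to
  log2((2(1 − t) + tc)/2) but exactly 0 for c = 2 — and via `np.log2`
  in both scalar and vectorized paths so the two agree bitwise.
- Fit reports serialize floats with shortest-roundtrip `repr` and are
  read back with round-trip float parsing, so write→read reproduces the
  loss curve bitwise.
- Upstream per-segment `weight` is carried through I/O but does not
  enter the loss, whose weighting is defined in terms of bin counts
  only.
- Grid argmin ties are detected at 1e−12 relative/absolute tolerance —
  wide enough to catch the exact aliasing ties, far below any noise
  scale.

## Test problem sizes

The suite runs entirely on synthetic data at desk scale: oracle
equivalence on 100 random sets of ≤ 20 segments against a
triple-nested-loop reference; noiseless recovery at all 99 grid values;
noisy recovery with 10 × 150-bin segments (states cycling 1, 2, 3, 4,
σ = 0.05) over 200 replicates at t ∈ {0.1, 0.3, 0.5, 0.7}, asserting
median |t̂ − t| ≤ 0.02 against a 0.01 grid; filter calibration with
10,000 beta-binomial null draws; threshold cross-checks against pmf
tail sums at depths up to 10,000; MSI brute-force KNN cross-checks and
1000 held-out loci.

## Known limitations

- Tumor fraction is only identifiable from aberrant segments; flat
  profiles yield `flat_loss`, and single-state gain-only profiles alias
  downward as described.
- The grid resolution (0.01) bounds precision; no sub-grid refinement is
  attempted because segment noise dominates below that scale.
- Pre-test odds, sensitivity, error rates and MSI features are inputs;
  the package provides the decision machinery, not the assay-specific
  calibrations behind those inputs.
- The consistency rule treats the ctFE as fixed, ignoring its own
  estimation error.
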