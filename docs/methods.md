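# Methods

## Model

All procedures start from the observation that under the global null —
every one of the m tested hypotheses true, every test proper — the
p-values p₁…p_m are i.i.d. Uniform(0, 1), so the count in any histogram
bin of width b is Binomial(m, b). "Proper" matters: for valid-but-
conservative tests (notably discrete ones such as the exact rank-sum test
at tiny n) P(p ≤ α) < α, the first-bin bound is conservative, and the QC
scan is not meaningful at all, because a bump may reflect the discreteness
of the test rather than a quality problem. The permutation machinery does
not share this limitation.

### Binning

Bins are left-closed, right-open, with the last bin closed at 1 so p = 1.0
is counted; a p-value exactly on an interior edge belongs to the upper
bin. The width must tile [0, 1] exactly (b = 1/K): the Bonferroni
correction in the QC test presumes exactly K bins, so non-tiling widths
are rejected rather than truncated. The default b = 0.05 (K = 20) is a
good general-purpose starting resolution; b is an ordinary parameter for
users who want to look more finely at the far-left end. No automatic
bin-width search is attempted. QQ coordinates use the plotting positions
(i − 0.5)/m against the sorted p-values.

### Decision rules

* HC: reject when the first-bin count **strictly** exceeds
  F₁₋α(m, b), the discrete quantile min{k : P(Bin(m,b) ≤ k) ≥ q}. A count
  exactly at the bound does not reject. The test is one-sided (an excess,
  not a deficit, of small p-values is the interesting alternative); a
  two-sided convention is available simply by halving α.
* QC: flag every bin whose count strictly exceeds F₁₋α/K(m, b). The scan
  includes the first bin, but a first-bin flag is reported separately from
  interior/right-side flags: an abundance of low p-values is the expected
  signature of signal, not of failure, so only non-first-bin flags drive
  the "irregular" classification.
* The quantiles are computed from the exact binomial CDF. Tukey's normal
  approximation is implemented in both variance conventions — the
  null-variance denominator √(α₀(1−α₀)) as the default, and the
  observed-proportion plug-in √(f(1−f)) — because the classical formula
  circulates in both forms and they bracket the exact rule: at m = 1000
  the exact bound first rejects at 63, the plug-in variant at 63, the
  null-variance variant at 62; across m = 100…5000 the null-variance rule
  never disagrees with the exact one by more than one count.
* Classification: `enriched` (HC only), `irregular` (interior QC flag
  only), `enriched_and_irregular`, `uniform`. When permutation thresholds
  are available they replace the analytic bounds in this classification;
  both sets are always reported.

### Permutation null

For an n×m feature matrix with independent two-group design, relabelling
rows (equivalently, permuting rows of X intact) removes any association
with the grouping while preserving the inter-feature correlation of every
row. For paired designs the analogue is swapping the members of a pair,
i.e. flipping the sign of the within-pair difference. Each replicate
reruns the original per-feature test, bins the p-values, and records the
first-bin and maximum bin counts; the correlation-adjusted HC and QC
bounds are the 95th (by default) empirical percentiles of those two
count series, with linear interpolation between order statistics.

Distinct-assignment counting treats two assignments that give the same
two-sided test identically: C(n₁+n₂, n₁) halved when n₁ = n₂ (label
swap), 2ᵏ halved to 2ᵏ⁻¹ (global sign flip). A percentile at level q
needs at least ⌈1/(1−q)⌉ distinct assignments (20 at the 95th percentile),
otherwise the estimate would just be the sample maximum and the run is
refused with an informative error — three pairs, with four distinct sign
assignments, cannot support a 95th percentile.

When the distinct set fits within the requested B, replicates enumerate
it exhaustively (including the observed assignment; no randomness is
consumed and reruns are bit-identical). Sampled mode excludes the
observed assignment from the null set — under strong signal it would bias
thresholds upward — and draws without replacement via combination
ranking/unranking whenever the distinct set is at most 10·B, falling back
to with-replacement sampling for astronomically large spaces. The engine
estimates histogram-level thresholds only; it does not produce per-feature
permutation p-values.

## Feature-wise tests

The pooled two-sample t (df = n₁+n₂−2) is the package default, with Welch
as a flag; paired data get the one-sample t on within-pair differences;
the Wilcoxon rank-sum test uses the exact enumerated null for group sizes
≤ 12 without ties and the tie-corrected normal approximation otherwise.
Zero-variance degenerate features return the documented limits (p = 1 for
equal means, p = 0 otherwise) instead of erroring, because simulators at
tiny n can generate constant columns. Any user-supplied callable with the
same `(FeatureMatrix, DesignInfo) → p-vector` signature plugs into the
permutation engine, which is how more exotic per-feature models (e.g. an
ANOVA interaction contrast) are accommodated without building them in.
BH and KS are delegated to statsmodels and scipy respectively behind the
package's interfaces; the KS p-value uses the exact small-sample null
below m = 35 and the asymptotic one above.

## Simulators

The generators encode the study conditions of the failure modes they
emulate, and those defaults are fixed:

* `low_power`: m = 10,000 features, π₀ = 0.8, null features N(0, 1) in
  both groups, non-null features with a group-2 mean shift drawn once per
  feature from Uniform(−2, 2) (recorded in the truth table), unit noise,
  n = 4 per group by default. Exactly round(π₀·m) features are null, with
  random placement. The replication studies reported here use Welch's
  two-sample test, the convention of the analyses the scenario reproduces;
  at n = 10 the mean BH rejection count at 5% FDR across 50 seeds is
  ≈ 504 of 10,000. At n = 4 the same generator yields a median of ~3
  rejections even at a liberal 30% FDR (zero in roughly a quarter of
  seeds) while the higher-criticism test detects the non-null features in
  essentially every seed — the "powerless but promising" signature.
* `misspecified`: m = 10,000 all-null features, both groups i.i.d.
  Exponential(rate 1), n = 3 per group. The t-statistic is scale
  invariant, so the rate cancels exactly; what distorts the histogram is
  the skewness and heavy tails at tiny n, and the distortion disappears by
  n = 30 (central limit theorem) or under the rank-sum test.
* `correlated`: all-null features in consecutive equicorrelated blocks;
  within a block each sample's values share a latent standard-normal
  factor, value = √ρ·factor + √(1−ρ)·noise, giving exchangeable
  within-block correlation ρ and zero across blocks. This block-factor
  construction is the package's own minimal generative mechanism for the
  "correlated bundle" phenomenology — a bundle's p-values travel together
  and bump the histogram wherever they land. Defaults ρ = 0.75,
  block_size = 500 emulate the magnitude of within-panel correlation seen
  in small curated expression panels (population RMS pairwise correlation
  ≈ √0.87·0.75 ≈ 0.70 over all pairs at m = 536).
* Seeding: one user seed is split via `numpy.random.SeedSequence.spawn`
  into independent streams for truth/effect draws and for noise, so runs
  are bit-reproducible and the truth stream is unaffected by, e.g.,
  changing n.

What the simulators deliberately do not model: count-valued or
heteroskedastic noise, normalization artifacts, correlation among
*samples* (which broadens the null and is invisible to these diagnostics),
and batch structure. Passing tests therefore demonstrate the correctness
and calibration of the procedures under their stated assumptions, not
robustness of real pipelines to everything that can go wrong in one.

## Problem sizes and numerical choices

The test suite calibrates null error rates on 2,000 simulated global-null
datasets (m = 201 for HC, m = 1,000 for QC), checks the
permutation-vs-analytic convergence with B = 200 replicates against a
direct 2,000-dataset Monte-Carlo oracle at m = 1,000, n = 10 per group,
and replicates the two-group study over 50 seeds; these sizes give
Monte-Carlo error comfortably inside the asserted bands. Discrete-quantile
inversion guards against floating-point ties by verifying the CDF on both
sides of the returned integer. Percentiles of permutation counts use
linear interpolation, so permutation thresholds may be fractional; the
comparison with an (integer) bin count is unaffected.

## Known limitations

* Analytic correlation-adjusted thresholds (estimating the full feature
  correlation matrix instead of permuting) are not provided.
* No adaptive variant of higher criticism that maximizes over the
  first-bin cutoff; b is fixed per run.
* The QC scan detects unimodal bin-level departures; the KS companion is
  more sensitive to multimodal ones and is always reported next to it.
* Permutation mode requires enough distinct assignments (see above), so
  very small paired designs fall back to analytic bounds only.
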