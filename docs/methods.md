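# Methods

## Differential expression

For feature *i* with `n₁` normal and `n₂` tumor observations on the log2
scale, the moderated statistic is

    d_i = (x̄_tumor − x̄_normal) / (s_i + s0)
    s_i = sqrt{ (1/n₁ + 1/n₂) · [ SS_normal + SS_tumor ] / (n₁ + n₂ − 2) }

Linear-scale input is transformed as `log2(x + 1)`; the pseudo-count keeps
count-like data (the miRNA side of the emulated design is sequencing-derived)
finite at zero. Fold changes are computed on the linear scale as
`mean(tumor)/mean(normal)`, and the selection rule is two-sided:
`q ≤ q_threshold` **and** `max(fc, 1/fc) ≥ fc_threshold`. Defaults are
`q ≤ 10⁻⁶` (a literal reading of an "FDR ≤ 0.0001 %" design), `fc ≥ 2.5`
for miRNAs and `fc ≥ 1.9` for genes; all three are configurable because
reported gene thresholds vary between 1.9 and 2 in comparable studies.

**Exchangeability constant.** `s0` is either the median of the `s_i`
(`median_s`) or chosen from the grid of s-percentiles {0, 5, …, 100} plus
literal 0 by minimizing the coefficient of variation of a robust spread
(scaled MAD) of `d` across up to ten equal-count s-quantile bins
(`percentile_search`, the default). Including 0 in the grid guarantees the
chosen value is never worse than no regularization under the search
criterion; ties break toward the smaller `s0`, and a constant scatter
vector therefore yields `s0 = 0`.

**Permutation FDR.** Group labels are permuted with fixed group sizes.
When the number of distinct assignments `C(n, n₂)` is at most the
permutation cap (default 1000) all assignments are enumerated and the
estimate is exact and deterministic; otherwise assignments are sampled
from the seeded generator. With each observed `|d_i|` as a cutoff `t`,

    q_i = median over permutations of #{ |d_perm| ≥ t }  /  #{ |d_obs| ≥ t }

clipped to [0, 1] and then monotonized (running maximum in decreasing
`|d|`) so `q` never increases with `|d|`. The median — the "median number
of falsely called features" convention of the reference SAM
implementation — rather than the mean is essential for the exactness
property that a well-separated feature reaches `q = 0`: the identity and
group-swap assignments always reproduce the observed statistic, so the
mean count is bounded below by 2/n_perm. The mean is available as
`null_aggregate="mean"`. `s0` is chosen once from the observed data and
reused across permutations.

Features with fewer than two observed values in either group (missing
values are `NA`) are flagged and excluded from selection.

## Target consensus

Records `(miRNA, gene, source)` are deduplicated on ingestion, so support
counts *distinct sources*, never record multiplicity. A pair qualifies
when the two directions are opposite (up-regulated miRNA with
down-regulated gene, or vice versa) and support ≥ `min_support`
(default 2, against the conventional three databases; the number of
sources is not hard-coded). Identifiers are matched exactly — mapping
mature-miRNA name variants is deliberately out of scope because it is
database-version dependent.

## Network construction

L1 is the set of genes with at least one PPI edge to an L0 (consensus
target) gene — one shell only, because the reproduced network tables
define exactly two layers. The edge set is the full induced subgraph on
L0 ∪ L1, so L1–L1 edges are retained; the printed quantities (node counts
per layer) are unaffected by this choice. L1 membership is *not*
restricted to differentially expressed genes: the reproduced enrichment
tables contain member genes absent from the differential lists, so the
expansion must draw from the full interactome. Isolated targets are legal
(networks may have zero L1 genes).

## GO enrichment

Per network with `n` genes inside the `N`-gene universe (all genes with at
least one annotation — configurable), each term with level ≥ 5 and at
least one annotated universe gene is scored with the inclusive upper tail
`P(X ≥ k)`, `X ~ Hypergeometric(N, K, n)`. A term's level is the number of
`is_a` edges on the shortest path from its namespace root (root = 0);
`part_of` and other relations are ignored, and annotations are taken as
given (no ancestor propagation). Networks with ≤ 5 genes are excluded
before testing (`min_pin_size = 6`); the alternative reading "fewer than
5" of the reproduced procedure is reachable via configuration.

The Benjamini–Yekutieli adjustment is applied per network (the family is
the set of terms tested for that network, mirroring a per-network
analysis), delegated to `statsmodels.multipletests(method="fdr_by")`; the
test suite checks it against an independent step-down evaluation of
`min_j { m·c(m)·p_j / rank_j }` with `c(m) = Σ 1/i`. BY is deliberately
conservative under the heavy term-overlap dependence of GO families.
Keyword classification is case-insensitive substring matching on the term
name with the default list (cell proliferation, cell death, apoptosis,
signaling, microtubule, actin).

## ROC markers

AUC is computed from average ranks (ties credited ½) — identical to the
Mann–Whitney U scaled by `n₊·n₋` and to the trapezoidal area under the
empirical ROC curve. Tumor is the positive class and scores are used
as-is: down-regulated markers legitimately show AUC < 0.5 and are reported
that way (an explicit `flip` option negates scores). Significance is a
one-sided z-test of `A` against 0.5 using the Hanley–McNeil closed-form SE
at the observed `A` (`se_mode="observed"`); evaluating the SE under the
null `A = 0.5` is available as `se_mode="null"`. When `A ∈ {0, 1}` the
closed-form SE degenerates to 0; the result is flagged
(`degenerate_se=True`) with `p` reported as 0 or 1.

The closed form weighs the two groups asymmetrically through `Q₁ − A²` and
`Q₂ − A²`. For Gaussian score distributions at the marker-evaluation sizes
used here (15 vs 101), the interval `A ± 1.96·se` is conservative
(≈ 94–96 % coverage of a true AUC of 0.75) when the 15-sample arm is the
positive group, and can undercover (≈ 87 %) with the roles reversed; this
is a known property of the exponential-model approximation behind Q₁/Q₂,
not of the implementation, and is a limitation to keep in mind when the
positive class is the much larger group.

## Synthetic studies

The generator produces every pipeline input with planted ground truth so
each stage is testable without downloads.

* **Expression**: log2-space baseline Uniform(4, 10) per feature, Gaussian
  noise (sd 0.5 by default), planted features shifted ±`log2_effect`
  (default 3.0, i.e. 8-fold) in tumor, split evenly up/down; exported on
  the linear scale (lognormal), the simplest model consistent with
  array-like data. Default sample sizes mirror the emulated design:
  11 normal vs 128 tumor (miRNA), 11 vs 110 (genes), and an independent
  15 vs 101 miRNA matrix for marker evaluation. Default feature counts
  (100 miRNAs, 500 genes, 10 % planted) are kept modest so a full study
  simulates in well under a second; they are study-shape parameters, not
  estimates of platform size.
* **Target databases**: planted pairs land in exactly
  `support_per_planted` (default 2) of the `n_sources` (default 3)
  sources; decoys land in exactly one source, so consensus at
  `min_support = 2` recovers precisely the planted pairs.
* **PPI**: each planted target gains `neighbors_per_target` (default 3)
  dedicated neighbors; Erdős–Rényi background edges are confined to
  non-planted, non-neighbor genes, so planted network sizes are exact by
  construction.
* **Ontology**: a rooted tree (`branching` children, default 2, to depth
  6) plus random extra `is_a` edges that only link to nodes exactly one
  level shallower, preserving every shortest-path level. One term at level
  5 is annotated to overlap one designated network (the planted miRNA with
  the most targets) by `planted_overlap` (default 15) genes among
  `planted_term_size` (default 30); all other terms receive uniform random
  annotations of size 5–30.

All generators consume a single seeded NumPy generator per call;
`simulate_study` derives per-component sub-seeds from the master seed and
its file output is byte-reproducible.

What the generator does **not** emulate: negative-binomial count noise,
batch effects, informative missingness, correlated co-expression, scale-free
interactome topology, or realistic GO term-size distributions. Passing
tests therefore demonstrate correctness of the algorithms under a clean
planted model, not robustness to the pathologies of real array/sequencing
data.

## Packaged supplementary tables

The reproduced study's result tables are shipped as TSV fixtures
(S1: 90 miRNAs, S2: 726 down genes, S3: 437 up genes, S4: 18 marker AUCs,
S5: 18 networks, S6: 129 enriched terms over 11 networks) and frozen by
the test suite. They anchor the count-based claims — 89 down / 1 up
miRNAs, 18 networks with `total = L0 + L1` in every row, and exactly 7
miRNAs with an apoptosis / cell-death / cell-proliferation enrichment —
but their numeric values (fold changes, adjusted p-values, AUCs) are *not*
recomputation targets: they depend on database releases and sample subsets
that are not recoverable, so the package re-counts them rather than
re-deriving them.

## Numerical and design notes

* Undirected PPI edges are stored once, lexicographically ordered;
  self-loops are dropped on ingestion.
* All output tables are written with sorted rows and fixed column order;
  re-running any stage with the same inputs and seed is byte-identical.
* Hypergeometric tails use the survival function of
  `scipy.stats.hypergeom`; `k = 0` returns exactly 1.
* The degenerate d-statistic case (a group with < 2 observations) is
  excluded rather than imputed.
* `fc` is undefined (flagged) when the normal-group mean is ≤ 0.
* Gene identity is the case-sensitive symbol string; no alias resolution.
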