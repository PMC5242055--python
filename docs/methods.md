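# Methods

This note documents the statistical model behind `epimodules`, the
parameters that matter, the synthetic-data generator used for validation,
and the numerical and design choices made where the method leaves room.

## Model overview

The pipeline treats every genomic context j of every gene i as a bundle of
dependent hypothesis tests. Locus p-values are folded to nonnegative
normal scores Z = Φ⁻¹(1 − p/2); the folding makes small p-values large
scores regardless of effect sign (direction is tracked separately from the
signed effects). The core statistical commitments are:

- **Dependence is estimated, not assumed.** Neighboring epigenomic
  p-values are correlated because the underlying modification is spatially
  smooth. The correlation is estimated empirically as a distance-binned
  profile and injected into each interval's correlation matrix; no
  parametric decay is fitted.
- **Nulls are empirical.** Every aggregate score is referred to a
  resampling null (quantile-permutation across intervals, bootstrap across
  genes) rather than an analytic distribution; the analytic N(0,1) form of
  the Stouffer statistic is only used as a transform between scales.

## Decorrelation

With Σ the interval's correlation matrix and C its upper Cholesky factor
(Σ = CᵀC), the whitening step solves Cᵀ z* = z by triangular forward
substitution, giving cov(z*) = C⁻ᵀ Σ C⁻¹ = I for exactly N(0, Σ) data. The
factor is never inverted explicitly.

Two robustness measures surround the textbook operation:

- **Positive-definite repair with a ridge floor.** Bin-lookup matrices are
  not guaranteed positive definite, and — more importantly — the profile is
  an estimate: it carries sampling noise and, in data with real signal,
  contamination (pairs of jointly-significant loci inflate bin
  correlations at all distances). Whitening amplifies any data–model
  mismatch by 1/√λ_min. Eigenvalues are therefore floored at **0.1**
  (amplification bounded at ≈ 3.2×), the matrix reconstructed and its
  diagonal renormalized to 1. Matrices that are already well conditioned
  (e.g. an exchangeable block with ρ = 0.6 has λ_min = 0.4) pass through
  untouched, so the floor does not degrade decorrelation where the model
  is trustworthy. With the floor at machine-epsilon scale instead, whitened
  scores on realistic synthetic data explode by two orders of magnitude
  and gene ranking is destroyed.
- **Negative bin correlations are retained** (not floored at zero); the
  whitening handles any valid correlation.

## Correlation profile estimation

Pairs are collected from loci at or below a significance threshold
(default 0.05; the choice is config-exposed) and their nearest upstream and
downstream neighbors within the same interval. Distances are partitioned
into **distance-quantile bins** (default request: 500), which automatically
produces single-base-pair bins at the shortest distances where correlation
is largest; duplicate quantile edges collapse, so the effective bin count
can be lower. Within each bin, pairs are resampled with replacement and the
Pearson correlation of the two Z vectors averaged over (default) 500
resamples. Bins with fewer than 3 pairs get correlation 0 and are flagged.

Bin count should be scaled with data volume: the default 500 bins is
appropriate for assay-scale inputs (~10⁵–10⁶ pairs); at ~10⁴ pairs, ~100
bins keeps per-bin Pearson noise (sd ≈ 1/√n_bin) small enough for the decay
to be resolvable. The validation suite uses 100 bins at that scale for
exactly this reason.

One profile is estimated per (track, context) pair; promoter and gene-body
correlation structure are not assumed equal.

## Size adjustment (quantile permutation)

Because folded Z scores are all positive, a Stouffer aggregate grows with
the number N of values combined even under the null. Scores are stratified
into (default 10) quantile strata of N; strata smaller than 5 merge with a
neighbor. Each observed score is compared against (default 100) same-size
resamples of its stratum; the per-resample proportion of scores at or above
the observed one — ties counted with the **midrank convention**, and floored
by (count+1)/(size+1) so the result is never 0 — is averaged into the
adjusted p. The midrank convention is what makes a perfectly tied stratum
come out at 0.5 rather than 1, and keeps downstream −ln(p) finite.

The expression table (one p per gene, N = 1) is routed through the same
adjustment so that all contexts reach the normalization step on the same
empirical-quantile scale.

## Normalization

Adjusted p-value distributions still differ across contexts, and the
widest-spread context would otherwise dominate the gene-level combination.
Default: logit-transform, rescale each context to the **pooled** mean/sd
(pooling makes the operation symmetric in contexts), invert. Alternative: a
Box-Cox power transform on −ln(p), with the exponent chosen by grid-search
maximum likelihood over λ ∈ [−2, 2] step 0.01; the standardized values are
mapped back through the inverse power transform, with the target spread
shrunk just enough to stay inside the inverse transform's domain so the map
remains strictly monotone. Both methods preserve ranks exactly (checked at
run time) and are idempotent within tolerance.

## Gene scoring

Per gene, present contexts are combined as
Σ_j w_j s_j z_j / √(Σ_j w_j²) with z_j = Φ⁻¹(1 − p_j/2) and
s_j = direction_j · B_j for B_j = ±1, or +1 for agnostic contexts
(B_j = 0). Missing contexts simply drop out of both sums — a gene is never
penalized for incomplete data. The combined statistic is referred to a
bootstrap null that resamples each context's signed contribution from that
context's gene-wide pool (an exchangeability null preserving every
context's marginal distribution); genes sharing a context pattern share a
cached null. Significance is two-sided on |statistic|; the sign is kept for
reporting. p = (count + 1)/(n_boot + 1), so G = −2 ln(p) is capped at
2 ln(n_boot + 1) — n_boot (default 1000) bounds score resolution.

High-scoring genes are selected against a bootstrap background of the score
vector: threshold at the (1 − α) pooled quantile (default α = 0.05).

## Modules

The scored network is undirected, deduplicated, largest-component only.
Spin-glass community detection runs at resolution γ = 0.5 with edge weights
1 + mean(endpoint Fisher scores normalized by the maximum) — the endpoint-
mean coupling keeps weights positive and is isolated in one function for
substitution. Communities outside [8, 100] genes are discarded after one
recursive re-split attempt for oversized ones. Unscored nodes participate
in topology with p = 1, contributing 0 to module significance while still
able to appear as structurally important members.

Module significance is Fisher's method over member genes: χ² = −2 Σ ln p_g
with 2k degrees of freedom. Under exchangeable null genes this is exact,
which the calibration suite verifies (5% nominal rejection recovered within
Monte-Carlo error).

The greedy maximum-weight connected subgraph (MWCS) routine stands in for
exact branch-and-cut solvers (out of scope; no ILP solver): node weights
are Fisher scores minus a background offset (the high-score threshold), and
the subgraph grows from the maximum-weight node by repeatedly absorbing the
positive-weight node whose cheapest connecting path (Dijkstra with node
cost max(0, −w)) yields a positive net gain. It crosses negative "bridge"
genes when the far side pays for them, and returns the single best node
when every weight is negative. On exhaustively solvable 8-node instances it
reaches ≥ 80% of the optimum in ≥ 90% of cases.

## Synthetic data generator

The generator emulates: genes tiled on a synthetic chromosome (5 kb genes,
15 kb spacing, alternating strands); one methylation-like track whose
locus Z values are drawn per gene from N(0, Σ) with Σ from an exponential
distance-decay model (default length scale 1 kb — the scale over which DNA
methylation is strongly locally correlated), an exchangeable block, or
independence; a one-row-per-gene expression table; enhancer peaks upstream
of every fourth gene; and an interaction network.

Planted genes (default 5% at desk scale, Z shift +3) carry a **biologically
coherent** signature: expression and gene-body Z shifted up, promoter
methylation Z shifted down — matching the prior encoded by the default
direction coefficients. Planting all contexts in the same direction would
make promoter evidence cancel expression evidence under B_promoter = −1 and
the fixture would not emulate a dysregulated gene. Effect signs agree with
the shift with probability 0.9, so direction assignment sees realistic
discordance.

The planted-partition network model is
`("planted_partition", sizes, p_in, p_cross[, p_bg])`: the planted block has
internal density p_in, is linked to the rest at p_cross, and the background
has density p_bg. The benchmark world is [20, 280] with p_in = 0.5,
p_cross = 0.005, p_bg = 0.02: an interactome-like connected background
(mean degree ≈ 6) containing a pathway-like block. This matters: with a
single outside probability of 0.01 the background is fragmented dust (mean
degree 1.4) and the 20-gene block has as many outgoing as internal edges —
at resolution 0.5 pendant background fragments accrete onto every
community and no modularity-based method recovers the block cleanly
(measured plateau at Jaccard ≈ 0.4–0.6 for any p_in up to 0.8).

What a green suite does **not** establish: the generator has no probe
design or coverage biases, no batch structure, no unequal per-locus
measurement error, and its correlation model is stationary within a gene —
claims about real-assay behavior require real data.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| promoter window | 1000 bp up / 500 bp down of TSS | context interval (assay convention; config-exposed) |
| enhancer→gene link | nearest TSS within 50 kb | custom-interval assignment, lexicographic tie-break |
| p-value floor | 1e−16 | Φ⁻¹ diverges at 0 |
| significance threshold (pairs) | 0.05 | loci anchoring neighbor pairs |
| profile bins / resamples | 500 / 500 | scale bins down with data volume (see above) |
| eigenvalue floor | 0.1 | whitening ridge |
| N strata / null draws | 10 / 100 | size adjustment |
| n_boot | 1000 | gene bootstrap; caps G at 2 ln 1001 |
| γ, module size | 0.5, 8–100 | spin-glass resolution and size filter |
| high-score α | 0.05 | background quantile for selection / MWCS offset |

## Determinism

A single global seed fans out to per-stage seeds by hashing the stage name
(adding a stage never perturbs earlier stages). The spin-glass backend
draws from Python's `random` module and is seeded per call. Two runs with
identical config and seed produce byte-identical outputs.

## Known limitations

- The correlation profile is estimated from significant-locus neighbor
  pairs; in data where most significant loci are true signal, bin
  correlations are inflated and decorrelation becomes conservative (the
  ridge floor bounds, but does not remove, this effect).
- The greedy MWCS is a heuristic with no optimality guarantee beyond the
  benchmarked regime.
- Alternative locus-level combiners (Sidak, Fisher, binomial) are provided
  behind the same interface but only the Stouffer default is covered by the
  decorrelation calibration guarantees.
- No FDR machinery on gene p-values: ranking and background-quantile
  thresholding are the supported selection tools.
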