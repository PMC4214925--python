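# Methods

`trainmap` reconstructs, as a tested pipeline, the transcriptome analysis
that contrasts a *training* stimulus (β-glucan, which reprograms monocytes
toward enhanced secondary responses) with a *non-training* stimulus (LPS,
which inflames but does not train). The end product is a functional
enrichment map: a graph whose nodes are gene sets significantly enriched
among genes responding more strongly to the trainer, and whose edges encode
membership overlap between those sets.

## The factorial model

Every gene is measured in a 2×2 design — stimulus ∈ {trainer, comparator} ×
state ∈ {baseline, stimulated} — with replicate arrays in each cell. The
per-gene model is ordinary least squares on log2 intensities:

    y = μ + a·[stimulated] + b·[trainer] + c·[stimulated × trainer] + ε

`a` is the comparator response, `a + c` the trainer response, and the
interaction `c` is exactly the quantity of interest: the amount by which the
trainer response exceeds the comparator response. Significance of `c` is the
partial F-test of the full model against the additive one (1 numerator df,
n − 4 residual df). Because the design matrix is shared by all genes, the
fits are computed for the whole matrix with two pseudoinverse products; a
single-gene wrapper exposes the same numbers.

We use plain OLS rather than moderated (empirical-Bayes) variance
estimation. With triplicate cells the OLS test is exactly calibrated (the
type-I criterion below verifies 5% rejections under the null) but has less
power per gene than limma-style shrinkage would; the enrichment stage
aggregates over set members, which compensates at the set level.

Degenerate genes with zero residual variance are given p = 0 when the
interaction estimate is nonzero and p = 1 when it is zero, with a logged
warning, rather than propagating NaNs. After quantile normalization such
genes occur only at the extreme ranks (a gene that is the minimum in every
column becomes exactly constant) and always take the benign p = 1 branch.

## Multiple testing and responder selection

Interaction p-values are Benjamini–Hochberg adjusted *within each K-means
cluster* by default — the clusters scope the test families — with a global
adjustment available as a flag. The step-up adjustment
q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j is implemented directly and cross-checked in the
tests against an explicit min-over-suffix oracle and against statsmodels.

Selection is two-step, mirroring the map's construction from genes with a
significantly weaker comparator response: adjusted p < α (default 0.05)
*and* interaction estimate > 0. A two-sided p with a sign gate was chosen
over a one-sided p because significance and direction are stated as separate
steps in the procedure being reconstructed.

## Clustering

Gene profiles are the 4-vectors (snr_trainer, snr_comparator,
response_trainer, response_comparator), standardized per dimension. The
signal:noise ratio is the GSEA-style (μ₁ − μ₂)/(σ₁ + σ₂) with the
denominator floored at 1e−8; the response is the stimulated-minus-baseline
mean difference in log2 units. This feature space captures both the
magnitude and the reliability of each stimulus response. K-means uses
Lloyd's algorithm with k-means++ seeding, best of 10 restarts by
within-cluster sum of squares, seed 17 by default; k defaults to 9 and is a
config parameter — k, the metric and the profile space are all free choices
here, as nothing in the source procedure pins them down.

## Enrichment and the map

The responder list is tested against every gene set with the one-sided
hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n), where N is
the universe (all post-normalization genes, flag-switchable), K the
universe-intersected set size, n the list size and k the hits. Sets with
fewer than 5 or more than 500 universe members are excluded (conventional
guard, config-exposed). The enrichment score is −log10(p); significance is
score > 1.3, i.e. p < 10^−1.3 ≈ 0.05, applied to the raw p by default with
a `--use-adjusted` gate available. BH-adjusted values across the merged
K/G/P/R family are always reported.

Significant sets become map nodes (size = universe-intersected member
count, the same count the statistic used). Edges carry the overlap score,
the average of the Jaccard coefficient |A∩B|/|A∪B| and the overlap
coefficient |A∩B|/min(|A|,|B|), computed on universe-intersected
memberships; an edge requires a non-empty intersection and an overlap score
at or above the edge threshold. Components are computed with an iterative
implementation of Tarjan's strongly-connected-components algorithm on the
digraph obtained by replacing each undirected edge with two opposed arcs —
the only well-defined reading of "strongly connected" on an undirected
similarity graph, under which SCCs coincide with connected components. The
implementation is cross-checked against brute-force reachability.

The default edge threshold is 0.25, the conventional value for
combined-overlap enrichment maps over real, hierarchically redundant
collections. For the synthetic planted-truth studies the threshold is 0:
planted sets draw their responder members independently from a 200-gene
pool, so two 30-gene sets share only E ≈ 2.9 genes (expected overlap score
≈ 0.075), and the meaningful connectivity signal at that geometry is "any
shared member". This choice follows from the generator's design, not from
any real-collection consideration.

## The synthetic generator

The generator stands in for the undeposited monocyte training arrays. It
emulates:

- a gene × sample log2 matrix over the full 2×2×replicates design
  (defaults: 5,000 genes, triplicates);
- per-gene baseline abundances drawn from N(8.0, 2.0) log2 units. The
  between-gene spread matters: real arrays span several log2 units, and that
  spread is precisely what makes quantile normalization effect-preserving.
  With a common baseline for all genes, responders pile up in the top ranks
  of the stimulated columns and normalization flattens the planted
  interaction (from 1.5 to ≈ 0.7 log2 units in our measurements), which no
  realistic array exhibits. Baselines cancel in every within-gene contrast,
  so the planted truth stays directly interpretable;
- 200 responder genes gaining 2.0 log2 units under (trainer, stimulated)
  and 0.5 under (comparator, stimulated); i.i.d. Gaussian noise, sd 0.5
  log2 units, in every cell;
- three planted 30-gene sets with 80% of members drawn from responders,
  plus 100 decoy sets drawn uniformly from all genes, spread across the
  four source tags.

One RNG stream is consumed in a fixed order (responder identity, baselines,
noise; then planted members, decoy members), so a seed fully determines the
output.

The generator does *not* emulate: probe-level or bead-level noise,
batch/donor effects, correlated noise between genes, intensity-dependent
variance, or down-regulated responders. Passing the planted-truth criteria
therefore shows that the pipeline recovers concentrated, trainer-dominant
set signal under honest noise — not that it is robust to array artifacts
those features would introduce.

## Numerical choices

- Quantile normalization maps each column value to the mean of the
  rank-sorted columns; ties receive the mean of the reference values their
  ranks span (order-independent, idempotent on tie-free data).
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`, verified
  against exhaustive enumeration to < 1e−12 for every N ≤ 12 configuration.
- p-values are floored at 1e−300 before taking −log10.
- Edge endpoints are stored smaller-name-first and all exported tables are
  sorted, so repeated exports are byte-identical.
- Gene identifiers are upper-cased at ingest; sets with equal names from
  different collections are keyed `name|tag`.

## Problem sizes

The recovery study runs the full pipeline on 20 independent simulations at
the default conditions (5,000 genes × 12 samples, 103 sets), which takes a
few seconds; the type-I calibration uses 10,000 null genes; oracle
equivalences enumerate all hypergeometric configurations with N ≤ 12,
1,000 random p-vectors up to length 200, and 100 random graphs of ≤ 12
nodes.

## Known limitations

- No probe-to-gene collapsing: the first matrix column is assumed to be a
  gene identifier already.
- No donor pairing or random effects; replicates are treated as independent.
- The per-cluster BH family means a gene's adjusted p depends on its
  cluster assignment; with unlucky clusterings (responders split across
  mixed clusters) power drops. The global-BH flag gives the
  cluster-independent alternative.
- The score threshold gates on raw p by default; with many candidate sets
  the decoy false-positive rate tracks the raw test level (≈ 1–2% observed),
  not an FDR.
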