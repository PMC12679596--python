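# Methods

This note documents the models, statistics and numerical choices behind
`dupdiverge`, and what the synthetic-data results do and do not establish.

## Coordinates and formats

All intervals are 0-based half-open internally (BED convention); GFF3's
1-based closed coordinates are converted exactly once, on read. Strand is
carried but ignored by all distance computations. Counts tables are genes ×
samples with sample labels `celltype.rep` (split on the last dot). Gene
trees are parsed with Bio.Phylo; FASTA access goes through pyfaidx.

## Expression-pattern classification

Per tissue: cell types whose replicate Spearman correlation is ≤ 0.75 are
removed (the boundary fails; with more than two replicates the minimum
pairwise correlation is used). Counts are CPM-normalized (column sums
exactly 10^6); genes with CPM ≥ 1 in ≥ 2 samples count as expressed,
all-zero genes as non-expressed. For a pair, per-cell-type replicate-mean
CPMs c1, c2 give the fold changes f_ct = log2((c1+1)/(c2+1)); the pair's
statistics are m = |mean(f)|, s = sd(f) (sample SD, n−1), and
r = Pearson correlation of the log2(CPM+1) profiles. The pseudocount
bounds fold changes for zero counts; at high expression it is negligible.

Choices made where the procedure was genuinely open:

* **Coexpression measure** — Pearson on log2(CPM+1) replicate-averaged
  profiles. It is the simplest statistic compatible with fixed 0.9/0.5
  thresholds; Spearman is a one-line swap.
* **m is |mean(f)|, not mean(|f|)** — paralogue dominance then requires a
  consistent direction of differential expression across cell types, which
  is what "dominance" should mean.
* **Low-expression filter** — the deterministic surrogate "CPM ≥ 1 in ≥ 2
  samples" replaces a count-model-driven filter; it is documented,
  reproducible, and close to common defaults.
* The rule list is applied exactly as printed; the region r > 0.9, m < 1,
  s ≥ 1 (and everything between the correlation thresholds) falls to
  "others". The classifier is a total function.

Across four conditions (stages or organs) the simplified categories
(non / mono / correlated / uncorrelated) are collected; "non" is dropped
whenever any expressed category co-occurs, so the shared-category count is
1 with category "non" only for pairs silent in all four conditions.

## Cell-type-specific genes (DE engine)

Per cell type, the target pseudobulk replicates are compared against an
equal number of replicate columns sampled (once, seeded) from the other
cell types. The test is a conditional exact negative-binomial test: with
replicate counts NB(μ, φ), group totals are NB with size n/φ, and given
the grand total the one-group total follows a Polya distribution depending
only on φ; the two-sided p-value is the double-tail mass of outcomes no
more probable than the observed split. The common dispersion maximizes the
within-group conditional likelihood summed over genes — with two
replicates per group, moment estimators are badly downward-biased (a
prototype inflated type-I error to ~0.09 versus ~0.05 for the
conditional-ML estimator). Benjamini–Hochberg adjustment runs across genes
within each cell type; an entry is called at log2FC > 1 and adjusted
p < 0.05. Columns are pre-scaled to the geometric-mean library size and
rounded, so the equal-library conditional test applies.

A method-inherent caveat: when a gene is genuinely specific in several
cell types, the randomly sampled control can include its other high cell
types and shrink the apparent fold change. End-to-end DE-derived
specificity matrices are therefore an approximation of the planted ones;
the trajectory stage consumes the specificity matrix as its input, and the
DE caller's own guarantees are stated for single-cell-type enrichment.

## ACR conservation

Association is nearest-gene by interval gap (0 on overlap), ties broken
lexicographically by gene id — deterministic and auditable. The reference
region of a duplicate runs from its nearest upstream neighbour's start to
its nearest downstream neighbour's end (gene bodies included), clipped to
chromosome bounds for terminal genes. Tandem duplicates therefore produce
overlapping regions and potential self-hits; the faithful default keeps
them, `mask_self` discards HSPs overlapping the query ACR's own interval.

The aligner implements the short-query nucleotide scheme: reward +1,
penalty −1, gap cost 5 + 2g, word size 7, E ≤ 1e−3, no low-complexity
masking. Search proceeds in two stages on each strand: exact 7-mer seeding,
cheap ungapped X-drop extensions through every seed pair, and a gapped
stage entered only when the best ungapped core comes within 4 points of
the minimum significant score. The gapped stage is an exact affine-gap
Smith–Waterman (numba) over the reference window spanned by shared
12-mers (7-mers match a multi-kb window essentially everywhere by chance;
12-mers localize genuine homology; without any shared 12-mer the full
matrix is scanned). Secondary HSPs come from masking the aligned query
span and re-running. Both stages only ever *restrict* the search, so the
reported best HSP score never exceeds the true local-alignment optimum —
misses are possible only when no seed survives, and the acceptance suite
confirms exact agreement with an independent full-DP oracle on planted
cases. Significance uses Karlin–Altschul statistics: λ is solved
numerically from the score distribution (= ln 3 for ±1 with uniform
bases), H follows from the aligned-pair distribution (0.549), and
K = 0.333 is the standard tabulated value for this scheme; effective
lengths use the usual fixed-point length adjustment. Gapped and ungapped
parameters coincide for this scheme.

Metrics: accepted HSPs are reduced greedily by score to a set with
non-overlapping query coverage. B = covered query length / query length
(bounded by 1); M = Σ mismatches / Σ reference-side aligned length over
the same set; B > 0.1 defines conserved, with the stricter thresholds
{0.2, 0.4, 0.6, 0.8} exposed in configuration. An ACR with no accepted
HSP is unBLASTed (B = 0, M = NA). For 4-gene sets the conservation count
over the three cross-alignments maps 0 → unique, 1 → two-copy,
2 or 3 → multi-copy. An adapter ingests external 12-column tabular hits,
so the metrics are provider-agnostic.

## Accessibility dynamics

The profile of an entity is a binary ACR × condition matrix. The distance
is the mean pairwise Jaccard distance over the condition pairs (the pooled
variant — shared = present in all, total = present in any — is behind a
flag; pairwise is the standard reading of cross-condition overlap). ACRs
absent everywhere do not affect the value; an entity with no presences is
NA. ctACR matching emits (gene, ACR, cell type) triples when an ACR's
cell-type label names a cell type where its associated gene is specific.

## Trajectory inference

Recent pairs are the two sister-leaf pairs (cherries) of the quad's gene
tree; topologies without two disjoint cherries over the four genes are
unresolved and excluded. Clustering input is the binary specificity matrix
with all-zero rows removed; removed rows rejoin as one extra
"no-specificity" group for size accounting (so {specific×3, zero×1} gives
sizes 3:1). Distances are Jaccard; agglomeration is Ward.D2 — merge
heights come from the Lance–Williams recurrence (scipy's `ward` linkage,
verified against a hand-coded recurrence). For the n ≤ 4 rows of a quad,
the partition reported at each k is the exact minimizer of the
distance-form Ward objective over all set partitions; exhaustive
enumeration is free at this size, coincides with greedy agglomeration
except on contrived ties, and makes the selection deterministic.

Choice of k: silhouette is undefined at k = 1 and degenerate at k = n, and
no scale-free score can distinguish "one noisy cluster" from a genuine
split — that requires the absolute distance scale. The rules, in order:

1. if all pairwise distances ≤ `k1_distance` (default 0.5), k = 1;
2. otherwise candidate partitions (k = 2..n) are admissible only if no
   cluster contains two genes farther apart than `max_within` (0.7);
3. among admissible partitions the mean silhouette width decides
   (singletons contribute 0; ties prefer more clusters). Within-cluster
   sums of squares are reported for elbow inspection; silhouette wins.

The defaults were set from the noise geometry of specificity vectors: one
flipped bit in a vector with four specific cell types moves Jaccard
distance by 0.2–0.5, while planted between-group distances are ≥ 0.857, so
0.5/0.7 separate single-bit noise from real splits. Both are configuration
knobs. A 2:2 split maps to "before the second WGD" only if it coincides
with the recent pairs (strict mode, default on — a 2:2 split across recent
pairs is biologically a different event; turning it off reproduces the
literal ratio rule).

## Synthetic data

The generator is first-class, tested code; its defaults define the study
conditions.

**Genomes.** Each duplicate occupies its own small chromosome as
[neighbour gene]–[upstream ACRs]–[focal gene]–[neighbour gene], with
gene length 800 bp, intergenic spacing 4 kb, and 1–3 ACRs of 300–500 bp
within 2 kb upstream of the TSS. The spacing exceeds the upstream window
plus ACR span so nearest-gene association is provably unambiguous. Partner
loci mirror the source slot layout; partner ACR copies are substituted at
per-base rate μ (always to a different base), optionally truncated by one
contiguous block (`del_frac`, the simplest model producing partial BLASTed
ratios), dropped (`p_acr_loss` = 0.1), or complemented by de novo ACRs
(`p_de_novo` = 0.1). Quads arise from two successive duplications with
per-branch substitution (ancestral branches at μ, recent branches at 0.3μ,
so recent copies diverge less); planted ACR classes are multi-copy
(present in all four), two-copy (one per recent pair) and unique
(one leaf), and the true ((A,B),(C,D)) topology is written as Newick.
Duplication-mechanism labels are drawn 50% WGD, 10% tandem, 10% proximal,
15% transposed, 15% dispersed.

**Expression.** Per tissue and pair a pattern label is drawn
(mix: dosage 0.20, dominance 0.15, specialization 0.15, divergence 0.15,
others 0.15, mono 0.10, non 0.10). Latent per-cell-type log2 means are
constructed per label — identical profiles; a constant ±2 offset; a +3.5
boost in the high half of the profile (specialization); negatively
correlated profiles with a ±3 offset (divergence); a balanced ±2.4 offset
(others, which lands outside every rule for any r) — and a draw is
accepted only if the *exact pipeline statistics* computed on the
noise-free latents sit inside the label's rule region with margin
(r ≥ 0.95 for the high-correlation classes, r ≤ 0.40 for divergence,
m and s at least 0.3 from their thresholds). This makes
separability-at-zero-noise constructive rather than probabilistic. Counts
are negative-binomial around the latents (shared dispersion 0.05; Poisson
at 0), with latent means scaled so a pseudobulk library is ~10^6.
12 cell types × 2 replicates × 4 tissues.

**Trajectories.** Scenario mix {① 0.08, ② 0.22, ③ 0.40, ④ 0.20, ⑤ 0.10} —
single-cluster sets rare, multi-cluster dominant, matching how such sets
distribute in real WGD data. Specificity vectors occupy disjoint
cell-type blocks of 4 (3 for the four-group scenario) on a per-quad
permutation of 12 cell types, making between-group distances maximal.
Optional bit-flip noise perturbs the matrix. Counts realizing the vectors
(8× boost in specific cell types) and matching ctACRs near the genes are
generated alongside.

**Accessibility.** First-condition presence Bernoulli(0.9); later
conditions flip each bit with the turnover probability, so distance grows
monotonically in turnover.

All randomness flows from one seeded generator; identical seeds give
byte-identical outputs, which the pipeline inherits (manifests contain no
timestamps).

## What the synthetic results do and do not show

Passing recovery on this generator shows the statistics, aligner and
clustering are implemented to contract and behave correctly under
controlled noise. It does not establish performance on real tissue:
real pseudobulk has correlated library composition, batch effects, and
dispersion varying by gene; real ACRs have repeats and low-complexity
sequence (no masking is applied, as in the printed parameter string);
real gene neighbourhoods make nearest-gene association genuinely
ambiguous; and real specificity matrices are sparser and noisier than the
block vectors planted here. The DE control-sampling caveat above applies
to multi-cell-type-specific genes.

## Problem sizes and tolerances

The default synthetic study is 200 pairs and 50 quads over 4 tissues; the
acceptance script measures pattern recovery on 500 pairs × 4 tissues,
aligner agreement on 200 planted cases, mismatch-rate calibration on ≥100
ACRs per substitution level, state recovery on 20 quads (260 ACR states)
per level, Jaccard on 1,000 random profiles, Ward checks on 100 random
matrices, trajectory recovery on 250 quads, and DE calibration on 300
genes × 30 null replicates — sizes chosen so the whole script completes in
a few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bounds. The DE null band [0.030, 0.065] reflects that exact
conditional tests are discrete (guaranteed ≤ α) with an estimated
dispersion. Floating-point assertions use exact equality only where the
arithmetic is exact (metric definitions, determinism) and otherwise the
tolerances stated in the tests.
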