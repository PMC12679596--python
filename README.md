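# dupdiverge

Transcriptional and cis-regulatory divergence of duplicated genes from
single-cell pseudobulk data.

Plant genomes carry large numbers of paralogs — soybean, after two rounds of
whole-genome duplication (WGD, ~59 and ~13 Mya), holds four-gene sets
descending from single ancestral genes. How duplicate copies diverge in
*where* they are expressed (which cell types, which tissues) and what the
cis-regulatory sequence around them did in the meantime is the question this
package addresses, for researchers working with snRNA-seq pseudobulk counts
and scATAC-seq accessible chromatin regions (ACRs).

## What it computes

**Expression-pattern classification.** For a duplicate pair in one tissue,
three statistics over cell types: the coexpression value
*r* = Pearson correlation of the two log2(CPM+1) profiles, and the absolute
mean *m* and standard deviation *s* of the per-cell-type log2 fold change
log2((c1+1)/(c2+1)). Categories:

| category | rule |
|---|---|
| dosage balanced | r > 0.9, m < 1, s < 1 |
| paralogue dominance | r > 0.9, m ≥ 1, s < 1 |
| specialization | r > 0.9, m ≥ 1, s ≥ 1 |
| divergence | r < 0.5, m ≥ 1, s ≥ 1 |
| mono-expression | exactly one gene expressed (r = NA) |
| non-expression | neither gene expressed |
| others | expressed pairs matching no rule |

Across four developmental stages or four organs, calls consolidate into
simplified categories (non / mono / correlated / uncorrelated) and the
number of shared categories per pair.

**ACR sequence conservation.** Each ACR is assigned to its nearest gene;
its sequence is aligned against the partner duplicate's *reference region*
(the span from the partner's upstream neighbour gene to its downstream
neighbour) under short-query nucleotide scoring (+1/−1, gap 5+2g, word
size 7, E ≤ 1e−3). The BLASTed ratio B = aligned query coverage / ACR
length (B > 0.1 ⇒ conserved, roughly 50 bp) and the mismatch rate
M = mismatches / aligned reference length measure conservation. For 4-gene
sets, each ACR is aligned against the other three reference regions; the
number of conserved alignments (0/1/2–3) classifies it as unique,
two-copy, or multi-copy conserved.

**Accessibility dynamics.** Per duplicate pair or set, the overlap of
accessible-ACR sets across stages or organs as the mean pairwise Jaccard
distance 1 − |A∩B|/|A∪B|.

**Trajectories of cell-type-specific expression.** Cell-type-specific genes
are called per cell type with a negative-binomial exact test of the target
pseudobulk against an equal number of randomly sampled replicates from
other cell types (log2FC > 1, BH-adjusted p < 0.05). The four genes of a
WGD set are clustered on their binary specificity vectors (Jaccard
distance, Ward.D2, silhouette-guided choice of k); the cluster-size ratio
maps to when specificity arose: 4 together → before the first WGD; 2:2
(matching the gene tree's sister pairs) → before the second; 1:3 → after
the second; 1:2:1 → combination; all distinct → complex.

Every stage is exercisable on synthetic data with planted ground truth
(`dupdiverge.simulate`), so the whole pipeline is testable without any
external download.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_expression_patterns.py
python analysis/03_acr_conservation.py
python analysis/04_accessibility.py
python analysis/05_trajectories.py
```

The first script writes a synthetic study (200 duplicate pairs, 50 WGD
quads, 4 seed stages, 12 cell types × 2 replicates) with known truth.
The second prints, per tissue:

```
cotyledon: 200 pairs, planted-label recovery 100.0%
```

i.e. every planted pattern label was recovered by the classifier at the
default count noise. The conservation step prints

```
200 pairs scored:
  mean fraction of conserved ACRs: 0.911
  mean M over conserved ACRs:      0.0197
650 quad ACRs: state proportions {'multi_copy': 0.615, 'two_copy': 0.308, 'unique': 0.077}, planted-state recovery 100.0%
  two_copy: mean B 1.000, mean M 0.0117
  multi_copy: mean B 0.999, mean M 0.0394
```

— the planted 2% substitution rate reappears as the measured mismatch rate
(0.0197), ~9% of ACRs are unBLASTed because the generator deleted their
partner copies, and multi-copy conserved ACRs carry more mismatches than
two-copy ones (0.039 vs 0.012), the expected signature of older duplication
events under per-branch mutation. The trajectory step reports

```
50 sets called; planted-scenario recovery 100.0%
```

The same pipeline runs from a shell on any inputs in standard formats
(GFF3 + FASTA + BED + TSV counts + Newick trees):

```bash
dupdiverge all --workdir run/ --seed 1          # synthetic end-to-end
dupdiverge simulate --out inputs/ --seed 1      # just the generator
```

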