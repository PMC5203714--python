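# junctionscope

Junction-level analysis of RNA-seq splicing diversity across aggregated
cohorts.

Large public sequencing archives contain orders of magnitude more RNA-seq
samples than the curated experiments behind standard gene annotations, and
a substantial share of the exon-exon junctions recurring across those
samples is missing from annotation. `junctionscope` is a library for
quantifying that gap. It operates downstream of alignment, on
*intropolis*-style aggregated junction calls — a sparse junction × sample
matrix of read counts `c_ij` — together with a union of transcript
annotation tracks, and provides:

- **Annotation-evidence classification.** Each junction (an intron interval
  with strand) is placed in exactly one of four classes: *fully annotated*
  (the pair appears in an annotated transcript), *exon skip* (donor and
  acceptor sites both annotated, but never together), *alternative
  donor/acceptor* (exactly one site annotated), or *novel* (neither).
  Site matching is strand- and role-aware.
- **Prevalence curves and per-sample fractions.** Junction counts at
  "found in ≥ S samples / ≥ P projects" thresholds split by evidence class;
  per-sample fractions of junctions and of junction overlaps (instances of
  a read mapping across a junction) that are annotated.
- **Discovery dates.** Each confidently called junction (≥ 20 reads cohort-
  wide by default) is dated by the earliest submission date among its
  samples; accumulation curves, top contributing dates, and first
  appearance across annotation releases follow.
- **Coverage PCA.** PCA of `x_ij = log2(c_ij / C_j + 1)` over unannotated
  junctions, computed through the row-centered Gram matrix `AᵗA`
  accumulated blockwise, with correlates `s_j = Σ_i x_ij` (junction
  sequencing depth), `ℓ_j = log2(1 + p_j)` (read length) and
  `m_j = log2(1 + C_j)` (library size).
- **Two-region inclusion ratio.** For a gene split into two disjoint exon
  groups with per-sample junction coverages A and B,
  `D = (B − A) / (A + B)` ranks samples by relative expression of the
  downstream group — the screen used to find intron-initiated *ALK*
  transcripts (ALK^ATI) and fusion-like signatures.
- **A synthetic cohort generator** whose evidence categories are built
  structurally (by choosing splice sites), so every stage of the pipeline
  is testable against exact ground truth without any external data.

## Worked example

The two-region screen, with the published per-sample coverage tallies of
the top-ranked archive samples as input
(`python examples/05_alk_inclusion_ratio.py`):

```
 rank  sample_id  A   B   C      D D_3dp
    1  SRR396804  0 172 172 1.0000 1.000
    1  SRR545713  0 139 139 1.0000 1.000
    1  SRR620100  0 108 108 1.0000 1.000
    4 SRR1289650  1  85  86 0.9767 0.977
    5 SRR1289651  1  77  78 0.9744 0.974
    6  SRR545716  2  94  96 0.9583 0.958
    7  SRR628586 12 111 123 0.8049 0.805
    8  DRR016705 38 285 333 0.7647 0.765
    9  SRR545714 14  63  77 0.6364 0.636
   10  ERR532612 16  53  69 0.5362 0.536
```

`A` and `B` are junction overlap counts wholly inside the upstream
(exons 1–19) and downstream (exons 20–29) regions; `C` additionally counts
junctions straddling the boundary, which is why `C ≥ A + B` (row
DRR016705: 333 vs 323). `D = (B − A)/(A + B)` near +1 flags samples whose
*ALK* expression is confined to the kinase-domain exons; ties share rank 1
and the next sample ranks 4 (competition ranking).

The other examples build synthetic cohorts and print, in order: exact
recovery of the generator's category mixture by the classifier, 400/400
(`01_classify_junctions.py`); prevalence curves whose annotated fraction
rises from 70.2% at S ≥ 1 to 100% at S ≥ 48 (`02_prevalence_and_profiles.py`);
discovery-date accumulation with 100% of confident junctions discovered
before the cohort midpoint, the bulk of them on the earliest project's
submission date (`03_discovery_dates.py`); and a coverage PCA whose PC1
explains 82.4% of variance with r = 0.999 against junction sequencing
depth, plus within-tissue-group collinearity R² = 1.0000
(`04_pca_depth_and_tissue.py`).

A thin CLI wraps the same functions for shell use
(`junctionscope simulate|classify|curves|profiles|discovery|pca|region-d|concordance`);
each run writes TSV/JSON artifacts and a manifest.

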