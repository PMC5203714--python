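# Methods

## Coordinates and identity

All junctions are intron intervals in 1-based, fully closed coordinates:
`start` is the first intronic base, `end` the last. GTF exons are 1-based
closed, so the intron between consecutive exons is
`(exon.end + 1, next_exon.start − 1)`. BED export converts to 0-based
half-open at the writer boundary only; nothing else ever changes
convention. Junction identity is `(chrom, start, end, strand)`; splice-site
motifs are carried as annotations but excluded from identity, so the same
interval called with and without motifs compares equal. Identical intervals
on opposite strands are distinct junctions — collapsing them would corrupt
donor/acceptor roles. Chromosome names match by exact string; an optional
`chr`-prefix add/strip is available at GTF read time but off by default,
because silent renaming makes annotation unions irreproducible.

Strand, when absent from an intropolis-style line, is inferred from the
splice motif pair via the canonical table GT..AG → +, CT..AC → −,
GC..AG → +, CT..GC → −, AT..AC → +, GT..AT → −. The default mode is strict
(a non-canonical pair with no strand column is a parse error); a lenient
mode drops such lines with a logged count. Junction callers emit canonical
motifs by construction, so strictness costs nothing on real inputs and
catches format confusion early.

## Evidence classification

Categories are mutually exclusive and exhaustive, checked in order:
identity membership (fully annotated), both sites annotated (exon skip),
exactly one (alternative donor/acceptor), neither (novel). Two decisions
are genuinely open in how "a site appears in annotation" is read:

- **Role preservation.** By default a query's donor matches only annotated
  *donor* sites and likewise for acceptors, because "alternative donor" is
  a per-role splicing concept. The looser positional interpretation (a
  boundary position on the same chromosome and strand, either role) is
  available as `site_match="positional"` for sensitivity analysis.
- **Strand awareness** is not optional: donor/acceptor identity is
  undefined without strand, so sites are keyed by chromosome, position,
  strand and role throughout.

The exon-skip class deliberately does *not* verify that the skipped
interval contains an annotated exon; it is purely the "both sites
annotated, pair never annotated" condition. Growing the annotation can only
move a junction up the evidence ordering (novel → alt → skip → fully),
which the property tests exercise by random augmentation.

## Prevalence, profiles, confidence

Prevalence is the number of distinct samples (or distinct projects) with
`c_ij ≥ 1`; a junction seen in several samples of one project counts once
at project level, so project prevalence never exceeds sample prevalence.
In per-sample fractions "annotated" means fully annotated only — partial
evidence counts as unannotated, which is the contrast the cohort-scale
analyses draw. An overlap is one instance of a read mapping across a
junction; a read spanning two junctions contributes two overlaps. This is
already the semantics of per-junction counts, so no de-duplication is
attempted. Cohort-scale defaults (S ∈ {1000, 8000}, P = 200, 100,000
junctions per retained sample, 20 reads for "confidently called", with the
multi-curve set {20, 40, 80, 160}) are exposed as constants; synthetic runs
scale them down through ordinary parameters.

## Discovery dates

A junction's discovery date is the minimum submission date over the dated
samples containing it, at calendar-day granularity (repository submission
dates carry no finer resolution; time zones are ignored). Samples without a
date are excluded from the minimum; junctions confined to dateless samples
are dropped with a logged count rather than given an imputed date. The
dominant project on a high-discovery date is computed over the samples that
realize the minimum date for at least one junction discovered that day,
with lexicographic tie-breaking (ties are also reported verbatim).
Annotation-release analysis treats a junction as documented if any release
contains it; per-first-release groups report junction counts, median and
mean sample-prevalence and median discovery date (median of an even-sized
date set takes the lower middle ordinal).

## PCA of unannotated coverage

The input is restricted to junctions whose category is not fully annotated
— partial-evidence junctions are included, since "unannotated" at cohort
scale means the complement of fully annotated; a flag restricts to novel
only — with prevalence and per-sample mapped-read thresholds. Normalization
is `x_ij = log2(c_ij / C_j + 1)`, computed on the sparse nonzeros so zero
counts stay exactly zero; centering subtracts row means taken over the
retained samples (the matrix is built after filtering). The sample × sample
Gram matrix `AᵗA` is accumulated over row blocks, densifying one block at a
time, so the junction dimension never materializes; the result is
symmetrized and independent of block size to roundoff. Components come from
a full symmetric eigendecomposition by default — the right choice at any
size where the Gram matrix fits — with a seeded randomized SVD available
for very wide problems; the two agree to ~1e−6 on variance fractions for
decaying spectra. Variance fractions are eigenvalues over `trace(AᵗA)`.
Signs are fixed deterministically: each component's largest-magnitude
coordinate is made positive, and PC1 is re-oriented so its correlation with
junction depth `s_j` is nonnegative. Correlations are computed from the
*uncentered* x for `s_j` and are invariant to component scaling; both
scaled (by singular value) and unscaled scores are emitted since either
plotting convention is legitimate. A zero-variance correlate yields NaN
with a flag, never a spurious zero.

## Two-region inclusion ratio

Region membership requires both intron endpoints inside the region's span;
junctions within the gene but not wholly in either region — including the
junction joining the last upstream exon to the first downstream exon —
count toward the whole-gene total C only. This is what makes C ≥ A + B,
and the published tallies are consistent only with the denominator A + B
(not C): row DRR016705, A = 38, B = 285, C = 333, prints D = 0.765 =
247/323. The ratio is undefined at A + B = 0; such samples are excluded
from ranking and returned separately. Ranking is competition ranking
(ties share the smallest rank, the next rank skips), reproducing the
published 1, 1, 1, 4 pattern. Display rounding is half-up to 3 decimals
with full precision always retained; one published cell (84/86 printed as
0.976 rather than 0.977) appears to be truncated, so that row is never used
in exact assertions.

## Synthetic cohorts

The generator's job is to produce inputs whose *structure* matches what the
analyses assume, with ground truth the tests can assert exactly.

**Annotation and universe.** Genes are laid out on a toy chromosome with
alternating strands; each gene's full exon chain forms one transcript, and
annotation tracks are the full set plus random subsets (their union is
always the whole annotation). Universe junctions get categories
structurally: fully annotated junctions are sampled from annotated introns;
exon skips join the donor of intron k to the acceptor of intron m > k
(both sites annotated, the pair never, since no skip transcript exists);
alternative-site junctions move exactly one endpoint of an annotated intron
to a fresh position colliding with no annotated site; novel junctions live
in intergenic gaps. The category mixture (default 70/10/15/5% fully/skip/
alt/novel) is hit exactly by largest-remainder apportionment, so classifier
tests compare against exact counts, not samples.

**Cohort.** Mapped reads `C_j` are log-normal (median 500k, log-sd 0.6,
a plausible archive spread); read lengths are drawn from {50, 76, 100};
projects partition the samples and share a submission date, earliest
project first — mimicking batch repository submissions — so widely shared
junctions are discovered early by construction. Expression of junction i in
sample j is Bernoulli with a per-junction probability drawn from the
category's range (fully annotated highest: 0.55–0.98, novel lowest:
0.02–0.80), attenuated outside the junction's preferred tissue group;
expressed entries get `1 + NB` counts with mean
`rate_i × usage_ij × capture_j × C_j` (negative binomial, size 5, the
overdispersion typical of RNA-seq; Poisson is the degenerate option).
Expression rates are log-uniform in reads-per-mapped-read, 1e−5 to 3e−4,
with a 3× boost for fully annotated junctions so well-covered junctions
tend to be annotated. The per-sample capture factor (log-normal) is the
junction-depth axis: it scales `c_ij / C_j` directly and is what the PCA's
PC1 picks up. Rates are kept small enough that
`log2(1 + c/C) ≈ (c/C)/ln 2`, so samples that differ only in capture
factor trace straight rays through the zero-depth point in component space
— the radial geometry the two-group configuration (`radial_config`)
demonstrates with within-group line-fit R² > 0.95. A depth-dominated
configuration (`depth_driven_config`: one tissue group, wide capture
spread) yields r(PC1, s_j) > 0.99.

**What passing these tests does and does not show.** The generator
reproduces the statistical relationships the analyses measure — prevalence/
annotation association, early discovery, depth-dominated PCA — but not
alignment artifacts, reference errors, duplicated genes, motif sequence
content, or non-canonical splicing; agreement on synthetic cohorts
validates the bookkeeping and numerics, not the biology of any real
archive.

## Problem sizes and determinism

Default synthetic cohorts are 400 junctions × 60 samples (80 × 500 for the
radial scenario) — large enough for every relationship to be
unambiguous, small enough that the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeds carried in the
configs; structure (gene layout, category assignment) is integer
arithmetic, so runs are reproducible across platforms. The CLI prints
floats at 6 significant digits (D additionally at 3 decimals) so repeated
runs diff byte-identically.

## Known limitations

- The intropolis writer cannot represent junctions observed in zero
  samples; round-trip identity holds for tables with at least one count
  per junction (the only kind the readers produce).
- Exon-skip classification does not check that the skipped interval
  contains an annotated exon (by design; see above).
- `set_concordance` compares junction identity sets only; it does not model
  per-aligner coverage differences.
- Liftover between assemblies is consumed, never performed: already-lifted
  junction tables are ordinary inputs with a different genome label.
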