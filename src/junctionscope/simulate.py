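"""Synthetic junction cohorts with known ground truth.

The generator emulates the statistical structure of a large aggregated
RNA-seq junction resource without any sequencing: a toy genome of
multi-exon genes yields an annotation (one or more tracks) and a junction
"universe" in which every junction's evidence category is *structural* —
fully annotated junctions are drawn from annotated introns, exon skips pair
two annotated sites never joined by any transcript, alternative
donor/acceptor junctions reuse exactly one annotated site, and novel
junctions live in intergenic space touching no annotated site.  Because the
labels are built by choosing sites rather than sampled post hoc, the
classifier can be tested against exact ground truth.

The cohort layer then emulates the observational structure: per-sample
sequencing depth (log-normal mapped reads ``C_j``), read-length variation,
a per-sample junction-capture factor, project blocks sharing a submission
date (early projects first), at least two tissue-like groups with shifted
usage of unannotated junctions, and negative-binomial read counts
(overdispersed, as RNA-seq counts are; Poisson available as the degenerate
option).  Widely shared junctions are predominantly annotated because the
per-category expression-probability ranges place fully annotated junctions
highest.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .classify import EvidenceCategory
from .io import write_intropolis, write_sample_metadata
from .model import (
    AnnotationIndex,
    Junction,
    JunctionTable,
    SampleMeta,
    junctions_from_transcripts,
    union_annotations,
)

__all__ = ["CohortConfig", "SyntheticAnnotation", "generate_annotation",
           "generate_cohort", "write_fixture", "radial_config",
           "depth_driven_config"]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults give a small, quick cohort
    with the qualitative structure of the real resource."""

    seed: int = 0
    # genome / annotation geometry
    n_genes: int = 45
    exons_per_gene: tuple[int, int] = (7, 9)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (400, 2000)
    gene_spacing: int = 20_000
    chrom: str = "chrS"
    n_annotated_tracks: int = 3
    # junction universe
    n_universe: int = 400
    #: target fractions (fully, exon_skip, alt, novel) among universe junctions
    category_mixture: tuple[float, float, float, float] = (0.70, 0.10, 0.15, 0.05)
    # cohort
    n_samples: int = 60
    n_projects: int = 8
    date_range: tuple[_dt.date, _dt.date] = (
        _dt.date(2009, 1, 1),
        _dt.date(2015, 6, 1),
    )
    read_length_choices: tuple[int, ...] = (50, 76, 100)
    #: log-normal parameters of mapped reads C_j (mean of log, sd of log)
    depth_log_mean: float = np.log(500_000.0)
    depth_log_sd: float = 0.6
    #: per-sample junction-capture factor spread (log-normal sd); this is the
    #: depth axis of the PCA, distinct from library size
    capture_log_sd: float = 0.5
    #: per-category (lo, hi) of the per-junction expression probability
    prevalence_model: dict = field(
        default_factory=lambda: {
            EvidenceCategory.FULLY_ANNOTATED: (0.55, 0.98),
            EvidenceCategory.EXON_SKIP: (0.10, 0.90),
            EvidenceCategory.ALT_DONOR_ACCEPTOR: (0.05, 0.85),
            EvidenceCategory.NOVEL: (0.02, 0.80),
        }
    )
    #: per-junction expression rate (reads per mapped read), log-uniform range
    rate_range: tuple[float, float] = (1e-5, 3e-4)
    #: rate multiplier for fully annotated junctions: well-expressed
    #: junctions tend to be the annotated ones
    annotated_rate_boost: float = 3.0
    count_model: str = "nb"  # "nb" | "poisson"
    nb_size: float = 5.0  # NB dispersion (variance = mu + mu^2/size)
    # tissue structure (applied to unannotated junctions only)
    n_tissue_groups: int = 2
    tissue_effect: float = 4.0  # usage multiplier in the preferred group
    tissue_dropout: float = 0.5  # expression-probability multiplier elsewhere

    def __post_init__(self) -> None:
        if abs(sum(self.category_mixture) - 1.0) > 1e-9:
            raise ValueError("category mixture must sum to 1")
        if any(f < 0 for f in self.category_mixture):
            raise ValueError("category mixture fractions must be nonnegative")
        if self.n_tissue_groups < 1:
            raise ValueError("need at least one tissue group")


def radial_config(seed: int = 0) -> CohortConfig:
    """Two tissue groups differing in junction usage, samples within a group
    differing only in capture depth: the scenario whose PCA embedding shows
    group-wise rays through the low-depth limit point."""
    return replace(
        CohortConfig(seed=seed),
        n_samples=80,
        n_projects=4,
        n_universe=500,
        category_mixture=(0.30, 0.20, 0.30, 0.20),
        prevalence_model={c: (1.0, 1.0) for c in EvidenceCategory},
        capture_log_sd=0.9,
        depth_log_sd=0.15,
        tissue_effect=6.0,
        tissue_dropout=1.0,  # usage differs, expression probability does not
        nb_size=50.0,
    )


def depth_driven_config(seed: int = 0) -> CohortConfig:
    """One tissue group and a wide per-sample capture spread, so the first
    principal component of the unannotated-coverage PCA tracks junction
    sequencing depth — the dominant technical axis of real cohorts."""
    return replace(
        CohortConfig(seed=seed),
        n_tissue_groups=1,
        capture_log_sd=1.0,
        prevalence_model={c: (0.8, 1.0) for c in EvidenceCategory},
        nb_size=20.0,
    )


@dataclass
class SyntheticAnnotation:
    """Annotation tracks plus the labelled junction universe."""

    exon_records: list[tuple[str, str, str, int, int]]
    tracks: list[set[Junction]]
    index: AnnotationIndex
    universe: list[Junction]
    truth: dict[tuple, EvidenceCategory]

    def mixture_counts(self) -> dict[EvidenceCategory, int]:
        out: dict[EvidenceCategory, int] = {c: 0 for c in EvidenceCategory}
        for c in self.truth.values():
            out[c] += 1
        return out


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = total - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def generate_annotation(cfg: CohortConfig) -> SyntheticAnnotation:
    """Build the toy genome, annotation tracks and labelled universe."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.intron_length[0] < 60:
        raise ValueError(
            "introns shorter than 60 bases leave no room for alternative sites"
        )

    exon_records: list[tuple[str, str, str, int, int]] = []
    gene_introns: list[list[Junction]] = []  # per gene, annotated introns in order
    gene_gaps: list[tuple[int, int]] = []  # intergenic space for novel junctions
    cursor = 1_000
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        tx = f"tx{g:04d}"
        pos = cursor
        exons = []
        for _ in range(n_ex):
            elen = int(rng.integers(*cfg.exon_length))
            exons.append((pos, pos + elen - 1))
            ilen = int(rng.integers(*cfg.intron_length))
            pos = pos + elen + ilen
        for s, e in exons:
            exon_records.append((tx, cfg.chrom, strand, s, e))
        introns = [
            Junction(cfg.chrom, a_end + 1, b_start - 1, strand)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
        ]
        gene_introns.append(introns)
        gene_end = exons[-1][1]
        gene_gaps.append((gene_end + 1_000, gene_end + cfg.gene_spacing - 1_000))
        cursor = gene_end + cfg.gene_spacing

    annotated = [j for introns in gene_introns for j in introns]
    if not annotated:
        raise ValueError("gene geometry produced no annotated junctions")

    # tracks: track 0 carries everything; the rest are random subsets, so the
    # union is always the full annotation
    tracks: list[set[Junction]] = [set(annotated)]
    for _ in range(max(0, cfg.n_annotated_tracks - 1)):
        keep = rng.random(len(annotated)) < 0.6
        tracks.append({j for j, k in zip(annotated, keep) if k})
    index = union_annotations(tracks)

    donor_pos = {(s.chrom, s.pos, s.strand) for s in index.donor_sites}
    acc_pos = {(s.chrom, s.pos, s.strand) for s in index.acceptor_sites}
    all_pos = {(c, p) for c, p, _ in donor_pos | acc_pos}

    n_full, n_skip, n_alt, n_novel = _largest_remainder(
        cfg.category_mixture, cfg.n_universe
    )
    universe: list[Junction] = []
    truth: dict[tuple, EvidenceCategory] = {}
    used: set[tuple] = set()

    def _add(j: Junction, cat: EvidenceCategory) -> bool:
        if j.key in used:
            return False
        universe.append(j)
        truth[j.key] = cat
        used.add(j.key)
        return True

    # fully annotated: sample without replacement from annotated introns
    if n_full > len(annotated):
        raise ValueError(
            f"mixture requires {n_full} annotated junctions but the geometry "
            f"yields only {len(annotated)}; increase n_genes or exons_per_gene"
        )
    for i in rng.choice(len(annotated), size=n_full, replace=False):
        _add(annotated[int(i)], EvidenceCategory.FULLY_ANNOTATED)

    # exon skips: join donor of intron k with acceptor of intron m (m > k);
    # both sites are annotated, the pair never is (no skip transcripts exist)
    skip_pool = []
    for introns in gene_introns:
        for k in range(len(introns)):
            for m in range(k + 1, len(introns)):
                skip_pool.append(
                    Junction(
                        cfg.chrom, introns[k].start, introns[m].end, introns[k].strand
                    )
                )
    if n_skip > len(skip_pool):
        raise ValueError("not enough exon-skip geometry; increase exons_per_gene")
    for i in rng.choice(len(skip_pool), size=n_skip, replace=False):
        _add(skip_pool[int(i)], EvidenceCategory.EXON_SKIP)

    # alternative donor/acceptor: keep one annotated site, move the other to
    # a fresh position inside the intron that collides with no annotated site
    placed = 0
    attempts = 0
    while placed < n_alt:
        attempts += 1
        if attempts > 50 * n_alt:
            raise ValueError("could not place alternative-site junctions")
        introns = gene_introns[int(rng.integers(cfg.n_genes))]
        j = introns[int(rng.integers(len(introns)))]
        move_start = bool(rng.integers(2))  # which genomic endpoint moves
        delta = int(rng.integers(5, min(50, (j.end - j.start) // 2)))
        if move_start:
            cand = Junction(j.chrom, j.start + delta, j.end, j.strand)
        else:
            cand = Junction(j.chrom, j.start, j.end - delta, j.strand)
        moved_pos = cand.start if move_start else cand.end
        if (j.chrom, moved_pos) in all_pos:
            continue
        if _add(cand, EvidenceCategory.ALT_DONOR_ACCEPTOR):
            placed += 1

    # novel: intergenic, touching no annotated site
    placed = 0
    attempts = 0
    while placed < n_novel:
        attempts += 1
        if attempts > 50 * max(1, n_novel):
            raise ValueError("could not place novel junctions")
        lo, hi = gene_gaps[int(rng.integers(cfg.n_genes))]
        a = int(rng.integers(lo, hi - 200))
        b = a + int(rng.integers(80, 200))
        strand = "+" if rng.integers(2) else "-"
        cand = Junction(cfg.chrom, a, b, strand)
        if (cand.chrom, cand.start) in all_pos or (cand.chrom, cand.end) in all_pos:
            continue
        if _add(cand, EvidenceCategory.NOVEL):
            placed += 1

    return SyntheticAnnotation(exon_records, tracks, index, universe, truth)


def generate_cohort(
    cfg: CohortConfig, ann: SyntheticAnnotation
) -> tuple[JunctionTable, list[SampleMeta]]:
    """Draw samples, metadata and a sparse count matrix over the universe.

    Expression of junction i in sample j is Bernoulli with a per-junction
    probability drawn from the category's range (annotated junctions widely
    expressed, novel ones rare), attenuated outside a junction's preferred
    tissue group; expressed entries get 1 + NB counts with mean
    ``rate_i * usage_ij * capture_j * C_j``.  Projects partition the samples
    and share a submission date, earliest project first.
    """
    if not ann.universe:
        raise ValueError("junction universe is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = len(ann.universe), cfg.n_samples

    # --- samples -------------------------------------------------------
    proj_of = np.array([j * cfg.n_projects // m for j in range(m)])
    d0, d1 = cfg.date_range
    span = (d1 - d0).days
    proj_dates = [
        d0 + _dt.timedelta(days=int(round(p * span / max(1, cfg.n_projects - 1))))
        for p in range(cfg.n_projects)
    ]
    group_of = np.array(
        [int(rng.integers(cfg.n_tissue_groups)) for _ in range(m)]
    )
    C = np.maximum(
        1_000,
        np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=m)),
    ).astype(np.int64)
    capture = rng.lognormal(0.0, cfg.capture_log_sd, size=m)
    read_len = rng.choice(cfg.read_length_choices, size=m)
    meta = [
        SampleMeta(
            sample_id=f"S{j:04d}",
            project_id=f"P{proj_of[j]:03d}",
            submission_date=proj_dates[proj_of[j]],
            read_length=int(read_len[j]),
            mapped_reads=int(C[j]),
            tissue_label=f"tissue{group_of[j]}",
        )
        for j in range(m)
    ]

    # --- per-junction parameters ---------------------------------------
    cats = np.array([int(ann.truth[j.key]) for j in ann.universe])
    p_expr = np.empty(n)
    for c, (lo, hi) in cfg.prevalence_model.items():
        mask = cats == int(c)
        p_expr[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    lo, hi = np.log(cfg.rate_range[0]), np.log(cfg.rate_range[1])
    rate = np.exp(rng.uniform(lo, hi, size=n))
    pref_group = rng.integers(cfg.n_tissue_groups, size=n)
    unannotated = cats != int(EvidenceCategory.FULLY_ANNOTATED)
    rate = np.where(unannotated, rate, rate * cfg.annotated_rate_boost)

    # --- counts ----------------------------------------------------------
    rows, cols, data = [], [], []
    for i in range(n):
        if unannotated[i] and cfg.n_tissue_groups > 1:
            preferred = group_of == pref_group[i]
            usage = np.where(preferred, cfg.tissue_effect, 1.0)
            p_ij = np.where(preferred, p_expr[i], p_expr[i] * cfg.tissue_dropout)
        else:
            usage = np.ones(m)
            p_ij = np.full(m, p_expr[i])
        expressed = rng.random(m) < p_ij
        if not expressed.any():
            continue
        mu = rate[i] * usage[expressed] * capture[expressed] * C[expressed]
        if cfg.count_model == "poisson":
            extra = rng.poisson(mu)
        elif cfg.count_model == "nb":
            p_nb = cfg.nb_size / (cfg.nb_size + mu)
            extra = rng.negative_binomial(cfg.nb_size, p_nb)
        else:
            raise ValueError(f"unknown count model {cfg.count_model!r}")
        counts = 1 + extra  # expressed implies at least one supporting read
        idx = np.flatnonzero(expressed)
        rows.extend([i] * len(idx))
        cols.extend(idx.tolist())
        data.extend(counts.tolist())

    counts = sp.coo_matrix((data, (rows, cols)), shape=(n, m), dtype=np.int64)
    table = JunctionTable(ann.universe, [mm.sample_id for mm in meta], counts.tocsr())
    empty = [mm.sample_id for j, mm in enumerate(meta) if table.counts.getnnz(0)[j] == 0]
    if empty:
        import logging

        logging.getLogger(__name__).warning(
            "%d samples have no expressed junctions: %s", len(empty), empty[:5]
        )
    return table, meta


def write_gtf(
    exon_records: Sequence[tuple[str, str, str, int, int]], path: str | Path
) -> Path:
    """Write exon records as a minimal GTF (feature type ``exon``)."""
    path = Path(path)
    with open(path, "w") as fh:
        for tx, chrom, strand, start, end in exon_records:
            gene = tx.replace("tx", "gene")
            attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
            fh.write(
                f"{chrom}\tsynthetic\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
    return path


def write_fixture(cfg: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a complete on-disk fixture: per-track GTFs, an
    intropolis-style junction TSV, sample metadata and ground-truth labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(cfg)
    table, meta = generate_cohort(cfg, ann)

    paths: dict[str, Path] = {}
    for k, track in enumerate(ann.tracks):
        track_txs = set()
        track_recs = []
        # keep only transcripts whose introns are all in the track
        by_tx: dict[str, list] = {}
        for rec in ann.exon_records:
            by_tx.setdefault(rec[0], []).append(rec)
        for tx, recs in by_tx.items():
            introns = junctions_from_transcripts(recs)
            if introns <= track:
                track_txs.add(tx)
                track_recs.extend(recs)
        paths[f"track{k}"] = write_gtf(track_recs, outdir / f"track{k}.gtf")
    paths["junctions"] = write_intropolis(table, outdir / "junctions.tsv")
    paths["metadata"] = write_sample_metadata(meta, outdir / "samples.tsv")
    truth_path = outdir / "truth_labels.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tcategory\n")
        for j in sorted(ann.universe, key=lambda j: j.key):
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t"
                f"{ann.truth[j.key].label}\n"
            )
    paths["truth"] = truth_path
    return paths
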