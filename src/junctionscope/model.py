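"""Core domain types for junction-level RNA-seq analysis.

The atomic object is an exon-exon :class:`Junction`, represented by its
intron's genomic interval in 1-based fully-closed coordinates (``start`` is
the first intronic base, ``end`` the last) together with its strand.  A
cohort of aggregated junction calls is a :class:`JunctionTable`: a sparse
junction x sample matrix of read counts ``c_ij`` with per-sample metadata in
:class:`SampleMeta` rows.  Annotated splicing is held in an
:class:`AnnotationIndex` keyed both by whole junctions and by individual
donor/acceptor splice sites.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Junction",
    "SpliceSite",
    "SampleMeta",
    "JunctionTable",
    "AnnotationIndex",
    "junctions_from_transcripts",
    "union_annotations",
    "MOTIF_STRAND",
]

#: Canonical splice-site dinucleotide pairs and the strand they imply.
#: Keys are (donor-side motif, acceptor-side motif) as read off the forward
#: strand of the reference at the intron boundaries.
MOTIF_STRAND: Mapping[tuple[str, str], str] = {
    ("GT", "AG"): "+",
    ("CT", "AC"): "-",
    ("GC", "AG"): "+",
    ("CT", "GC"): "-",
    ("AT", "AC"): "+",
    ("GT", "AT"): "-",
}


class SpliceSite(NamedTuple):
    """One intron boundary: a donor (5') or acceptor (3') site.

    ``pos`` is the 1-based first/last intronic base; identity is the full
    tuple, so sites on opposite strands or with different roles never match.
    """

    chrom: str
    pos: int
    strand: str
    role: str  # "donor" | "acceptor"


@dataclass(frozen=True)
class Junction:
    """An exon-exon junction, identified by its intron interval and strand.

    ``start``/``end`` are 1-based and inclusive: the first and last base of
    the intron.  Splice-site motifs are carried as annotations but excluded
    from identity and hashing.
    """

    chrom: str
    start: int
    end: int
    strand: str
    donor_motif: str = field(default="", compare=False)
    acceptor_motif: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"junction start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"junction end {self.end} precedes start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def donor_site(self) -> SpliceSite:
        """5' intron boundary: ``start`` on '+', ``end`` on '-'."""
        pos = self.start if self.strand == "+" else self.end
        return SpliceSite(self.chrom, pos, self.strand, "donor")

    @property
    def acceptor_site(self) -> SpliceSite:
        """3' intron boundary: ``end`` on '+', ``start`` on '-'."""
        pos = self.end if self.strand == "+" else self.start
        return SpliceSite(self.chrom, pos, self.strand, "acceptor")

    def sites(self) -> tuple[SpliceSite, SpliceSite]:
        return (self.donor_site, self.acceptor_site)


@dataclass
class SampleMeta:
    """Per-sample covariates for one sequencing run."""

    sample_id: str
    project_id: str = ""
    submission_date: _dt.date | None = None
    read_length: int | None = None  # p_j, bases
    mapped_reads: int | None = None  # C_j
    tissue_label: str | None = None

    def __post_init__(self) -> None:
        if self.mapped_reads is not None and self.mapped_reads < 0:
            raise ValueError(f"{self.sample_id}: mapped_reads must be >= 0")
        if self.read_length is not None and self.read_length < 1:
            raise ValueError(f"{self.sample_id}: read_length must be >= 1")


class JunctionTable:
    """Sparse junction x sample read-count matrix with junction metadata.

    Stored counts are strictly positive; a junction absent from a sample is
    an implicit zero.  Row support (number of samples with ``c_ij >= 1``) is
    the junction's sample-prevalence used by every downstream analysis.
    """

    def __init__(
        self,
        junctions: Sequence[Junction],
        sample_ids: Sequence[str],
        counts: sp.spmatrix | np.ndarray,
    ) -> None:
        self.junctions: list[Junction] = list(junctions)
        self.sample_ids: list[str] = list(sample_ids)
        counts = sp.csr_matrix(counts, dtype=np.int64)
        counts.eliminate_zeros()
        if counts.shape != (len(self.junctions), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.junctions)} junctions x {len(self.sample_ids)} samples"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len({j.key for j in self.junctions}) != len(self.junctions):
            raise ValueError("duplicate junction identities")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.counts: sp.csr_matrix = counts

    # -- basic geometry -------------------------------------------------
    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def junction_index(self) -> dict[tuple, int]:
        return {j.key: i for i, j in enumerate(self.junctions)}

    # -- derived quantities ---------------------------------------------
    def sample_prevalence(self) -> np.ndarray:
        """Number of distinct samples with c_ij >= 1, per junction."""
        return np.asarray(self.counts.getnnz(axis=1))

    def total_reads(self) -> np.ndarray:
        """Sum of counts across samples, per junction."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def project_prevalence(self, meta: Sequence[SampleMeta]) -> np.ndarray:
        """Number of distinct projects with c_ij >= 1, per junction.

        A junction seen in several samples of one project counts once.
        """
        by_id = {m.sample_id: m.project_id for m in meta}
        missing = [s for s in self.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        projects = sorted({by_id[s] for s in self.sample_ids})
        pidx = {p: k for k, p in enumerate(projects)}
        cols = np.array([pidx[by_id[s]] for s in self.sample_ids])
        onehot = sp.csr_matrix(
            (np.ones(self.n_samples), (np.arange(self.n_samples), cols)),
            shape=(self.n_samples, len(projects)),
        )
        per_project = (self.counts > 0) @ onehot  # junction x project
        return np.asarray((per_project > 0).sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        junction_mask: np.ndarray | None = None,
        sample_mask: np.ndarray | None = None,
    ) -> "JunctionTable":
        juncs = self.junctions
        sids = self.sample_ids
        counts = self.counts
        if junction_mask is not None:
            junction_mask = np.asarray(junction_mask)
            juncs = [j for j, keep in zip(juncs, junction_mask) if keep]
            counts = counts[junction_mask]
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            sids = [s for s, keep in zip(sids, sample_mask) if keep]
            counts = counts[:, sample_mask]
        return JunctionTable(juncs, sids, counts)

    def sample_counts(self, i: int) -> dict[str, int]:
        """Mapping sample id -> count for junction row ``i`` (nonzeros only)."""
        row = self.counts.getrow(i)
        return {self.sample_ids[j]: int(v) for j, v in zip(row.indices, row.data)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionTable):
            return NotImplemented
        return (
            self.junctions == other.junctions
            and self.sample_ids == other.sample_ids
            and (self.counts != other.counts).nnz == 0
        )

    def __repr__(self) -> str:
        return (
            f"JunctionTable({self.n_junctions} junctions x "
            f"{self.n_samples} samples, {self.counts.nnz} nonzero)"
        )


@dataclass
class AnnotationIndex:
    """Annotated junctions plus the strand/role-aware site sets they imply."""

    junction_set: frozenset[tuple]
    donor_sites: frozenset[SpliceSite]
    acceptor_sites: frozenset[SpliceSite]

    @classmethod
    def from_junctions(cls, junctions: Iterable[Junction]) -> "AnnotationIndex":
        keys, donors, acceptors = set(), set(), set()
        for j in junctions:
            keys.add(j.key)
            donors.add(j.donor_site)
            acceptors.add(j.acceptor_site)
        return cls(frozenset(keys), frozenset(donors), frozenset(acceptors))

    def __contains__(self, j: Junction) -> bool:
        return j.key in self.junction_set

    def __len__(self) -> int:
        return len(self.junction_set)


def junctions_from_transcripts(
    exons: Iterable[tuple[str, str, str, int, int]],
) -> set[Junction]:
    """Derive the intron set implied by transcripts' exon chains.

    Parameters
    ----------
    exons
        Records ``(transcript_id, chrom, strand, exon_start, exon_end)`` with
        1-based inclusive exon coordinates.  Exons of one transcript must be
        non-overlapping and non-abutting.

    Returns
    -------
    set of Junction
        One junction per consecutive exon pair (sorted by start), i.e. the
        intron ``(exon_k.end + 1, exon_{k+1}.start - 1)``; duplicates across
        transcripts collapse.
    """
    by_tx: dict[str, list[tuple[str, str, int, int]]] = {}
    for tx, chrom, strand, start, end in exons:
        by_tx.setdefault(tx, []).append((chrom, strand, start, end))
    out: set[Junction] = set()
    for tx, recs in by_tx.items():
        recs.sort(key=lambda r: (r[2], r[3]))
        for (c1, s1, a1, b1), (c2, s2, a2, b2) in zip(recs, recs[1:]):
            if c1 != c2 or s1 != s2:
                raise ValueError(
                    f"transcript {tx}: exons on mixed chrom/strand"
                )
            if a2 <= b1 + 1:
                raise ValueError(
                    f"transcript {tx}: overlapping or abutting exons "
                    f"({a1}-{b1}, {a2}-{b2})"
                )
            out.add(Junction(c1, b1 + 1, a2 - 1, s1))
    return out


def union_annotations(tracks: Sequence[Iterable[Junction]]) -> AnnotationIndex:
    """Union one or more annotation tracks into a single index.

    Junction identity includes strand, so identical intervals on opposite
    strands stay distinct.  Union is idempotent, commutative and associative.
    """
    if not tracks:
        raise ValueError("at least one annotation track is required")
    merged: set[Junction] = set()
    for t in tracks:
        merged.update(t)
    return AnnotationIndex.from_junctions(merged)
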