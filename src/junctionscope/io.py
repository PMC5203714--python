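"""Readers and writers: intropolis-style TSV, GTF exons, metadata, BED.

The intropolis-style format is a tab-separated file with one junction per
line: chromosome, intron start, intron end (both 1-based inclusive), a
strand and/or motif field block, a comma-separated list of sample ids and a
matching comma-separated list of read counts.  Both dialects observed in
the wild are supported: an explicit strand column, or donor/acceptor motif
columns from which strand is inferred via the canonical table
(GT..AG/+, CT..AC/-, GC..AG/+, CT..GC/-, AT..AC/+, GT..AT/-).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .model import MOTIF_STRAND, Junction, JunctionTable, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "IntropolisDialect",
    "IntropolisParseError",
    "read_intropolis",
    "write_intropolis",
    "read_gtf_exons",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_bed",
]


class IntropolisParseError(ValueError):
    """Malformed intropolis-style line; message names the line number."""


@dataclass(frozen=True)
class IntropolisDialect:
    """Layout of the columns between the coordinates and the sample lists.

    ``has_strand`` / ``has_motifs`` describe the middle column block:
    strand only (1 column), motifs only (2), or strand followed by donor and
    acceptor motifs (3).  When only motifs are present, strand is inferred
    from the canonical motif table.
    """

    has_strand: bool = True
    has_motifs: bool = True

    @property
    def n_middle(self) -> int:
        return int(self.has_strand) + 2 * int(self.has_motifs)


def _infer_dialect(n_columns: int) -> IntropolisDialect:
    middle = n_columns - 5  # chrom, start, end, ..., sample ids, counts
    if middle == 1:
        return IntropolisDialect(has_strand=True, has_motifs=False)
    if middle == 2:
        return IntropolisDialect(has_strand=False, has_motifs=True)
    if middle == 3:
        return IntropolisDialect(has_strand=True, has_motifs=True)
    raise IntropolisParseError(
        f"cannot infer dialect from {n_columns} columns "
        "(expected 6, 7 or 8 per line)"
    )


def read_intropolis(
    path: str | Path,
    dialect: IntropolisDialect | None = None,
    strict: bool = True,
) -> JunctionTable:
    """Read an intropolis-style TSV into a :class:`JunctionTable`.

    With ``strict=True`` (default) a line whose strand cannot be resolved —
    a non-canonical motif pair and no strand column — raises
    :class:`IntropolisParseError`; with ``strict=False`` such lines are
    dropped with a logged count.  Structural problems (wrong column count,
    non-integer coordinates, mismatched id/count list lengths) always raise.
    """
    path = Path(path)
    junctions: list[Junction] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    sample_index: dict[str, int] = {}
    dropped = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            d = dialect or _infer_dialect(len(fields))
            if len(fields) != 5 + d.n_middle:
                raise IntropolisParseError(
                    f"{path}:{lineno}: expected {5 + d.n_middle} columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise IntropolisParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            mid = fields[3 : 3 + d.n_middle]
            strand: str | None = None
            donor_motif = acceptor_motif = ""
            if d.has_strand:
                strand = mid[0]
                mid = mid[1:]
            if d.has_motifs:
                donor_motif = "" if mid[0] == "." else mid[0].upper()
                acceptor_motif = "" if mid[1] == "." else mid[1].upper()
            if strand is None:
                strand = MOTIF_STRAND.get((donor_motif, acceptor_motif))
                if strand is None:
                    if strict:
                        raise IntropolisParseError(
                            f"{path}:{lineno}: motif pair "
                            f"({donor_motif!r}, {acceptor_motif!r}) not in "
                            "the canonical table and no strand column"
                        )
                    dropped += 1
                    continue
            ids = fields[-2].split(",")
            try:
                counts = [int(c) for c in fields[-1].split(",")]
            except ValueError:
                raise IntropolisParseError(
                    f"{path}:{lineno}: non-integer count in {fields[-1]!r}"
                ) from None
            if len(ids) != len(counts):
                raise IntropolisParseError(
                    f"{path}:{lineno}: {len(ids)} sample ids but "
                    f"{len(counts)} counts"
                )
            try:
                j = Junction(chrom, start, end, strand, donor_motif, acceptor_motif)
            except ValueError as exc:
                raise IntropolisParseError(f"{path}:{lineno}: {exc}") from None
            row = len(junctions)
            junctions.append(j)
            for sid, c in zip(ids, counts):
                col = sample_index.setdefault(sid, len(sample_index))
                rows.append(row)
                cols.append(col)
                data.append(c)

    if dropped:
        logger.warning("%s: dropped %d lines with unresolvable strand", path, dropped)
    sample_ids = [s for s, _ in sorted(sample_index.items(), key=lambda kv: kv[1])]
    counts = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(junctions), len(sample_ids)), dtype=np.int64
    )
    return JunctionTable(junctions, sample_ids, counts.tocsr())


def write_intropolis(table: JunctionTable, path: str | Path) -> Path:
    """Write a table in the full dialect (strand + motif columns).

    Output is deterministic: junctions sorted by (chrom, start, end, strand),
    sample ids ascending within each line; ``read_intropolis`` inverts it
    exactly up to that canonical ordering.  Missing motifs are written as
    ``.``.
    """
    path = Path(path)
    order = sorted(range(table.n_junctions), key=lambda i: table.junctions[i].key)
    with open(path, "w") as fh:
        for i in order:
            j = table.junctions[i]
            per_sample = sorted(table.sample_counts(i).items())
            if not per_sample:
                continue  # empty rows are not representable; implicit zeros
            ids = ",".join(s for s, _ in per_sample)
            counts = ",".join(str(c) for _, c in per_sample)
            fh.write(
                "\t".join(
                    [
                        j.chrom,
                        str(j.start),
                        str(j.end),
                        j.strand,
                        j.donor_motif or ".",
                        j.acceptor_motif or ".",
                        ids,
                        counts,
                    ]
                )
                + "\n"
            )
    return path


def read_gtf_exons(
    path: str | Path, chr_prefix: str | None = None
) -> list[tuple[str, str, str, int, int]]:
    """Read exon records from a GTF/GFF2 file.

    Only features of type ``exon`` carrying a ``transcript_id`` attribute are
    used; exons may appear in any order within a transcript.  Returns records
    ``(transcript_id, chrom, strand, start, end)`` suitable for
    :func:`junctionscope.model.junctions_from_transcripts`.

    ``chr_prefix``: ``"add"`` prepends ``chr`` to names lacking it, ``"strip"``
    removes a leading ``chr``; default ``None`` leaves names untouched
    (chromosome matching elsewhere is exact-string).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for ex in db.features_of_type("exon"):
        tx = ex.attributes.get("transcript_id")
        if not tx:
            continue
        chrom = ex.seqid
        if chr_prefix == "add" and not chrom.startswith("chr"):
            chrom = "chr" + chrom
        elif chr_prefix == "strip" and chrom.startswith("chr"):
            chrom = chrom[3:]
        out.append((tx[0], chrom, ex.strand, ex.start, ex.end))
    return out


_META_COLUMNS = [
    "sample_id",
    "project_id",
    "submission_date",
    "read_length",
    "mapped_reads",
    "tissue_label",
]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV (ISO-8601 dates; empty fields = missing)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file lacks required columns: {missing}")
    metas = []
    for rec in df.to_dict("records"):
        date = rec.get("submission_date", "")
        metas.append(
            SampleMeta(
                sample_id=rec["sample_id"],
                project_id=rec.get("project_id", ""),
                submission_date=_dt.date.fromisoformat(date) if date else None,
                read_length=int(rec["read_length"]) if rec.get("read_length") else None,
                mapped_reads=int(rec["mapped_reads"]) if rec.get("mapped_reads") else None,
                tissue_label=rec.get("tissue_label") or None,
            )
        )
    return metas


def write_sample_metadata(meta: Sequence[SampleMeta], path: str | Path) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "project_id": m.project_id,
                "submission_date": m.submission_date.isoformat()
                if m.submission_date
                else "",
                "read_length": m.read_length if m.read_length is not None else "",
                "mapped_reads": m.mapped_reads if m.mapped_reads is not None else "",
                "tissue_label": m.tissue_label or "",
            }
            for m in meta
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_bed(
    junctions: Sequence[Junction],
    path: str | Path,
    scores: Sequence[int] | None = None,
) -> Path:
    """Export junctions as BED6 intervals of their introns.

    The 1-based closed intron ``[start, end]`` converts to 0-based half-open
    ``[start-1, end)``; the score column carries sample-prevalence when given
    (clamped to BED's 0-1000 range).
    """
    path = Path(path)
    if scores is None:
        scores = [0] * len(junctions)
    order = sorted(range(len(junctions)), key=lambda i: junctions[i].key)
    with open(path, "w") as fh:
        for i in order:
            j = junctions[i]
            name = f"{j.chrom}:{j.start}-{j.end}:{j.strand}"
            fh.write(
                f"{j.chrom}\t{j.start - 1}\t{j.end}\t{name}"
                f"\t{min(int(scores[i]), 1000)}\t{j.strand}\n"
            )
    return path
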