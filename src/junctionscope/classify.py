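"""Annotation-evidence classification of exon-exon junctions.

Every RNA-seq junction receives exactly one of four mutually exclusive
evidence categories relative to an annotation index:

* ``FULLY_ANNOTATED`` — the junction itself (chrom, start, end, strand)
  appears in some annotated transcript;
* ``EXON_SKIP`` — both its donor and its acceptor site are annotated, but
  never paired in one annotated junction (typically an exon-skipping event);
* ``ALT_DONOR_ACCEPTOR`` — exactly one of the two sites is annotated;
* ``NOVEL`` — neither site appears in annotation.

Site matching is strand-aware and, by default, role-aware: a query donor
matches only annotated donor sites.  The looser positional mode
(``site_match="positional"``) lets a donor match any annotated boundary
position on the same chromosome and strand, for sensitivity analysis.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Literal, Mapping

from .model import AnnotationIndex, Junction, JunctionTable

__all__ = ["EvidenceCategory", "classify_junction", "classify_table"]

SiteMatch = Literal["role", "positional"]


class EvidenceCategory(enum.IntEnum):
    """Annotation-evidence class; the integer value orders by evidence level."""

    NOVEL = 0
    ALT_DONOR_ACCEPTOR = 1
    EXON_SKIP = 2
    FULLY_ANNOTATED = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    EvidenceCategory.FULLY_ANNOTATED: "fully_annotated",
    EvidenceCategory.EXON_SKIP: "exon_skip",
    EvidenceCategory.ALT_DONOR_ACCEPTOR: "alt_donor_acceptor",
    EvidenceCategory.NOVEL: "novel",
}


def _positional_sites(idx: AnnotationIndex) -> frozenset[tuple[str, int, str]]:
    return frozenset(
        (s.chrom, s.pos, s.strand)
        for s in (*idx.donor_sites, *idx.acceptor_sites)
    )


def classify_junction(
    j: Junction,
    idx: AnnotationIndex,
    site_match: SiteMatch = "role",
) -> EvidenceCategory:
    """Classify one junction against the annotation index.

    Total on valid inputs; identity membership is checked first, then the
    two site memberships.
    """
    if j.key in idx.junction_set:
        return EvidenceCategory.FULLY_ANNOTATED
    if site_match == "role":
        donor_hit = j.donor_site in idx.donor_sites
        acceptor_hit = j.acceptor_site in idx.acceptor_sites
    elif site_match == "positional":
        pos = _positional_sites(idx)
        d, a = j.donor_site, j.acceptor_site
        donor_hit = (d.chrom, d.pos, d.strand) in pos
        acceptor_hit = (a.chrom, a.pos, a.strand) in pos
    else:
        raise ValueError(f"site_match must be 'role' or 'positional', got {site_match!r}")
    if donor_hit and acceptor_hit:
        return EvidenceCategory.EXON_SKIP
    if donor_hit or acceptor_hit:
        return EvidenceCategory.ALT_DONOR_ACCEPTOR
    return EvidenceCategory.NOVEL


def classify_table(
    t: JunctionTable,
    idx: AnnotationIndex,
    site_match: SiteMatch = "role",
) -> tuple[dict[tuple, EvidenceCategory], Counter]:
    """Classify every junction in a table.

    Returns a mapping from junction identity key to category, plus a
    Counter of category totals (which sum to the table size).
    """
    pos = _positional_sites(idx) if site_match == "positional" else None
    cats: dict[tuple, EvidenceCategory] = {}
    for j in t.junctions:
        if j.key in idx.junction_set:
            c = EvidenceCategory.FULLY_ANNOTATED
        else:
            if pos is None:
                donor_hit = j.donor_site in idx.donor_sites
                acceptor_hit = j.acceptor_site in idx.acceptor_sites
            else:
                d, a = j.donor_site, j.acceptor_site
                donor_hit = (d.chrom, d.pos, d.strand) in pos
                acceptor_hit = (a.chrom, a.pos, a.strand) in pos
            if donor_hit and acceptor_hit:
                c = EvidenceCategory.EXON_SKIP
            elif donor_hit or acceptor_hit:
                c = EvidenceCategory.ALT_DONOR_ACCEPTOR
            else:
                c = EvidenceCategory.NOVEL
        cats[j.key] = c
    return cats, Counter(cats.values())


def category_array(
    t: JunctionTable, categories: Mapping[tuple, EvidenceCategory]
):
    """Vector of categories aligned with the table's junction order."""
    import numpy as np

    return np.array([int(categories[j.key]) for j in t.junctions], dtype=np.int8)
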