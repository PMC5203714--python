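"""Cohort-level aggregation: prevalence curves, per-sample annotated
fractions, confidence filters and cross-set membership statistics.

"Prevalence" of a junction is the number of distinct samples (or distinct
projects) in which it was observed with at least one read.  "Annotated" in
the per-sample fractions means fully annotated only: junctions with partial
evidence (exon skip, alternative donor/acceptor) count as unannotated, the
contrast the cohort-scale analyses draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import EvidenceCategory, category_array
from .model import Junction, JunctionTable, SampleMeta

__all__ = [
    "prevalence_curve",
    "per_sample_profiles",
    "confident_junctions",
    "set_concordance",
    "cross_cohort_membership",
    "SampleAnnotationProfile",
    "DEFAULT_SAMPLE_THRESHOLDS",
    "DEFAULT_PROJECT_THRESHOLD",
    "DEFAULT_MIN_JUNCTIONS_PER_SAMPLE",
    "DEFAULT_CONFIDENT_READS",
    "CONFIDENT_READ_THRESHOLDS",
]

# Cohort-scale defaults; synthetic runs scale these down.
DEFAULT_SAMPLE_THRESHOLDS = (1000, 8000)
DEFAULT_PROJECT_THRESHOLD = 200
DEFAULT_MIN_JUNCTIONS_PER_SAMPLE = 100_000
DEFAULT_CONFIDENT_READS = 20
CONFIDENT_READ_THRESHOLDS = (20, 40, 80, 160)

_CATEGORY_ORDER = [
    EvidenceCategory.FULLY_ANNOTATED,
    EvidenceCategory.EXON_SKIP,
    EvidenceCategory.ALT_DONOR_ACCEPTOR,
    EvidenceCategory.NOVEL,
]


def prevalence_curve(
    t: JunctionTable,
    categories: Mapping[tuple, EvidenceCategory],
    unit: str = "sample",
    meta: Sequence[SampleMeta] | None = None,
    thresholds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Count junctions found in at least S samples (or P projects), by category.

    Returns a DataFrame indexed by threshold with one column per evidence
    category plus a ``total`` column; each category's counts are
    nonincreasing in the threshold and rows sum to ``total``.
    """
    if unit not in ("sample", "project"):
        raise ValueError(f"unit must be 'sample' or 'project', got {unit!r}")
    if unit == "project":
        if meta is None:
            raise ValueError("project-level prevalence requires sample metadata")
        prev = t.project_prevalence(meta)
    else:
        prev = t.sample_prevalence()
    if thresholds is None:
        thresholds = sorted({1, *DEFAULT_SAMPLE_THRESHOLDS})
    thresholds = sorted(thresholds)
    cats = category_array(t, categories)
    rows = []
    for s in thresholds:
        mask = prev >= s
        row = {"threshold": s, "total": int(mask.sum())}
        for c in _CATEGORY_ORDER:
            row[c.label] = int((mask & (cats == int(c))).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


@dataclass
class SampleAnnotationProfile:
    """Per-sample junction tallies and fully-annotated fractions.

    ``n_overlaps`` is the number of junction overlaps — instances of a read
    mapping across a junction; a read spanning two junctions contributes two.
    """

    sample_id: str
    n_junctions: int
    n_overlaps: int
    frac_overlaps_annotated: float
    frac_junctions_annotated: float


def per_sample_profiles(
    t: JunctionTable,
    categories: Mapping[tuple, EvidenceCategory],
    min_junctions: int = DEFAULT_MIN_JUNCTIONS_PER_SAMPLE,
) -> list[SampleAnnotationProfile]:
    """Annotated fractions per sample, restricted to samples with at least
    ``min_junctions`` distinct junctions (the guard against tiny or
    mislabeled runs)."""
    cats = category_array(t, categories)
    annotated = cats == int(EvidenceCategory.FULLY_ANNOTATED)
    csc = t.counts.tocsc()
    n_junc = csc.getnnz(axis=0)
    overlaps = np.asarray(csc.sum(axis=0)).ravel()
    binar = (csc > 0).astype(np.int64)
    ann_junc = np.asarray(binar[annotated].sum(axis=0)).ravel()
    ann_over = np.asarray(csc[annotated].sum(axis=0)).ravel()
    out = []
    for j, sid in enumerate(t.sample_ids):
        if n_junc[j] < min_junctions or n_junc[j] == 0:
            continue
        out.append(
            SampleAnnotationProfile(
                sample_id=sid,
                n_junctions=int(n_junc[j]),
                n_overlaps=int(overlaps[j]),
                frac_overlaps_annotated=float(ann_over[j] / overlaps[j]),
                frac_junctions_annotated=float(ann_junc[j] / n_junc[j]),
            )
        )
    return out


def confident_junctions(
    t: JunctionTable, min_total_reads: int = DEFAULT_CONFIDENT_READS
) -> set[Junction]:
    """Junctions supported by >= ``min_total_reads`` reads summed over all
    samples ("confidently called")."""
    if min_total_reads < 1:
        raise ValueError("min_total_reads must be >= 1")
    total = t.total_reads()
    return {j for j, tot in zip(t.junctions, total) if tot >= min_total_reads}


def set_concordance(
    reference: JunctionTable,
    others: Sequence[set[Junction]],
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Concordance of reference junctions with independent call sets.

    For each prevalence threshold S, among reference junctions found in at
    least S samples: how many are found in >= 1, >= 2, ..., all of the other
    sets.  Counts and fractions are both reported.
    """
    if not others:
        raise ValueError("at least one comparison set is required")
    other_keys = [{j.key for j in s} for s in others]
    prev = reference.sample_prevalence()
    hits = np.zeros(reference.n_junctions, dtype=np.int64)
    for keys in other_keys:
        hits += np.array([j.key in keys for j in reference.junctions])
    rows = []
    for s in sorted(thresholds):
        mask = prev >= s
        n = int(mask.sum())
        row: dict = {"threshold": s, "n_reference": n}
        for k in range(1, len(others) + 1):
            nk = int((mask & (hits >= k)).sum())
            row[f"found_ge_{k}"] = nk
            row[f"frac_ge_{k}"] = nk / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


def cross_cohort_membership(
    query: set[Junction],
    t: JunctionTable,
    prevalence_thresholds: Sequence[int],
    categories: Mapping[tuple, EvidenceCategory],
) -> pd.DataFrame:
    """Membership of an external junction set in the cohort, by prevalence.

    For each threshold k: the number of query junctions whose identity
    appears in the cohort with prevalence >= k, and the evidence-category
    breakdown (counts and fractions) of those found.  The query must share
    the cohort's coordinate system (liftover, when needed, happens upstream).
    """
    prev = t.sample_prevalence()
    prev_by_key = {j.key: p for j, p in zip(t.junctions, prev)}
    rows = []
    for k in sorted(prevalence_thresholds):
        found = [q for q in query if prev_by_key.get(q.key, 0) >= k]
        row: dict = {"threshold": k, "n_query_found": len(found)}
        for c in _CATEGORY_ORDER:
            n = sum(1 for q in found if categories[q.key] == c)
            row[f"n_{c.label}"] = n
            row[f"frac_{c.label}"] = n / len(found) if found else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")
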