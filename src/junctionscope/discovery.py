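"""Discovery-date accumulation and annotation-release first appearance.

The discovery date of a junction is the earliest repository submission date
among the samples in which it was observed.  Only "confidently called"
junctions (total read support over the whole cohort above a threshold,
default 20) enter the analysis.  Samples without a submission date are
excluded from the minimum; junctions seen only in dateless samples are
dropped with a logged count rather than given an imputed date.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Junction, JunctionTable, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "DiscoveryRecord",
    "ReleaseHistory",
    "discovery_dates",
    "accumulation_curve",
    "fraction_discovered_by",
    "top_contributing_dates",
    "release_first_appearance",
]


@dataclass
class DiscoveryRecord:
    junction: Junction
    discovery_date: _dt.date
    n_samples: int  # sample-prevalence
    total_reads: int


@dataclass
class ReleaseHistory:
    """Ordered annotation releases: (label, date, junction set) triples."""

    releases: list[tuple[str, _dt.date, set[Junction]]]

    def __post_init__(self) -> None:
        dates = [d for _, d, _ in self.releases]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("release dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.releases)


def discovery_dates(
    t: JunctionTable,
    meta: Sequence[SampleMeta],
    min_total_reads: int = 20,
) -> list[DiscoveryRecord]:
    """Earliest submission date per confidently called junction.

    Raises if no sample carries a date.  Junctions confined to dateless
    samples are dropped (count logged).
    """
    date_by_id = {m.sample_id: m.submission_date for m in meta}
    dates = [date_by_id.get(s) for s in t.sample_ids]
    if all(d is None for d in dates):
        raise ValueError("no sample has a submission date")
    # ordinal encoding; dateless samples get a sentinel larger than any date
    sentinel = np.iinfo(np.int64).max
    ords = np.array(
        [d.toordinal() if d is not None else sentinel for d in dates], dtype=np.int64
    )
    total = t.total_reads()
    prev = t.sample_prevalence()
    keep = total >= min_total_reads
    records: list[DiscoveryRecord] = []
    dropped = 0
    indptr, indices = t.counts.indptr, t.counts.indices
    for i in np.flatnonzero(keep):
        cols = indices[indptr[i] : indptr[i + 1]]
        mn = ords[cols].min() if len(cols) else sentinel
        if mn == sentinel:
            dropped += 1
            continue
        records.append(
            DiscoveryRecord(
                junction=t.junctions[i],
                discovery_date=_dt.date.fromordinal(int(mn)),
                n_samples=int(prev[i]),
                total_reads=int(total[i]),
            )
        )
    if dropped:
        logger.warning(
            "%d confident junctions found only in dateless samples; dropped", dropped
        )
    return records


def accumulation_curve(
    records: Sequence[DiscoveryRecord],
    read_thresholds: Sequence[int] = (20, 40, 80, 160),
) -> pd.DataFrame:
    """Cumulative junctions discovered by date, one step curve per threshold.

    Rows are the distinct discovery dates (ascending); column ``ge_<r>``
    gives the cumulative count of junctions with ``total_reads >= r``
    discovered on or before that date.  Each curve is nondecreasing and its
    final value equals the number of junctions meeting the threshold; curves
    for higher thresholds lie pointwise at or below lower ones.
    """
    thresholds = sorted(read_thresholds)
    if list(read_thresholds) != thresholds:
        raise ValueError("read_thresholds must be ascending")
    dates = sorted({r.discovery_date for r in records})
    out = pd.DataFrame(index=pd.Index(dates, name="date"))
    for thr in thresholds:
        sub = sorted(
            r.discovery_date for r in records if r.total_reads >= thr
        )
        counts = np.searchsorted(sub, dates, side="right")
        out[f"ge_{thr}"] = counts
    return out


def fraction_discovered_by(
    records: Sequence[DiscoveryRecord], cutoff: _dt.date
) -> float:
    """Fraction of records with discovery date strictly before ``cutoff``."""
    if not records:
        return float("nan")
    n = sum(1 for r in records if r.discovery_date < cutoff)
    return n / len(records)


def top_contributing_dates(
    records: Sequence[DiscoveryRecord],
    t: JunctionTable,
    meta: Sequence[SampleMeta],
    k: int = 5,
) -> pd.DataFrame:
    """Dates ranked by number of junctions discovered, with dominant project.

    The dominant project on a date is the one contributing the most of that
    date's discovering samples — samples whose submission date realizes the
    minimum for at least one junction discovered that day.  Ties break
    lexicographically (and are reported in ``tied_projects``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    date_by_id = {m.sample_id: m.submission_date for m in meta}
    proj_by_id = {m.sample_id: m.project_id for m in meta}
    key_to_row = t.junction_index()
    indptr, indices = t.counts.indptr, t.counts.indices

    by_date: dict[_dt.date, list[DiscoveryRecord]] = {}
    for r in records:
        by_date.setdefault(r.discovery_date, []).append(r)

    rows = []
    for date, recs in by_date.items():
        contributing: dict[str, int] = {}
        for r in recs:
            i = key_to_row[r.junction.key]
            for col in indices[indptr[i] : indptr[i + 1]]:
                sid = t.sample_ids[col]
                if date_by_id.get(sid) == date:
                    p = proj_by_id.get(sid, "")
                    contributing[p] = contributing.get(p, 0) + 1
        best = max(contributing.values(), default=0)
        tied = sorted(p for p, n in contributing.items() if n == best)
        rows.append(
            {
                "date": date,
                "n_new_junctions": len(recs),
                "dominant_project": tied[0] if tied else "",
                "tied_projects": ",".join(tied),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["n_new_junctions", "date"], ascending=[False, True]
    )
    return df.head(k).reset_index(drop=True)


def release_first_appearance(
    records: Sequence[DiscoveryRecord],
    hist: ReleaseHistory,
    cutoff: _dt.date | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """First annotation release containing each confidently called junction.

    A junction is "documented" if it appears in at least one release; its
    first release is the earliest containing it.  Returns

    * per-junction table (junction key, first release or None, n_samples,
      discovery date),
    * per-first-release summary (junction count, median/mean n_samples,
      median discovery date),
    * overall summary: fraction of documented junctions first appearing in
      release 1, and — when ``cutoff`` is given — fractions of documented
      and of all confident junctions discovered before the cutoff.
    """
    if not len(hist):
        raise ValueError("release history is empty")
    release_keys = [(label, {j.key for j in js}) for label, _, js in hist.releases]
    per = []
    for r in records:
        first = next(
            (label for label, keys in release_keys if r.junction.key in keys), None
        )
        per.append(
            {
                "chrom": r.junction.chrom,
                "start": r.junction.start,
                "end": r.junction.end,
                "strand": r.junction.strand,
                "first_release": first,
                "n_samples": r.n_samples,
                "discovery_date": r.discovery_date,
            }
        )
    per_df = pd.DataFrame(per)
    documented = per_df[per_df["first_release"].notna()]
    summaries = []
    for label, _, _ in hist.releases:
        grp = documented[documented["first_release"] == label]
        summaries.append(
            {
                "release": label,
                "n_junctions": len(grp),
                "median_n_samples": float(grp["n_samples"].median())
                if len(grp)
                else float("nan"),
                "mean_n_samples": float(grp["n_samples"].mean())
                if len(grp)
                else float("nan"),
                "median_discovery_date": _median_date(grp["discovery_date"])
                if len(grp)
                else None,
            }
        )
    summary_df = pd.DataFrame(summaries)
    first_label = hist.releases[0][0]
    overall = {
        "n_confident": len(per_df),
        "n_documented": len(documented),
        "frac_first_release": (
            float((documented["first_release"] == first_label).mean())
            if len(documented)
            else float("nan")
        ),
    }
    if cutoff is not None:
        overall["frac_documented_discovered_by_cutoff"] = (
            float((documented["discovery_date"] < cutoff).mean())
            if len(documented)
            else float("nan")
        )
        overall["frac_confident_discovered_by_cutoff"] = (
            float((per_df["discovery_date"] < cutoff).mean())
            if len(per_df)
            else float("nan")
        )
    return per_df, summary_df, overall


def _median_date(s: pd.Series) -> _dt.date:
    ords = sorted(d.toordinal() for d in s)
    return _dt.date.fromordinal(int(np.median(ords)))
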