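"""Two-region junction inclusion ratio D and sample ranking.

Given two disjoint exon-group regions of one gene (the motivating case:
*ALK* exons 1-19 versus exons 20-29, the screen for the intron-19
alternative-transcription-initiation isoform ALK^ATI), each sample gets

* ``A`` — junction overlap count wholly inside region 1,
* ``B`` — junction overlap count wholly inside region 2,
* ``C`` — total overlap count across the gene span (straddling junctions,
  e.g. the one joining the last exon of region 1 to the first of region 2,
  contribute to C only, which is why C can exceed A + B),
* ``D = (B − A) / (A + B)`` — +1 when region 1 is silent relative to
  region 2, −1 for the reverse; undefined when A + B = 0.

Samples are ranked by descending D with competition ranking (ties share the
smallest rank; the next rank skips), so three tied leaders rank 1, 1, 1, 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Junction, JunctionTable

__all__ = ["RegionSpec", "RegionCounts", "assign_region", "region_ratio"]

Interval = tuple[int, int]  # 1-based inclusive


def _span(intervals: Sequence[Interval]) -> Interval:
    return (min(a for a, _ in intervals), max(b for _, b in intervals))


@dataclass
class RegionSpec:
    """Two disjoint interval groups of one gene, plus the containing span."""

    gene: str
    chrom: str
    region1: list[Interval]
    region2: list[Interval]
    gene_span: Interval | None = None
    strand: str | None = field(default=None)  # None = strand-agnostic

    def __post_init__(self) -> None:
        s1, s2 = _span(self.region1), _span(self.region2)
        if not (s1[1] < s2[0] or s2[1] < s1[0]):
            raise ValueError(f"{self.gene}: region spans overlap ({s1}, {s2})")
        if self.gene_span is None:
            self.gene_span = (min(s1[0], s2[0]), max(s1[1], s2[1]))
        g = self.gene_span
        if not (g[0] <= min(s1[0], s2[0]) and g[1] >= max(s1[1], s2[1])):
            raise ValueError(f"{self.gene}: regions extend beyond gene span")

    @property
    def span1(self) -> Interval:
        return _span(self.region1)

    @property
    def span2(self) -> Interval:
        return _span(self.region2)


def assign_region(j: Junction, spec: RegionSpec) -> str:
    """Place a junction: ``region1`` / ``region2`` / ``straddle_or_other`` /
    ``outside``.

    Membership in a region requires BOTH intron endpoints inside that
    region's span; a junction within the gene span but not wholly in either
    region (straddlers included) is ``straddle_or_other``.
    """
    if j.chrom != spec.chrom or (
        spec.strand is not None and j.strand != spec.strand
    ):
        return "outside"
    g = spec.gene_span
    if not (g[0] <= j.start and j.end <= g[1]):
        return "outside"
    a, b = spec.span1, spec.span2
    if a[0] <= j.start and j.end <= a[1]:
        return "region1"
    if b[0] <= j.start and j.end <= b[1]:
        return "region2"
    return "straddle_or_other"


@dataclass
class RegionCounts:
    sample_id: str
    A: int
    B: int
    C: int
    D: float | None  # None when A + B == 0

    @property
    def D_rounded(self) -> float | None:
        """Half-up display rounding to 3 decimals (full precision in ``D``)."""
        if self.D is None:
            return None
        return float(np.floor(abs(self.D) * 1000 + 0.5) / 1000 * np.sign(self.D))


def region_ratio(
    t: JunctionTable, spec: RegionSpec
) -> tuple[pd.DataFrame, list[RegionCounts]]:
    """Per-sample region counts and D, ranked by descending D.

    Returns a ranked DataFrame (samples with A + B > 0, competition ranks)
    and the list of samples where D is undefined (A + B = 0), kept separate
    rather than silently ranked.
    """
    if t.n_junctions == 0:
        raise ValueError("junction table is empty")
    assignment = np.array([assign_region(j, spec) for j in t.junctions])
    csc = t.counts.tocsc()

    def _sum(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.zeros(t.n_samples, dtype=np.int64)
        return np.asarray(csc[mask].sum(axis=0)).ravel()

    A = _sum(assignment == "region1")
    B = _sum(assignment == "region2")
    C = A + B + _sum(assignment == "straddle_or_other")

    ranked_rows, undefined = [], []
    for s, a, b, c in zip(t.sample_ids, A, B, C):
        a, b, c = int(a), int(b), int(c)
        if a + b == 0:
            undefined.append(RegionCounts(s, a, b, c, None))
            continue
        d = (b - a) / (a + b)
        rc = RegionCounts(s, a, b, c, d)
        ranked_rows.append(
            {"sample_id": s, "A": a, "B": b, "C": c, "D": d, "D_3dp": rc.D_rounded}
        )
    if not ranked_rows:
        import warnings

        warnings.warn(f"{spec.gene}: no sample has junction coverage in either region")
        return (
            pd.DataFrame(columns=["rank", "sample_id", "A", "B", "C", "D", "D_3dp"]),
            undefined,
        )
    df = pd.DataFrame(ranked_rows)
    df["rank"] = df["D"].rank(method="min", ascending=False).astype(int)
    df = df.sort_values(["rank", "sample_id"]).reset_index(drop=True)
    return df[["rank", "sample_id", "A", "B", "C", "D", "D_3dp"]], undefined
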