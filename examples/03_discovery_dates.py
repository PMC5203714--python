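"""Accumulation of confidently called junctions by discovery date.

A junction's discovery date is the earliest submission date among the
samples containing it; "confidently called" means at least 20 supporting
reads summed over the cohort.  Curves for stricter read thresholds flatten
earlier.
"""

import datetime as dt

from junctionscope import CohortConfig, generate_annotation, generate_cohort
from junctionscope.discovery import (
    accumulation_curve,
    discovery_dates,
    fraction_discovered_by,
    top_contributing_dates,
)

cfg = CohortConfig(seed=42)
ann = generate_annotation(cfg)
table, meta = generate_cohort(cfg, ann)

records = discovery_dates(table, meta, min_total_reads=20)
curve = accumulation_curve(records, [20, 40, 80, 160])
print("cumulative junctions discovered (rows = submission dates):")
print(curve.to_string())

mid = cfg.date_range[0] + (cfg.date_range[1] - cfg.date_range[0]) / 2
print(f"\nfraction discovered before {mid}: "
      f"{fraction_discovered_by(records, mid):.1%}")

top = top_contributing_dates(records, table, meta, k=3)
print("\ntop contributing dates (dominant project per date):")
print(top.to_string(index=False))
# Early, large submissions contribute the bulk of discoveries; later samples
# mostly re-observe known junctions.
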