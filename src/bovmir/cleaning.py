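"""Raw-read cleaning: adapter trimming, contaminant ledger, tag collapsing.

Each high-quality read is assigned to exactly one ledger category, checked
in a fixed priority order:

1. ``adaptor3_null``   — the 3' adapter (its first k bases) is absent;
2. ``insert_null``     — the adapter starts at position 0 (empty insert);
3. ``adaptor5_contaminants`` — the insert begins with the 3'-most bases of
   the 5' adapter (adapter-dimer style artefact);
4. ``small_than_18nt`` — insert shorter than the minimum length;
5. ``polyA``           — insert dominated by adenosines;
6. clean               — everything else, collapsed to unique tags.

The ledger identity
``clean_reads = high_quality - (sum of the five filters)`` holds exactly
for every input, and the collapsed tag counts sum to ``clean_reads``.
Quality strings are not interpreted: "high quality" is every parseable
read (no quality rule is modelled).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .config import PipelineConfig
from .util import normalize_seq, pct

LEDGER_FILTERS = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminants",
    "small_than_18nt",
    "polyA",
)


@dataclass
class CleaningSummary:
    """Per-library ledger of reads removed by each filter (one table column)."""

    total_read: int
    high_quality: int
    adaptor3_null: int
    insert_null: int
    adaptor5_contaminants: int
    small_than_18nt: int
    polyA: int

    @property
    def clean_reads(self) -> int:
        return self.high_quality - (
            self.adaptor3_null
            + self.insert_null
            + self.adaptor5_contaminants
            + self.small_than_18nt
            + self.polyA
        )

    def percent(self, field: str) -> float:
        """Share of high-quality reads, rounded to two decimals as printed."""
        return pct(getattr(self, field), self.high_quality)

    def validate(self) -> None:
        counts = [getattr(self, f) for f in LEDGER_FILTERS]
        if any(c < 0 for c in counts) or self.clean_reads < 0:
            raise ValueError("negative count in cleaning ledger")

    def to_series(self) -> pd.Series:
        rows = {"total_read": self.total_read, "high_quality": self.high_quality}
        for f in LEDGER_FILTERS:
            rows[f] = getattr(self, f)
        rows["clean_reads"] = self.clean_reads
        return pd.Series(rows, dtype="int64")


def clean_library(
    reads: Iterable[str],
    config: PipelineConfig | None = None,
    *,
    total_read: int | None = None,
) -> tuple[Counter, CleaningSummary]:
    """Clean one library of raw read sequences.

    Returns the collapsed clean tags (sequence -> read count, DNA alphabet)
    and the cleaning ledger.  ``total_read`` may exceed the number of
    parseable reads handed in (reads dropped upstream); it defaults to the
    high-quality count.
    """
    cfg = config or PipelineConfig()
    seed = normalize_seq(cfg.adapter3)[: cfg.adapter3_seed_len]
    if not seed:
        raise ValueError("empty 3' adapter")
    a5_tail = normalize_seq(cfg.adapter5)[-cfg.adapter5_tail_len :]
    if not a5_tail:
        raise ValueError("empty 5' adapter")

    tags: Counter = Counter()
    ledger = dict.fromkeys(LEDGER_FILTERS, 0)
    high_quality = 0
    for read in reads:
        high_quality += 1
        seq = normalize_seq(read)
        idx = seq.find(seed)
        if idx < 0:
            ledger["adaptor3_null"] += 1
            continue
        insert = seq[:idx]
        if not insert:
            ledger["insert_null"] += 1
            continue
        if insert.startswith(a5_tail):
            ledger["adaptor5_contaminants"] += 1
            continue
        if len(insert) < cfg.min_len:
            ledger["small_than_18nt"] += 1
            continue
        if insert.count("A") / len(insert) >= cfg.polya_fraction:
            ledger["polyA"] += 1
            continue
        tags[insert] += 1

    summary = CleaningSummary(
        total_read=high_quality if total_read is None else total_read,
        high_quality=high_quality,
        **ledger,
    )
    assert sum(tags.values()) == summary.clean_reads
    return tags, summary


def merge_tag_counts(per_library: Mapping[str, Counter]) -> pd.DataFrame:
    """Unique tag x library count matrix (the pipeline's atom set)."""
    df = pd.DataFrame(per_library).fillna(0).astype("int64")
    df.index.name = "tag"
    return df.sort_index()


def summaries_to_table(per_library: Mapping[str, CleaningSummary]) -> pd.DataFrame:
    """Ledger table in the standard column order, with percentage columns."""
    cols = {}
    for lib, summary in per_library.items():
        series = summary.to_series()
        cols[f"{lib}_count"] = series
        pct_rows = {name: summary.percent(name) for name in series.index if name != "total_read"}
        cols[f"{lib}_pct"] = pd.Series(pct_rows)
    return pd.DataFrame(cols)


def length_distribution(tag_counts: Mapping[str, int] | pd.DataFrame) -> pd.DataFrame:
    """Read-weighted insert length histogram (count and fraction per length)."""
    if isinstance(tag_counts, pd.DataFrame):
        weights = tag_counts.sum(axis=1)
    else:
        weights = pd.Series(tag_counts)
    if weights.empty or weights.sum() == 0:
        raise ValueError("empty tag set")
    lengths = weights.index.map(len)
    counts = weights.groupby(lengths).sum()
    counts = counts.reindex(range(counts.index.min(), counts.index.max() + 1), fill_value=0)
    out = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    out.index.name = "length"
    return out
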