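"""Perfect-match genome mapping of clean tags and RNA-category annotation.

Mapping is exact and exhaustive over both strands (a k-mer prefix index
with full-length verification), mirroring a perfect-match short-read
aligner.  Annotation assigns every genome-matched tag to exactly one RNA
category using a fixed priority order, so the category table is an exact
partition of the genome-matched tags.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .config import DEFAULT_PRIORITY, PipelineConfig
from .util import pct, revcomp


@dataclass(frozen=True)
class GenomeHit:
    tag: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    klass: str  # e.g. miRNA, rRNA, tRNA, exon, intron, repeat, ...
    strand: str
    start: int  # 1-based inclusive
    end: int


class GenomeIndex:
    """Exact-match index: k-mer prefix lookup + full verification."""

    def __init__(self, genome: Mapping[str, str], k: int = 18):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.lengths = {name: len(seq) for name, seq in self.genome.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((name, i))
        self._index = index

    def query(self, tag: str) -> list[GenomeHit]:
        """All perfect full-length hits of `tag` on either strand."""
        if len(tag) < self.k:
            return []
        hits = []
        for strand in "+-":
            s = tag if strand == "+" else revcomp(tag)
            for chrom, i in self._index.get(s[: self.k], ()):
                if self.genome[chrom][i : i + len(s)] == s:
                    hits.append(GenomeHit(tag, chrom, strand, i + 1, i + len(s)))
        return hits


def map_tags(
    tags: Iterable[str], index: GenomeIndex
) -> tuple[dict[str, list[GenomeHit]], set[str]]:
    """Map tags exactly; returns (hits per matched tag, unmatched tag set)."""
    hits: dict[str, list[GenomeHit]] = {}
    unmatched: set[str] = set()
    for tag in tags:
        h = index.query(tag)
        if h:
            hits[tag] = h
        else:
            unmatched.add(tag)
    return hits, unmatched


def _category_of(hit: GenomeHit, locus: Locus) -> str:
    if locus.klass in ("exon", "intron"):
        orientation = "sense" if locus.strand == hit.strand else "antisense"
        return f"{locus.klass}_{orientation}"
    return locus.klass


def build_locus_trees(loci: Sequence[Locus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        trees.setdefault(locus.chrom, IntervalTree())[locus.start : locus.end + 1] = locus
    return trees


def annotate_tags(
    tag_hits: Mapping[str, Sequence[GenomeHit]],
    loci: Sequence[Locus],
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Assign each genome-matched tag one category by the fixed priority.

    A tag hitting several annotated loci (across all of its genome hits)
    takes the highest-priority category; tags hitting no locus are
    'unknown'.  A >=1 bp overlap places a hit inside a locus.
    """
    cfg = config or PipelineConfig()
    priority = {name: rank for rank, name in enumerate(cfg.annotation_priority)}
    known = set(priority)
    trees = build_locus_trees(loci)
    for locus in loci:
        probe = _category_of(GenomeHit("", locus.chrom, "+", 1, 1), locus)
        if probe not in known and _category_of(
            GenomeHit("", locus.chrom, "-", 1, 1), locus
        ) not in known:
            raise ValueError(f"unknown locus class {locus.klass!r}")

    assignment: dict[str, str] = {}
    for tag, hits in tag_hits.items():
        best = "unknown"
        best_rank = priority["unknown"]
        for hit in hits:
            tree = trees.get(hit.chrom)
            if tree is None:
                continue
            for interval in tree.overlap(hit.start, hit.end + 1):
                category = _category_of(hit, interval.data)
                rank = priority.get(category)
                if rank is not None and rank < best_rank:
                    best, best_rank = category, rank
        assignment[tag] = best
    return assignment


def category_summary(
    assignment: Mapping[str, str],
    tag_counts: pd.DataFrame,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Category x library table of unique-tag and read counts.

    Rows partition the genome-matched tags exactly: per library, unique and
    read counts sum to the genome-matched totals.
    """
    matched = tag_counts.loc[tag_counts.index.intersection(list(assignment))]
    cats = pd.Series({t: assignment[t] for t in matched.index}, name="category")
    out = {}
    for lib in matched.columns:
        counts = matched[lib]
        present = counts > 0
        out[f"{lib}_unique"] = (
            cats[present].groupby(cats[present]).size().reindex(priority, fill_value=0)
        )
        out[f"{lib}_reads"] = counts.groupby(cats).sum().reindex(priority, fill_value=0)
    df = pd.DataFrame(out).astype("int64")
    df.index.name = "category"
    return df


def category_percentages(df: pd.DataFrame, totals: Mapping[str, int]) -> pd.DataFrame:
    """Percentages of given totals (e.g. clean-read totals), 2 decimals."""
    out = df.copy().astype("float64")
    for col in df.columns:
        lib = col.rsplit("_", 1)[0]
        out[col] = df[col].map(lambda v: pct(v, totals[col] if col in totals else totals[lib]))
    return out
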