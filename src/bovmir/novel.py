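"""Novel miRNA discovery from unannotated genome-matched tags.

The screen follows the classical hairpin-precursor criteria: extract the
genomic window around each candidate tag cluster (150 nt each side), fold
it, trim to the minimal stem-loop containing the mature candidate and its
star region, and require that

(a) the mature candidate sits wholly within one arm of a single stem-loop
    (no overlap with the terminal loop, no break);
(b) the precursor folds with MFE below -20 kcal/mol;
(c) the minimal folding energy index (MFEI) exceeds 0.85;
(d) the precursor AU content lies in 30-70%;
(e) the mature has fewer than six mismatches (unpaired bases) against the
    star region in the opposite arm;
(f) the mature candidate is 20-22 nt long.

Tags with more than ten perfect genome hits are removed before
evaluation.  Candidates whose star sequence is itself observed in the tag
data are flagged high-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .folding import compute_mfei, fold_rna, pair_table
from .mapping import GenomeHit, GenomeIndex, map_tags
from .util import au_fraction, revcomp

CRITERIA = ("hairpin_arm", "mfe", "mfei", "au_content", "star_mismatches", "mature_length")


@dataclass
class HairpinCandidate:
    chrom: str
    strand: str
    start: int  # 1-based inclusive precursor coords on the genome
    end: int
    precursor: str
    structure: str
    mfe: float
    amfe: float
    mfei: float
    au_content: float
    mature: str
    mature_span: tuple[int, int]  # 0-based [start, end) within the precursor
    arm: str  # '5p' / '3p' / 'loop'
    star_span: tuple[int, int] | None
    star_mismatches: int
    star_observed: bool = False
    criteria: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.get(name, False) for name in CRITERIA)

    @property
    def confidence(self) -> str:
        return "high" if self.passed and self.star_observed else "candidate"


@dataclass
class NovelMiRNA:
    novel_id: str
    mature: str
    candidate: HairpinCandidate
    counts: dict  # library -> reads
    loci: list  # (chrom, strand, start, end) of the mature tag

    @property
    def high_confidence(self) -> bool:
        return self.candidate.star_observed


@dataclass
class DiscoveryResult:
    novel: list
    candidates: list  # every evaluated HairpinCandidate
    per_library: dict  # library -> set of novel ids
    overlap: set


def extract_flanks(
    hit: GenomeHit, genome: Mapping[str, str], flank: int | tuple[int, int] = 150
) -> tuple[str, int]:
    """Strand-oriented window of up to `flank` nt each side of the hit.

    `flank` may be a single width or an (upstream, downstream) pair in the
    tag's own 5'->3' orientation.  Returns (window sequence, 0-based offset
    of the tag within the window).  Windows are clipped at chromosome
    ends; minus-strand windows are reverse-complemented so the tag reads
    5'->3' inside them.
    """
    left, right = (flank, flank) if isinstance(flank, int) else flank
    if hit.strand == "-":  # oriented-upstream is genomic-downstream
        left, right = right, left
    seq = genome[hit.chrom]
    if not (1 <= hit.start <= hit.end <= len(seq)):
        raise ValueError("hit outside genome bounds")
    lo = max(0, hit.start - 1 - left)
    hi = min(len(seq), hit.end + right)
    window = seq[lo:hi].upper()
    offset = hit.start - 1 - lo
    if hit.strand == "-":
        window = revcomp(window)
        offset = len(window) - (offset + (hit.end - hit.start + 1))
    return window, offset


def _hairpin_loops(table: Sequence[int]) -> list[tuple[int, int]]:
    """Innermost pairs (i, j): pairs enclosing no other pair."""
    loops = []
    for i, j in ((i, j) for i, j in enumerate(table) if j > i):
        if all(table[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def trim_to_hairpin(
    window: str, structure: str, mature_span: tuple[int, int]
) -> tuple[int, int] | None:
    """Minimal [lo, hi] window slice containing mature and star sites.

    The star region is taken from the *majority* side of the mature's
    pairing partners (in wide windows a few mature bases often pair into
    the flank on the other side; following every partner would drag the
    wrong arm into the precursor).  The chosen side is extended by the
    number of unpaired/minority mature bases plus a small pad, so the
    refold of the slice can recruit the full star.  None when the mature
    pairs with nothing.
    """
    spans = candidate_spans(window, structure, mature_span)
    return spans[0] if spans else None


def candidate_spans(
    window: str, structure: str, mature_span: tuple[int, int]
) -> list[tuple[int, int]]:
    """Candidate precursor spans ordered by partner support.

    One span per partner side (majority first), plus the combined
    min-to-max span when the partners straddle the mature.
    """
    table = pair_table(structure)
    m_start, m_end = mature_span
    n = len(window)
    pairs = [(i, table[i]) for i in range(m_start, m_end) if table[i] != -1]
    partners = [p for _, p in pairs]
    up = [p for p in partners if p < m_start]
    down = [p for p in partners if p >= m_end]

    # contiguous duplex runs: consecutive mature positions whose partners
    # step along with them (small bulges tolerated)
    runs: list[list[int]] = []
    for i, p in pairs:
        if runs and i - runs[-1][-2] <= 2 and 0 < runs[-1][-1] - p <= 4:
            runs[-1].extend((i, p))
        else:
            runs.append([i, p])
    run_sides = []
    for run in runs:
        ps = run[1::2]
        # ignore incidental short contacts and mature self-pairing
        if len(ps) >= 4 and (ps[0] < m_start or ps[0] >= m_end):
            run_sides.append(ps)
    run_sides.sort(key=len, reverse=True)

    def side_span(side: list[int]) -> tuple[int, int]:
        s_lo, s_hi = min(side), max(side)
        pad = (m_end - m_start) - len(side) + 4
        if s_lo >= m_end:  # star downstream of the mature
            s_lo = max(m_end, s_lo - pad)
            s_hi = min(n - 1, s_hi + pad)
        else:
            s_lo = max(0, s_lo - pad)
            s_hi = min(m_start - 1, s_hi + pad)
        return (min(m_start, s_lo), max(m_end - 1, s_hi))

    spans: list[tuple[int, int]] = []
    for side in run_sides[:2]:
        span = side_span(side)
        if span not in spans:
            spans.append(span)
    for side in sorted((s for s in (up, down) if s), key=len, reverse=True):
        span = side_span(side)
        if span not in spans:
            spans.append(span)
    if up and down:
        span = (min(m_start, min(partners)), max(m_end - 1, max(partners)))
        if span not in spans:
            spans.append(span)
    return spans


def evaluate_candidate(
    precursor: str,
    structure: str,
    mfe: float,
    mature_span: tuple[int, int],
    config: PipelineConfig | None = None,
) -> HairpinCandidate:
    """Apply the screening criteria to a folded precursor.

    `mature_span` is the 0-based half-open span of the mature candidate
    within the precursor.  Genomic coordinates are filled by the caller.
    """
    cfg = config or PipelineConfig()
    if len(precursor) != len(structure):
        raise ValueError("structure/sequence length mismatch")
    m_start, m_end = mature_span
    if not (0 <= m_start < m_end <= len(precursor)):
        raise ValueError("mature span outside precursor")
    table = pair_table(structure)
    loops = _hairpin_loops(table)
    partners = [table[i] for i in range(m_start, m_end) if table[i] != -1]

    # the mature must sit wholly within one arm of the stem-loop that
    # separates it from its star: some terminal loop lies strictly between
    # the mature (loop-free, break-free) and all of its pairing partners
    arm = "loop"
    for li, lj in loops:
        if m_end - 1 <= li and partners and all(p >= lj for p in partners):
            arm = "5p"
            break
        if m_start >= lj and partners and all(p <= li for p in partners):
            arm = "3p"
            break
    in_one_arm = arm in ("5p", "3p")
    star_span = (min(partners), max(partners)) if partners else None
    # mature/star mismatches: one per unpaired base on either side of the
    # duplex (a substitution leaves one unpaired base on each side and
    # counts once; a bulge counts one per bulged base)
    paired = len(partners)
    unpaired_mature = (m_end - m_start) - paired
    if star_span is not None:
        unpaired_star = (star_span[1] - star_span[0] + 1) - paired
    else:
        unpaired_star = m_end - m_start
    mismatches = max(unpaired_mature, unpaired_star)

    if mfe <= 0 and ("G" in precursor or "C" in precursor):
        amfe, mfei = compute_mfei(mfe, precursor)
    else:  # GC-free precursor: MFEI undefined, treated as failing the screen
        amfe, mfei = ((-mfe / len(precursor)) * 100.0 if mfe < 0 else 0.0), 0.0
    au = au_fraction(precursor)
    lo_len, hi_len = cfg.mature_len_range
    criteria = {
        "hairpin_arm": in_one_arm,
        "mfe": mfe < cfg.mfe_max,
        "mfei": mfei > cfg.mfei_min,
        "au_content": cfg.au_range[0] <= au <= cfg.au_range[1],
        "star_mismatches": mismatches <= cfg.max_star_mismatches,
        "mature_length": lo_len <= (m_end - m_start) <= hi_len,
    }
    return HairpinCandidate(
        chrom="",
        strand="+",
        start=0,
        end=0,
        precursor=precursor,
        structure=structure,
        mfe=mfe,
        amfe=amfe,
        mfei=mfei,
        au_content=au,
        mature=precursor[m_start:m_end],
        mature_span=mature_span,
        arm=arm,
        star_span=star_span,
        star_mismatches=mismatches,
        criteria=criteria,
    )


def evaluate_window(
    window: str,
    tag_offset: int,
    tag_len: int,
    config: PipelineConfig | None = None,
) -> HairpinCandidate | None:
    """Fold a flanked window, trim to the stem-loop, refold and evaluate.

    The mature's pairing partners in the wide window propose one or more
    precursor spans (each partner side, then both combined); each span is
    refolded and re-trimmed until stable and evaluated against the
    criteria.  The first passing candidate wins; otherwise the
    best-supported one is reported.  Returns None when the candidate tag
    pairs with nothing in the folded window.
    """
    structure0, _ = fold_rna(window)
    spans = candidate_spans(window, structure0, (tag_offset, tag_offset + tag_len))
    fallback = None
    for start_span in spans:
        lo, hi = start_span
        precursor = window[lo : hi + 1]
        offset = tag_offset - lo
        structure, mfe = fold_rna(precursor)
        for _ in range(4):
            span = trim_to_hairpin(precursor, structure, (offset, offset + tag_len))
            if span is None:
                break
            new_lo, new_hi = lo + span[0], lo + span[1]
            if (new_lo, new_hi) == (lo, hi):
                break
            lo, hi = new_lo, new_hi
            precursor = window[lo : hi + 1]
            offset = tag_offset - lo
            structure, mfe = fold_rna(precursor)
        if not (0 <= offset and offset + tag_len <= len(precursor)):
            continue
        candidate = evaluate_candidate(
            precursor, structure, mfe, (offset, offset + tag_len), config
        )
        candidate.start = lo  # window-relative; caller converts to genome coords
        candidate.end = hi
        if candidate.passed:
            return candidate
        if fallback is None:
            fallback = candidate
    return fallback


def _clusters(
    hits_by_tag: Mapping[str, Sequence[GenomeHit]], gap: int
) -> list[list[GenomeHit]]:
    """Group hits into clusters of overlapping / near-adjacent intervals."""
    flat = [h for hits in hits_by_tag.values() for h in hits]
    flat.sort(key=lambda h: (h.chrom, h.strand, h.start, h.end))
    clusters: list[list[GenomeHit]] = []
    for hit in flat:
        if (
            clusters
            and clusters[-1][-1].chrom == hit.chrom
            and clusters[-1][-1].strand == hit.strand
            and hit.start <= max(h.end for h in clusters[-1]) + gap
        ):
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    return clusters


def discover_novel(
    leftover: pd.DataFrame,
    index: GenomeIndex,
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> DiscoveryResult:
    """Run the full novel-miRNA screen on unannotated tags.

    `leftover` is the tag x library count matrix of tags that matched
    neither known miRNAs nor any other annotated RNA class.
    """
    cfg = config or PipelineConfig()
    libraries = list(leftover.columns)
    totals = leftover.sum(axis=1)

    hits_by_tag, _ = map_tags(leftover.index, index)
    hits_by_tag = {
        tag: hits
        for tag, hits in hits_by_tag.items()
        if len(hits) <= cfg.max_genome_hits
    }

    candidates: list[HairpinCandidate] = []
    accepted: dict[str, NovelMiRNA] = {}  # mature tag -> record
    for cluster in _clusters(hits_by_tag, cfg.cluster_gap):
        tags = sorted({h.tag for h in cluster})
        cluster_reads = int(sum(totals[t] for t in tags))
        if cluster_reads < cfg.min_cluster_reads:
            continue
        mature_tag = max(tags, key=lambda t: (totals[t], t))
        hit = next(h for h in cluster if h.tag == mature_tag)
        # widest window first; genuine precursors are short and extend
        # mostly to one side of the mature, so when the wide fold buries
        # the mature in flank pairings, rescan narrower and asymmetric
        # pre-miRNA-scale windows
        candidate = None
        g_flank: tuple[int, int] = (cfg.flank, cfg.flank)
        ladder = [(cfg.flank, cfg.flank), (100, 100), (60, 60), (10, 45), (45, 10)]
        for flank in ladder:
            if max(flank) > cfg.flank:
                continue
            window, offset = extract_flanks(hit, genome, flank)
            trial = evaluate_window(window, offset, len(mature_tag), cfg)
            if trial is not None and (candidate is None or trial.passed):
                candidate = trial
                g_flank = flank
            if candidate is not None and candidate.passed:
                break
        if candidate is None:
            continue
        window, offset = extract_flanks(hit, genome, g_flank)
        # window-relative precursor span -> genome coordinates
        w_lo = candidate.start
        w_hi = candidate.end
        win_len = len(window)
        genomic_left = g_flank[0] if hit.strand == "+" else g_flank[1]
        g_lo = max(0, hit.start - 1 - genomic_left)
        if hit.strand == "+":
            candidate.start = g_lo + w_lo + 1
            candidate.end = g_lo + w_hi + 1
        else:
            candidate.start = g_lo + (win_len - 1 - w_hi) + 1
            candidate.end = g_lo + (win_len - 1 - w_lo) + 1
        candidate.chrom = hit.chrom
        candidate.strand = hit.strand

        if candidate.star_span is not None:
            s_lo, s_hi = candidate.star_span
            star_lo_w = w_lo + s_lo
            star_hi_w = w_lo + s_hi
            star_len = s_hi - s_lo + 1
            observed = False
            for other in tags:
                if other == mature_tag:
                    continue
                for h in hits_by_tag[other]:
                    if h.chrom != hit.chrom or h.strand != hit.strand:
                        continue
                    if hit.strand == "+":
                        o_lo = h.start - 1 - g_lo
                        o_hi = h.end - 1 - g_lo
                    else:
                        o_hi = win_len - 1 - (h.start - 1 - g_lo)
                        o_lo = win_len - 1 - (h.end - 1 - g_lo)
                    overlap = min(o_hi, star_hi_w) - max(o_lo, star_lo_w) + 1
                    if overlap >= min(16, star_len):
                        observed = True
                        break
                if observed:
                    break
            candidate.star_observed = observed
        candidates.append(candidate)
        if not candidate.passed:
            continue
        locus = (hit.chrom, hit.strand, hit.start, hit.end)
        if mature_tag in accepted:
            accepted[mature_tag].loci.append(locus)
            if candidate.star_observed:
                accepted[mature_tag].candidate.star_observed = True
        else:
            accepted[mature_tag] = NovelMiRNA(
                novel_id="",
                mature=mature_tag,
                candidate=candidate,
                counts={lib: int(leftover.loc[mature_tag, lib]) for lib in libraries},
                loci=[locus],
            )

    novel = sorted(
        accepted.values(),
        key=lambda n: (n.candidate.chrom, n.candidate.start, n.mature),
    )
    for i, record in enumerate(novel, start=1):
        record.novel_id = f"miRn{i}"
    per_library = {
        lib: {n.novel_id for n in novel if n.counts.get(lib, 0) > 0} for lib in libraries
    }
    overlap = set.intersection(*per_library.values()) if per_library else set()
    return DiscoveryResult(novel, candidates, per_library, overlap)


def novel_table(result: DiscoveryResult, libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for n in result.novel:
        c = n.candidate
        row = {
            "novel_id": n.novel_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "mature": n.mature,
            "precursor": c.precursor,
            "structure": c.structure,
            "mfe": round(c.mfe, 2),
            "amfe": round(c.amfe, 2),
            "mfei": round(c.mfei, 3),
            "au_content": round(c.au_content, 3),
            "star_mismatches": c.star_mismatches,
            "confidence": c.confidence,
            "n_loci": len(n.loci),
        }
        for lib in libraries:
            row[f"{lib}_reads"] = n.counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)
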