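"""Synthetic small-RNA world with planted ground truth.

The generator builds a toy study that mirrors a two-library (fetal vs
adult muscle) small-RNA sequencing experiment: a random genome carrying
planted known and novel miRNA hairpins plus loci of the other annotated
RNA classes; miRBase-style mature/hairpin references and a family file for
the known set; raw reads with 3' adapters, contaminant classes, isomiRs,
single-base edits, untemplated 3' A/U additions and planted between-library
fold changes; and a triplicate qPCR Ct table.  Every read traces to
exactly one provenance label, and every planted novel hairpin passes the
discovery criteria when re-evaluated in isolation (verified at
construction time).

Coordinates in the ground truth are 1-based inclusive with explicit
strand.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig, SimulationConfig
from .mapping import Locus
from .novel import evaluate_window
from .util import revcomp

CHROM = "chr1"
BASES = np.array(list("ACGT"))

#: Typical fragment-source lengths for the non-miRNA locus classes.
CLASS_LOCUS_LENGTH = {
    "rRNA": 120,
    "tRNA": 75,
    "snRNA": 100,
    "snoRNA": 100,
    "scRNA": 100,
    "srpRNA": 300,
    "repeat": 200,
    "exon": 150,
    "intron": 150,
}

MIRNA_LENGTH_WEIGHTS = {20: 0.08, 21: 0.17, 22: 0.75}

#: Read-abundance preference by mature length: 22-nt species dominate real
#: muscle libraries, so shorter matures are planted at lower expression.
LENGTH_ABUNDANCE_FACTOR = {20: 0.25, 21: 0.4, 22: 1.0, 23: 0.6}


@dataclass
class PlantedMiRNA:
    mirna_id: str  # reference id of the mature arm
    star_id: str | None  # reference id of the star arm (None: unnamed)
    precursor_id: str
    mature: str
    star: str
    arm: str  # arm carrying the mature: '5p' or '3p'
    known: bool
    locus: Locus  # precursor span on the genome
    mature_offset: int  # 0-based offset of the mature within the precursor
    star_offset: int
    precursor: str
    family: str | None = None


@dataclass
class GroundTruth:
    loci: list = field(default_factory=list)
    mirnas: list = field(default_factory=list)
    fold_changes: dict = field(default_factory=dict)  # precursor_id -> fetal/adult
    provenance: dict = field(default_factory=dict)  # library -> Counter(label)
    true_counts: dict = field(default_factory=dict)  # library -> Counter(arm id)
    true_exact_counts: dict = field(default_factory=dict)

    @property
    def known(self) -> list:
        return [m for m in self.mirnas if m.known]

    @property
    def novel(self) -> list:
        return [m for m in self.mirnas if not m.known]

    def mature_fasta(self) -> dict[str, str]:
        out = {}
        for m in self.known:
            out[m.mirna_id] = m.mature
            if m.star_id:
                out[m.star_id] = m.star
        return out

    def hairpin_fasta(self) -> dict[str, str]:
        return {m.precursor_id: m.precursor for m in self.known}

    def family_map(self) -> dict[str, str]:
        return {m.precursor_id: m.family for m in self.known if m.family}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _random_mature(rng: np.random.Generator, config: SimulationConfig) -> str:
    lengths = sorted(MIRNA_LENGTH_WEIGHTS)
    weights = np.array([MIRNA_LENGTH_WEIGHTS[l] for l in lengths])
    seed = config.adapter3[:8].upper()
    a5_tail = config.adapter5[-6:].upper()
    while True:
        length = int(rng.choice(lengths, p=weights / weights.sum()))
        seq = _random_seq(rng, length, gc=0.5)
        gc = (seq.count("G") + seq.count("C")) / length
        if not 0.38 <= gc <= 0.62:
            continue
        if seed in seq or seq.startswith(a5_tail):
            continue
        if seq.count("A") / length >= 0.7:
            continue
        return seq


def build_hairpin(
    rng: np.random.Generator,
    mature: str,
    star_mismatches: int = 0,
    loop_len: int = 12,
    arm: str | None = None,
) -> tuple[str, str, str, int, int]:
    """Construct a precursor: mature + loop + near-reverse-complement star.

    Returns (precursor, star, arm, mature_offset, star_offset).  Raises for
    matures outside 20-23 nt or star mismatch requests of six or more
    (such a construct would violate the screening criteria by design).
    """
    if not 20 <= len(mature) <= 23:
        raise ValueError("mature must be 20-23 nt")
    if star_mismatches > 5:
        raise ValueError("star may differ from the mature's complement by at most 5 bases")
    star = list(revcomp(mature))
    if star_mismatches:
        positions = rng.choice(
            np.arange(2, len(star) - 2), size=star_mismatches, replace=False
        )
        for pos in positions:
            choices = [b for b in "ACGT" if b != star[pos]]
            star[pos] = choices[int(rng.integers(len(choices)))]
    star_seq = "".join(star)
    # A/C loop: those bases cannot pair with each other, keeping the loop open
    loop = "".join(rng.choice(np.array(list("AC")), size=loop_len, p=[0.6, 0.4]))
    if arm is None:
        arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + star_seq
        m_off, s_off = 0, len(mature) + loop_len
    else:
        precursor = star_seq + loop + mature
        m_off, s_off = len(star_seq) + loop_len, 0
    return precursor, star_seq, arm, m_off, s_off


def _compliant_hairpin(
    rng: np.random.Generator,
    config: SimulationConfig,
    star_mismatches: int,
    max_tries: int = 50,
) -> tuple[str, str, str, str, int, int]:
    """Draw hairpins until one passes the full discovery screen in isolation."""
    pipe = PipelineConfig()
    for _ in range(max_tries):
        mature = _random_mature(rng, config)
        precursor, star, arm, m_off, s_off = build_hairpin(rng, mature, star_mismatches)
        candidate = evaluate_window(precursor, m_off, len(mature), pipe)
        if candidate is not None and candidate.passed:
            return mature, precursor, star, arm, m_off, s_off
    raise RuntimeError("failed to construct a criteria-compliant hairpin")


def _place(
    rng: np.random.Generator, used: list[tuple[int, int]], span: int, genome_len: int,
    margin: int = 200, spacing: int = 400,
) -> int:
    """Random non-overlapping 0-based start with clearance around neighbours."""
    for _ in range(2000):
        start = int(rng.integers(margin, genome_len - span - margin))
        if all(start + span + spacing < lo or start > hi + spacing for lo, hi in used):
            used.append((start, start + span - 1))
            return start
    raise RuntimeError("genome too small for the requested loci")


def _default_fold_changes(n_known: int) -> dict[str, float]:
    folds = {}
    for k in range(1, n_known + 1):
        if k <= min(10, n_known // 3):
            folds[f"bta-mir-s{k}"] = 4.0
        elif k <= min(20, 2 * n_known // 3):
            folds[f"bta-mir-s{k}"] = 0.25
        else:
            folds[f"bta-mir-s{k}"] = 1.0
    return folds


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GroundTruth]:
    """Random genome with planted hairpins and annotated loci."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genome = list(_random_seq(rng, config.genome_length, config.gc_content))
    gt = GroundTruth()
    used: list[tuple[int, int]] = []

    def plant(precursor: str, strand: str) -> tuple[int, int]:
        start = _place(rng, used, len(precursor), config.genome_length)
        inserted = precursor if strand == "+" else revcomp(precursor)
        genome[start : start + len(precursor)] = list(inserted)
        return start + 1, start + len(precursor)  # 1-based inclusive

    # known miRNA hairpins (annotated as class miRNA)
    for k in range(1, config.n_known_mirna + 1):
        mismatches = int(rng.integers(0, 4))  # 0-3 by default
        mature, precursor, star, arm, m_off, s_off = _compliant_hairpin(
            rng, config, mismatches
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = plant(precursor, strand)
        pid = f"bta-mir-s{k}"
        if k % 7 == 0:
            mid = f"bta-miR-s{k}-{arm}"
            star_id = f"bta-miR-s{k}-{'3p' if arm == '5p' else '5p'}"
        elif k % 3 == 0:
            mid, star_id = f"bta-miR-s{k}", f"bta-miR-s{k}*"
        else:
            mid, star_id = f"bta-miR-s{k}", None
        locus = Locus(pid, CHROM, "miRNA", strand, start, end)
        gt.loci.append(locus)
        gt.mirnas.append(
            PlantedMiRNA(mid, star_id, pid, mature, star, arm, True, locus, m_off, s_off, precursor)
        )

    # novel miRNA hairpins (present in the genome, absent from annotation
    # and references)
    for k in range(1, config.n_novel_mirna + 1):
        mismatches = int(rng.integers(0, 4))
        mature, precursor, star, arm, m_off, s_off = _compliant_hairpin(
            rng, config, mismatches
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = plant(precursor, strand)
        pid = f"novel-s{k}"
        locus = Locus(pid, CHROM, "novel_mirna", strand, start, end)
        gt.loci.append(locus)
        gt.mirnas.append(
            PlantedMiRNA(
                f"novel-miR-s{k}", None, pid, mature, star, arm, False, locus, m_off, s_off, precursor
            )
        )

    # other annotated locus classes
    for klass, length in CLASS_LOCUS_LENGTH.items():
        for j in range(1, config.n_other_loci_per_class + 1):
            strand = "+" if rng.random() < 0.5 else "-"
            start = _place(rng, used, length, config.genome_length)
            gt.loci.append(
                Locus(f"{klass}-{j}", CHROM, klass, strand, start + 1, start + length)
            )

    # family plan: six small families over the first known precursors,
    # a tail of singletons, and a few precursors left unassigned
    known = gt.known
    cursor = 0
    for fam_idx in range(1, 7):
        size = 2 + (fam_idx % 3)
        for m in known[cursor : cursor + size]:
            m.family = f"mir-fam{fam_idx}"
        cursor += size
    for m in known[cursor:-3]:
        m.family = f"mir-{m.precursor_id.rsplit('s', 1)[-1]}"

    folds = (
        dict(config.planted_fold_changes)
        if config.planted_fold_changes is not None
        else _default_fold_changes(config.n_known_mirna)
    )
    for m in gt.novel:
        folds.setdefault(m.precursor_id, 1.0)
    gt.fold_changes = folds
    return {CHROM: "".join(genome)}, gt


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, bool]:
    if rate <= 0:
        return seq, False
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq, False
    chars = list(seq)
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars), True


def _isomir(rng: np.random.Generator, m: PlantedMiRNA) -> str:
    """Shift one mature end by 1-2 nt, 3'-biased, templated on the precursor."""
    start, end = m.mature_offset, m.mature_offset + len(m.mature)
    deltas = [-2, -1, 1, 2]
    for _ in range(8):
        delta = deltas[int(rng.integers(4))]
        if rng.random() < 0.9:  # 3' end
            new_start, new_end = start, end + delta
        else:
            new_start, new_end = start - delta, end
        if 0 <= new_start < new_end <= len(m.precursor) and new_end - new_start >= 18:
            return m.precursor[new_start:new_end]
    return m.mature


def _edit(rng: np.random.Generator, seq: str) -> str:
    if rng.random() < 0.3:  # untemplated 3' addition
        return seq + ("A" if rng.random() < 0.5 else "T")
    pos = int(rng.integers(len(seq)))
    choices = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + choices[int(rng.integers(3))] + seq[pos + 1 :]


@dataclass
class SimulatedReads:
    reads: dict  # library -> list of raw read sequences
    libraries: tuple = ("fetal", "adult")

    def write_fastq(self, paths: Mapping[str, str]) -> None:
        from .io import write_fastq

        for lib, path in paths.items():
            write_fastq(self.reads[lib], path)


def _arm_sources(gt: GroundTruth, config: SimulationConfig, rng: np.random.Generator):
    """Relative adult-library read weight per expressed arm."""
    sources = []
    known = gt.known
    rel = rng.lognormal(mean=0.0, sigma=1.2, size=len(known))
    rel *= np.array([LENGTH_ABUNDANCE_FACTOR.get(len(m.mature), 0.3) for m in known])
    rel /= rel.sum()
    star_factors = {}
    if len(known) >= 3:
        star_factors[known[2].precursor_id] = 1.5  # a star-dominant precursor
    if len(known) >= 6:
        star_factors[known[5].precursor_id] = 0.9  # a near-equal precursor
    weights = []
    for m, w in zip(known, rel):
        weights.append((m, "mature", w))
        if m.star_id is not None:
            weights.append((m, "star", w * star_factors.get(m.precursor_id, config.star_fraction)))
    z = sum(w for _, _, w in weights)
    for m, which, w in weights:
        sources.append((m, which, config.mirna_share * w / z))

    novel = gt.novel
    if novel:
        rel_n = rng.lognormal(mean=0.0, sigma=0.8, size=len(novel))
        rel_n /= rel_n.sum()
        weights_n = []
        for m, w in zip(novel, rel_n):
            weights_n.append((m, "mature", w))
            weights_n.append((m, "star", w * config.star_fraction))
        z = sum(w for _, _, w in weights_n)
        for m, which, w in weights_n:
            sources.append((m, which, config.novel_share * w / z))
    return sources


def simulate_reads(
    genome: Mapping[str, str], gt: GroundTruth, config: SimulationConfig
) -> SimulatedReads:
    """Draw the two raw libraries; fills provenance and true counts in `gt`."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    seq = genome[CHROM]
    adapter3 = config.adapter3.upper()
    a5_tail = config.adapter5.upper()[-6:]
    seed8 = adapter3[:8]
    libraries = ("fetal", "adult")
    arm_sources = _arm_sources(gt, config, rng)
    loci_by_class: dict[str, list[Locus]] = {}
    for locus in gt.loci:
        loci_by_class.setdefault(locus.klass, []).append(locus)

    # assemble the per-library probability vector over read sources
    entries: list[tuple[str, object]] = []  # (kind, payload)
    probs = {lib: [] for lib in libraries}
    for m, which, p_adult in arm_sources:
        entries.append(("mirna", (m, which)))
        fold = gt.fold_changes.get(m.precursor_id, 1.0)
        probs["adult"].append(p_adult)
        probs["fetal"].append(p_adult * fold)
    # The planted fold changes inflate the fetal miRNA pool; if it would
    # overflow the library, shrink the pool by a common factor in *both*
    # libraries so every planted between-library ratio stays exact.
    other_share = (
        sum(s for k, s in config.class_shares.items() if loci_by_class.get(k))
        + config.unknown_genomic_share
        + config.adapter3_null_rate
        + config.insert_null_rate
        + config.adapter5_contaminant_rate
        + config.short_rate
        + config.polyA_rate
    )
    allowed = 0.97 - other_share
    worst = max(sum(probs[lib]) for lib in libraries)
    if worst > allowed:
        scale = allowed / worst
        for lib in libraries:
            probs[lib] = [p * scale for p in probs[lib]]
    for klass, share in config.class_shares.items():
        if loci_by_class.get(klass):
            entries.append(("locus", klass))
            for lib in libraries:
                probs[lib].append(share)
    entries.append(("unknown_genomic", None))
    for lib in libraries:
        probs[lib].append(config.unknown_genomic_share)
    contaminants = [
        ("adapter3_null", config.adapter3_null_rate),
        ("insert_null", config.insert_null_rate),
        ("adapter5_contaminant", config.adapter5_contaminant_rate),
        ("too_short", config.short_rate),
        ("polyA", config.polyA_rate),
    ]
    for name, rate in contaminants:
        entries.append((name, None))
        for lib in libraries:
            probs[lib].append(rate)
    entries.append(("nongenome", None))
    for lib in libraries:
        total = sum(probs[lib])
        if total >= 0.999:
            raise ValueError("source shares exceed the library; lower mirna/class shares")
        probs[lib].append(1.0 - total)

    def finish(insert: str) -> str:
        read = insert + adapter3
        if len(read) < config.read_length:
            read += _random_seq(rng, config.read_length - len(read), 0.5)
        return read[: config.read_length]

    def random_nonadapter(length: int) -> str:
        while True:
            s = _random_seq(rng, length, 0.5)
            if seed8 not in s:
                return s

    reads: dict[str, list[str]] = {}
    for lib_idx, lib in enumerate(libraries):
        n = config.library_sizes[lib_idx]
        counts = rng.multinomial(n, np.array(probs[lib]))
        provenance: Counter = Counter()
        true_counts: Counter = Counter()
        true_exact: Counter = Counter()
        lib_reads: list[str] = []
        for (kind, payload), count in zip(entries, counts):
            for _ in range(int(count)):
                if kind == "mirna":
                    m, which = payload
                    arm_id = m.mirna_id if which == "mature" else (
                        m.star_id or f"{m.precursor_id}:star"
                    )
                    base = m.mature if which == "mature" else m.star
                    r = rng.random()
                    variant = "exact"
                    if m.known and r < config.edit_rate:
                        insert, variant = _edit(rng, base), "edit"
                    elif m.known and r < config.edit_rate + config.isomir_rate:
                        insert = _isomir(rng, m) if which == "mature" else base
                        variant = "isomir" if insert != base else "exact"
                    else:
                        insert = base
                    insert, errored = _apply_errors(rng, insert, config.error_rate)
                    label = f"{'known' if m.known else 'novel'}_{variant}"
                    true_counts[arm_id] += 1
                    if variant == "exact" and not errored:
                        true_exact[arm_id] += 1
                elif kind == "locus":
                    locus = loci_by_class[payload][int(rng.integers(len(loci_by_class[payload])))]
                    frag_len = int(rng.integers(20, 25))
                    lo = int(rng.integers(locus.start - 1, locus.end - frag_len + 1))
                    frag = seq[lo : lo + frag_len]
                    if locus.strand == "-":
                        frag = revcomp(frag)
                    insert, _ = _apply_errors(rng, frag, config.error_rate)
                    label = f"class_{payload}"
                elif kind == "unknown_genomic":
                    frag_len = int(rng.integers(20, 25))
                    lo = int(rng.integers(0, len(seq) - frag_len))
                    frag = seq[lo : lo + frag_len]
                    if rng.random() < 0.5:
                        frag = revcomp(frag)
                    insert, _ = _apply_errors(rng, frag, config.error_rate)
                    label = "unknown_genomic"
                elif kind == "nongenome":
                    insert = random_nonadapter(int(rng.integers(20, 25)))
                    label = "nongenome"
                elif kind == "adapter3_null":
                    lib_reads.append(random_nonadapter(config.read_length))
                    provenance["adapter3_null"] += 1
                    continue
                elif kind == "insert_null":
                    lib_reads.append(finish(""))
                    provenance["insert_null"] += 1
                    continue
                elif kind == "adapter5_contaminant":
                    insert = a5_tail + _random_seq(rng, int(rng.integers(12, 20)), 0.5)
                    lib_reads.append(finish(insert))
                    provenance["adapter5_contaminant"] += 1
                    continue
                elif kind == "too_short":
                    while True:
                        insert = _random_seq(rng, int(rng.integers(1, 18)), 0.5)
                        if not insert.startswith(a5_tail):
                            break
                    lib_reads.append(finish(insert))
                    provenance["too_short"] += 1
                    continue
                elif kind == "polyA":
                    lib_reads.append(finish("A" * int(rng.integers(20, 27))))
                    provenance["polyA"] += 1
                    continue
                else:  # pragma: no cover
                    raise AssertionError(kind)
                lib_reads.append(finish(insert))
                provenance[label] += 1
        assert len(lib_reads) == n and sum(provenance.values()) == n
        reads[lib] = lib_reads
        gt.provenance[lib] = provenance
        gt.true_counts[lib] = true_counts
        gt.true_exact_counts[lib] = true_exact
    return SimulatedReads(reads=reads, libraries=libraries)


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(
    abundances: Mapping[str, Mapping[str, float]],
    config: SimulationConfig,
    reference_gene: str = "RPS18",
    replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate Ct table from true relative abundances per sample.

    Ct = intercept - log2(abundance) + N(0, noise_sd); the reference gene
    sits at abundance 1 in every sample, so a doubling of a target's
    abundance lowers its Ct by exactly one cycle at zero noise.
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    for sample in sorted(abundances):
        targets = dict(abundances[sample])
        targets.setdefault(reference_gene, 1.0)
        for gene in sorted(targets):
            abundance = targets[gene]
            if abundance <= 0:
                raise ValueError(f"non-positive abundance for {sample}/{gene}")
            base_ct = config.qpcr_intercept - math.log2(abundance)
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "ct": base_ct + noise}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negative control


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide composition
    (Altschul-Erickson Eulerian-walk shuffle)."""
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = s[-1]
    # choose last-edges forming a tree into `last`
    for _ in range(10000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("dinucleotide shuffle failed to find a spanning tree")
    walk_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        walk_edges[v] = rest
    out = [s[0]]
    pointers = dict.fromkeys(vertices, 0)
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = walk_edges[cur][pointers[cur]]
        pointers[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
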