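"""Known-miRNA identification and descriptive profiling.

A tag is assigned to a known miRNA when it matches the reference mature
sequence exactly, or when it lies wholly within the annotated hairpin and
overlaps the mature site by a configurable minimum (variant-inclusive
counting of end variants / isomiRs).  Tags matching neither are returned
untouched for base-edit scanning and novel discovery — known matching and
the leftover set partition the input exactly.

Profiles feed the descriptive analyses: arm (miR vs miR*) usage,
per-position nucleotide bias, single-base edits and untemplated 3' A/U
additions, end-variant cataloguing, and family grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .util import normalize_seq, to_rna

ARM_CLASSES = ("miR", "miR*", "miR-5p", "miR-3p")
SEED_REGION = (2, 8)  # 1-based positions of the seed


@dataclass
class MatureRef:
    """One reference mature sequence located within its hairpin."""

    mirna_id: str
    seq: str  # DNA alphabet
    precursor_id: str
    arm_class: str
    start_in_hairpin: int  # 0-based offset of the mature within the hairpin

    @property
    def end_in_hairpin(self) -> int:
        return self.start_in_hairpin + len(self.seq)


@dataclass
class MiRNAProfile:
    """Per-miRNA counts split into exact and variant-inclusive totals."""

    mirna_id: str
    precursor_id: str
    arm_class: str
    seq: str
    exact: dict = field(default_factory=dict)  # library -> reads
    total: dict = field(default_factory=dict)  # library -> reads (incl. variants)
    variants: list = field(default_factory=list)  # (tag, offset_in_hairpin, counts)

    def reads(self, library: str | None = None) -> int:
        if library is not None:
            return self.total.get(library, 0)
        return sum(self.total.values())


@dataclass(frozen=True)
class BaseEdit:
    tag: str
    mirna_id: str
    position: int  # 1-based within the mature; 0 for 3' additions
    ref_base: str
    obs_base: str
    counts: tuple
    kind: str  # 'substitution' or 'addition3p'

    @property
    def in_seed(self) -> bool:
        return SEED_REGION[0] <= self.position <= SEED_REGION[1]

    @property
    def a_to_g(self) -> bool:
        return self.kind == "substitution" and self.ref_base == "A" and self.obs_base == "G"


def arm_class_of(mirna_id: str) -> str:
    if mirna_id.endswith("*"):
        return "miR*"
    if mirna_id.endswith("-5p"):
        return "miR-5p"
    if mirna_id.endswith("-3p"):
        return "miR-3p"
    return "miR"


def _precursor_of(mirna_id: str, hairpins: Mapping[str, str]) -> str | None:
    base = mirna_id.rstrip("*")
    for suffix in ("-5p", "-3p"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    for candidate in (base, base.replace("miR", "mir"), base.lower()):
        if candidate in hairpins:
            return candidate
    return None


def build_mature_refs(
    matures: Mapping[str, str], hairpins: Mapping[str, str]
) -> dict[str, MatureRef]:
    """Locate every mature sequence inside its hairpin (miRBase-style ids)."""
    refs: dict[str, MatureRef] = {}
    norm_hairpins = {k: normalize_seq(v) for k, v in hairpins.items()}
    for mid, seq in matures.items():
        mseq = normalize_seq(seq)
        pid = _precursor_of(mid, norm_hairpins)
        if pid is None:
            # fall back to a containment scan over all hairpins
            pid = next((h for h, hseq in norm_hairpins.items() if mseq in hseq), None)
        if pid is None or mseq not in norm_hairpins[pid]:
            raise ValueError(f"mature {mid} not found in any declared hairpin")
        refs[mid] = MatureRef(
            mirna_id=mid,
            seq=mseq,
            precursor_id=pid,
            arm_class=arm_class_of(mid),
            start_in_hairpin=norm_hairpins[pid].find(mseq),
        )
    return refs


def match_known(
    tag_counts: pd.DataFrame,
    matures: Mapping[str, str],
    hairpins: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> tuple[dict[str, MiRNAProfile], pd.DataFrame]:
    """Assign tags to known miRNAs; returns (profiles, leftover tag matrix)."""
    cfg = config or PipelineConfig()
    refs = build_mature_refs(matures, hairpins)
    norm_hairpins = {k: normalize_seq(v) for k, v in hairpins.items()}
    by_precursor: dict[str, list[MatureRef]] = {}
    for ref in refs.values():
        by_precursor.setdefault(ref.precursor_id, []).append(ref)
    exact_lookup: dict[str, MatureRef] = {}
    for ref in sorted(refs.values(), key=lambda r: r.mirna_id):
        exact_lookup.setdefault(ref.seq, ref)

    profiles = {
        mid: MiRNAProfile(mid, ref.precursor_id, ref.arm_class, ref.seq)
        for mid, ref in refs.items()
    }
    libraries = list(tag_counts.columns)
    leftover_rows = []
    for tag in tag_counts.index:
        counts = tag_counts.loc[tag]
        ref = exact_lookup.get(tag)
        if ref is not None:
            prof = profiles[ref.mirna_id]
            for lib in libraries:
                prof.exact[lib] = prof.exact.get(lib, 0) + int(counts[lib])
                prof.total[lib] = prof.total.get(lib, 0) + int(counts[lib])
            continue
        assigned = False
        for pid, hseq in norm_hairpins.items():
            pos = hseq.find(tag)
            if pos < 0:
                continue
            for ref in by_precursor.get(pid, ()):
                overlap = min(pos + len(tag), ref.end_in_hairpin) - max(
                    pos, ref.start_in_hairpin
                )
                if overlap >= cfg.mature_overlap_min:
                    prof = profiles[ref.mirna_id]
                    for lib in libraries:
                        prof.total[lib] = prof.total.get(lib, 0) + int(counts[lib])
                    prof.variants.append((tag, pos, tuple(int(counts[l]) for l in libraries)))
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            leftover_rows.append(tag)
    leftover = tag_counts.loc[leftover_rows]
    return profiles, leftover


def profile_table(profiles: Mapping[str, MiRNAProfile], libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for mid in sorted(profiles):
        p = profiles[mid]
        row = {
            "mirna_id": mid,
            "precursor_id": p.precursor_id,
            "arm_class": p.arm_class,
            "sequence": to_rna(p.seq),
        }
        for lib in libraries:
            row[f"{lib}_exact"] = p.exact.get(lib, 0)
            row[f"{lib}_total"] = p.total.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id")


def total_categories(class_counts: Mapping[str, int]) -> int:
    """Total matched miRNA categories: the sum over the four arm classes."""
    return sum(int(class_counts[cls]) for cls in ARM_CLASSES)


def class_summary(profiles: Mapping[str, MiRNAProfile], library: str) -> pd.Series:
    """Detected miRNAs per arm class in one library (miR/miR*/5p/3p),
    plus the number of distinct precursors and total matched reads."""
    detected = [p for p in profiles.values() if p.total.get(library, 0) > 0]
    counts = {cls: sum(1 for p in detected if p.arm_class == cls) for cls in ARM_CLASSES}
    counts["categories"] = total_categories(counts)
    counts["pre_miRs"] = len({p.precursor_id for p in detected})
    counts["reads"] = sum(p.total[library] for p in detected)
    return pd.Series(counts)


def arm_usage(
    profiles: Mapping[str, MiRNAProfile], near_equal_minority: float = 1 / 3
) -> pd.DataFrame:
    """Per-precursor miR vs miR* read counts and the dominance verdict.

    The near-equal flag marks precursors whose minority arm still carries
    at least `near_equal_minority` of the precursor's reads; the default
    third covers the canonical nearly-equal pairs (447/680, 186/314 reads)
    while leaving ordinary star arms (a few percent) unflagged.
    """
    by_precursor: dict[str, dict[str, int]] = {}
    for p in profiles.values():
        slot = by_precursor.setdefault(p.precursor_id, {"miR": 0, "miR*": 0})
        if p.arm_class == "miR*":
            slot["miR*"] += p.reads()
        else:
            slot["miR"] += p.reads()
    rows = []
    for pid in sorted(by_precursor):
        mir, star = by_precursor[pid]["miR"], by_precursor[pid]["miR*"]
        total = mir + star
        if total == 0:
            continue
        rows.append(
            {
                "precursor_id": pid,
                "miR_reads": mir,
                "miR_star_reads": star,
                "dominant_arm": "miR" if mir >= star else "miR*",
                "near_equal": min(mir, star) / total >= near_equal_minority,
            }
        )
    if not rows:
        raise ValueError("no precursor with observed reads")
    return pd.DataFrame(rows).set_index("precursor_id")


def nucleotide_bias(
    profiles: Mapping[str, MiRNAProfile], weight: str = "reads"
) -> pd.DataFrame:
    """Position x base (A/C/G/U) frequency matrix over mature sequences.

    Sequences align from position 1; a sequence contributes only to the
    positions it covers, and each row renormalises over what it saw.
    `weight` is 'reads' (abundance-weighted) or 'unique' (one per miRNA).
    """
    seqs = [
        (p.seq, p.reads() if weight == "reads" else 1)
        for p in profiles.values()
        if weight == "unique" or p.reads() > 0
    ]
    seqs = [(s, w) for s, w in seqs if w > 0]
    if not seqs:
        raise ValueError("no mature sequences to profile")
    max_len = max(len(s) for s, _ in seqs)
    counts = pd.DataFrame(0.0, index=range(1, max_len + 1), columns=list("ACGU"))
    for seq, w in seqs:
        rna = to_rna(seq)
        for i, base in enumerate(rna, start=1):
            counts.loc[i, base] += w
    freqs = counts.div(counts.sum(axis=1), axis=0)
    freqs.index.name = "position"
    freqs["GC"] = freqs["G"] + freqs["C"]
    freqs["AU"] = freqs["A"] + freqs["U"]
    return freqs


def _hamming_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def detect_base_edits(
    leftover: pd.DataFrame,
    matures: Mapping[str, str],
    hairpins: Mapping[str, str],
    ref_weights: Mapping[str, int] | None = None,
) -> tuple[list[BaseEdit], pd.DataFrame]:
    """Scan leftover tags for single-base edits against reference matures.

    A tag yields a substitution record iff its Hamming distance to some
    equal-length window of a reference mature (anchored at the 5' or the
    3' end) is exactly one; a tag equal to a mature plus one untemplated
    3'-terminal A or U yields an addition record.  Ties across references
    break toward the highest-count reference, then lexicographic id.
    Returns the edit list and the remaining (unexplained) tag matrix.
    """
    norm_hairpins = {k: normalize_seq(v) for k, v in hairpins.items()}
    refs = build_mature_refs(matures, hairpins)
    weights = ref_weights or {}

    # pigeonhole half-key lookup: a 1-mismatch tag agrees exactly with one
    # half of the reference window
    window_index: dict[tuple, list[tuple[str, str, int]]] = {}
    lengths = {len(normalize_seq(s)) for s in leftover.index} if len(leftover) else set()
    for mid, ref in refs.items():
        for L in lengths:
            if L > len(ref.seq):
                continue
            for offset in {0, len(ref.seq) - L}:
                window = ref.seq[offset : offset + L]
                half = L // 2
                window_index.setdefault((L, "first", window[:half]), []).append(
                    (mid, window, offset)
                )
                window_index.setdefault((L, "second", window[half:]), []).append(
                    (mid, window, offset)
                )

    addition_lookup: dict[str, list[str]] = {}
    for mid, ref in refs.items():
        addition_lookup.setdefault(ref.seq, []).append(mid)

    libraries = list(leftover.columns)
    edits: list[BaseEdit] = []
    unexplained = []
    for tag in leftover.index:
        counts = tuple(int(leftover.loc[tag, l]) for l in libraries)
        record = None
        # untemplated 3' A/U addition first: it is not a substitution
        if tag[-1] in "AT" and tag[:-1] in addition_lookup:
            candidates = sorted(
                addition_lookup[tag[:-1]], key=lambda m: (-weights.get(m, 0), m)
            )
            for mid in candidates:
                ref = refs[mid]
                hseq = norm_hairpins[ref.precursor_id]
                templated = (
                    ref.end_in_hairpin < len(hseq)
                    and hseq[ref.end_in_hairpin] == tag[-1]
                )
                if not templated:
                    record = BaseEdit(
                        tag, mid, 0, "-", to_rna(tag[-1]), counts, "addition3p"
                    )
                    break
        if record is None:
            L = len(tag)
            half = L // 2
            candidates = window_index.get((L, "first", tag[:half]), []) + window_index.get(
                (L, "second", tag[half:]), []
            )
            best = None
            for mid, window, offset in candidates:
                diff = _hamming_positions(tag, window)
                if len(diff) != 1:
                    continue
                key = (-weights.get(mid, 0), mid)
                if best is None or key < best[0]:
                    pos = offset + diff[0] + 1  # 1-based within the mature
                    best = (key, mid, pos, window[diff[0]], tag[diff[0]])
            if best is not None:
                _, mid, pos, ref_base, obs_base = best
                record = BaseEdit(
                    tag, mid, pos, to_rna(ref_base), to_rna(obs_base), counts, "substitution"
                )
        if record is not None:
            edits.append(record)
        else:
            unexplained.append(tag)
    return edits, leftover.loc[unexplained]


def edited_fraction(
    edits: Sequence[BaseEdit], profiles: Mapping[str, MiRNAProfile]
) -> float:
    """Read-weighted share of miRNA-attributed reads that carry an edit."""
    edited = sum(sum(e.counts) for e in edits)
    matched = sum(p.reads() for p in profiles.values())
    if edited + matched == 0:
        raise ValueError("no miRNA-attributed reads")
    return edited / (edited + matched)


def edits_table(edits: Sequence[BaseEdit], libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for e in edits:
        row = {
            "tag": to_rna(e.tag),
            "mirna_id": e.mirna_id,
            "kind": e.kind,
            "position": e.position,
            "ref_base": e.ref_base,
            "obs_base": e.obs_base,
            "in_seed": e.in_seed,
            "A_to_G": e.a_to_g,
        }
        for lib, c in zip(libraries, e.counts):
            row[f"{lib}_reads"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def catalog_end_variants(
    profiles: Mapping[str, MiRNAProfile], matures: Mapping[str, str], hairpins: Mapping[str, str]
) -> pd.DataFrame:
    """End-variant table from the variant-inclusive matches.

    Offsets are signed nt relative to the reference mature: a 5' offset of
    +1 means the tag starts one base upstream (5' extension); a 3' offset
    of -2 means the tag ends two bases short (3' trim).
    """
    refs = build_mature_refs(matures, hairpins)
    rows = []
    for mid in sorted(profiles):
        p = profiles[mid]
        ref = refs[mid]
        for tag, pos, counts in p.variants:
            off5 = ref.start_in_hairpin - pos
            off3 = (pos + len(tag)) - ref.end_in_hairpin
            rows.append(
                {
                    "mirna_id": mid,
                    "tag": to_rna(tag),
                    "offset5": off5,
                    "offset3": off3,
                    "reads": sum(counts),
                    "variant_type": (
                        "both"
                        if off5 and off3
                        else "5p_only"
                        if off5
                        else "3p_only"
                        if off3
                        else "none"
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["mirna_id", "tag", "offset5", "offset3", "reads", "variant_type"]
    )


def end_variant_summary(variants: pd.DataFrame) -> pd.Series:
    """Read-weighted shares of 5'-only / 3'-only / both-end variants."""
    changed = variants[variants["variant_type"] != "none"]
    total = changed["reads"].sum()
    if total == 0:
        raise ValueError("no end variants observed")
    shares = changed.groupby("variant_type")["reads"].sum() / total
    return shares.reindex(["3p_only", "5p_only", "both"], fill_value=0.0)


def parse_family_file(text: str) -> dict[str, str]:
    """Parse miFam-like stanzas; returns precursor id -> family id."""
    families: dict[str, str] = {}
    family = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("ID"):
            family = line.split(None, 1)[1]
        elif line.startswith("MI"):
            parts = line.split()
            precursor = parts[-1]
            if precursor in families and families[precursor] != family:
                raise ValueError(f"{precursor} listed in two families")
            families[precursor] = family
        elif line == "//":
            family = None
    return families


def assign_families(
    profiles: Mapping[str, MiRNAProfile], families: Mapping[str, str]
) -> tuple[pd.DataFrame, list[str]]:
    """Family summary (member count, read range, total) + unassigned list."""
    rows: dict[str, dict] = {}
    unassigned = []
    for mid in sorted(profiles):
        p = profiles[mid]
        fam = families.get(p.precursor_id)
        if fam is None:
            unassigned.append(mid)
            continue
        slot = rows.setdefault(fam, {"members": 0, "reads": []})
        slot["members"] += 1
        slot["reads"].append(p.reads())
    table = pd.DataFrame(
        [
            {
                "family": fam,
                "members": slot["members"],
                "min_reads": min(slot["reads"]),
                "max_reads": max(slot["reads"]),
                "total_reads": sum(slot["reads"]),
            }
            for fam, slot in sorted(rows.items())
        ]
    )
    if not table.empty:
        table = table.set_index("family")
    return table, unassigned
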