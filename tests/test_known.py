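"""Known-miRNA matching and the descriptive profiles built on it."""

import numpy as np
import pandas as pd
import pytest

from bovmir.config import PipelineConfig
from bovmir.known import (
    MiRNAProfile,
    arm_usage,
    assign_families,
    catalog_end_variants,
    class_summary,
    detect_base_edits,
    edited_fraction,
    match_known,
    nucleotide_bias,
    parse_family_file,
    total_categories,
)
from bovmir.simulate import build_hairpin
from bovmir.util import revcomp

MATURE = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt, let-7 style
RNG = np.random.default_rng(0)
PRECURSOR, STAR, ARM, M_OFF, S_OFF = build_hairpin(RNG, MATURE, star_mismatches=0, arm="5p")

MATURES = {"bta-miR-t1": MATURE}
HAIRPINS = {"bta-mir-t1": PRECURSOR}


def frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = ["fetal", "adult"]
    return df


def test_exact_match_counts_exactly():
    tags = frame({MATURE: [10, 4]})
    profiles, leftover = match_known(tags, MATURES, HAIRPINS)
    p = profiles["bta-miR-t1"]
    assert p.exact == {"fetal": 10, "adult": 4}
    assert p.total == {"fetal": 10, "adult": 4}
    assert leftover.empty


def test_hairpin_variant_counts_toward_mature():
    trimmed = MATURE[:-2]  # 3' trimmed isomiR, still inside the hairpin
    tags = frame({MATURE: [5, 0], trimmed: [2, 1]})
    profiles, leftover = match_known(tags, MATURES, HAIRPINS)
    p = profiles["bta-miR-t1"]
    assert p.exact == {"fetal": 5, "adult": 0}
    assert p.total == {"fetal": 7, "adult": 1}
    assert leftover.empty


def test_loop_only_tag_not_assigned():
    # a tag overlapping the mature by < 16 nt stays unassigned
    loop_tag = PRECURSOR[M_OFF + 14 : M_OFF + 14 + 20]
    tags = frame({loop_tag: [3, 3]})
    profiles, leftover = match_known(tags, MATURES, HAIRPINS)
    assert profiles["bta-miR-t1"].total == {}
    assert list(leftover.index) == [loop_tag]


def test_match_and_leftover_partition_tags():
    other = "GC" * 11
    tags = frame({MATURE: [1, 1], other: [2, 2]})
    profiles, leftover = match_known(tags, MATURES, HAIRPINS)
    matched_reads = sum(profiles["bta-miR-t1"].total.values())
    assert matched_reads + leftover.to_numpy().sum() == tags.to_numpy().sum()


def test_mature_absent_from_hairpin_rejected():
    with pytest.raises(ValueError):
        match_known(frame({MATURE: [1, 1]}), {"x": MATURE}, {"y": "ACGT" * 30})


def make_profile(mid, arm_cls, reads, precursor="p1", seq="ACGT" * 5 + "AC"):
    return MiRNAProfile(mid, precursor, arm_cls, seq, total={"fetal": reads})


@pytest.mark.parametrize(
    "mir,star,dominant,near_equal",
    [
        (447, 680, "miR*", True),  # miR-151/151*-like near-equal pair
        (186, 314, "miR*", True),  # miR-455/455*-like near-equal pair
        (1000, 0, "miR", False),
        (1000, 50, "miR", False),
    ],
)
def test_arm_usage_verdicts(mir, star, dominant, near_equal):
    profiles = {
        "m": make_profile("m", "miR", mir),
        "s": make_profile("s", "miR*", star),
    }
    row = arm_usage(profiles).loc["p1"]
    assert row["miR_reads"] == mir and row["miR_star_reads"] == star
    assert row["dominant_arm"] == dominant
    assert bool(row["near_equal"]) is near_equal


def test_arm_usage_requires_observed_reads():
    with pytest.raises(ValueError):
        arm_usage({"m": make_profile("m", "miR", 0)})


def test_class_summary_sums_arm_classes():
    profiles = {
        "a": make_profile("a", "miR", 5, "p1"),
        "b": make_profile("b", "miR*", 3, "p1"),
        "c": make_profile("c", "miR-5p", 2, "p2"),
        "d": make_profile("d", "miR-3p", 0, "p2"),
    }
    s = class_summary(profiles, "fetal")
    assert s["categories"] == s["miR"] + s["miR*"] + s["miR-5p"] + s["miR-3p"] == 3
    assert s["pre_miRs"] == 2
    assert total_categories({"miR": 344, "miR*": 21, "miR-5p": 21, "miR-3p": 21}) == 407


def test_nucleotide_bias_single_sequence():
    profiles = {"a": make_profile("a", "miR", 4, seq="A" * 20)}
    bias = nucleotide_bias(profiles)
    assert bias.loc[1, "A"] == 1.0
    assert bias.loc[1, "AU"] == 1.0


def test_nucleotide_bias_equal_weights_split():
    profiles = {
        "a": make_profile("a", "miR", 5, seq="A" + "C" * 19),
        "b": make_profile("b", "miR", 5, "p2", seq="G" + "C" * 19),
    }
    bias = nucleotide_bias(profiles)
    assert bias.loc[1, "A"] == pytest.approx(0.5)
    assert bias.loc[1, "G"] == pytest.approx(0.5)
    assert bias.loc[2, "C"] == pytest.approx(1.0)
    # every position's A/C/G/U frequencies sum to one
    assert bias[list("ACGU")].sum(axis=1).to_numpy() == pytest.approx(1.0)


def test_base_edit_detected_at_position():
    edited = MATURE[:4] + ("A" if MATURE[4] != "A" else "C") + MATURE[5:]
    edits, rest = detect_base_edits(frame({edited: [3, 0]}), MATURES, HAIRPINS)
    assert len(edits) == 1 and rest.empty
    e = edits[0]
    assert e.position == 5 and e.kind == "substitution"
    assert e.in_seed  # position 5 lies in the 2-8 seed window
    assert e.counts == (3, 0)


def test_untemplated_3p_addition_is_not_a_substitution():
    # the planted hairpin continues after the mature; pick the letter that
    # is NOT templated at the next position
    next_base = PRECURSOR[M_OFF + len(MATURE)]
    added = MATURE + ("A" if next_base != "A" else "T")
    edits, rest = detect_base_edits(frame({added: [2, 2]}), MATURES, HAIRPINS)
    assert len(edits) == 1 and rest.empty
    assert edits[0].kind == "addition3p"
    assert edits[0].position == 0


def test_two_mismatch_tag_not_called_an_edit():
    tag = "A" + MATURE[1:-1] + "G"
    if tag != MATURE:
        edits, rest = detect_base_edits(frame({tag: [1, 0]}), MATURES, HAIRPINS)
        assert not edits and list(rest.index) == [tag]


def test_edit_never_fires_on_known_matched_tag():
    tags = frame({MATURE: [5, 5]})
    profiles, leftover = match_known(tags, MATURES, HAIRPINS)
    edits, _ = detect_base_edits(leftover, MATURES, HAIRPINS)
    assert not edits


def test_edited_fraction_read_weighted():
    profiles = {"a": make_profile("a", "miR", 90)}
    edited = MATURE[:8] + ("G" if MATURE[8] != "G" else "C") + MATURE[9:]
    edits, _ = detect_base_edits(frame({edited: [10, 0]}), MATURES, HAIRPINS)
    assert edited_fraction(edits, profiles) == pytest.approx(0.1)


@pytest.mark.parametrize(
    "tag,off5,off3",
    [
        (MATURE[:-2], 0, -2),   # 3' trimmed by 2
        (MATURE[2:], -2, 0),    # 5' trimmed by 2
    ],
)
def test_end_variant_offsets(tag, off5, off3):
    profiles, _ = match_known(frame({tag: [1, 0]}), MATURES, HAIRPINS)
    variants = catalog_end_variants(profiles, MATURES, HAIRPINS)
    row = variants.iloc[0]
    assert (row["offset5"], row["offset3"]) == (off5, off3)


def test_end_variant_5p_extension_templated():
    # put the mature on the 3' arm so a templated 5' extension exists
    precursor3, _, _, m_off3, _ = build_hairpin(
        np.random.default_rng(1), MATURE, star_mismatches=0, arm="3p"
    )
    matures3 = {"bta-miR-t3": MATURE}
    hairpins3 = {"bta-mir-t3": precursor3}
    extended = precursor3[m_off3 - 1 : m_off3 + len(MATURE)]
    profiles, _ = match_known(frame({extended: [1, 0]}), matures3, hairpins3)
    variants = catalog_end_variants(profiles, matures3, hairpins3)
    assert (variants.iloc[0]["offset5"], variants.iloc[0]["offset3"]) == (1, 0)


FAMILY_TEXT = """\
AC   MIPF0000001
ID   mir-2284
MI   MI0000001  bta-mir-2284a
MI   MI0000002  bta-mir-2284x
//
AC   MIPF0000002
ID   mir-t
MI   MI0000003  bta-mir-t1
//
"""


def test_family_file_round_trip_and_ranges():
    families = parse_family_file(FAMILY_TEXT)
    assert families["bta-mir-2284a"] == "mir-2284"
    profiles = {
        "bta-miR-2284a": MiRNAProfile(
            "bta-miR-2284a", "bta-mir-2284a", "miR", MATURE, total={"fetal": 1}
        ),
        "bta-miR-2284x": MiRNAProfile(
            "bta-miR-2284x", "bta-mir-2284x", "miR", MATURE, total={"fetal": 46548}
        ),
        "orphan": MiRNAProfile("orphan", "no-family", "miR", MATURE, total={"fetal": 7}),
    }
    table, unassigned = assign_families(profiles, families)
    row = table.loc["mir-2284"]
    assert (row["members"], row["min_reads"], row["max_reads"]) == (2, 1, 46548)
    assert unassigned == ["orphan"]


def test_singleton_family_min_equals_max():
    families = {"p1": "famX"}
    profiles = {"a": make_profile("a", "miR", 12)}
    table, _ = assign_families(profiles, families)
    assert table.loc["famX", "min_reads"] == table.loc["famX", "max_reads"] == 12


def test_duplicate_family_membership_rejected():
    text = FAMILY_TEXT + "AC   MIPF0000003\nID   other\nMI   MI9  bta-mir-2284a\n//\n"
    with pytest.raises(ValueError):
        parse_family_file(text)
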