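"""Novel-miRNA discovery: window extraction, criteria evaluation,
hairpin construction round trips, and the discovery-level rules."""

import numpy as np
import pandas as pd
import pytest

from bovmir.config import PipelineConfig
from bovmir.folding import fold_rna
from bovmir.mapping import GenomeHit, GenomeIndex
from bovmir.novel import (
    discover_novel,
    evaluate_candidate,
    evaluate_window,
    extract_flanks,
)
from bovmir.simulate import build_hairpin
from bovmir.util import revcomp

RNG = np.random.default_rng(123)
MATURE = "TGAGGTAGTAGGTTGTATAGTT"


def compliant_hairpin(seed=0, mismatches=0, arm="5p"):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        from bovmir.simulate import _random_mature
        from bovmir.config import SimulationConfig

        mature = _random_mature(rng, SimulationConfig())
        precursor, star, got_arm, m_off, s_off = build_hairpin(
            rng, mature, mismatches, arm=arm
        )
        cand = evaluate_window(precursor, m_off, len(mature))
        if cand is not None and cand.passed:
            return mature, precursor, m_off
    raise AssertionError("no compliant hairpin found")


# --- extract_flanks -------------------------------------------------------


def test_flanks_clip_at_genome_start():
    genome = {"c": "ACGT" * 50}
    tag = genome["c"][2:20]  # 1-based positions 3-20
    hit = GenomeHit(tag, "c", "+", 3, 20)
    window, offset = extract_flanks(hit, genome, flank=150)
    assert window.startswith(genome["c"][:2])
    assert offset == 2
    assert window[offset : offset + 18] == tag


def test_flank_windows_are_strand_symmetric():
    genome = {"c": "".join(np.random.default_rng(4).choice(list("ACGT"), 500))}
    tag = genome["c"][200:222]
    plus = extract_flanks(GenomeHit(tag, "c", "+", 201, 222), genome, 50)
    minus = extract_flanks(GenomeHit(revcomp(tag), "c", "-", 201, 222), genome, 50)
    assert minus[0] == revcomp(plus[0])
    assert minus[0][minus[1] : minus[1] + 22] == revcomp(tag)


def test_out_of_bounds_hit_rejected():
    with pytest.raises(ValueError):
        extract_flanks(GenomeHit("A" * 20, "c", "+", 100, 119), {"c": "ACGT" * 10}, 150)


def test_window_contains_planted_precursor():
    mature, precursor, m_off = compliant_hairpin(seed=2)
    rng = np.random.default_rng(8)
    left = "".join(rng.choice(list("ACGT"), 300))
    right = "".join(rng.choice(list("ACGT"), 300))
    genome = {"c": left + precursor + right}
    start = len(left) + m_off + 1
    hit = GenomeHit(mature, "c", "+", start, start + len(mature) - 1)
    window, offset = extract_flanks(hit, genome, 150)
    assert precursor in window
    assert window[offset : offset + len(mature)] == mature


# --- evaluate_candidate ---------------------------------------------------


def test_planted_hairpin_passes_all_criteria():
    mature, precursor, m_off = compliant_hairpin(seed=3, mismatches=2)
    cand = evaluate_window(precursor, m_off, len(mature))
    assert cand is not None and cand.passed
    assert cand.arm in ("5p", "3p")
    assert cand.star_mismatches <= 5


def test_mature_spanning_loop_fails_arm_criterion():
    mature, precursor, m_off = compliant_hairpin(seed=4)
    structure, mfe = fold_rna(precursor)
    # a fake mature centred on the terminal loop
    centre = len(precursor) // 2
    cand = evaluate_candidate(precursor, structure, mfe, (centre - 11, centre + 11))
    assert not cand.criteria["hairpin_arm"]
    assert not cand.passed


def test_au_rich_precursor_fails_composition():
    seq = ("AT" * 40) + "AAAA" + ("AT" * 40)
    structure, mfe = fold_rna(seq)
    cand = evaluate_candidate(seq, structure, mfe, (0, 22))
    assert not cand.criteria["au_content"]


def test_mature_length_bounds_enforced():
    mature, precursor, m_off = compliant_hairpin(seed=5)
    structure, mfe = fold_rna(precursor)
    cand = evaluate_candidate(precursor, structure, mfe, (m_off, m_off + 19))
    assert not cand.criteria["mature_length"]


def test_structure_length_mismatch_rejected():
    with pytest.raises(ValueError):
        evaluate_candidate("ACGT" * 10, "." * 39, -5.0, (0, 20))


def test_mfei_threshold_monotone_in_accepted_count():
    """Tightening the MFEI cutoff can only shrink the accepted set."""
    candidates = []
    for seed in range(3, 9):
        mature, precursor, m_off = compliant_hairpin(seed=seed)
        candidates.append((precursor, m_off, len(mature)))
    accepted = []
    for threshold in (0.5, 0.85, 1.5, 2.5):
        cfg = PipelineConfig(mfei_min=threshold)
        count = sum(
            1
            for prec, off, ln in candidates
            if (c := evaluate_window(prec, off, ln, cfg)) is not None and c.passed
        )
        accepted.append(count)
    assert accepted == sorted(accepted, reverse=True)


# --- hairpin construction contracts --------------------------------------


def test_build_hairpin_refuses_bad_mature_length():
    with pytest.raises(ValueError):
        build_hairpin(RNG, "ACGTACGTACGTACGT", 0)  # 16 nt


def test_build_hairpin_refuses_seven_star_mismatches():
    with pytest.raises(ValueError):
        build_hairpin(RNG, MATURE, 7)


def test_star_is_near_reverse_complement():
    rng = np.random.default_rng(9)
    precursor, star, arm, m_off, s_off = build_hairpin(rng, MATURE, 3)
    diff = sum(a != b for a, b in zip(star, revcomp(MATURE)))
    assert diff == 3


# --- discover_novel -------------------------------------------------------


def _genome_with_hairpins(hairpins, seed=10):
    rng = np.random.default_rng(seed)
    parts = []
    for precursor in hairpins:
        parts.append("".join(rng.choice(list("ACGT"), 400)))
        parts.append(precursor)
    parts.append("".join(rng.choice(list("ACGT"), 400)))
    return {"chr1": "".join(parts)}


def test_discovery_recovers_planted_hairpin_and_star_flag():
    mature, precursor, m_off = compliant_hairpin(seed=6, mismatches=1)
    genome = _genome_with_hairpins([precursor])
    index = GenomeIndex(genome, k=18)
    # star tag: the candidate's own star region sequence, observed in data
    cand = evaluate_window(precursor, m_off, len(mature))
    s_lo, s_hi = cand.star_span
    star_tag = precursor[s_lo : s_hi + 1]
    leftover = pd.DataFrame(
        {"fetal": [8, 2], "adult": [6, 1]}, index=[mature, star_tag]
    )
    result = discover_novel(leftover, index, genome)
    assert len(result.novel) == 1
    rec = result.novel[0]
    assert rec.mature == mature
    assert rec.candidate.star_observed and rec.high_confidence
    assert rec.counts == {"fetal": 8, "adult": 6}
    assert result.overlap == {rec.novel_id}
    # idempotent audit: the accepted candidate re-passes the evaluator
    c = rec.candidate
    again = evaluate_candidate(c.precursor, c.structure, c.mfe, c.mature_span)
    assert again.passed


def test_tag_with_too_many_genome_hits_excluded():
    mature, precursor, m_off = compliant_hairpin(seed=7)
    genome = _genome_with_hairpins([precursor] * 11, seed=11)
    index = GenomeIndex(genome, k=18)
    leftover = pd.DataFrame({"fetal": [50], "adult": [50]}, index=[mature])
    result = discover_novel(leftover, index, genome)
    assert result.novel == [] and result.candidates == []


def test_low_read_clusters_not_evaluated():
    mature, precursor, m_off = compliant_hairpin(seed=8)
    genome = _genome_with_hairpins([precursor], seed=12)
    index = GenomeIndex(genome, k=18)
    leftover = pd.DataFrame({"fetal": [2], "adult": [1]}, index=[mature])
    result = discover_novel(leftover, index, genome)  # 3 reads < 5
    assert result.candidates == []


def test_hairpin_in_both_libraries_appears_once_in_overlap():
    mature, precursor, m_off = compliant_hairpin(seed=9)
    genome = _genome_with_hairpins([precursor], seed=13)
    index = GenomeIndex(genome, k=18)
    leftover = pd.DataFrame({"fetal": [10], "adult": [10]}, index=[mature])
    result = discover_novel(leftover, index, genome)
    assert len(result.novel) == 1
    assert result.overlap == {result.novel[0].novel_id}
    assert len(result.per_library["fetal"] & result.per_library["adult"]) == 1
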