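"""Small sequence helpers shared across the pipeline.

The internal canonical alphabet is DNA (ACGT); RNA input (U) is normalised
on the way in, and U is only re-introduced for display (nucleotide-bias
tables use the RNA alphabet because mature miRNAs are RNA).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert U->T so tags compare in one alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def au_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = normalize_seq(seq)
    return (s.count("A") + s.count("T")) / len(s)


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded to `ndigits`, as printed in summary tables."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)
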