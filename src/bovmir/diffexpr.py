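"""Count-based differential expression between two sequencing libraries.

Expression is normalised to transcripts per million clean reads
(NE = count / total x 1e6).  Fold change is log2(NE1 / NE2) with a small
pseudo-TPM substituted for zeros in the ratio only.  Significance uses
the exact conditional test for digital expression data (Audic-Claverie
style): given x reads in library 1 (depth N1), the count y in library 2
(depth N2) follows

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative-binomial mass normalised over y.  The lower tail
C = sum_{k<=y} p(k|x) and upper tail D = sum_{k>=y} p(k|x) = 1 - C(y-1)
give the two-sided p-value 2*min(C, D), capped at 1.  All masses are
evaluated in log-gamma space, so large counts do not overflow.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig


def normalize(count: int, total: int) -> float:
    """Normalized expression in transcripts per million clean reads."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total * 1e6


def ratio_ne(count: int, total: int, pseudo_tpm: float = 0.01) -> float:
    """NE with the zero-count pseudo-TPM applied (for ratios only)."""
    ne = normalize(count, total)
    return ne if ne > 0 else pseudo_tpm

def fold_change(ne1: float, ne2: float) -> float:
    """log2(NE1/NE2); inputs must already carry the pseudo-count."""
    if ne1 <= 0 or ne2 <= 0:
        raise ValueError("fold change needs positive (pseudo-counted) NEs")
    return math.log2(ne1 / ne2)


def _log_pmf(ks: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    r = n2 / n1
    return (
        ks * math.log(r)
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * math.log1p(r)
    )


def conditional_log_pmf(y: int, x: int, n1: float, n2: float) -> float:
    """log p(y | x) of the conditional count distribution."""
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    return float(_log_pmf(np.array([y], dtype=float), int(x), n1, n2)[0])


def _upper_tail(y: int, x: int, n1: float, n2: float) -> float:
    """P(k >= y | x) by chunked summation until the tail is negligible."""
    log_total = -np.inf
    start = y
    chunk = 256
    while True:
        ks = np.arange(start, start + chunk, dtype=float)
        log_chunk = float(logsumexp(_log_pmf(ks, x, n1, n2)))
        log_total = float(np.logaddexp(log_total, log_chunk))
        if log_chunk < log_total + math.log(1e-18):
            break
        start += chunk
        chunk = min(chunk * 2, 1 << 16)
    return float(np.exp(log_total))


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value for observing counts (x, y) at depths (N1, N2).

    Two-sided p = 2 * min(C, D) capped at 1, where C = P(k <= y | x) and
    D = P(k >= y | x); both tails include the observed count.
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    ks = np.arange(0, y + 1, dtype=float)
    logs = _log_pmf(ks, x, n1, n2)
    c = float(np.exp(logsumexp(logs)))  # P(k <= y)
    c_below = float(np.exp(logsumexp(logs[:-1]))) if y > 0 else 0.0
    if c_below < 0.5:
        d = 1.0 - c_below  # normalisation identity; accurate when D is large
    else:
        # sum the upper tail directly: 1 - C(y-1) would cancel to noise
        d = _upper_tail(y, x, n1, n2)
    return min(1.0, 2.0 * min(c, d))


def classify_expression(log2_fc: float) -> str:
    """Three-way fold-change class: 'up' (>2-fold), 'down' (<=1/2), else
    'unchanged' (the 1/2 boundary belongs to 'down')."""
    if log2_fc > 1.0:
        return "up"
    if log2_fc <= -1.0:
        return "down"
    return "unchanged"


def de_table(
    counts1: Mapping[str, int],
    counts2: Mapping[str, int],
    n1: int,
    n2: int,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-miRNA differential expression table, sorted by p-value.

    `counts1` / `counts2` map miRNA id to raw read count in the two
    libraries (library 1 first in the fold-change numerator); miRNAs
    absent from both are excluded.  Adjusted p-values use the configured
    multiple-testing method (Benjamini-Hochberg by default) and the
    significance flag is padj <= alpha.
    """
    cfg = config or PipelineConfig()
    ids = sorted(set(counts1) | set(counts2))
    rows = []
    for mid in ids:
        x = int(counts1.get(mid, 0))
        y = int(counts2.get(mid, 0))
        if x == 0 and y == 0:
            continue
        ne1 = normalize(x, n1)
        ne2 = normalize(y, n2)
        r1 = ratio_ne(x, n1, cfg.pseudo_tpm)
        r2 = ratio_ne(y, n2, cfg.pseudo_tpm)
        fc = fold_change(r1, r2)
        rows.append(
            {
                "mirna_id": mid,
                "x": x,
                "y": y,
                "NE1": ne1,
                "NE2": ne2,
                "log2_fc": fc,
                "p_value": audic_claverie_p(x, y, n1, n2),
                "class": classify_expression(fc),
            }
        )
    if not rows:
        raise ValueError("no miRNA observed in either library")
    df = pd.DataFrame(rows).set_index("mirna_id")
    _, padj, _, _ = multipletests(df["p_value"], method=cfg.padj_method)
    df["p_adj"] = padj
    df["significant"] = df["p_adj"] <= cfg.alpha
    return df.sort_values("p_value")


def de_summary(df: pd.DataFrame) -> pd.Series:
    sig = df[df["significant"]]
    return pd.Series(
        {
            "tested": len(df),
            "significant": len(sig),
            "up": int(((sig["class"] == "up")).sum()),
            "down": int(((sig["class"] == "down")).sum()),
        }
    )


def scatter_plot(df: pd.DataFrame, path: str) -> None:
    """Log-log scatter of NE in the two libraries, coloured by class
    (red: >2-fold up, blue: unchanged, green: <=1/2 down)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"up": "red", "unchanged": "blue", "down": "green"}
    fig, ax = plt.subplots(figsize=(5, 5))
    floor = 0.01
    for cls, sub in df.groupby("class"):
        ax.scatter(
            np.maximum(sub["NE2"], floor),
            np.maximum(sub["NE1"], floor),
            s=8,
            c=colors[cls],
            label=cls,
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("NE library 2 (TPM)")
    ax.set_ylabel("NE library 1 (TPM)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
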