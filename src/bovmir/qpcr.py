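"""Relative quantification of stem-loop qPCR data by the 2^-ddCt method.

Per (sample, target): dCt = mean Ct(target) - mean Ct(reference gene);
ddCt = dCt(sample) - dCt(calibrator sample); N = 2^-ddCt.  The calibrator
sample's N is exactly 1 for every detected target.  Ct values above the
detection cutoff (40 cycles by default) or missing are treated as
non-detected, never as N = 0.  No amplification-efficiency correction is
applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PipelineConfig

CT_COLUMNS = ("sample", "gene", "replicate", "ct")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _aggregate(df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Mean Ct and SD per (sample, gene), with outlier/usability flags."""
    usable = df[(df["ct"].notna()) & (df["ct"] > 0) & (df["ct"] <= cfg.max_ct)]
    rows = []
    for (sample, gene), grp in usable.groupby(["sample", "gene"]):
        cts = grp["ct"].to_numpy(dtype=float)
        if len(cts) < 2:
            warnings.warn(f"fewer than 2 usable replicates for {sample}/{gene}")
        median = float(np.median(cts))
        outliers = int(np.sum(np.abs(cts - median) > cfg.ct_outlier_cycles))
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "mean_ct": float(np.mean(cts)),
                "sd_ct": float(np.std(cts, ddof=1)) if len(cts) > 1 else 0.0,
                "n_replicates": len(cts),
                "outlier_replicates": outliers,
            }
        )
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    calibrator_sample: str,
    reference_gene: str | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Relative expression N = 2^-ddCt per (sample, target).

    Targets not detected in a sample (all replicates missing or beyond the
    Ct cutoff) are reported with N = NaN and detected = False.
    """
    cfg = config or PipelineConfig()
    ref = reference_gene or cfg.reference_gene
    agg = _aggregate(ct_table, cfg)
    if agg.empty:
        raise ValueError("no usable Ct measurements")
    samples = sorted(ct_table["sample"].unique())
    ref_ct = {
        row["sample"]: row["mean_ct"] for _, row in agg[agg["gene"] == ref].iterrows()
    }
    for sample in samples:
        if sample not in ref_ct:
            raise ValueError(f"reference gene {ref} not measured in sample {sample}")
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from table")

    targets = sorted(set(ct_table["gene"]) - {ref})
    agg_map = {(r["sample"], r["gene"]): r for _, r in agg.iterrows()}
    dct_cal = {}
    for target in targets:
        row = agg_map.get((calibrator_sample, target))
        dct_cal[target] = row["mean_ct"] - ref_ct[calibrator_sample] if row is not None else None

    rows = []
    for sample in samples:
        for target in targets:
            row = agg_map.get((sample, target))
            detected = row is not None
            dct = row["mean_ct"] - ref_ct[sample] if detected else np.nan
            if detected and dct_cal[target] is not None:
                ddct = dct - dct_cal[target]
                n = 2.0 ** (-ddct)
            else:
                ddct, n = np.nan, np.nan
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "mean_ct": row["mean_ct"] if detected else np.nan,
                    "sd_ct": row["sd_ct"] if detected else np.nan,
                    "delta_ct": dct,
                    "delta_delta_ct": ddct,
                    "relative_expression": n,
                    "detected": detected,
                    "outlier_replicates": row["outlier_replicates"] if detected else 0,
                }
            )
    return pd.DataFrame(rows)


def expression_barplot(result: pd.DataFrame, path: str) -> None:
    """Grouped bar plot of relative expression per target across samples."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = result.pivot(index="target", columns="sample", values="relative_expression")
    ax = pivot.plot.bar(figsize=(max(6, len(pivot) * 0.6), 4))
    ax.set_ylabel("relative expression (2^-ddCt)")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=100)
    plt.close(ax.figure)
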