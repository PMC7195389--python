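"""Differential HDX-MS at peptide level: summed uptake differences with a
confidence threshold and Wood's-plot classification.

For each peptide the deuterium-uptake difference between two states is summed
over all exposure timepoints; a peptide is called protected (deprotected) when
the summed difference falls below (above) the ±threshold set by a Student-t
confidence interval at 1−α.  The default threshold is global: per-timepoint
variances are pooled across peptides (the Houde/Deuteros convention), summed
in quadrature over timepoints, and scaled by the t quantile at the pooled
Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HdxError", "load_uptake", "woods_analysis", "woods_per_timepoint"]

REQUIRED_COLUMNS = ["start", "end", "sequence", "state", "exposure", "replicate", "uptake"]

PROTECTED, DEPROTECTED, NOT_SIGNIFICANT = "protected", "deprotected", "not significant"


class HdxError(ValueError):
    pass


def load_uptake(csv_content: str | pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format uptake table (DynamX-state-data-like).

    Columns: start, end, sequence, state, exposure (min), replicate, uptake
    (Da).  Rows with negative uptake are rejected with a message; cells with
    fewer than 2 replicates are reported (they are excluded from confidence
    intervals downstream).
    """
    if isinstance(csv_content, pd.DataFrame):
        df = csv_content.copy()
    else:
        df = pd.read_csv(io.StringIO(csv_content), skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise HdxError(f"uptake table missing column(s): {missing}")
    neg = df["uptake"] < 0
    if neg.any():
        warnings.warn(f"rejected {int(neg.sum())} row(s) with negative uptake")
        df = df[~neg]
    if (df["start"] > df["end"]).any():
        raise HdxError("peptide with start > end")
    counts = df.groupby(["start", "end", "state", "exposure"])["replicate"].count()
    low = counts[counts < 2]
    if len(low):
        warnings.warn(
            f"{len(low)} (peptide, state, time) cell(s) have < 2 replicates; "
            "they will be excluded from confidence intervals"
        )
    return df.reset_index(drop=True)


def _cell_stats(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby(["start", "end", "sequence", "exposure"])["uptake"]
    out = g.agg(mean="mean", var=lambda x: x.var(ddof=1), n="count").reset_index()
    return out


def woods_analysis(
    table: pd.DataFrame,
    state_a: str,
    state_b: str,
    alpha: float = 0.01,
    method: str = "global",
) -> pd.DataFrame:
    """Per-peptide summed uptake difference ΔD_sum = Σ_t (mean_B − mean_A) with
    a 1−α significance threshold and protected/deprotected classification.

    Sign convention: state B is the ligand-bound state, so negative ΔD_sum
    means protection upon binding.  ``method="global"`` (default) pools
    per-timepoint variances across peptides for one common threshold;
    ``method="perpeptide"`` uses each peptide's own Welch interval.
    Both states must share the peptide set and timepoints.
    """
    if method not in ("global", "perpeptide"):
        raise HdxError(f"unknown method {method!r}")
    if not (0 < alpha < 1):
        raise HdxError("alpha must be in (0, 1)")
    a = _cell_stats(table[table["state"] == state_a])
    b = _cell_stats(table[table["state"] == state_b])
    if a.empty or b.empty:
        raise HdxError(f"state(s) not found: {state_a!r} and/or {state_b!r}")
    keys = ["start", "end", "sequence", "exposure"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"), how="outer", indicator=True)
    asym = merged[merged["_merge"] != "both"]
    if len(asym):
        cells = asym[keys].to_dict("records")
        raise HdxError(f"states have mismatched peptide/timepoint cells: {cells[:5]}")
    merged = merged.drop(columns="_merge")
    # cells with < 2 replicates cannot contribute a variance
    merged.loc[merged["n_a"] < 2, "var_a"] = np.nan
    merged.loc[merged["n_b"] < 2, "var_b"] = np.nan
    merged["se2"] = merged["var_a"] / merged["n_a"] + merged["var_b"] / merged["n_b"]

    grouped = merged.groupby(["start", "end", "sequence"], sort=True)
    rows = []
    for (start, end, seq), grp in grouped:
        dd_sum = float((grp["mean_b"] - grp["mean_a"]).sum())
        se = float(np.sqrt(np.nansum(grp["se2"]))) if grp["se2"].notna().any() else np.nan
        rows.append(
            {"start": start, "end": end, "sequence": seq, "dd_sum": dd_sum, "se": se}
        )
    result = pd.DataFrame(rows)

    if method == "global":
        # pooled per-timepoint variances across peptides, quadrature over times
        pooled = merged.groupby("exposure").agg(
            va=("var_a", "mean"), vb=("var_b", "mean"),
            na=("n_a", "mean"), nb=("n_b", "mean"),
        )
        se2_sum = float((pooled["va"] / pooled["na"] + pooled["vb"] / pooled["nb"]).sum())
        # Welch-Satterthwaite df aggregated over all contributing cells
        fin = merged[np.isfinite(merged["se2"])]
        df_num = float(fin["se2"].sum())
        df_den = float(
            (
                (fin["var_a"] / fin["n_a"]) ** 2 / (fin["n_a"] - 1)
                + (fin["var_b"] / fin["n_b"]) ** 2 / (fin["n_b"] - 1)
            ).sum()
        )
        dof = df_num**2 / df_den if df_den > 0 else 1.0
        threshold = float(stats.t.ppf(1 - alpha / 2, dof) * np.sqrt(se2_sum))
        result["threshold"] = threshold
    else:
        # per-peptide Welch df
        thresholds = []
        for (start, end, seq), grp in grouped:
            se2 = np.nansum(grp["se2"])
            den = np.nansum(
                (grp["var_a"] / grp["n_a"]) ** 2 / (grp["n_a"] - 1)
                + (grp["var_b"] / grp["n_b"]) ** 2 / (grp["n_b"] - 1)
            )
            dof = se2**2 / den if den > 0 else 1.0
            thresholds.append(float(stats.t.ppf(1 - alpha / 2, dof) * np.sqrt(se2)))
        result["threshold"] = thresholds

    result["class"] = NOT_SIGNIFICANT
    result.loc[result["dd_sum"] < -result["threshold"], "class"] = PROTECTED
    result.loc[result["dd_sum"] > result["threshold"], "class"] = DEPROTECTED
    result.attrs["alpha"] = alpha
    result.attrs["method"] = method
    result.attrs["state_a"] = state_a
    result.attrs["state_b"] = state_b
    return result


def woods_per_timepoint(
    table: pd.DataFrame, state_a: str, state_b: str, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-timepoint uptake differences with a pooled confidence threshold.

    Companion to :func:`woods_analysis` (whose summed-difference
    classification is the headline result): one row per (peptide, exposure)
    with the difference mean_B − mean_A and a per-timepoint global threshold.
    """
    a = _cell_stats(table[table["state"] == state_a])
    b = _cell_stats(table[table["state"] == state_b])
    keys = ["start", "end", "sequence", "exposure"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged["dd"] = merged["mean_b"] - merged["mean_a"]
    merged["se2"] = merged["var_a"] / merged["n_a"] + merged["var_b"] / merged["n_b"]
    out = []
    for t, grp in merged.groupby("exposure"):
        se_pool = np.sqrt(np.nanmean(grp["se2"]))
        dof = max(float(((grp["n_a"] - 1) + (grp["n_b"] - 1)).sum()), 1.0)
        th = float(stats.t.ppf(1 - alpha / 2, dof) * se_pool)
        sub = grp[keys + ["dd"]].copy()
        sub["threshold"] = th
        sub["class"] = NOT_SIGNIFICANT
        sub.loc[sub["dd"] < -th, "class"] = PROTECTED
        sub.loc[sub["dd"] > th, "class"] = DEPROTECTED
        out.append(sub)
    return pd.concat(out, ignore_index=True)
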