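"""Per-protein two-group testing with FDR adjustment.

Differential NPX expression between the two sides of a contrast is tested
protein by protein with a two-sample t-test (pooled-variance Student by
default, Welch available as a sensitivity option) and the raw p-values are
adjusted with the Benjamini-Hochberg step-up procedure. The report mirrors
the published summary layout: group mean (SD) per side, adjusted p, and a
rank by ascending adjusted p with ties broken by raw p, then name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ContrastSpec, NpxMatrix, make_contrast


@dataclass(frozen=True)
class ProteinSummary:
    protein: str
    mean0: float
    sd0: float
    mean1: float
    sd1: float
    t: float
    p: float
    adj_p: float
    rank: int


def two_group_ttest(
    values0: np.ndarray, values1: np.ndarray, variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``student`` pools the variances (equal-variance assumption); ``welch``
    uses the Satterthwaite degrees of freedom. The sign convention is
    ``t = (mean0 - mean1) / SE``. Zero variance in both groups with equal
    means returns ``(0.0, 1.0)`` by convention.
    """

    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    v0 = np.asarray(values0, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    v0 = v0[np.isfinite(v0)]
    v1 = v1[np.isfinite(v1)]
    if len(v0) < 2 or len(v1) < 2:
        raise ValueError("each group needs at least 2 finite values")
    if v0.std(ddof=1) == 0 and v1.std(ddof=1) == 0:
        if v0.mean() == v1.mean():
            return 0.0, 1.0
        return (np.inf if v0.mean() > v1.mean() else -np.inf), 0.0
    res = stats.ttest_ind(v0, v1, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_expression(
    m: NpxMatrix,
    contrast: ContrastSpec,
    report_threshold: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-protein differential-expression summary for one contrast.

    Tests every protein, adjusts across the full panel, ranks by adjusted p
    (ties by raw p, then protein name) and reports only rows with adjusted
    p below ``report_threshold``. Columns: ``protein, mean0, sd0, mean1,
    sd1, t, p, adj_p, rank``.
    """

    sub, labels = make_contrast(m, contrast)
    g0 = sub.values.loc[labels == 0]
    g1 = sub.values.loc[labels == 1]
    rows = []
    for prot in sub.proteins:
        t, p = two_group_ttest(g0[prot].to_numpy(), g1[prot].to_numpy(), variant)
        rows.append(
            {
                "protein": prot,
                "mean0": g0[prot].mean(),
                "sd0": g0[prot].std(ddof=1),
                "mean1": g1[prot].mean(),
                "sd1": g1[prot].std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["adj_p", "p", "protein"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.loc[df["adj_p"] < report_threshold].reset_index(drop=True)


def format_expression_table(df: pd.DataFrame) -> pd.DataFrame:
    """Render a :func:`summarize_expression` frame in the published layout:
    ``protein, group0 'mean (sd)', group1 'mean (sd)', adj p, rank``."""

    out = pd.DataFrame()
    out["protein"] = df["protein"]
    out["group0_mean_sd"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(df["mean0"], df["sd0"])
    ]
    out["group1_mean_sd"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(df["mean1"], df["sd1"])
    ]
    out["adj_p"] = ["<0.001" if p < 0.001 else f"{p:.3f}" for p in df["adj_p"]]
    out["rank"] = df["rank"]
    return out
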