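"""Per-feature differential-activity screen in CLR space.

For every feature a two-sided Mann-Whitney U test compares cases against
controls on the CLR-transformed values; p-values are Benjamini-Hochberg
adjusted within each feature table (species and KOs are screened as two
separate families). A feature is called significant when its BH q-value
is below ``alpha`` *and* the absolute case-minus-control difference of
CLR means is at least ``lfc_threshold`` (default ``ln 2``, i.e. a twofold
mean ratio).

The rank test is exact for small samples without ties (both groups <= 8)
and otherwise uses the tie-corrected normal approximation with midranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .compstats import ClrMatrix

LN2 = float(np.log(2.0))


@dataclass
class DiffResult:
    feature_id: str
    kind: str
    u_stat: float
    p_raw: float
    q_bh: float
    clr_mean_diff: float  # case minus control
    clr_median_diff: float
    direction: str  # "up" in cases or "down"
    significant: bool


def mwu(case_values: np.ndarray, control_values: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U statistic of the case group, p-value).

    Identical pooled values carry no rank information: p = 1 by convention.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one value")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    clr: ClrMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    lfc_threshold: float = LN2,
) -> pd.DataFrame:
    """Screen every feature of a CLR matrix for differential activity.

    ``labels`` maps sample id to "case"/"control". Returns one row per
    feature with U statistic, raw and BH-adjusted p, CLR mean and median
    differences (case - control), direction and the significance call.
    """
    labels = labels.reindex(clr.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples in the CLR matrix")
    is_case = (labels == "case").to_numpy()
    is_control = (labels == "control").to_numpy()
    if is_case.sum() < 2 or is_control.sum() < 2:
        raise ValueError("need at least 2 samples per class")

    X = clr.values
    case_X, ctrl_X = X[is_case], X[is_control]
    records = []
    for j, fid in enumerate(clr.feature_ids):
        u, p = mwu(case_X[:, j], ctrl_X[:, j])
        records.append((fid, u, p))
    p_raw = np.array([r[2] for r in records])
    q = bh_adjust(p_raw)
    mean_diff = case_X.mean(axis=0) - ctrl_X.mean(axis=0)
    median_diff = np.median(case_X, axis=0) - np.median(ctrl_X, axis=0)

    df = pd.DataFrame(
        {
            "feature_id": [r[0] for r in records],
            "kind": clr.kind,
            "u_stat": [r[1] for r in records],
            "p_raw": p_raw,
            "q_bh": q,
            "clr_mean_diff": mean_diff,
            "clr_median_diff": median_diff,
        }
    )
    df["direction"] = np.where(df["clr_mean_diff"] >= 0, "up", "down")
    df["significant"] = (df["q_bh"] < alpha) & (df["clr_mean_diff"].abs() >= lfc_threshold)
    return df.set_index("feature_id")


def annotate_groups(
    results: pd.DataFrame,
    grouping: dict[str, tuple[str, ...]] | None,
    level_names: tuple[str, ...],
) -> pd.DataFrame:
    """Attach hierarchy columns (genus/phylum or KEGG levels) to a result
    table; with no mapping the columns are present but empty."""
    out = results.copy()
    for i, name in enumerate(level_names):
        if grouping is None:
            out[name] = ""
        else:
            out[name] = [
                grouping.get(f, ("unmapped",) * len(level_names))[i] for f in out.index
            ]
    return out
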