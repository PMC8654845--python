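"""Compositional transforms and alpha-diversity descriptors.

Relative-activity vectors are compositions: only ratios between features
carry information. All ratio work here goes through the centered log-ratio
(CLR) transform, ``clr(x)_i = ln(x_i / g(x))`` with ``g`` the geometric
mean, after zeros are imputed by multiplicative replacement. Natural log
is fixed by convention so that a twofold ratio corresponds to a CLR
difference of ``ln 2 ~= 0.69``; it is deliberately not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _skbio_multi_replace

from .tables import FeatureTable

#: Default multiplicative-replacement delta: this fraction of the smallest
#: observed nonzero relative activity in the table.
DELTA_SHRINK = 0.65


@dataclass
class ClrMatrix:
    """Zero-imputed, CLR-transformed feature table (natural-log units)."""

    data: pd.DataFrame
    kind: str
    delta_used: float

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("CLR matrix must be finite (impute zeros first)")
        if len(vals) and np.abs(vals.sum(axis=1)).max() > 1e-6:
            raise ValueError("CLR rows must sum to 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class DiversitySummary:
    """Per-sample richness, Shannon (nats), inverse Simpson and Pielou evenness."""

    richness: pd.Series
    shannon: pd.Series
    inv_simpson: pd.Series
    pielou: pd.Series  # NaN where richness < 2 (evenness undefined)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "richness": self.richness,
                "shannon": self.shannon,
                "inv_simpson": self.inv_simpson,
                "pielou": self.pielou,
            }
        )


def multiplicative_replacement(row: np.ndarray, delta: float) -> np.ndarray:
    """Impute zeros in a composition: zeros become ``delta``, nonzeros are
    scaled by ``1 - z * delta`` (``z`` = number of zeros) so the output is
    closed to 1 and nonzero ratios are preserved.
    """
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("composition must be non-negative")
    total = row.sum()
    if total <= 0:
        raise ValueError("composition must have positive sum")
    row = row / total
    z = int(np.count_nonzero(row == 0))
    if z == 0:
        return row
    if delta * z >= 1:
        raise ValueError(f"delta={delta} with {z} zeros would exceed total mass 1")
    return np.asarray(_skbio_multi_replace(row, delta=delta), dtype=float).reshape(-1)


def clr(row: np.ndarray) -> np.ndarray:
    """Centered log-ratio of a strictly positive composition (natural log)."""
    row = np.asarray(row, dtype=float)
    if (row <= 0).any():
        raise ValueError("CLR requires strictly positive entries; impute zeros first")
    return _skbio_clr(row)


def default_delta(values: np.ndarray) -> float:
    """Delta for a whole table: DELTA_SHRINK x smallest nonzero relative activity."""
    values = np.asarray(values, dtype=float)
    rel = values / values.sum(axis=1, keepdims=True)
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero entries")
    return DELTA_SHRINK * float(nz.min())


def clr_transform(table: FeatureTable, delta: float | None = None) -> ClrMatrix:
    """Close rows to 1, impute zeros, and CLR-transform a feature table.

    ``delta`` defaults to :func:`default_delta` of the table (0.65 x the
    smallest observed nonzero relative activity).
    """
    rel = table.to_relative()
    vals = rel.values
    if delta is None:
        delta = default_delta(vals)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = clr(multiplicative_replacement(vals[i], delta))
    df = pd.DataFrame(out, index=rel.data.index, columns=rel.data.columns)
    return ClrMatrix(df, kind=rel.kind.value, delta_used=float(delta))


def richness(row: np.ndarray) -> int:
    """Number of strictly positive entries."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("activities must be non-negative")
    return int(np.count_nonzero(row > 0))


def diversity_row(row: np.ndarray) -> tuple[int, float, float, float]:
    """(richness, Shannon in nats, inverse Simpson, Pielou) for one
    relative-activity row. Pielou is NaN when richness < 2."""
    row = np.asarray(row, dtype=float)
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValueError("diversity expects a relative-activity row summing to 1")
    p = row[row > 0]
    r = int(p.size)
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p**2).sum())
    pielou = shannon / np.log(r) if r >= 2 else float("nan")
    return r, shannon, inv_simpson, pielou


def diversity(table: FeatureTable) -> DiversitySummary:
    """Per-sample diversity summary of a (relative) feature table."""
    rel = table.to_relative()
    rows = [diversity_row(v) for v in rel.values]
    idx = rel.data.index
    arr = np.array(rows, dtype=float)
    return DiversitySummary(
        richness=pd.Series(arr[:, 0].astype(int), index=idx, name="richness"),
        shannon=pd.Series(arr[:, 1], index=idx, name="shannon"),
        inv_simpson=pd.Series(arr[:, 2], index=idx, name="inv_simpson"),
        pielou=pd.Series(arr[:, 3], index=idx, name="pielou"),
    )


def describe_groups(table: FeatureTable, labels: pd.Series) -> pd.DataFrame:
    """Group-wise descriptive summary (richness/diversity medians and means
    per label, with two-sided Mann-Whitney p-values between groups)."""
    from scipy.stats import mannwhitneyu

    summ = diversity(table).frame()
    labels = labels.reindex(summ.index)
    out = []
    for col in summ.columns:
        rec: dict[str, object] = {"metric": col}
        groups = {}
        for lab, sub in summ.groupby(labels)[col]:
            sub = sub.dropna()
            groups[lab] = sub.to_numpy()
            rec[f"{lab}_median"] = float(np.median(sub)) if len(sub) else float("nan")
            rec[f"{lab}_mean"] = float(np.mean(sub)) if len(sub) else float("nan")
        if len(groups) == 2:
            a, b = (groups[k] for k in sorted(groups))
            if len(a) and len(b):
                rec["mwu_p"] = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out.append(rec)
    return pd.DataFrame(out).set_index("metric")
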