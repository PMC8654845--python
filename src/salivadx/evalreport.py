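"""Classifier performance metrics and structured reports.

ROC/AUC, confusion counts at the clinical decision threshold,
sensitivity and specificity with exact Clopper-Pearson intervals,
per-stage detection tallies, PCA on the top-|coefficient| signature
features, interference (paired-sample) robustness, and hierarchy
grouping of feature-level outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        if self.n_cases == 0:
            return float("nan")
        return self.tp / self.n_cases

    @property
    def specificity(self) -> float:
        if self.n_controls == 0:
            return float("nan")
        return self.tn / self.n_controls


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("TPR/FPR must be non-decreasing along the curve")
        area = float(np.trapezoid(self.tpr, self.fpr))
        if abs(area - self.auc) > 1e-9:
            raise ValueError("AUC does not match the trapezoidal area of the curve")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Beta-quantile form: lower = Beta(alpha/2; k, n-k+1),
    upper = Beta(1-alpha/2; k+1, n-k); lower is exactly 0 when k=0 and
    upper exactly 1 when k=n.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC (midrank tie handling; AUC equals the normalised
    Mann-Whitney U statistic)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def confusion(probabilities: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    """Confusion counts with the strict rule: case iff p > threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = p > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        threshold=float(threshold),
    )


def sens_spec(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    level: float = 0.95,
) -> tuple[ConfusionCounts, dict, dict]:
    """Sensitivity and specificity at a threshold, each with its exact
    Clopper-Pearson interval. Zero-denominator metrics come back NaN with
    ``defined=False`` rather than raising."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cc = confusion(probabilities, labels, threshold)
    return cc, _proportion(cc.tp, cc.n_cases, level), _proportion(cc.tn, cc.n_controls, level)


def _proportion(k: int, n: int, level: float) -> dict:
    if n == 0:
        return {"estimate": float("nan"), "lower": float("nan"),
                "upper": float("nan"), "k": k, "n": n, "defined": False}
    lo, hi = clopper_pearson(k, n, level)
    return {"estimate": k / n, "lower": lo, "upper": hi, "k": k, "n": n, "defined": True}


def per_stage_sensitivity(
    probabilities: pd.Series,
    labels: pd.Series,
    stages: pd.Series,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Detected/total tally per lesion stage at the decision threshold.

    Only cases enter; cases with stage "none"/missing are reported in an
    explicit "unstaged" bucket, never forced into a stage. Stages with no
    cases appear as 0/0 with ``defined=False``.
    """
    labels = labels.reindex(probabilities.index)
    stages = stages.reindex(probabilities.index)
    is_case = labels == "case"
    stage_vals = stages.where(is_case).fillna("none")
    stage_vals = stage_vals.where(stage_vals != "none", "unstaged")
    detected = probabilities > threshold
    rows = []
    for stage in ["OPMD", "S1", "S2", "S3", "S4", "unstaged"]:
        in_stage = is_case & (stage_vals == stage)
        total = int(in_stage.sum())
        det = int((detected & in_stage).sum())
        rows.append(
            {
                "stage": stage,
                "detected": det,
                "total": total,
                "sensitivity": det / total if total else float("nan"),
                "defined": total > 0,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def pca_top_features(
    clr_joined: pd.DataFrame,
    coefficients: pd.Series,
    k: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA on the k features with the largest absolute final-model
    coefficients. Returns per-sample coordinates and the fraction of
    variance explained per component."""
    if k > len(coefficients):
        raise ValueError(f"k={k} exceeds the {len(coefficients)} available features")
    top = coefficients.abs().sort_values(ascending=False).index[:k]
    X = clr_joined[list(top)].to_numpy(dtype=float)
    n_comp = min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=clr_joined.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def interference_delta(
    probabilities: pd.Series, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-subject |probability change| between the baseline sample and
    each interference sample. Subjects without a baseline are skipped."""
    meta = metadata.reindex(probabilities.index)
    rows = []
    for subject, grp in meta.groupby("subject_id"):
        base = grp.index[grp["interference"] == "none"]
        if len(base) == 0:
            continue
        p0 = float(probabilities[base[0]])
        for sid in grp.index[grp["interference"] != "none"]:
            rows.append(
                {
                    "subject_id": subject,
                    "interference": meta.loc[sid, "interference"],
                    "baseline_probability": p0,
                    "perturbed_probability": float(probabilities[sid]),
                    "delta": abs(float(probabilities[sid]) - p0),
                }
            )
    df = pd.DataFrame(rows)
    summary = {
        "n_pairs": len(df),
        "mean_delta": float(df["delta"].mean()) if len(df) else float("nan"),
        "max_delta": float(df["delta"].max()) if len(df) else float("nan"),
    }
    return df, summary


def group_by_hierarchy(
    results: pd.DataFrame,
    mapping: dict[str, tuple[str, ...]],
    level_names: tuple[str, ...],
    value_column: str,
) -> pd.DataFrame:
    """Aggregate a feature-level result table along a hierarchy.

    ``mapping`` sends feature id to a tuple of labels, one per level name
    (e.g. species -> (genus, phylum), or KO -> (level3, level2)). Features
    absent from the map fall into an "unmapped" bucket; grouped totals of
    ``value_column`` equal the ungrouped total.
    """
    ann = results.copy()
    for i, name in enumerate(level_names):
        ann[name] = [
            mapping.get(f, ("unmapped",) * len(level_names))[i] for f in ann.index
        ]
    grouped = (
        ann.groupby(list(level_names))[value_column]
        .agg(["sum", "count"])
        .rename(columns={"sum": f"{value_column}_sum", "count": "n_features"})
        .reset_index()
    )
    return grouped


@dataclass
class PredictionReport:
    """Everything the evaluation emits, JSON-serialisable via as_dict()."""

    probabilities: pd.Series
    confusion: ConfusionCounts
    roc: RocCurve
    sensitivity: dict
    specificity: dict
    per_stage: pd.DataFrame
    subgroups: dict = field(default_factory=dict)
    interference: dict = field(default_factory=dict)
    schema_version: str = "1"

    def as_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "probabilities": {str(k): float(v) for k, v in self.probabilities.items()},
            "threshold": self.confusion.threshold,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
            },
            "auc": self.roc.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_stage": self.per_stage.reset_index().to_dict(orient="records"),
            "subgroups": self.subgroups,
            "interference": self.interference,
        }


def build_report(
    probabilities: pd.Series,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
    level: float = 0.95,
) -> PredictionReport:
    """Assemble the full report from per-sample probabilities and metadata
    (columns: label, stage, sex, smoking, and optionally subject_id +
    interference)."""
    meta = metadata.reindex(probabilities.index)
    if meta["label"].isna().any():
        raise ValueError("metadata missing for some predicted samples")
    y = (meta["label"] == "case").astype(int).to_numpy()
    p = probabilities.to_numpy(dtype=float)
    cc, sens, spec = sens_spec(p, y, threshold, level)
    roc = roc_auc(p, y) if len(np.unique(y)) == 2 else None
    stage_df = per_stage_sensitivity(probabilities, meta["label"], meta["stage"], threshold)

    subgroups: dict = {}
    for col in ("sex", "smoking"):
        if col in meta.columns:
            subgroups[col] = {
                str(k): {
                    "n": int(len(g)),
                    "mean_probability": float(np.mean(g)),
                    "median_probability": float(np.median(g)),
                }
                for k, g in probabilities.groupby(meta[col])
            }

    interference: dict = {}
    if "interference" in meta.columns and (meta["interference"] != "none").any():
        _, interference = interference_delta(probabilities, meta)

    if roc is None:
        raise ValueError("report requires both classes present")
    return PredictionReport(
        probabilities=probabilities,
        confusion=cc,
        roc=roc,
        sensitivity=sens,
        specificity=spec,
        per_stage=stage_df,
        subgroups=subgroups,
        interference=interference,
    )
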