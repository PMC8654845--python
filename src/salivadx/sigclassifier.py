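"""Bootstrap-stability-selected L2 logistic classifier with LOOCV.

Pipeline (all in CLR space, species and KO matrices concatenated
column-wise after separate closure):

1. drop features whose variance falls below the 25th percentile of all
   per-feature variances (a single global pre-pass by default);
2. leave-one-out cross-validation: for each held-out sample, resample the
   training set B times with replacement (stratified by class), fit an
   L2-penalised logistic model on every resample, and keep the features
   whose empirical 95% bootstrap CI of the coefficient excludes zero;
3. fit the fold model on the selected features and record the held-out
   probability;
4. the *signature* is the intersection of the per-fold selections; a
   final logistic model restricted to the signature is fit on all samples
   and exported.

The B bootstrap fits inside each fold share one design matrix, so they
are solved jointly: a resample is encoded as per-sample multinomial count
weights and the B independent penalised log-likelihoods are summed into a
single L-BFGS problem (two matrix products per iteration). This is the
same estimator as scikit-learn's ``LogisticRegression(C=l2_strength)``
with sample weights — the tests pin the two against each other — just
batched. Per-fold and final models use scikit-learn directly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

from .compstats import ClrMatrix

MIN_BOOTSTRAP = 20

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the diagnostic model.

    ``l2_strength`` is the inverse regularisation strength (scikit-learn's
    ``C``); 1.0 by default. ``variance_filter_scope`` is "global" (one
    pre-pass on the full matrix) or "per_fold" (recomputed on each
    training set, avoiding the mild leakage of the global pass).
    """

    l2_strength: float = 1.0
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    variance_percentile: float = 25.0
    decision_threshold: float = 0.5
    seed: int = 0
    variance_filter_scope: str = "global"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 <= self.variance_percentile < 100:
            raise ValueError("variance_percentile must be in [0, 100)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        if self.variance_filter_scope not in ("global", "per_fold"):
            raise ValueError("variance_filter_scope must be 'global' or 'per_fold'")


@dataclass
class FoldArtifacts:
    held_out_sample_id: str
    selected_features: frozenset[str]
    probability: float
    degenerate: bool = False  # True when no feature was selected


@dataclass
class Signature:
    """The stable feature set plus the final exported model."""

    feature_ids: list[str]
    coefficients: pd.Series
    intercept: float
    n_species: int
    n_kos: int


def variance_filter(clr: ClrMatrix | pd.DataFrame, percentile: float) -> list[str]:
    """Feature ids whose variance is >= the given percentile of all
    per-feature variances (strictly-below features are dropped; boundary
    ties are kept, so equal variances retain everything)."""
    df = clr.data if isinstance(clr, ClrMatrix) else clr
    if df.shape[0] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    variances = df.var(axis=0, ddof=1).to_numpy()
    if percentile == 0:
        return list(df.columns)
    cutoff = np.percentile(variances, percentile)
    keep = variances >= cutoff
    return list(df.columns[keep])


def _as_pm1(labels: np.ndarray) -> np.ndarray:
    y = np.where(np.asarray(labels).astype(bool), 1.0, -1.0)
    return y


def fit_logistic_batch(
    X: np.ndarray,
    y01: np.ndarray,
    counts: np.ndarray,
    C: float,
    tol: float = 1e-7,
    max_iter: int = 1000,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit B weighted L2 logistic regressions sharing one design matrix.

    ``counts`` is (B, n) non-negative sample weights (a bootstrap resample
    is its multinomial count vector). Minimises, for each replicate b,

        sum_i counts[b,i] * log(1 + exp(-y_i (x_i . w_b + c_b)))
        + ||w_b||^2 / (2 C)

    (intercept unpenalised), all replicates in one L-BFGS problem since
    the objective is separable. The problem is strictly convex, so the
    optional warm start ``w0`` (shape (p+1, B), e.g. the previous LOOCV
    fold's solution) changes only the iteration count, not the optimum.
    Returns (coefs (B, p), intercepts (B,)).
    """
    X = np.asarray(X, dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n, p = X.shape
    B = counts.shape[0]
    y = _as_pm1(y01)
    Xa = np.hstack([X, np.ones((n, 1))])
    CT = counts.T  # (n, B)
    lam = 1.0 / C

    def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
        W = flat.reshape(p + 1, B)
        Z = Xa @ W  # (n, B)
        M = -y[:, None] * Z
        loss = float(np.sum(CT * np.logaddexp(0.0, M)))
        penalty = 0.5 * lam * float(np.sum(W[:p] ** 2))
        S = 1.0 / (1.0 + np.exp(-M))  # sigma(-y z)
        G = CT * (-y[:, None]) * S  # d loss / d Z
        grad = Xa.T @ G
        grad[:p] += lam * W[:p]
        return loss + penalty, grad.ravel()

    if w0 is None:
        x0 = np.zeros((p + 1) * B)
    else:
        if w0.shape != (p + 1, B):
            raise ValueError("w0 must have shape (n_features + 1, n_replicates)")
        x0 = w0.ravel().copy()
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    W = res.x.reshape(p + 1, B)
    return W[:p].T, W[p]


def _stratified_bootstrap_counts(
    y01: np.ndarray, n_bootstrap: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, n) multinomial count weights resampling each class separately,
    so every draw contains both classes."""
    n = len(y01)
    counts = np.zeros((n_bootstrap, n))
    for cls in (0, 1):
        idx = np.flatnonzero(np.asarray(y01) == cls)
        k = len(idx)
        counts[:, idx] = rng.multinomial(k, np.full(k, 1.0 / k), size=n_bootstrap)
    return counts


def _bootstrap_coefs(
    train: pd.DataFrame,
    y01: np.ndarray,
    cfg: ClassifierConfig,
    rng: np.random.Generator,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    counts = _stratified_bootstrap_counts(y01, cfg.n_bootstrap, rng)
    coefs, intercepts = fit_logistic_batch(
        train.to_numpy(), y01, counts, C=cfg.l2_strength, w0=w0
    )
    return coefs, intercepts


def _ci_select(coefs: np.ndarray, columns, ci_level: float) -> list[str]:
    tail = 100.0 * (1.0 - ci_level) / 2.0
    lo = np.percentile(coefs, tail, axis=0)
    hi = np.percentile(coefs, 100.0 - tail, axis=0)
    keep = (lo > 0) | (hi < 0)
    return list(columns[keep])


def bootstrap_select(
    train: pd.DataFrame,
    train_labels: np.ndarray,
    cfg: ClassifierConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Features whose bootstrap coefficient CI excludes zero.

    Resamples the training set ``cfg.n_bootstrap`` times (stratified by
    class), fits the L2 logistic model on all columns each time, and keeps
    features whose empirical ``[(1-ci)/2, 1-(1-ci)/2]`` percentile interval
    of the coefficient does not cross zero.
    """
    if cfg.n_bootstrap < MIN_BOOTSTRAP:
        raise ValueError(
            f"n_bootstrap={cfg.n_bootstrap} gives a degenerate CI; need >= {MIN_BOOTSTRAP}"
        )
    y01 = np.asarray(train_labels).astype(int)
    if len(np.unique(y01)) < 2:
        raise ValueError("both classes must be present in the training labels")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 51349]))
    coefs, _ = _bootstrap_coefs(train, y01, cfg, rng)
    return _ci_select(coefs, train.columns, cfg.ci_level)


def _sklearn_fit(X: np.ndarray, y01: np.ndarray, C: float) -> LogisticRegression:
    # default penalty is l2; C is the inverse regularisation strength
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-8)
    model.fit(X, y01)
    return model


def join_clr(species_clr: ClrMatrix, ko_clr: ClrMatrix) -> pd.DataFrame:
    """Concatenate the two CLR matrices column-wise over shared samples."""
    if list(species_clr.sample_ids) != list(ko_clr.sample_ids):
        raise ValueError("species and KO CLR matrices must share sample order")
    overlap = set(species_clr.feature_ids) & set(ko_clr.feature_ids)
    if overlap:
        raise ValueError(f"feature id collision between tables: {sorted(overlap)[:5]}")
    return pd.concat([species_clr.data, ko_clr.data], axis=1)


def _fold_rng(cfg: ClassifierConfig, fold: int) -> np.random.Generator:
    # independent, reproducible stream per fold
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729, fold]))


def loocv(
    species_clr: ClrMatrix,
    ko_clr: ClrMatrix,
    labels: pd.Series,
    cfg: ClassifierConfig,
) -> tuple[list[FoldArtifacts], list[str]]:
    """Leave-one-out cross-validation with per-fold bootstrap selection.

    Returns the per-fold artifacts (held-out probability + selected
    feature set) and the signature feature list: the intersection of the
    selections of all non-degenerate folds, in joined-matrix column order.
    The held-out sample never enters its fold's variance filter (when
    per-fold), bootstrap selection, or model fit.
    """
    joined = join_clr(species_clr, ko_clr)
    labels = labels.reindex(joined.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y01 = (labels == "case").astype(int).to_numpy()
    if y01.sum() < 2 or (1 - y01).sum() < 2:
        raise ValueError("need at least 2 samples per class")

    if cfg.variance_filter_scope == "global":
        global_keep = variance_filter(joined, cfg.variance_percentile)

    artifacts: list[FoldArtifacts] = []
    intersection: set[str] | None = None
    warm: tuple[list[str], np.ndarray] | None = None  # (columns, W) of last fold
    for i, sample_id in enumerate(joined.index):
        train_mask = np.ones(len(joined), dtype=bool)
        train_mask[i] = False
        train = joined.iloc[train_mask]
        y_train = y01[train_mask]
        if cfg.variance_filter_scope == "per_fold":
            keep = variance_filter(train, cfg.variance_percentile)
        else:
            keep = global_keep
        # warm-start the batch solve from the previous fold's optimum: the
        # objective is strictly convex, so this is purely an iteration saver
        t0 = time.perf_counter()
        w0 = warm[1] if warm is not None and warm[0] == keep else None
        coefs, intercepts = _bootstrap_coefs(
            train[keep], y_train, cfg, _fold_rng(cfg, i), w0=w0
        )
        warm = (keep, np.vstack([coefs.T, intercepts[None, :]]))
        selected = _ci_select(coefs, train[keep].columns, cfg.ci_level)
        if selected:
            model = _sklearn_fit(train[selected].to_numpy(), y_train, cfg.l2_strength)
            prob = float(model.predict_proba(joined.iloc[[i]][selected].to_numpy())[0, 1])
            degenerate = False
            intersection = (
                set(selected) if intersection is None else intersection & set(selected)
            )
        else:
            prob = float(y_train.mean())  # intercept-only fallback
            degenerate = True
        artifacts.append(
            FoldArtifacts(
                held_out_sample_id=str(sample_id),
                selected_features=frozenset(selected),
                probability=prob,
                degenerate=degenerate,
            )
        )
        logger.debug(
            "loocv fold=%d held_out=%s n_filtered=%d n_selected=%d "
            "probability=%.4f elapsed=%.2fs",
            i, sample_id, len(keep), len(selected), prob,
            time.perf_counter() - t0,
        )
    signature = [] if intersection is None else [f for f in joined.columns if f in intersection]
    return artifacts, signature


def fit_final(
    species_clr: ClrMatrix,
    ko_clr: ClrMatrix,
    labels: pd.Series,
    signature_features: list[str],
    cfg: ClassifierConfig,
) -> Signature:
    """Fit the exported model: one L2 logistic fit on all samples,
    restricted to the signature features."""
    if not signature_features:
        raise ValueError(
            "empty signature: no feature was selected in every fold; "
            "loosen ci_level or lower n_bootstrap variance"
        )
    joined = join_clr(species_clr, ko_clr)
    labels = labels.reindex(joined.index)
    y01 = (labels == "case").astype(int).to_numpy()
    model = _sklearn_fit(joined[signature_features].to_numpy(), y01, cfg.l2_strength)
    species_set = set(species_clr.feature_ids)
    n_sp = sum(1 for f in signature_features if f in species_set)
    return Signature(
        feature_ids=list(signature_features),
        coefficients=pd.Series(model.coef_[0], index=signature_features, name="coefficient"),
        intercept=float(model.intercept_[0]),
        n_species=n_sp,
        n_kos=len(signature_features) - n_sp,
    )


def predict(model: Signature, sample_clr_row: pd.Series) -> float:
    """Case probability for one CLR-transformed sample.

    The row must provide every signature feature; the decision rule is
    case iff probability strictly exceeds the threshold (ties -> control).
    """
    missing = [f for f in model.feature_ids if f not in sample_clr_row.index]
    if missing:
        raise KeyError(f"sample is missing signature features: {missing[:10]}")
    x = sample_clr_row[model.feature_ids].to_numpy(dtype=float)
    z = model.intercept + float(model.coefficients.to_numpy() @ x)
    return float(1.0 / (1.0 + np.exp(-z)))


def predict_table(model: Signature, clr_joined: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`predict` over the rows of a joined CLR matrix."""
    missing = [f for f in model.feature_ids if f not in clr_joined.columns]
    if missing:
        raise KeyError(f"table is missing signature features: {missing[:10]}")
    X = clr_joined[model.feature_ids].to_numpy(dtype=float)
    z = model.intercept + X @ model.coefficients.to_numpy()
    return pd.Series(1.0 / (1.0 + np.exp(-z)), index=clr_joined.index, name="probability")
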