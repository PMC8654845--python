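"""EM quantification of relative activities from ambiguous read mappings.

Reads that map to several references (strains, or genes sharing sequence)
are grouped into *read classes*: sets of reads compatible with the same
references at the same weights. Classes are sufficient statistics for the
mixture likelihood

    L(a) = sum_c n_c * log( sum_j w_cj * a_j )

where ``n_c`` is the class count, ``w_cj >= 0`` the compatibility weight of
class ``c`` for reference ``j`` and ``a`` the relative-activity simplex
vector. EM alternates distributing each class across its compatible
references proportional to ``w_cj * a_j`` (E-step) and renormalising the
expected counts (M-step); the log-likelihood is non-decreasing.

Aggregation to higher taxonomic ranks or from genes to KEGG orthologs is
mass-preserving summation over a user-supplied map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .tables import FeatureKind, FeatureTable

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass
class CompatibilityStructure:
    """Read-class counts plus their reference-compatibility sets.

    ``compat[c]`` is a list of ``(reference_id, weight)`` pairs with
    weight > 0; every counted class must be compatible with at least one
    reference.
    """

    read_class_counts: np.ndarray
    compat: list[list[tuple[str, float]]]
    reference_ids: list[str]

    def __post_init__(self) -> None:
        self.read_class_counts = np.asarray(self.read_class_counts, dtype=float)
        if len(self.read_class_counts) != len(self.compat):
            raise ValueError("counts and compatibility lists differ in length")
        if not np.all(np.isfinite(self.read_class_counts)):
            raise ValueError("read-class counts must be finite")
        if (self.read_class_counts < 0).any():
            raise ValueError("read-class counts must be non-negative")
        if self.read_class_counts.sum() <= 0:
            raise ValueError("total read count must be positive")
        refset = set(self.reference_ids)
        if len(refset) != len(self.reference_ids):
            raise ValueError("duplicate reference ids")
        for c, pairs in enumerate(self.compat):
            if not any(w > 0 for _, w in pairs):
                raise ValueError(f"read class {c} has no compatible reference with weight > 0")
            for ref, w in pairs:
                if ref not in refset:
                    raise ValueError(f"read class {c} references unknown id {ref!r}")
                if w < 0:
                    raise ValueError(f"negative weight for class {c}, reference {ref!r}")

    def weight_matrix(self) -> sparse.csr_matrix:
        """Sparse classes x references weight matrix."""
        ref_index = {r: j for j, r in enumerate(self.reference_ids)}
        rows, cols, vals = [], [], []
        for c, pairs in enumerate(self.compat):
            for ref, w in pairs:
                if w > 0:
                    rows.append(c)
                    cols.append(ref_index[ref])
                    vals.append(w)
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.compat), len(self.reference_ids)),
        )


@dataclass
class RelativeActivity:
    """EM output: the activity simplex plus convergence diagnostics."""

    reference_ids: list[str]
    activity: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    identifiable: bool = True
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if (self.activity < 0).any():
            raise ValueError("activities must be non-negative")
        if abs(self.activity.sum() - 1.0) > 1e-9:
            raise ValueError("activity must sum to 1")

    def series(self) -> pd.Series:
        return pd.Series(self.activity, index=self.reference_ids, name="activity")


def em_quantify(
    cs: CompatibilityStructure,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: np.ndarray | None = None,
) -> RelativeActivity:
    """Run mixture EM on a compatibility structure.

    Stops when the max absolute activity change or the log-likelihood
    change drops below ``tol``; if ``max_iter`` is hit first the result is
    returned with ``converged=False``. Initialisation is uniform unless
    ``init`` is given. When every counted read class is compatible with
    more than one reference at proportional weights the solution is not
    unique; the result is flagged ``identifiable=False`` (EM then keeps
    whatever symmetry the initialisation has).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    W = cs.weight_matrix()
    n = cs.read_class_counts
    counted = n > 0
    n_refs = W.shape[1]
    if init is None:
        a = np.full(n_refs, 1.0 / n_refs)
    else:
        a = np.asarray(init, dtype=float)
        if a.shape != (n_refs,) or (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("init must be a probability vector over references")
    total = n.sum()

    # Identifiability heuristic: a class pins down its references only if it
    # is counted and unique; with no unique counted class the likelihood has
    # a flat direction whenever two refs share all their counted classes.
    unique_refs = set()
    for c in np.flatnonzero(counted):
        pos = [j for j, (_, w) in enumerate(cs.compat[c]) if w > 0]
        if len(pos) == 1:
            unique_refs.add(cs.compat[c][pos[0]][0])
    identifiable = len(unique_refs) == n_refs

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = W @ a  # per-class mixture mass
        if (mix[counted] <= 0).any():
            raise ValueError("a counted read class has zero mixture mass")
        ll = float(n[counted] @ np.log(mix[counted]))
        # E+M in one sweep: expected count for ref j is
        # sum_c n_c * w_cj * a_j / mix_c
        ratio = np.where(mix > 0, n / np.where(mix > 0, mix, 1.0), 0.0)
        expected = a * (W.T @ ratio)
        a_new = expected / total
        delta = float(np.max(np.abs(a_new - a)))
        ll_change = abs(ll - trace[-1]) if trace else np.inf
        trace.append(ll)
        a = a_new
        if delta < tol or ll_change < tol:
            converged = True
            break
    return RelativeActivity(
        reference_ids=list(cs.reference_ids),
        activity=a / a.sum(),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        identifiable=identifiable,
        tol=tol,
        max_iter=max_iter,
    )


@dataclass
class TaxonomyMap:
    """species id -> (genus, phylum) labels."""

    mapping: dict[str, tuple[str, str]]

    def rank_label(self, species: str, rank: str) -> str:
        genus, phylum = self.mapping[species]
        if rank == "species":
            return species
        if rank == "genus":
            return genus
        if rank == "phylum":
            return phylum
        raise ValueError(f"unknown rank {rank!r}")


@dataclass
class GeneKOMap:
    """gene id -> KO id (None for unannotated genes)."""

    mapping: dict[str, str | None]

    def __post_init__(self) -> None:
        for gene, ko in self.mapping.items():
            if ko is not None and not (ko.startswith("K") and ko[1:].isdigit()):
                raise ValueError(f"malformed KO id {ko!r} for gene {gene!r}")


def aggregate_taxa(table: FeatureTable, tmap: TaxonomyMap, rank: str) -> FeatureTable:
    """Aggregate a species-level table to genus or phylum by summation.

    Row sums are preserved exactly; ``rank='species'`` is the identity.
    Missing mappings are an error listing the offending species.
    """
    if rank == "species":
        return table
    missing = [f for f in table.feature_ids if f not in tmap.mapping]
    if missing:
        raise KeyError(f"species missing from taxonomy map: {missing[:10]}")
    groups = {f: tmap.rank_label(f, rank) for f in table.feature_ids}
    agg = table.data.T.groupby(table.data.columns.map(groups)).sum().T
    return FeatureTable(agg, kind=table.kind, is_relative=table.is_relative)


def aggregate_ko(
    gene_table: FeatureTable, gmap: GeneKOMap
) -> tuple[FeatureTable, pd.Series]:
    """Aggregate gene-level activities to KEGG orthologs.

    Genes with no KO annotation are dropped; their per-sample mass is
    returned separately so nothing disappears silently.
    """
    ko_of = {g: gmap.mapping.get(g) for g in gene_table.feature_ids}
    annotated = [g for g, ko in ko_of.items() if ko is not None]
    dropped = [g for g, ko in ko_of.items() if ko is None]
    dropped_mass = gene_table.data[dropped].sum(axis=1)
    dropped_mass.name = "dropped_mass"
    if not annotated:
        empty = pd.DataFrame(index=gene_table.data.index)
        return FeatureTable(empty, kind=FeatureKind.ko, is_relative=False), dropped_mass
    sub = gene_table.data[annotated]
    agg = sub.T.groupby(sub.columns.map(ko_of)).sum().T
    return FeatureTable(agg, kind=FeatureKind.ko, is_relative=False), dropped_mass
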