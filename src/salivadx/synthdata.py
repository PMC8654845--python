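"""Synthetic salivary-metatranscriptome cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: heavy-tailed compositional feature tables (species and KEGG
orthologs) with many structural zeros, a planted minority of
discriminative features carrying a controlled case-vs-control shift in
CLR space, and nuisance covariates (sex, age, smoking) independent of the
label by default.

Generative scheme per sample
----------------------------
1. latent log-abundance  ``log lam_sf = mu_f + beta_f * 1[case_s] + eps_sf``
   with feature base levels ``mu_f ~ N(0, sigma_base^2)`` (log-normal
   abundance across features), planted effects ``beta_f = +-effect_size``
   for discriminative features (0 otherwise) and sample-level noise
   ``eps_sf ~ N(0, overdispersion^2)``;
2. structural zeros via a core/rare prevalence model: a ``core_fraction``
   of features is structurally present in every sample (the "core
   microbiome"); each remaining feature f gets a prevalence ``pi_f`` drawn
   from a zero-skewed Beta whose mean makes the overall expected presence
   equal ``1 - zero_fraction``, and is present in a sample with
   probability ``pi_f`` (independent Bernoulli masks). Planted features
   are core members: structurally present in both classes, so the
   calibrated CLR shift survives masking and presence carries no label
   information — mirroring real discriminative taxa, which are common
   organisms whose *activity* shifts, not presence/absence artifacts;
3. reads: counts ~ Multinomial(depth, lam / sum lam).

Because effects are additive in log-abundance space, the mean CLR-space
case-control difference of a planted feature equals ``effect_size`` up to
a small ``O(k/D)`` closure term, where ``k`` planted features out of
``D`` total.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emquant import CompatibilityStructure
from .tables import (
    FeatureKind,
    FeatureTable,
    Interference,
    Label,
    SampleMetadata,
    Stage,
)

#: Between-feature spread of base log-abundances (log-normal abundance model).
SIGMA_BASE = 1.5

_CASE_STAGES = [Stage.opmd, Stage.s1, Stage.s2, Stage.s3, Stage.s4]
# Stage mix follows the discovery cohort's staged-case proportions
# (OPMD 10, S1 13, S2 16, S3 2, S4 14 of 55 staged), with the remainder
# unstaged cases folded into OPMD for synthetic purposes.
_STAGE_WEIGHTS = np.array([13, 13, 16, 2, 14], dtype=float) / 58.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    ``effect_size`` is the CLR-space mean shift planted between classes for
    discriminative features; ``direction_down_fraction`` is the fraction of
    those shifts that are negative in cases (downregulated).
    ``zero_fraction_ko`` lets the KO table carry a different structural-zero
    rate than the species table (the two differ in real data); ``None``
    falls back to ``zero_fraction``.
    """

    n_cases: int = 58
    n_controls: int = 59
    n_species: int = 1587
    n_kos: int = 4932
    n_discriminative_species: int = 0
    n_discriminative_kos: int = 0
    effect_size: float = 0.0
    depth_mean: int = 100_000
    zero_fraction: float = 0.715
    zero_fraction_ko: float | None = 0.50
    overdispersion: float = 0.7
    direction_down_fraction: float = 0.5
    core_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_species", "n_kos", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_discriminative_species > self.n_species:
            raise ValueError("n_discriminative_species exceeds n_species")
        if self.n_discriminative_kos > self.n_kos:
            raise ValueError("n_discriminative_kos exceeds n_kos")
        if min(self.n_discriminative_species, self.n_discriminative_kos) < 0:
            raise ValueError("discriminative feature counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.zero_fraction_ko is not None and not 0 <= self.zero_fraction_ko < 1:
            raise ValueError("zero_fraction_ko must be in [0, 1)")
        if not 0 <= self.direction_down_fraction <= 1:
            raise ValueError("direction_down_fraction must be in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must be in (0, 1)")
        for zf, what in ((self.zero_fraction, "zero_fraction"),
                         (self.zero_fraction_ko, "zero_fraction_ko")):
            if zf is not None and 1.0 - zf <= self.core_fraction:
                raise ValueError(
                    f"{what}={zf} leaves expected presence <= core_fraction="
                    f"{self.core_fraction}; lower one of them"
                )

    @staticmethod
    def discovery_like(seed: int = 0, **overrides) -> "CohortSpec":
        """Defaults emulating the discovery cohort's shape: 58/59 samples,
        1587 species at ~438 per-sample richness, 4932 KOs at ~2270."""
        return CohortSpec(seed=seed, **overrides)

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    kind: str
    effect: float  # signed CLR-space shift, case minus control


def _rng(seed: int, *stream: object) -> np.random.Generator:
    """Named substream generator: one master seed, independent streams.

    Stream names are hashed with CRC32 (stable across processes, unlike
    built-in ``hash``) so partial regeneration is reproducible.
    """
    words = [int(seed)] + [zlib.crc32(str(s).encode()) for s in stream]
    return np.random.default_rng(np.random.SeedSequence(words))


def _sample_table(
    spec: CohortSpec,
    kind: FeatureKind,
    n_features: int,
    n_disc: int,
    zero_fraction: float,
    is_case: np.ndarray,
    sample_ids: list[str],
) -> tuple[FeatureTable, list[PlantedFeature]]:
    prefix = "sp" if kind is FeatureKind.species else "K"
    if kind is FeatureKind.species:
        feature_ids = [f"sp{j:05d}" for j in range(n_features)]
    else:
        feature_ids = [f"K{j + 1:05d}" for j in range(n_features)]
    del prefix

    rng_ab = _rng(spec.seed, "abundance", kind.value)
    rng_mask = _rng(spec.seed, "mask", kind.value)
    rng_samp = _rng(spec.seed, "sampling", kind.value)

    mu = rng_ab.normal(0.0, SIGMA_BASE, size=n_features)
    n_core = max(int(round(spec.core_fraction * n_features)), n_disc, 1)
    core_idx = rng_ab.choice(n_features, size=n_core, replace=False)
    disc_idx = rng_ab.choice(core_idx, size=n_disc, replace=False)
    n_down = int(round(spec.direction_down_fraction * n_disc))
    signs = np.ones(n_disc)
    signs[:n_down] = -1.0
    rng_ab.shuffle(signs)
    beta = np.zeros(n_features)
    beta[disc_idx] = signs * spec.effect_size

    n_samples = len(sample_ids)
    eps = rng_ab.normal(0.0, spec.overdispersion, size=(n_samples, n_features))
    log_lam = mu[None, :] + beta[None, :] * is_case[:, None] + eps

    # core/rare prevalence: core features always present, rare features get
    # a zero-skewed Beta prevalence whose mean matches the target presence
    presence = 1.0 - zero_fraction
    rare_mean = (presence - n_core / n_features) / max(1.0 - n_core / n_features, 1e-12)
    rare_mean = float(np.clip(rare_mean, 1e-6, 1.0 - 1e-6))
    conc = 2.0
    prevalence = rng_mask.beta(rare_mean * conc, (1.0 - rare_mean) * conc, size=n_features)
    prevalence[core_idx] = 1.0
    # per-sample coverage factor (shared by the species and KO tables via a
    # kind-independent stream) spreads per-sample richness the way uneven
    # sampling does in real data; it scales rare-feature prevalence only
    coverage = _rng(spec.seed, "coverage").gamma(shape=16.0, scale=1.0 / 16.0, size=n_samples)
    pi = np.clip(prevalence[None, :] * coverage[:, None], 0.0, 1.0)
    pi[:, core_idx] = 1.0
    keep = rng_mask.random((n_samples, n_features)) < pi
    if (keep.sum(axis=1) < 2).any():
        raise ValueError(
            "zero_fraction leaves a sample with fewer than 2 nonzero features; "
            "lower zero_fraction or raise the feature count"
        )

    lam = np.exp(log_lam) * keep
    probs = lam / lam.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, n_features), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng_samp.multinomial(spec.depth_mean, probs[i])

    table = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=feature_ids),
        kind=kind,
        is_relative=False,
    )
    truth = [
        PlantedFeature(feature_ids[j], kind.value, float(beta[j])) for j in sorted(disc_idx)
    ]
    return table, truth


def _metadata(spec: CohortSpec, sample_ids: list[str], is_case: np.ndarray) -> list[SampleMetadata]:
    rng = _rng(spec.seed, "covariates")
    out = []
    for i, sid in enumerate(sample_ids):
        case = bool(is_case[i])
        stage = (
            _CASE_STAGES[rng.choice(len(_CASE_STAGES), p=_STAGE_WEIGHTS / _STAGE_WEIGHTS.sum())]
            if case
            else Stage.none
        )
        out.append(
            SampleMetadata(
                sample_id=sid,
                subject_id=f"subj{i:04d}",
                label=Label.case if case else Label.control,
                stage=stage,
                sex=str(rng.choice(["F", "M"])),
                age=float(np.round(rng.normal(62.0, 9.0), 1)),
                smoking=str(rng.choice(["never", "ex", "current"], p=[0.4, 0.35, 0.25])),
            )
        )
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[FeatureTable, FeatureTable, list[SampleMetadata], list[PlantedFeature]]:
    """Generate species and KO count tables over shared samples, metadata,
    and the list of planted discriminative features with signed effects.

    Fully reproducible from ``spec.seed``.
    """
    n = spec.n_cases + spec.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n)]
    is_case = np.zeros(n)
    is_case[: spec.n_cases] = 1.0
    zf_ko = spec.zero_fraction if spec.zero_fraction_ko is None else spec.zero_fraction_ko

    species, truth_sp = _sample_table(
        spec, FeatureKind.species, spec.n_species, spec.n_discriminative_species,
        spec.zero_fraction, is_case, sample_ids,
    )
    kos, truth_ko = _sample_table(
        spec, FeatureKind.ko, spec.n_kos, spec.n_discriminative_kos,
        zf_ko, is_case, sample_ids,
    )
    meta = _metadata(spec, sample_ids, is_case)
    return species, kos, meta, truth_sp + truth_ko


def generate_null_cohort(
    spec: CohortSpec,
) -> tuple[FeatureTable, FeatureTable, list[SampleMetadata], list[PlantedFeature]]:
    """A cohort with no planted effects: labels are exchangeable."""
    null_spec = spec.replace(
        n_discriminative_species=0, n_discriminative_kos=0, effect_size=0.0
    )
    return generate_cohort(null_spec)


def generate_compatibility(
    n_refs: int,
    n_read_classes: int,
    true_activity: np.ndarray,
    depth: int,
    ambiguity: float,
    seed: int,
) -> tuple[CompatibilityStructure, np.ndarray]:
    """EM fixture with known truth.

    Each read class has a home reference (round-robin) and, with
    probability ``ambiguity``, is additionally compatible with one other
    random reference at equal weight. Each reference emits uniformly over
    its compatible classes; class counts are Multinomial(depth) from the
    mixture ``p_c = sum_j w~_cj a*_j`` with per-reference-normalised
    emissions, which is exactly the likelihood the EM quantifier fits, so
    EM is consistent for ``a*`` as depth grows (given identifiability).

    Returns the structure and the true activity vector.
    """
    true_activity = np.asarray(true_activity, dtype=float)
    if true_activity.shape != (n_refs,) or abs(true_activity.sum() - 1.0) > 1e-9:
        raise ValueError("true_activity must be a length-n_refs probability vector")
    if not 0 <= ambiguity <= 1:
        raise ValueError("ambiguity must be in [0, 1]")
    if n_read_classes < n_refs:
        raise ValueError("need at least one read class per reference")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9151]))
    refs = [f"ref{j}" for j in range(n_refs)]

    membership = np.zeros((n_read_classes, n_refs), dtype=bool)
    home = np.arange(n_read_classes) % n_refs
    membership[np.arange(n_read_classes), home] = True
    if n_refs > 1:
        shared = rng.random(n_read_classes) < ambiguity
        for c in np.flatnonzero(shared):
            other = rng.integers(n_refs - 1)
            if other >= home[c]:
                other += 1
            membership[c, other] = True

    # emission matrix: ref j uniform over its compatible classes
    per_ref = membership.sum(axis=0)
    emission = membership / np.where(per_ref > 0, per_ref, 1)[None, :]
    p_class = emission @ true_activity
    if p_class.sum() <= 0:
        raise ValueError("degenerate fixture: no class can be emitted")
    counts = rng.multinomial(depth, p_class / p_class.sum())

    if ambiguity >= 1 and n_refs > 1 and not np.any(membership.sum(axis=1) == 1):
        # every class shared: references may be indistinguishable
        pass  # em_quantify flags identifiability itself

    compat = []
    keep = counts > 0
    for c in np.flatnonzero(keep):
        compat.append([(refs[j], float(emission[c, j])) for j in np.flatnonzero(membership[c])])
    cs = CompatibilityStructure(
        read_class_counts=counts[keep],
        compat=compat,
        reference_ids=refs,
    )
    return cs, true_activity


def generate_interference_pairs(
    n_subjects: int,
    perturbation_sd: float,
    seed: int,
    n_features: int = 300,
    perturbed_fraction: float = 0.05,
) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Paired control samples with and without an interfering substance.

    Each subject contributes one baseline sample and one sample per
    interference type (gum, chewing tobacco, brushing); all share the
    subject's latent composition. The perturbation multiplies a small
    random feature subset by ``exp(N(0, perturbation_sd^2))``. Relative
    activities are emitted directly (no count sampling), so
    ``perturbation_sd = 0`` yields bit-identical pair members.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 40277]))
    feature_ids = [f"sp{j:05d}" for j in range(n_features)]
    kinds = [Interference.none, Interference.gum, Interference.chew_tobacco, Interference.brushing]

    rows, meta = [], []
    ids = []
    for s in range(n_subjects):
        base_log = rng.normal(0.0, SIGMA_BASE, size=n_features)
        n_pert = max(1, int(round(perturbed_fraction * n_features)))
        for interf in kinds:
            log_lam = base_log.copy()
            if interf is not Interference.none:
                idx = rng.choice(n_features, size=n_pert, replace=False)
                log_lam[idx] += rng.normal(0.0, 1.0, size=n_pert) * perturbation_sd
            lam = np.exp(log_lam)
            rows.append(lam / lam.sum())
            sid = f"subj{s:03d}_{interf.value}"
            ids.append(sid)
            meta.append(
                SampleMetadata(
                    sample_id=sid,
                    subject_id=f"subj{s:03d}",
                    label=Label.control,
                    stage=Stage.none,
                    interference=interf,
                )
            )
    table = FeatureTable(
        pd.DataFrame(np.asarray(rows), index=ids, columns=feature_ids),
        kind=FeatureKind.species,
        is_relative=True,
    )
    return table, meta
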