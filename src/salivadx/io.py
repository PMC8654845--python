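"""Plain-text readers/writers: feature tables and metadata as TSV,
compatibility structures as TSV, models and truth sets as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emquant import CompatibilityStructure, GeneKOMap, TaxonomyMap
from .sigclassifier import Signature
from .synthdata import PlantedFeature
from .tables import FeatureTable, SampleMetadata, metadata_frame


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Rows = samples, header = feature ids, first column = sample_id."""
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_feature_table(path: str | Path, kind: str, is_relative: bool = False) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index.name = None
    return FeatureTable(df, kind=kind, is_relative=is_relative)


def write_metadata(metadata: list[SampleMetadata], path: str | Path) -> None:
    metadata_frame(metadata).to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"subject_id": str})
    required = {"label", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return df


def write_truth(truth: list[PlantedFeature], path: str | Path) -> None:
    payload = [
        {"feature_id": t.feature_id, "kind": t.kind, "effect": t.effect} for t in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> list[PlantedFeature]:
    payload = json.loads(Path(path).read_text())
    return [PlantedFeature(**rec) for rec in payload]


def write_compatibility(cs: CompatibilityStructure, path: str | Path) -> None:
    """TSV with columns: count, comma-separated ref:weight pairs."""
    lines = ["count\tcompat"]
    for n, pairs in zip(cs.read_class_counts, cs.compat):
        enc = ",".join(f"{ref}:{w:.17g}" for ref, w in pairs)
        lines.append(f"{int(n)}\t{enc}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_compatibility(path: str | Path) -> CompatibilityStructure:
    counts: list[float] = []
    compat: list[list[tuple[str, float]]] = []
    refs: dict[str, None] = {}
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].split("\t") != ["count", "compat"]:
        raise ValueError(f"{path}: expected header 'count\\tcompat'")
    for lineno, line in enumerate(lines[1:], start=2):
        try:
            raw_count, enc = line.split("\t")
            pairs = []
            for item in enc.split(","):
                ref, w = item.rsplit(":", 1)
                pairs.append((ref, float(w)))
                refs.setdefault(ref)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        counts.append(float(raw_count))
        compat.append(pairs)
    return CompatibilityStructure(
        read_class_counts=np.asarray(counts), compat=compat, reference_ids=list(refs)
    )


def read_taxonomy_map(path: str | Path) -> TaxonomyMap:
    """TSV with columns species, genus, phylum."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species", "genus", "phylum"):
        if col not in df.columns:
            raise ValueError(f"taxonomy map missing column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()][:5] + 2
            raise ValueError(f"taxonomy map has empty {col!r} at lines {list(bad)}")
    return TaxonomyMap({r.species: (r.genus, r.phylum) for r in df.itertuples()})


def read_gene_ko_map(path: str | Path) -> GeneKOMap:
    """TSV with columns gene, ko (empty ko = unannotated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "ko" not in df.columns:
        raise ValueError("gene-KO map needs columns 'gene' and 'ko'")
    return GeneKOMap(
        {r.gene: (None if pd.isna(r.ko) or r.ko == "" else r.ko) for r in df.itertuples()}
    )


def read_ko_hierarchy(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns ko, level3, level2 (optionally level1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ko", "level3", "level2"):
        if col not in df.columns:
            raise ValueError(f"KO hierarchy missing column {col!r}")
    return {r.ko: (r.level3, r.level2) for r in df.itertuples()}


def write_model(sig: Signature, cfg, path: str | Path) -> None:
    """Serialise the final model (signature + coefficients + config)."""
    import dataclasses as _dc

    payload = {
        "schema_version": "1",
        "feature_ids": sig.feature_ids,
        "coefficients": {f: float(c) for f, c in sig.coefficients.items()},
        "intercept": sig.intercept,
        "n_species": sig.n_species,
        "n_kos": sig.n_kos,
        "config": _dc.asdict(cfg),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path) -> tuple[Signature, dict]:
    payload = json.loads(Path(path).read_text())
    coef = pd.Series(payload["coefficients"], name="coefficient")
    coef = coef.reindex(payload["feature_ids"])
    sig = Signature(
        feature_ids=payload["feature_ids"],
        coefficients=coef,
        intercept=float(payload["intercept"]),
        n_species=int(payload["n_species"]),
        n_kos=int(payload["n_kos"]),
    )
    return sig, payload.get("config", {})
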