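"""Core containers for sample-by-feature activity tables and sample metadata.

A :class:`FeatureTable` is a samples x features matrix of non-negative
counts or relative activities for one feature kind ("species" or "KO").
Species and KO tables are kept as two separate compositions throughout;
they are only joined column-wise after CLR transformation, inside the
classifier.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-9


class FeatureKind(str, enum.Enum):
    species = "species"
    ko = "KO"


class Label(str, enum.Enum):
    case = "case"
    control = "control"


class Stage(str, enum.Enum):
    none = "none"
    opmd = "OPMD"
    s1 = "S1"
    s2 = "S2"
    s3 = "S3"
    s4 = "S4"


class Interference(str, enum.Enum):
    none = "none"
    gum = "gum"
    chew_tobacco = "chew_tobacco"
    brushing = "brushing"


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical annotations.

    Controls carry ``stage == Stage.none``; cases carry a lesion stage
    (OPMD or tumor stage S1-S4).
    """

    sample_id: str
    subject_id: str
    label: Label
    stage: Stage = Stage.none
    sex: str = "F"
    age: float = 60.0
    smoking: str = "never"
    interference: Interference = Interference.none

    def __post_init__(self) -> None:
        label = Label(self.label)
        stage = Stage(self.stage)
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "stage", stage)
        object.__setattr__(self, "interference", Interference(self.interference))
        if label is Label.control and stage is not Stage.none:
            raise ValueError(f"control sample {self.sample_id!r} cannot have stage {stage.value}")
        if label is Label.case and stage is Stage.none:
            raise ValueError(f"case sample {self.sample_id!r} must have a stage")


def metadata_frame(metadata: list[SampleMetadata]) -> pd.DataFrame:
    """Tabulate metadata records, one row per sample, indexed by sample id."""
    rows = []
    for m in metadata:
        d = dataclasses.asdict(m)
        for k in ("label", "stage", "interference"):
            d[k] = d[k].value
        rows.append(d)
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative activities.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and feature ids as columns.
    kind
        Feature kind, ``"species"`` or ``"KO"``.
    is_relative
        If True every row must sum to 1 (within ``1e-9``); rows of an
        all-zero input cannot be closed and are rejected.
    """

    data: pd.DataFrame
    kind: FeatureKind
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature table contains non-finite values")
        if (values < 0).any():
            raise ValueError("feature table contains negative values")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.is_relative and len(values):
            bad = np.abs(values.sum(axis=1) - 1.0) > ROW_SUM_TOL
            if bad.any():
                ids = list(self.data.index[bad][:5])
                raise ValueError(f"relative table rows do not sum to 1: {ids}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_relative(self) -> "FeatureTable":
        """Close each row to sum 1. Rows with zero total are rejected."""
        if self.is_relative:
            return self
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            bad = list(self.data.index[totals <= 0])
            raise ValueError(f"cannot normalise all-zero samples: {bad}")
        rel = self.data.div(totals, axis=0)
        return FeatureTable(rel, kind=self.kind, is_relative=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.is_relative == other.is_relative
            and self.data.equals(other.data)
        )
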