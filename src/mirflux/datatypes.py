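"""Shared domain containers.

The pipeline's in-memory currency is the pandas DataFrame; the dataclasses
here wrap DataFrames with the metadata and invariants each stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import SCALES, AnalysisConfig, VocabularyError

SAMPLE_COLUMNS = ("tissue", "age", "replicate", "count_unit")
COUNT_UNITS = ("reads", "UMI")

RNA_ALPHABET = frozenset("ACGU")


class SchemaError(ValueError):
    """A table violates the documented file schema."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library (one matrix column)."""

    sample_id: str
    tissue: str
    age: str
    replicate: int
    count_unit: str = "reads"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.count_unit not in COUNT_UNITS:
            raise ValueError(f"count_unit must be one of {COUNT_UNITS}")


def samples_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Build the canonical sample sheet (index: sample_id) from metadata."""
    rows = list(samples)
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in rows],
            "tissue": [s.tissue for s in rows],
            "age": [s.age for s in rows],
            "replicate": [s.replicate for s in rows],
            "count_unit": [s.count_unit for s in rows],
        }
    ).set_index("sample_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise SchemaError(f"duplicate sample ids: {dups}")
    return df


def validate_samples(samples: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Validate a sample sheet: required columns, unique ids, known labels."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample sheet missing columns: {missing}")
    if samples.index.duplicated().any():
        raise SchemaError(
            f"duplicate sample ids: {samples.index[samples.index.duplicated()].tolist()}"
        )
    if (samples["replicate"].astype(int) < 1).any():
        raise SchemaError("replicate numbers must be >= 1")
    bad_units = set(samples["count_unit"]) - set(COUNT_UNITS)
    if bad_units:
        raise SchemaError(f"unknown count_unit values: {sorted(bad_units)}")
    if config is not None:
        for label in samples["tissue"].unique():
            config.check_tissue(label)
        for label in samples["age"].unique():
            config.check_age(label)
    return samples


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with per-column sample metadata.

    ``values`` is indexed by feature id with one column per sample;
    ``samples`` is the sample sheet indexed by sample_id in column order.
    ``scale`` tracks which transforms have been applied and is only changed
    by the declared operations in :mod:`mirflux.normalize`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw_count"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if list(self.values.columns) != list(self.samples.index):
            raise SchemaError(
                "matrix columns and sample sheet disagree: "
                f"{list(self.values.columns)} vs {list(self.samples.index)}"
            )
        validate_samples(self.samples)
        vals = self.values.to_numpy()
        if self.scale in ("raw_count", "tpm", "relative_abundance") and (vals < 0).any():
            raise ValueError("negative entries are not allowed on this scale")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, tissue: str, age: str) -> list[str]:
        """Sample ids belonging to one (tissue, age) group, replicate order."""
        mask = (self.samples["tissue"] == tissue) & (self.samples["age"] == age)
        sub = self.samples[mask].sort_values("replicate")
        return list(sub.index)

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (tissue, age) groups present, in sample-sheet order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.samples.iterrows():
            key = (row["tissue"], row["age"])
            if key not in seen:
                seen.append(key)
        return seen

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, samples=self.samples.copy(), scale=scale)


@dataclass
class DetectionTable:
    """Boolean expressed/not-expressed calls.

    ``per_replicate`` is features x sample_ids; ``per_group`` is features x
    (tissue, age) MultiIndex columns, derived deterministically from the
    replicate calls of each group.
    """

    per_replicate: pd.DataFrame
    per_group: pd.DataFrame

    def expressed(self, feature: str, tissue: str, age: str) -> bool:
        return bool(self.per_group.loc[feature, (tissue, age)])

    def group_keys(self) -> list[tuple[str, str]]:
        return list(self.per_group.columns)


@dataclass
class MirnaAnnotation:
    """Mature-arm level annotation table.

    Indexed by mature_id with columns gene_id, family_id, arm,
    conserved_in_mammals and (optionally) mature_sequence.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "family_id", "arm", "conserved_in_mammals")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"annotation missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise SchemaError("duplicate mature ids in annotation")
        bad_arm = set(self.table["arm"]) - {"3p", "5p", "unspecified"}
        if bad_arm:
            raise SchemaError(f"unknown arm labels: {sorted(bad_arm)}")
        if "mature_sequence" in self.table.columns:
            for mid, seq in self.table["mature_sequence"].dropna().items():
                check_rna(seq, name=mid, min_len=18, max_len=30)

    @property
    def mature_ids(self) -> list[str]:
        return list(self.table.index)

    def matures_of_gene(self, gene_id: str) -> list[str]:
        return list(self.table.index[self.table["gene_id"] == gene_id])

    def gene_of(self, mature_id: str) -> str:
        return str(self.table.loc[mature_id, "gene_id"])


@dataclass
class TranscriptionMap:
    """Promoter-activity (transcription) calls per miRNA gene x tissue x age.

    ``calls`` is genes x (tissue, age) MultiIndex boolean columns; absent
    combinations are False. ``provenance`` optionally records the reporter
    strain or literature source per gene.
    """

    calls: pd.DataFrame
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            raise SchemaError("duplicate gene ids in transcription map")
        self.calls = self.calls.astype(bool)

    def transcribed(self, gene: str, tissue: str, age: str) -> bool:
        if gene not in self.calls.index or (tissue, age) not in self.calls.columns:
            return False
        return bool(self.calls.loc[gene, (tissue, age)])

    def to_mature(self, annotation: MirnaAnnotation) -> pd.DataFrame:
        """Lift gene-level calls to mature arms (both arms inherit the gene's T)."""
        rows = {}
        for mid in annotation.mature_ids:
            gene = annotation.gene_of(mid)
            if gene in self.calls.index:
                rows[mid] = self.calls.loc[gene]
        lifted = pd.DataFrame(rows).T
        lifted.columns = self.calls.columns
        return lifted.astype(bool)


def check_rna(seq: str, name: str = "sequence", min_len: int = 1, max_len: int | None = None) -> str:
    """Validate an RNA string over {A, C, G, U}."""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{name}: invalid RNA characters {sorted(bad)}")
    if len(seq) < min_len:
        raise ValueError(f"{name}: sequence shorter than {min_len} nt")
    if max_len is not None and len(seq) > max_len:
        raise ValueError(f"{name}: sequence longer than {max_len} nt")
    return seq
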