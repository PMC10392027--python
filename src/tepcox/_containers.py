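"""Core in-memory containers shared by every pipeline stage.

An :class:`ExpressionMatrix` is a genes x samples numeric matrix with
identifiers and per-sample batch labels; a :class:`ClinicalTable` carries one
row per sample with the survival outcome (time in months, event indicator)
and the clinical covariates used downstream (age, FIGO stage, residual
disease, CA125, platelet count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "sample_id",
    "time_months",
    "event",
    "age",
    "stage",
    "residual",
    "ca125",
    "platelet_count",
    "batch",
    "cohort",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifiers and batch labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    batch: list[str] | None = None
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if not self.is_normalized and np.any(self.values < 0):
            raise ValueError("raw counts must be nonnegative")
        if self.batch is not None:
            self.batch = [str(b) for b in self.batch]
            if len(self.batch) != len(self.sample_ids):
                raise ValueError("batch labels must match sample count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), values=self.values[rows])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        batch = [self.batch[c] for c in cols] if self.batch is not None else None
        return replace(
            self,
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            batch=batch,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            batch=list(self.batch) if self.batch is not None else None,
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and clinical covariates."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample_id", "time_months", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        bad_time = df.index[~(df["time_months"] > 0)]
        if len(bad_time):
            raise ValueError(
                f"nonpositive survival time for sample "
                f"{df.loc[bad_time[0], 'sample_id']!r}"
            )
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample_id"].iloc[0]
            raise ValueError(f"event indicator must be 0/1; offending sample {bad!r}")
        if "stage" in df.columns and not df["stage"].isin([1, 2, 3, 4]).all():
            raise ValueError("stage must be an ordinal in 1..4")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["sample_id"]]

    @property
    def time(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def aligned_to(self, sample_ids: list[str]) -> "ClinicalTable":
        """Reorder rows to match ``sample_ids`` (all must be present)."""
        indexed = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(indexed.loc[sample_ids].reset_index())

    def __len__(self) -> int:
        return len(self.data)
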