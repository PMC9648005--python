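"""Gene x sample expression matrices with batch/phenotype annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A dense gene x sample matrix plus per-sample annotations.

    ``values`` rows are genes, columns are samples.  ``batch`` and
    ``phenotype`` are per-sample labels aligned with the columns; phenotype
    is optional (``None`` entries allowed only when the whole series is
    absent).
    """

    values: pd.DataFrame
    batch: Optional[pd.Series] = None
    phenotype: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        for name in ("batch", "phenotype"):
            series = getattr(self, name)
            if series is None:
                continue
            series = pd.Series(series)
            if len(series) != self.n_samples:
                raise ValueError(f"{name} annotation length does not match samples")
            series.index = self.values.columns
            setattr(self, name, series)

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, batch=self.batch, phenotype=self.phenotype)

    # -- I/O ----------------------------------------------------------------

    def to_files(self, matrix_path: str, annotation_path: Optional[str] = None) -> None:
        """Write the matrix as TSV and the annotations as a sidecar CSV."""
        self.values.to_csv(matrix_path, sep="\t")
        if annotation_path is not None:
            ann = pd.DataFrame({"sample": self.samples})
            ann["batch"] = self.batch.values if self.batch is not None else ""
            ann["phenotype"] = self.phenotype.values if self.phenotype is not None else ""
            ann.to_csv(annotation_path, index=False)

    @classmethod
    def from_files(cls, matrix_path: str, annotation_path: Optional[str] = None) -> "ExpressionMatrix":
        sep = "\t" if matrix_path.endswith((".tsv", ".txt")) else ","
        values = pd.read_csv(matrix_path, sep=sep, index_col=0)
        batch = phenotype = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path).set_index("sample").reindex(values.columns)
            if "batch" in ann and not ann["batch"].isna().all():
                batch = ann["batch"]
            if "phenotype" in ann and not ann["phenotype"].isna().all():
                phenotype = ann["phenotype"]
        return cls(values=values, batch=batch, phenotype=phenotype)
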