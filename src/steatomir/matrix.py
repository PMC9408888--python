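"""Core data containers: raw miRNA count matrices and normalized matrices.

Counts are stored miRNA-by-sample (rows = miRBase-style mature IDs such as
``hsa-miR-10a-5p``, columns = sample IDs), the conventional orientation for
small-RNA-seq count tables.  Modeling code transposes to samples-by-features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormalizedMatrix", "PhenotypeVector"]


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class CountMatrix:
    """Raw integer read counts, miRNAs x samples.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer grid; index = miRNA IDs, columns = sample IDs.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "miRNA IDs")
        _check_unique(self.counts.columns, "sample IDs")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValidationError("counts must be nonnegative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "mirna_id"

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset(self, mirna_ids) -> "CountMatrix":
        """Row subset preserving the given ID order."""
        return CountMatrix(self.counts.loc[list(mirna_ids)])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="mirna_id"))


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression values: counts divided by per-sample size factors."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "miRNA IDs")
        _check_unique(self.values.columns, "sample IDs")
        if not (self.size_factors > 0).all():
            raise ValidationError("size factors must all be positive")
        if list(self.size_factors.index) != list(self.values.columns):
            raise ValidationError("size-factor index must match sample columns")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2p1(self) -> "NormalizedMatrix":
        """log2(x + 1) transform of the normalized values."""
        return NormalizedMatrix(np.log2(self.values + 1.0), self.size_factors)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.10g")


@dataclass
class PhenotypeVector:
    """One continuous response per sample (liver TG in ug/mg protein, or biopsy fat %)."""

    values: pd.Series
    unit: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample IDs")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def align(self, sample_ids) -> np.ndarray:
        """Values reordered to the given sample IDs; missing IDs raise."""
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise ValidationError(f"phenotype missing samples: {missing[:5]}")
        return self.values.loc[list(sample_ids)].to_numpy()

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"sample_id": self.values.index, "value": self.values.to_numpy()})
        df["unit"] = self.unit
        # full precision so a file-mode rerun reproduces in-memory results exactly
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PhenotypeVector":
        df = pd.read_csv(path)
        unit = str(df["unit"].iloc[0]) if "unit" in df and len(df) else ""
        return cls(pd.Series(df["value"].to_numpy(), index=df["sample_id"]), unit=unit)
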