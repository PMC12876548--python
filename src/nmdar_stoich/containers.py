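"""Shared data containers for the quantification pipeline.

The central object is :class:`IntensityMatrix`, a protein x sample
quantification table with the per-protein annotations the proteomic ruler
needs (molecular weight, histone flag) and a sample sheet mapping each
sample to its genotype group.  Tables are stored as pandas objects and
round-trip through plain TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["protein_id", "gene", "mw_da", "is_histone"]


@dataclass
class IntensityMatrix:
    """Protein-level quantification with ruler annotations.

    Parameters
    ----------
    proteins
        Per-protein annotations indexed by ``protein_id`` with columns
        ``gene`` (symbol), ``mw_da`` (molecular weight, daltons) and
        ``is_histone`` (bool ruler flag).
    intensities
        Float matrix indexed by ``protein_id`` with one column per sample;
        missing measurements are NaN.
    sample_groups
        Series mapping sample id -> group label, in sample-column order.
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.intensities.index):
            raise ValueError("protein annotations and intensities must share an index")
        if list(self.intensities.columns) != list(self.sample_groups.index):
            raise ValueError("sample sheet must list exactly the intensity columns, in order")
        if self.intensities.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        mw = self.proteins["mw_da"].to_numpy(dtype=float)
        if not np.all(np.isfinite(mw) & (mw > 0)):
            raise ValueError("mw_da must be finite and > 0 for every protein")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.proteins.copy(), self.intensities.copy(), self.sample_groups.copy()
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(self.proteins, intensities, self.sample_groups)

    # --- TSV round trip -------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        table = pd.concat([self.proteins, self.intensities], axis=1)
        table.index.name = "protein_id"
        table.reset_index().to_csv(matrix_path, sep="\t", index=False)
        sheet = pd.DataFrame(
            {"sample_id": self.sample_groups.index, "group": self.sample_groups.to_numpy()}
        )
        sheet.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, samples_path: str | Path) -> "IntensityMatrix":
        table = pd.read_csv(matrix_path, sep="\t").set_index("protein_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        groups = pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"].astype(str))
        proteins = table[[c for c in META_COLUMNS if c != "protein_id"]].copy()
        proteins["is_histone"] = proteins["is_histone"].astype(bool)
        sample_cols = [c for c in table.columns if c not in META_COLUMNS]
        intensities = table[sample_cols].astype(float)
        intensities.columns = intensities.columns.astype(str)
        return cls(proteins, intensities[list(groups.index)], groups)


@dataclass
class CopyNumberTable:
    """Per-sample protein copies per cell, with gene labels and groups."""

    copies: pd.DataFrame
    genes: pd.Series
    sample_groups: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.copies.copy()
        out.insert(0, "gene", self.genes)
        out.index.name = "protein_id"
        out.reset_index().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SubunitCopyNumbers:
    """Relative (or absolute) GluN subunit copy numbers for one group.

    After normalization the reference group has ``cn1 == 1`` and
    ``reference_cn1`` records the absolute GluN1 mean the division used.
    """

    group: str
    cn1: float
    cn2a: float
    cn2b: float
    reference_cn1: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        for name in ("cn1", "cn2a", "cn2b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def scaled(self, factor: float) -> "SubunitCopyNumbers":
        return replace(
            self, cn1=self.cn1 * factor, cn2a=self.cn2a * factor, cn2b=self.cn2b * factor
        )
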