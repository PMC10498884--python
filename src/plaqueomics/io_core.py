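"""Tabular I/O and the shared data model for fraction-resolved plaque proteomics.

Tissue proteins are solubilised sequentially (NaCl -> SDS -> GuHCl), yielding a
loosely bound *soluble matrisome* pool, a *cellular* pool, and a tightly bound
*core matrisome* pool.  Each pool is quantified as a proteins x samples matrix of
log2 abundances with missing values, accompanied by per-sample clinical metadata
and a protein annotation table (matrisome class, signature membership).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Fraction",
    "AbundanceMatrix",
    "SampleMetadata",
    "AnnotationTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "read_annotation_table",
    "filter_missing",
    "filter_matrisome",
    "normalize_median_center",
]

#: tokens accepted as "missing" in abundance tables (case-insensitive)
NA_TOKENS = {"", "na", "nan"}

MATRISOME_CLASSES = ("core_matrisome", "matrisome_associated", "non_matrisome")

SIGNATURE_VOCABULARY = (
    "inflammation",
    "calcification",
    "proteoglycan",
    "smc",
    "structural_ecm",
)


class Fraction(str, Enum):
    """Sequential-extraction fraction a matrix was quantified in."""

    SDS = "SDS"  # cellular proteome
    NACL = "NaCl"  # soluble matrisome
    GUHCL = "GuHCl"  # core matrisome

    @classmethod
    def coerce(cls, value: "Fraction | str") -> "Fraction":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise ValueError(f"unknown fraction {value!r}; expected one of "
                         f"{[m.value for m in cls]}")


@dataclass
class AbundanceMatrix:
    """Proteins x samples matrix of log2 abundances for one extraction fraction.

    ``data`` holds floats with NaN encoding missingness.  Row index = protein
    ids, column index = sample ids; both must be unique.
    """

    fraction: Fraction
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.fraction = Fraction.coerce(self.fraction)
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("abundance values must be finite where present")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_proteins(self, protein_ids: Iterable[str]) -> "AbundanceMatrix":
        keep = [p for p in self.protein_ids if p in set(protein_ids)]
        return AbundanceMatrix(self.fraction, self.data.loc[keep])

    def imputed(self) -> pd.DataFrame:
        """Per-protein median imputation (for matrix methods that need
        complete data: PCA, k-means, network reconstruction)."""
        medians = self.data.median(axis=1)
        return self.data.apply(lambda row: row.fillna(medians[row.name]), axis=1)


METADATA_BOOL_COLUMNS = ("calcified", "symptomatic", "statin", "event")
METADATA_REQUIRED = (
    "sample_id", "patient_id", "region", "sex", "calcified", "symptomatic",
    "statin", "age", "ultrasound", "follow_up", "event",
)


@dataclass
class SampleMetadata:
    """One row per sample: clinical covariates, group labels and outcome."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if (self.table["follow_up"] < 0).any():
            raise ValueError("follow_up must be >= 0")
        self.table = self.table.set_index(
            self.table["sample_id"].astype(str), drop=False)
        self.table.index.name = None

    def aligned(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        ids = list(sample_ids)
        absent = [s for s in ids if s not in self.table.index]
        if absent:
            raise KeyError(f"samples without metadata rows: {absent[:5]}")
        return self.table.loc[ids]


@dataclass
class AnnotationTable:
    """Protein-level annotation: matrisome class + signature membership tags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "protein_id" not in self.table.columns:
            raise ValueError("annotation requires a protein_id column")
        if self.table["protein_id"].duplicated().any():
            raise ValueError("duplicate protein_id in annotation")
        bad = set(self.table["matrisome_class"]) - set(MATRISOME_CLASSES)
        if bad:
            raise ValueError(f"unknown matrisome_class values: {sorted(bad)}")
        self.table = self.table.set_index(
            self.table["protein_id"].astype(str), drop=False)
        self.table.index.name = None

    def matrisome_class(self, protein_id: str) -> str:
        """Class for a protein; proteins absent from the table are treated as
        non-matrisome."""
        if protein_id in self.table.index:
            return str(self.table.loc[protein_id, "matrisome_class"])
        return "non_matrisome"

    def tags(self, protein_id: str) -> set[str]:
        if protein_id not in self.table.index:
            return set()
        raw = self.table.loc[protein_id].get("signature_tags", "")
        if not isinstance(raw, str) or not raw:
            return set()
        return {t for t in raw.split(";") if t}

    def members_of(self, tag: str) -> list[str]:
        return [p for p in self.table.index if tag in self.tags(p)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    fraction: Fraction | str,
    sep: str | None = None,
    log2_transform: bool = False,
) -> AbundanceMatrix:
    """Read a delimited proteins x samples table (first column protein ids,
    header row sample ids).  Blank, ``NA`` and ``NaN`` cells (case-insensitive)
    are recorded as missing; any other non-numeric cell is an error.

    ``log2_transform`` applies log2(x+1) for tables on the raw intensity scale
    (abundances are otherwise assumed to be log2 already).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.shape[0] == 0:
        raise ValueError(f"no data rows in {path}")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate protein row: {dup!r}")

    def parse_cell(cell: str, protein: str, sample: str) -> float:
        if cell.strip().lower() in NA_TOKENS:
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {cell!r} at protein {protein!r}, "
                f"sample {sample!r}") from None

    values = np.empty(raw.shape, dtype=float)
    for i, protein in enumerate(raw.index):
        for j, sample in enumerate(raw.columns):
            values[i, j] = parse_cell(raw.iat[i, j], str(protein), str(sample))
    data = pd.DataFrame(values, index=raw.index.astype(str),
                        columns=raw.columns.astype(str))
    if log2_transform:
        data = np.log2(data + 1.0)
    return AbundanceMatrix(Fraction.coerce(fraction), data)


def write_abundance_table(m: AbundanceMatrix, path: str | Path,
                          sep: str | None = None, float_format: str = "%.6g",
                          ) -> None:
    path = Path(path)
    m.data.to_csv(path, sep=_sep_for(path, sep), na_rep="NA",
                  float_format=float_format, index_label="protein_id")


def read_sample_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in METADATA_BOOL_COLUMNS:
        if col in table.columns and table[col].dtype != bool:
            table[col] = table[col].astype(str).str.lower().isin(
                {"true", "1", "yes"})
    table["sample_id"] = table["sample_id"].astype(str)
    table["patient_id"] = table["patient_id"].astype(str)
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path: str | Path,
                          sep: str | None = None) -> None:
    path = Path(path)
    meta.table.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_annotation_table(path: str | Path, sep: str | None = None) -> AnnotationTable:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path, sep), keep_default_na=False)
    return AnnotationTable(table)


def write_annotation_table(ann: AnnotationTable, path: str | Path,
                           sep: str | None = None) -> None:
    path = Path(path)
    ann.table.to_csv(path, sep=_sep_for(path, sep), index=False)


# ---------------------------------------------------------------------------
# filtering / normalization
# ---------------------------------------------------------------------------

def filter_missing(m: AbundanceMatrix, min_fraction_observed: float = 0.8,
                   ) -> AbundanceMatrix:
    """Keep proteins observed in at least ``min_fraction_observed`` of samples.

    The sample set and protein order are unchanged.  Raises if every protein
    would be removed.
    """
    if not 0 < min_fraction_observed <= 1:
        raise ValueError("min_fraction_observed must be in (0, 1]")
    n = m.data.shape[1]
    observed = m.data.notna().sum(axis=1)
    keep = observed / n >= min_fraction_observed
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    return AbundanceMatrix(m.fraction, m.data.loc[keep])


def filter_matrisome(m: AbundanceMatrix, ann: AnnotationTable) -> AbundanceMatrix:
    """Keep ECM / extracellular proteins: matrisome_class != non_matrisome.

    Proteins absent from the annotation are treated as non-matrisome and
    dropped.  An empty result is allowed (with a warning).
    """
    keep = [p for p in m.protein_ids
            if ann.matrisome_class(p) != "non_matrisome"]
    if not keep:
        warnings.warn("no matrisome proteins retained", stacklevel=2)
    return AbundanceMatrix(m.fraction, m.data.loc[keep])


def normalize_median_center(m: AbundanceMatrix) -> AbundanceMatrix:
    """Center each sample so its observed values have median 0.

    Idempotent; the missingness pattern is unchanged.  Raises for a sample
    with zero observed values.
    """
    empty = m.data.notna().sum(axis=0) == 0
    if empty.any():
        sample = m.data.columns[empty][0]
        raise ValueError(f"sample {sample!r} has no observed values")
    centered = m.data - m.data.median(axis=0, skipna=True)
    return AbundanceMatrix(m.fraction, centered)
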