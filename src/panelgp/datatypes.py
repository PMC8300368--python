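"""Core in-memory containers shared by the whole pipeline.

Genotypes are held as minor-allele dosage codes (0 = major homozygote,
1 = heterozygote, 2 = minor homozygote) with an explicit missingness mask;
marker metadata, phenotypes/covariates and gene intervals ride along as
small dataclasses wrapping numpy arrays / pandas frames.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "TraitTable",
    "GeneAnnotation",
    "FormatError",
]

#: Trait names carried by the standard beef-cattle phenotype table:
#: growth (average daily gain, live weight), carcass (carcass weight,
#: dressing/lean percentage, striploin, tenderloin, spencer roll, chuck
#: roll, retail meat weight) and meat quality (eye muscle areas, marbling).
TRAIT_NAMES = (
    "ADG", "LW", "CW", "DP", "LP", "ST", "TD",
    "SR", "CR", "RMW", "EMA12", "EMA13", "MB",
)

FIXED_EFFECT_COLS = ("sex", "year", "entry_weight", "fattening_days")


class FormatError(ValueError):
    """Raised when an input file or container violates its format contract."""


@dataclass
class MarkerMap:
    """Per-SNP identity: id, autosome label, 1-based bp position, alleles."""

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        if len({len(self.marker_id), len(self.chromosome), len(self.position_bp),
                len(self.allele_a), len(self.allele_b)}) != 1:
            raise FormatError("marker map fields have unequal lengths")
        ids, counts = np.unique(self.marker_id.astype(str), return_counts=True)
        if (counts > 1).any():
            raise FormatError(f"duplicate marker ids: {ids[counts > 1][:5].tolist()}")
        if (self.position_bp < 0).any():
            raise FormatError("negative marker positions")

    def __len__(self) -> int:
        return len(self.marker_id)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[idx], self.chromosome[idx],
                         self.position_bp[idx], self.allele_a[idx], self.allele_b[idx])

    def argsort_genome(self) -> np.ndarray:
        """Indices sorting markers by (chromosome, position, id)."""
        return np.lexsort((self.marker_id.astype(str), self.position_bp, self.chromosome))

    def index_of(self, marker_ids) -> np.ndarray:
        """Positions of the given ids in this map; KeyError on unknown id."""
        lookup = {m: i for i, m in enumerate(self.marker_id)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_id.astype(str),
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
            "allele_a": self.allele_a.astype(str),
            "allele_b": self.allele_b.astype(str),
        })


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage codes with a missing mask."""

    values: np.ndarray
    missing: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.values.shape != self.missing.shape:
            raise FormatError("values and missing mask shapes differ")
        if self.values.shape[0] != len(self.individual_ids):
            raise FormatError("row count does not match number of individual ids")
        valid = self.values[~self.missing]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise FormatError("genotype codes outside {0,1,2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def dosages(self) -> np.ndarray:
        """Float copy with missing entries as nan."""
        out = self.values.astype(float)
        out[self.missing] = np.nan
        return out

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = slice(None) if rows is None else rows
        cols = slice(None) if cols is None else cols
        return GenotypeMatrix(self.values[rows][:, cols], self.missing[rows][:, cols],
                              self.individual_ids[rows])


@dataclass
class TraitTable:
    """Phenotypes plus fixed-effect covariates, indexed by individual id.

    ``data`` holds one row per individual with trait columns (possibly NaN),
    the categorical fixed effects (sex, year), the covariates (entry_weight,
    fattening_days) and birth_year for the before/after split.
    """

    data: pd.DataFrame
    traits: tuple = TRAIT_NAMES

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        missing_cols = [c for c in self.traits if c not in self.data.columns]
        if missing_cols:
            raise FormatError(f"trait columns absent from table: {missing_cols}")
        if "individual_id" in self.data.columns:
            self.data = self.data.set_index("individual_id")
        self.data.index = self.data.index.astype(str)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    def phenotype(self, trait: str) -> np.ndarray:
        return self.data[trait].to_numpy(dtype=float)

    def fixed_design(self, covariates=FIXED_EFFECT_COLS) -> tuple:
        """Full-rank fixed-effect design (intercept + dummies + covariates).

        Returns (matrix, column_names).  Categorical columns are dummy-coded
        dropping the first level.
        """
        cols = [np.ones(len(self.data))]
        names = ["intercept"]
        for c in covariates:
            if c not in self.data.columns:
                continue
            col = self.data[c]
            if col.dtype == object or str(col.dtype) == "category" or c in ("sex", "year"):
                levels = pd.unique(col)
                for lev in levels[1:]:
                    cols.append((col == lev).to_numpy(dtype=float))
                    names.append(f"{c}[{lev}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
        return np.column_stack(cols), names


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open (BED convention)."""

    gene_id: np.ndarray
    chromosome: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.start_bp = np.asarray(self.start_bp, dtype=np.int64)
        self.end_bp = np.asarray(self.end_bp, dtype=np.int64)
        if (self.start_bp > self.end_bp).any():
            bad = self.gene_id[self.start_bp > self.end_bp][:5]
            raise FormatError(f"gene interval start > end: {bad.tolist()}")
        ids, counts = np.unique(self.gene_id.astype(str), return_counts=True)
        if (counts > 1).any():
            raise FormatError(f"duplicate gene ids: {ids[counts > 1][:5].tolist()}")

    def __len__(self) -> int:
        return len(self.gene_id)

    def contains(self, chromosome: int, position_bp: int) -> np.ndarray:
        """Boolean mask of genes containing a 1-based marker position.

        A marker at 1-based position p lies in the half-open interval
        [start, end) iff start < p <= end.
        """
        return ((self.chromosome == chromosome)
                & (self.start_bp < position_bp)
                & (position_bp <= self.end_bp))
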