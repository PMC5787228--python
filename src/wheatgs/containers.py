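"""Shared data containers for marker, map, phenotype, and kinship data.

Markers are biallelic and coded -1/+1 for the two homozygous states and 0 for
heterozygotes; missing calls are NaN.  After imputation calls may be
fractional in [-1, +1].  All containers are thin wrappers around pandas
objects so that standard tooling (CSV/TSV IO, joins, groupbys) applies
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["line", "trial", "year", "rep", "trait", "value", "is_check"]


@dataclass
class MarkerMatrix:
    """Lines x markers genotype matrix.

    ``calls`` is indexed by line id with one column per marker id.  Values are
    in {-1, 0, +1}, NaN for missing, or fractional in [-1, +1] after
    imputation.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated line ids: {dups}")
        if self.calls.columns.has_duplicates:
            dups = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated marker ids: {dups}")
        vals = self.calls.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < -1) | (vals > 1))
        if bad:
            raise ValueError(f"{int(bad)} genotype calls outside [-1, +1]")

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missingness(self) -> pd.Series:
        """Fraction of missing calls per marker."""
        return self.calls.isna().mean(axis=0)

    def call_rate(self) -> pd.Series:
        return 1.0 - self.missingness()

    def allele_freq(self) -> pd.Series:
        """Frequency of the +1-coded allele per marker (heterozygotes count half)."""
        return (self.calls + 1.0).mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def has_missing(self) -> bool:
        return bool(self.calls.isna().to_numpy().any())

    def subset(self, lines=None, markers=None) -> "MarkerMatrix":
        calls = self.calls
        if lines is not None:
            calls = calls.loc[list(lines)]
        if markers is not None:
            calls = calls[list(markers)]
        return MarkerMatrix(calls.copy())


@dataclass
class MarkerMap:
    """Genetic map: one row per marker with chromosome and position in cM."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cM

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos_cM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            raise ValueError("duplicated marker ids in map")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker"])

    def positions(self) -> pd.DataFrame:
        return self.table.set_index("marker")

    def sorted_within_chromosomes(self) -> bool:
        return all(
            grp["pos_cM"].is_monotonic_increasing
            for _, grp in self.table.groupby("chrom", sort=False)
        )


@dataclass
class PhenotypeRecords:
    """Long-format plot-level phenotype records.

    Columns: line, trial, year, rep, trait, value, is_check.  One row per
    trait measurement on one plot (= line x trial x rep).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PHENO_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite phenotype values")
        keys = self.records[["line", "trial", "trait", "rep"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (line, trial, trait, rep) records")

    @property
    def traits(self) -> list[str]:
        return list(self.records["trait"].unique())

    @property
    def trials(self) -> list[str]:
        return list(self.records["trial"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait].copy()

    def for_trial(self, trial, trait: str | None = None) -> "PhenotypeRecords":
        sub = self.records[self.records["trial"] == trial]
        if trait is not None:
            sub = sub[sub["trait"] == trait]
        return PhenotypeRecords(sub.copy())


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix K = W W' / (2 sum p_k (1 - p_k)).

    ``values`` is symmetric lines x lines; ``denominator`` stores the
    normalisation scalar 2 sum p_k (1 - p_k) used to build it.
    """

    values: np.ndarray
    line_ids: list[str] = field(default_factory=list)
    denominator: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")
        if self.line_ids and len(self.line_ids) != self.values.shape[0]:
            raise ValueError("line ids inconsistent with matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def indexer(self, lines) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([pos[l] for l in lines], dtype=int)
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} not present in kinship matrix") from exc

    def submatrix(self, rows, cols) -> np.ndarray:
        ri = self.indexer(rows)
        ci = self.indexer(cols)
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)
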