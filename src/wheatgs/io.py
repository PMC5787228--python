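"""Plain-text readers and writers for genotype, map, phenotype, and result files.

Formats (all inspectable text):

* genotype TSV — rows = lines (first column ``line``), columns = markers,
  values -1/0/1 (fractional after imputation) or NA;
* map TSV — columns ``marker``, ``chrom``, ``pos_cM``;
* phenotype CSV — long format ``line, trial, year, rep, trait, value, is_check``;
* truth CSV — ``line, trait, true_bv``;
* BLUEs CSV — ``line, trait, blue``; kinship TSV with line ids on both axes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PHENO_COLUMNS, KinshipMatrix, MarkerMap, MarkerMatrix

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_map", "write_map",
    "read_phenotypes", "write_phenotypes",
    "read_truth", "write_truth",
    "read_blues", "write_blues",
    "read_kinship", "write_kinship",
    "write_json", "read_json",
]

def write_genotypes(markers: MarkerMatrix, path) -> Path:
    path = Path(path)
    markers.calls.to_csv(path, sep="\t", index_label="line", na_rep="NA", float_format="%g")
    return path


def read_genotypes(path) -> MarkerMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col="line", na_values=["NA"])
    df.index.name = None
    df = df.astype(float)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated line id(s) in {path}: {dup}")
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(vals) & ((vals < -1) | (vals > 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"illegal genotype code {vals[i, j]!r} at line {df.index[i]!r}, "
            f"marker {df.columns[j]!r} in {path}"
        )
    return MarkerMatrix(df)


def write_map(marker_map: MarkerMap, path) -> Path:
    path = Path(path)
    marker_map.table.to_csv(path, sep="\t", index=False)
    return path


def read_map(path, genotype_markers: list[str] | None = None) -> MarkerMap:
    df = pd.read_csv(Path(path), sep="\t")
    mmap = MarkerMap(df)
    if genotype_markers is not None:
        unmapped = sorted(set(genotype_markers) - set(mmap.marker_ids))
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} genotyped markers have no map position "
                f"(e.g. {unmapped[:3]}); they are retained unmapped"
            )
    return mmap


def write_phenotypes(pheno, path) -> Path:
    path = Path(path)
    df = pheno.records if hasattr(pheno, "records") else pheno
    df.to_csv(path, index=False)
    return path


def read_phenotypes(path) -> "PhenotypeRecords":
    from .containers import PhenotypeRecords

    df = pd.read_csv(Path(path))
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} missing columns: {sorted(missing)}")
    return PhenotypeRecords(df)


def write_truth(true_bv: pd.DataFrame, path) -> Path:
    path = Path(path)
    long = true_bv.reset_index(names="line").melt(
        id_vars="line", var_name="trait", value_name="true_bv"
    )
    long.to_csv(path, index=False)
    return path


def read_truth(path) -> pd.DataFrame:
    long = pd.read_csv(Path(path))
    return long.pivot(index="line", columns="trait", values="true_bv")


def write_blues(blues: pd.DataFrame | pd.Series, path, trait: str | None = None) -> Path:
    path = Path(path)
    if isinstance(blues, pd.Series):
        blues = blues.rename("blue").to_frame().assign(trait=trait or blues.name)
        blues = blues.reset_index(names="line")[["line", "trait", "blue"]]
    else:
        blues = blues.reset_index(names="line").melt(
            id_vars="line", var_name="trait", value_name="blue"
        )
    blues.dropna(subset=["blue"]).to_csv(path, index=False)
    return path


def read_blues(path) -> pd.DataFrame:
    long = pd.read_csv(Path(path))
    return long.pivot(index="line", columns="trait", values="blue")


def write_kinship(K: KinshipMatrix, path) -> Path:
    path = Path(path)
    df = K.to_frame()
    df.attrs["denominator"] = K.denominator
    df.to_csv(path, sep="\t", index_label="line")
    return path


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col="line")
    return KinshipMatrix(values=df.to_numpy(float), line_ids=list(df.index))


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
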