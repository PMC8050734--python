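"""Reading, validation and writing of the standard tabular inputs.

Abundance matrices are plain TSV (first column = feature identifiers,
header = sample identifiers); the sample design is a TSV with columns
``sample_id, zt, condition, replicate, regime``.  Gene sets use the GMT
format.  Result tables round-trip losslessly through TSV or JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ["sample_id", "zt", "condition", "replicate", "regime"]

__all__ = [
    "DESIGN_COLUMNS",
    "GeneSet",
    "GeneSetCollection",
    "read_matrix",
    "read_design",
    "read_gmt",
    "write_matrix",
    "write_design",
    "write_gmt",
    "write_results",
    "read_results",
    "validate_matrix",
    "validate_design",
    "file_sha256",
]


class ValidationError(ValueError):
    """Raised when an input file violates a documented invariant."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset


@dataclass
class GeneSetCollection:
    """Named gene sets with unique names and non-empty member sets."""

    sets: dict = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValidationError(f"duplicate gene-set name: {gene_set.name!r}")
        if not gene_set.members:
            raise ValidationError(f"gene set {gene_set.name!r} has no members")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name) -> bool:
        return name in self.sets

    def __getitem__(self, name) -> GeneSet:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-design invariants and return a clean copy.

    Zeitgeber times must lie in [0, 24); each (condition, zt) cell needs at
    least one replicate and the zt grid must be common to all conditions.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design is missing columns: {missing}")
    design = design[DESIGN_COLUMNS].copy()
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in design: {dups}")
    zt = pd.to_numeric(design["zt"], errors="coerce")
    if zt.isna().any():
        raise ValidationError("non-numeric zt values in design")
    if ((zt < 0) | (zt >= 24)).any():
        bad = sorted(zt[(zt < 0) | (zt >= 24)].unique().tolist())
        raise ValidationError(f"zt values outside [0, 24): {bad}")
    design["zt"] = zt.astype(float)
    rep = pd.to_numeric(design["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.round()).any():
        raise ValidationError("replicate must be a positive integer")
    design["replicate"] = rep.astype(int)
    grids = design.groupby("condition")["zt"].apply(lambda s: tuple(sorted(s.unique())))
    if len(set(grids)) > 1:
        raise ValidationError(f"zt grids differ between conditions: {dict(grids)}")
    return design


def validate_matrix(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check matrix invariants against a validated design; reorder columns.

    Values must be finite and nonnegative; missing entries are NaN (empty
    TSV cells), never zero-coded.
    """
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValidationError(f"duplicate feature ids: {dups}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in matrix: {dups}")
    design_ids = list(design["sample_id"])
    matrix_ids = set(matrix.columns)
    absent = [s for s in design_ids if s not in matrix_ids]
    if absent:
        raise ValidationError(f"design sample ids absent from matrix: {absent}")
    extra = [s for s in matrix.columns if s not in set(design_ids)]
    if extra:
        raise ValidationError(f"matrix sample ids absent from design: {extra}")
    matrix = matrix[design_ids].copy()
    values = matrix.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValidationError("matrix contains non-finite abundances")
    if np.nanmin(values, initial=0.0) < 0:
        raise ValidationError("matrix contains negative abundances")
    return matrix.astype(float)


def read_design(design_path) -> pd.DataFrame:
    design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str},
                         float_precision="round_trip")
    return validate_design(design)


def read_matrix(matrix_path, design_path) -> tuple:
    """Read a feature x sample TSV and its design; return validated pair.

    Samples are reordered to design order.  Non-numeric abundances raise;
    empty cells become NaN (explicit missingness).
    """
    design = read_design(design_path)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad = coerced.isna() & matrix[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric abundance in sample {col!r}, "
                f"features {matrix.index[bad].tolist()[:5]}"
            )
        matrix[col] = coerced
    return validate_matrix(matrix, design), design


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set collapse; duplicate set names raise.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            collection.add(GeneSet(name, description, members))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for gene_set in collection:
            members = "\t".join(sorted(gene_set.members))
            handle.write(f"{gene_set.name}\t{gene_set.description}\t{members}\n")


def write_results(table: pd.DataFrame, path, format: str = "tsv") -> None:
    """Serialize a result table losslessly (full float precision).

    ``format`` is ``"tsv"`` or ``"json"`` (records orientation).  Column
    order is preserved as-is, which downstream code keeps stable.
    """
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        records = table.to_dict(orient="records")
        with open(path, "w") as handle:
            json.dump(
                {"columns": list(table.columns), "records": records},
                handle,
                indent=1,
                default=_json_default,
            )
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'json'")


def read_results(path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    if format == "json":
        with open(path) as handle:
            payload = json.load(handle)
        return pd.DataFrame(payload["records"], columns=payload["columns"])
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'json'")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_sha256(path) -> str:
    """Hex digest of a file, logged so analyses are replayable."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
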