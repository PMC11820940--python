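"""Reading and writing of phenotype tables, marker matrices, relationship
matrices, fold assignments and metric outputs.

All on-disk formats are plain CSV (UTF-8, header required):

* phenotypes — long format with columns ``line_id, environment, trait, value``
  (column names remappable via a schema); ``value`` holds adjusted line means
  (BLUEs) on the trait scale.  Missing values may be coded ``NA`` or left
  empty; they are kept and flagged, never silently dropped.
* markers — first column ``line_id``, one column per SNP, dosage codes
  0/1/2 (missing allowed as ``NA``/empty; imputation is done later so raw
  files round-trip).
* relationship matrix — symmetric, line ids as header row and first column.
* fold assignments — ``line_id, outer_fold``.
* metrics — long format ``dataset, environment, trait, model, method, fold,
  metric, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "MarkerMatrix",
    "SchemaError",
    "ValidationError",
    "read_phenotypes",
    "read_markers",
    "write_markers",
    "write_phenotypes",
    "write_metrics",
    "read_metrics",
    "write_grm",
    "read_grm",
    "write_folds",
    "read_folds",
    "check_line_consistency",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = [
    "dataset", "environment", "trait", "model", "method", "fold", "metric", "value",
]

#: numeric precision used when writing floating-point columns; read-back
#: round-trips bit-identically at this precision.
FLOAT_FORMAT = "%.12g"

_MISSING_CODES = {"", "NA", "na", "NaN", "nan"}


class SchemaError(ValueError):
    """A declared column is absent from the file."""


class ValidationError(ValueError):
    """File contents violate a container invariant."""


@dataclass
class PhenotypeTable:
    """Long-format table of adjusted line means.

    ``records`` has columns line_id, environment, trait, value; missing
    values are NaN and flagged in the boolean ``missing`` column.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line_id", "environment", "trait", "value"}
        if not required.issubset(self.records.columns):
            raise SchemaError(f"phenotype records need columns {sorted(required)}")
        if "missing" not in self.records.columns:
            self.records = self.records.assign(missing=self.records["value"].isna())
        dup = self.records.duplicated(subset=["line_id", "environment", "trait"])
        if dup.any():
            keys = self.records.loc[dup, ["line_id", "environment", "trait"]]
            raise ValidationError(
                "duplicate (line_id, environment, trait) triples: "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )
        vals = self.records["value"].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("non-finite phenotype values present")

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["line_id"]))

    @property
    def n_missing(self) -> int:
        return int(self.records["missing"].sum())

    def slice(self, environment: str, trait: str) -> pd.DataFrame:
        """Non-missing records of one (environment, trait) combination."""
        r = self.records
        out = r[(r["environment"] == environment) & (r["trait"] == trait) & ~r["missing"]]
        return out.reset_index(drop=True)

    def combinations(self) -> list[tuple[str, str]]:
        combos = self.records[["environment", "trait"]].drop_duplicates()
        return list(combos.itertuples(index=False, name=None))


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix, codes in [0, 2], NaN = missing."""

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float (n, p), NaN for missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValidationError("id lengths do not match dosage matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValidationError("duplicated line_ids")
        if len(set(self.marker_ids)) != p:
            raise ValidationError("duplicated marker_ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"dosage out of [0, 2] at line {self.line_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r}: {self.dosages[i, j]}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.marker_ids)
        df.insert(0, "line_id", self.line_ids)
        return df


def read_phenotypes(path: str | Path, schema: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a long-format phenotype CSV.

    ``schema`` maps the canonical names line_id/environment/trait/value to
    the file's column names; default assumes canonical names.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = schema or {}
    cols = {k: schema.get(k, k) for k in ("line_id", "environment", "trait", "value")}
    for canon, name in cols.items():
        if name not in raw.columns:
            raise SchemaError(f"column {name!r} (for {canon}) missing from {path}")
    df = raw[[cols["line_id"], cols["environment"], cols["trait"], cols["value"]]].copy()
    df.columns = ["line_id", "environment", "trait", "value"]
    values = df["value"].astype(str).str.strip()
    missing = values.isin(_MISSING_CODES)
    parsed = pd.to_numeric(values.where(~missing), errors="coerce")
    bad = parsed.isna() & ~missing
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-numeric phenotype value {values.iloc[row]!r} at data row {row}")
    df["value"] = parsed
    df["missing"] = missing.to_numpy()
    return PhenotypeTable(df)


def read_markers(path: str | Path) -> MarkerMatrix:
    """Read a marker CSV (first column line_id, one column per SNP)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: need a line_id column plus at least one marker")
    line_col = raw.columns[0]
    marker_ids = list(raw.columns[1:])
    line_ids = raw[line_col].tolist()
    dosages = np.empty((len(line_ids), len(marker_ids)), dtype=float)
    for j, mid in enumerate(marker_ids):
        col = raw[mid].astype(str).str.strip()
        missing = col.isin(_MISSING_CODES)
        parsed = pd.to_numeric(col.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-numeric genotype code {col.iloc[i]!r} at line {line_ids[i]!r}, marker {mid!r}"
            )
        dosages[:, j] = parsed.to_numpy(dtype=float)
    return MarkerMatrix(line_ids, marker_ids, dosages)


def write_markers(m: MarkerMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = m.to_frame()
    # integer codes written without decimal point so files stay readable
    if np.all(np.isnan(m.dosages) | (m.dosages == np.round(m.dosages))):
        df[m.marker_ids] = df[m.marker_ids].astype("Int64")
    df.to_csv(path, index=False, na_rep="NA")
    return path


def write_phenotypes(t: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    out = t.records[["line_id", "environment", "trait", "value"]]
    out.to_csv(path, index=False, na_rep="NA", float_format=FLOAT_FORMAT)
    return path


def write_metrics(results: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format metrics table (columns fixed and ordered)."""
    if len(results) == 0:
        raise ValidationError("refusing to write an empty metrics table")
    missing = [c for c in METRICS_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"metrics table missing columns {missing}")
    path = Path(path)
    results[METRICS_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metrics file missing columns {missing}")
    return df


def write_grm(line_ids: list[str], G: np.ndarray, path: str | Path) -> Path:
    df = pd.DataFrame(G, index=line_ids, columns=line_ids)
    df.to_csv(path, index_label="line_id", float_format=FLOAT_FORMAT)
    return Path(path)


def read_grm(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    line_ids = list(df.columns)
    if list(df.index.astype(str)) != line_ids:
        raise ValidationError("relationship matrix row and column ids differ")
    return line_ids, df.to_numpy(dtype=float)


def write_folds(assignment: pd.DataFrame, path: str | Path) -> Path:
    """Persist outer-fold membership as (line_id, outer_fold)."""
    if not {"line_id", "outer_fold"}.issubset(assignment.columns):
        raise SchemaError("fold assignment needs columns line_id, outer_fold")
    assignment[["line_id", "outer_fold"]].to_csv(path, index=False)
    return Path(path)


def read_folds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"line_id", "outer_fold"}.issubset(df.columns):
        raise SchemaError("fold assignment needs columns line_id, outer_fold")
    return df


def check_line_consistency(phenotypes: PhenotypeTable, markers: MarkerMatrix) -> list[str]:
    """Return every phenotype line_id absent from the marker matrix.

    The check is total: all mismatches are reported, none dropped.
    """
    have = set(markers.line_ids)
    return [lid for lid in phenotypes.line_ids if lid not in have]
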