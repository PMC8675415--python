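"""Shared data model, region catalog, and tabular readers/writers.

The pipeline operates on flat per-subject morphometry tables: one row per
subject, a handful of covariate columns (cohort, sex, age, scanner field
strength, segmentation-software version, optionally a global measure such as
total brain volume), and one numeric column per regional measure.  Regional
measures follow the standard whole-brain layout used in large consortium
studies: 14 subcortical volumes (7 structures per hemisphere) and 68 cortical
surface-area plus 68 cortical-thickness measures on the Desikan-Killiany
parcellation (34 regions per hemisphere).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "RegionCatalog",
    "SubjectTable",
    "AdjustedTable",
    "default_catalog",
    "read_subject_table",
    "write_subject_table",
    "write_results",
    "read_results",
    "REQUIRED_COLUMNS",
    "MEASURE_CLASSES",
]


class SchemaError(ValueError):
    """A required column is missing or the table layout is unusable."""


class ValidationError(ValueError):
    """Column values violate the declared data model."""


REQUIRED_COLUMNS = (
    "subject_id",
    "cohort",
    "sex",
    "age",
    "field_strength",
    "software_version",
)

GLOBAL_COV_COLUMN = "global_cov"

MEASURE_CLASSES = ("subcortical_volume", "cortical_area", "cortical_thickness")

SUBCORTICAL_STRUCTURES = (
    "accumbens",
    "caudate",
    "pallidum",
    "putamen",
    "amygdala",
    "hippocampus",
    "thalamus",
)

# Desikan-Killiany cortical parcellation, 34 regions per hemisphere.
DESIKAN_KILLIANY_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

_CLASS_SUFFIX = {
    "subcortical_volume": "vol",
    "cortical_area": "area",
    "cortical_thickness": "thick",
}


@dataclass(frozen=True)
class RegionCatalog:
    """Catalog of regional measures: id, class, hemisphere, region, atlas."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"measure_id", "measure_class", "hemisphere", "region_name", "atlas"}
        missing = required - set(self.entries.columns)
        if missing:
            raise SchemaError(f"catalog missing columns: {sorted(missing)}")
        ids = self.entries["measure_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate measure_ids in catalog: {dupes}")
        bad = set(self.entries["measure_class"]) - set(MEASURE_CLASSES)
        if bad:
            raise ValidationError(f"unknown measure classes: {sorted(bad)}")

    def measure_ids(self, measure_class: str | None = None) -> list[str]:
        if measure_class is None:
            return list(self.entries["measure_id"])
        if measure_class not in MEASURE_CLASSES:
            raise ValueError(f"unknown measure class {measure_class!r}")
        sel = self.entries["measure_class"] == measure_class
        return list(self.entries.loc[sel, "measure_id"])

    def n_measures(self, measure_class: str | None = None) -> int:
        return len(self.measure_ids(measure_class))

    def n_region_pairs(self, measure_class: str) -> int:
        """Number of unique unordered region pairs, n(n-1)/2."""
        n = self.n_measures(measure_class)
        return n * (n - 1) // 2

    def class_of(self, measure_id: str) -> str:
        row = self.entries.loc[self.entries["measure_id"] == measure_id]
        if row.empty:
            raise KeyError(f"measure {measure_id!r} not in catalog")
        return str(row["measure_class"].iloc[0])


def default_catalog() -> RegionCatalog:
    """Build the default 14 + 68 + 68 measure catalog."""
    rows = []
    for hemi in ("lh", "rh"):
        for structure in SUBCORTICAL_STRUCTURES:
            rows.append(
                (f"{hemi}_{structure}_vol", "subcortical_volume", hemi, structure, "aseg")
            )
    for cls in ("cortical_area", "cortical_thickness"):
        suffix = _CLASS_SUFFIX[cls]
        for hemi in ("lh", "rh"):
            for region in DESIKAN_KILLIANY_REGIONS:
                rows.append((f"{hemi}_{region}_{suffix}", cls, hemi, region, "desikan_killiany"))
    entries = pd.DataFrame(
        rows, columns=["measure_id", "measure_class", "hemisphere", "region_name", "atlas"]
    )
    return RegionCatalog(entries)


_SEX_ALIASES = {"m": "M", "male": "M", "males": "M", "f": "F", "female": "F", "females": "F"}


def _canonical_sex(series: pd.Series, sex_map: dict | None) -> pd.Series:
    norm_map = {str(k).strip().casefold(): v for k, v in (sex_map or {}).items()}

    def convert(v):
        key = str(v).strip().casefold()
        if key in norm_map:
            v = norm_map[key]
        s = str(v).strip().casefold()
        if s in _SEX_ALIASES:
            return _SEX_ALIASES[s]
        raise ValidationError(
            f"unrecognized sex value {v!r}; expected M/F or male/female "
            "(numeric codings require an explicit sex_map)"
        )

    return series.map(convert)


@dataclass
class SubjectTable:
    """Per-subject raw measures plus covariates, bound to a region catalog.

    ``data`` holds one row per subject with the covariate columns of
    :data:`REQUIRED_COLUMNS` (plus optionally ``global_cov``) followed by one
    column per measure.  ``meta`` carries provenance: validation reports,
    simulation ground truth, adjustment recipes.
    """

    data: pd.DataFrame
    catalog: RegionCatalog
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"subject table missing required columns: {missing}")
        if self.data["subject_id"].duplicated().any():
            raise ValidationError("subject_id values are not unique")
        bad_sex = set(self.data["sex"].unique()) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"sex column contains non-canonical values: {sorted(bad_sex)}")
        if (pd.to_numeric(self.data["age"], errors="coerce") <= 0).any():
            raise ValidationError("age must be positive")
        known = set(self.catalog.measure_ids())
        extra_ok = set(REQUIRED_COLUMNS) | {GLOBAL_COV_COLUMN}
        unknown = [c for c in self.data.columns if c not in known and c not in extra_ok]
        if unknown:
            raise ValidationError(f"measure columns not in catalog: {unknown}")

    @property
    def measures(self) -> list[str]:
        known = set(self.catalog.measure_ids())
        return [c for c in self.data.columns if c in known]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def male_mask(self) -> np.ndarray:
        return (self.data["sex"] == "M").to_numpy()

    def subset_measures(self, measure_ids: list[str]) -> "SubjectTable":
        cols = [c for c in self.data.columns if c not in set(self.catalog.measure_ids())]
        return SubjectTable(self.data[cols + list(measure_ids)].copy(), self.catalog, dict(self.meta))


@dataclass
class AdjustedTable(SubjectTable):
    """Residualized measures (r_i = y_i - yhat_i), same row order as the source.

    The adjustment recipe (which covariates were removed, whether age was in
    the mean model, RF seed and hyperparameters) lives in ``meta['recipe']``.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if "recipe" not in self.meta:
            self.meta["recipe"] = {}


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_subject_table(
    path: str | Path,
    catalog: RegionCatalog | None = None,
    sex_map: dict | None = None,
) -> SubjectTable:
    """Read a TSV/CSV subject table, auto-detecting the separator.

    Unparseable measure cells become missing values; the per-column counts of
    coerced cells are recorded in ``meta['validation']``.  Unknown columns
    (resolving in neither the covariate schema nor the catalog) are dropped
    with a note in the validation report.
    """
    path = Path(path)
    catalog = catalog or default_catalog()
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"input file {path} missing required columns: {missing}")

    known = set(catalog.measure_ids())
    covariates = set(REQUIRED_COLUMNS) | {GLOBAL_COV_COLUMN}
    measure_cols = [c for c in raw.columns if c in known]
    dropped = [c for c in raw.columns if c not in known and c not in covariates]

    out = pd.DataFrame(index=raw.index)
    out["subject_id"] = raw["subject_id"].astype(str)
    out["cohort"] = raw["cohort"].astype(str)
    out["sex"] = _canonical_sex(raw["sex"], sex_map)
    out["age"] = pd.to_numeric(raw["age"], errors="raise").astype(float)
    out["field_strength"] = raw["field_strength"].astype(str)
    out["software_version"] = raw["software_version"].astype(str)
    if GLOBAL_COV_COLUMN in raw.columns:
        out[GLOBAL_COV_COLUMN] = pd.to_numeric(raw[GLOBAL_COV_COLUMN], errors="coerce")

    coerced: dict[str, int] = {}
    for col in measure_cols:
        vals = pd.to_numeric(raw[col], errors="coerce")
        n_coerced = int((vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")).sum())
        if n_coerced:
            coerced[col] = n_coerced
        out[col] = vals.astype(float)

    meta = {
        "validation": {
            "source": str(path),
            "n_rows": len(out),
            "coerced_cells": coerced,
            "missing_per_measure": {c: int(out[c].isna().sum()) for c in measure_cols},
            "dropped_columns": dropped,
        }
    }
    return SubjectTable(out, catalog, meta)


def write_subject_table(table: SubjectTable, path: str | Path) -> Path:
    """Write a subject table as TSV (lossless float text representation)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(result, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a result as a TSV table plus a JSON metadata sidecar.

    ``result`` is either a DataFrame or any object exposing ``to_frame()``
    (and optionally a ``metadata`` attribute).  Numeric round trip is exact to
    well beyond 12 significant digits (%.17g text representation).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, pd.DataFrame):
        frame = result
        meta = dict(metadata or {})
    else:
        frame = result.to_frame()
        meta = dict(getattr(result, "metadata", {}) or {})
        if metadata:
            meta.update(metadata)
    try:
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back a result TSV and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return frame, meta


def sig_round(x: float, digits: int = 12) -> float:
    """Round to a number of significant digits (testing helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
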