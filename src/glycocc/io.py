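"""Data model and tabular I/O for per-sample glycan peak tables.

The on-disk exchange format is a delimited text table (UTF-8, tab for
``.tsv``/``.txt``, comma for ``.csv``) with one row per sample: identifier
and covariate columns followed by the 24 peak-area columns GP1..GP24.
Optional clinical columns (``ana``, ``pericarditis``, ``proteinuria``,
``duration_years``) are preserved when present and recorded as missing,
never as zero, when absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from ._errors import IntegrityError, SchemaError
from .panel import N_PEAKS, PEAKS, GlycanAnnotation

SCALES = ("raw_area", "percent_total", "log", "corrected_log", "proportion")

META_COLUMNS = ["sample_id", "cohort", "plate", "age", "sex", "status"]
CLINICAL_FLAGS = ["ana", "pericarditis", "proteinuria"]
CLINICAL_COLUMNS = CLINICAL_FLAGS + ["duration_years"]

_SEX_MAP = {"f": "F", "female": "F", "0": "F", "m": "M", "male": "M", "1": "M"}
_STATUS_MAP = {"case": "case", "1": "case", "control": "control", "0": "control"}


def _check_scale(scale: str) -> str:
    if scale not in SCALES:
        raise SchemaError(f"unknown scale {scale!r}; expected one of {SCALES}")
    return scale


@dataclass
class GlycanProfile:
    """One sample's 24 peak quantities on a declared scale."""

    values: Mapping[str, float]
    scale: str = "raw_area"

    def __post_init__(self) -> None:
        _check_scale(self.scale)
        if set(self.values) != set(PEAKS):
            raise SchemaError(
                f"profile must contain exactly the {N_PEAKS} peaks GP1..GP24"
            )
        arr = np.array([self.values[p] for p in PEAKS], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("profile contains non-finite values")
        if self.scale in ("raw_area", "percent_total", "proportion") and np.any(arr < 0):
            raise ValueError(f"negative value on scale {self.scale!r}")
        if self.scale == "percent_total" and not math.isclose(
            arr.sum(), 100.0, rel_tol=1e-9
        ):
            raise ValueError(f"percent_total profile sums to {arr.sum()!r}, not 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in PEAKS], dtype=float)


@dataclass
class SampleRecord:
    """Profile plus covariates for one sample."""

    sample_id: str
    cohort: str
    plate: str
    age: float
    sex: str  # "F" or "M"
    status: str  # "case" or "control"
    profile: GlycanProfile
    clinical: dict = field(default_factory=dict)
    duration_years: float | None = None

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case'/'control', got {self.status!r}")


class CohortTable:
    """Ordered collection of samples from one cohort, sharing one scale.

    Thin wrapper around a :class:`pandas.DataFrame` (metadata + GP columns)
    carrying a scale tag and provenance metadata.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        scale: str = "raw_area",
        name: str | None = None,
        provenance: dict | None = None,
    ) -> None:
        _check_scale(scale)
        missing = [c for c in ["sample_id", "age", "sex", "status"] if c not in frame.columns]
        if missing:
            raise SchemaError(f"cohort table missing mandatory column(s): {missing}")
        gp_missing = [p for p in PEAKS if p not in frame.columns]
        if gp_missing:
            raise SchemaError(f"cohort table missing peak column(s): {gp_missing}")
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate sample_id(s): {sorted(set(dup))}")
        self.frame = frame.reset_index(drop=True)
        self.scale = scale
        self.name = name or (
            str(frame["cohort"].iloc[0]) if "cohort" in frame.columns and len(frame) else "cohort"
        )
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_cases(self) -> int:
        return int((self.frame["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.frame["status"] == "control").sum())

    def matrix(self) -> "GlycanMatrix":
        """The samples x 24 peak matrix, indexed by sample_id."""
        data = self.frame.set_index("sample_id")[list(PEAKS)].astype(float)
        return GlycanMatrix(data, self.scale)

    def with_matrix(self, matrix: "GlycanMatrix") -> "CohortTable":
        """Copy of this table with peak values replaced by ``matrix``."""
        if list(matrix.data.index) != list(self.frame["sample_id"]):
            raise IntegrityError("matrix sample labels do not align with cohort table")
        frame = self.frame.copy()
        frame[list(PEAKS)] = matrix.data.to_numpy()
        return CohortTable(frame, matrix.scale, self.name, dict(self.provenance))

    def records(self) -> Iterator[SampleRecord]:
        for _, row in self.frame.iterrows():
            clinical = {
                f: (None if pd.isna(row[f]) else bool(row[f]))
                for f in CLINICAL_FLAGS
                if f in row.index
            }
            dur = row.get("duration_years")
            yield SampleRecord(
                sample_id=str(row["sample_id"]),
                cohort=str(row.get("cohort", self.name)),
                plate=str(row.get("plate", "")),
                age=float(row["age"]),
                sex=str(row["sex"]),
                status=str(row["status"]),
                profile=GlycanProfile(
                    {p: float(row[p]) for p in PEAKS}, self.scale
                ),
                clinical=clinical,
                duration_years=None if dur is None or pd.isna(dur) else float(dur),
            )


@dataclass
class GlycanMatrix:
    """samples x features matrix of peak values with a scale tag.

    Cohort-level matrices carry the full GP1..GP24 panel (enforced by
    :meth:`CohortTable.matrix`); smaller feature sets are permitted so the
    preprocessing operations stay usable on sub-panels.
    """

    data: pd.DataFrame
    scale: str = "raw_area"

    def __post_init__(self) -> None:
        _check_scale(self.scale)
        if len(self.data.columns) == 0 or self.data.columns.duplicated().any():
            raise SchemaError("GlycanMatrix needs non-empty, unique feature columns")
        if self.data.isna().any().any():
            raise ValueError("GlycanMatrix contains missing cells")

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def replace(self, values: np.ndarray, scale: str) -> "GlycanMatrix":
        return GlycanMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            scale,
        )


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def normalize_sex(value) -> str:
    key = str(value).strip().lower()
    if key not in _SEX_MAP:
        raise ValueError(f"cannot interpret sex value {value!r}")
    return _SEX_MAP[key]


def normalize_status(value) -> str:
    key = str(value).strip().lower()
    if key not in _STATUS_MAP:
        raise ValueError(f"cannot interpret status value {value!r}")
    return _STATUS_MAP[key]


def read_cohort_table(
    path: str | Path,
    panel: GlycanAnnotation | None = None,
    scale: str = "raw_area",
) -> CohortTable:
    """Read and validate a per-sample cohort table.

    Raises
    ------
    SchemaError
        if a mandatory column (sample_id, age, sex, status, or any GP) is
        absent.
    ValueError
        for non-numeric or negative peak areas, citing row and column.
    IntegrityError
        for duplicate sample identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ["sample_id", "age", "sex", "status"]:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    for p in PEAKS:
        if p not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {p!r}")
    for p in PEAKS:
        col = pd.to_numeric(df[p], errors="coerce")
        bad = df.index[col.isna() & df[p].notna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric peak area in column {p}, row {int(bad[0])}"
            )
        if col.isna().any():
            raise ValueError(
                f"{path.name}: missing peak area in column {p}, "
                f"row {int(df.index[col.isna()][0])}"
            )
        neg = df.index[col < 0]
        if len(neg):
            raise ValueError(
                f"{path.name}: negative peak area {col[neg[0]]} in column {p}, "
                f"row {int(neg[0])}"
            )
        df[p] = col.astype(float)
    df["sex"] = df["sex"].map(normalize_sex)
    df["status"] = df["status"].map(normalize_status)
    df["age"] = pd.to_numeric(df["age"])
    # optional clinical columns stay as-is; absent ones are simply not present
    return CohortTable(df, scale=scale, provenance={"file": str(path)})


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# association result tables

ASSOC_COLUMNS = [
    "glycan",
    "description",
    "cohort",
    "n_cases",
    "n_controls",
    "beta",
    "se",
    "OR",
    "ci_low",
    "ci_high",
    "p",
    "p_adjusted",
]


def write_association_table(results, path: str | Path) -> None:
    """Serialize association results (list of AssociationResult or DataFrame).

    Columns mirror a meta-analysis summary table: glycan, description,
    cohort (or "meta"), OR with CI bounds, raw and adjusted p.  Numbers keep
    12 significant digits so a read-back round-trip is exact to 1e-9.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        results = list(results)
        if not results:
            raise ValueError("refusing to write an empty association table")
        df = pd.DataFrame([r.as_dict() for r in results])
    if df.empty:
        raise ValueError("refusing to write an empty association table")
    df = df.reindex(columns=[c for c in ASSOC_COLUMNS if c in df.columns])
    try:
        df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing association table to {path}: {exc}") from exc


def read_association_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
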