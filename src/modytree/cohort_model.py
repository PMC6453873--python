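"""Domain types for patients and cohorts, plus delimited-table I/O.

A cohort is an ordered collection of patient records, one per subject, each
carrying a diagnostic group label (HNF1A MODY, GCK MODY, type 1 or type 2
diabetes), basic clinical characteristics and the fasting biomarkers used by
the diagnostic tree: serum C-peptide (ng/ml), hsCRP (mg/l) and
1,5-anhydroglucitol (μg/ml).

The on-disk format is a plain CSV with a fixed lowercase snake-case header,
comma delimiter and decimal point; missing values are empty cells. Units are
fixed per column and never auto-converted.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .exceptions import CohortFormatError, CohortValidationError

__all__ = [
    "Group",
    "Sex",
    "Treatment",
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "COLUMNS",
    "NUMERIC_FIELDS",
    "BIOMARKER_FIELDS",
]


class Group(str, enum.Enum):
    """Diagnostic group (ground-truth label)."""

    HNF1A = "HNF1A"
    GCK = "GCK"
    T1D = "T1D"
    T2D = "T2D"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Treatment(str, enum.Enum):
    INSULIN = "insulin"
    NON_INSULIN = "non_insulin"
    DIET = "diet"


#: fixed CSV column order (also the full field list of :class:`PatientRecord`)
COLUMNS: tuple[str, ...] = (
    "id",
    "group",
    "sex",
    "age",
    "diabetes_duration",
    "age_at_diagnosis",
    "bmi",
    "creatinine",
    "hba1c",
    "fasting_glucose",
    "c_peptide",
    "hscrp",
    "ag15",
    "treatment",
)

NUMERIC_FIELDS: tuple[str, ...] = (
    "age",
    "diabetes_duration",
    "age_at_diagnosis",
    "bmi",
    "creatinine",
    "hba1c",
    "fasting_glucose",
    "c_peptide",
    "hscrp",
    "ag15",
)

#: markers eligible for the decision tree
BIOMARKER_FIELDS: tuple[str, ...] = ("c_peptide", "bmi", "ag15", "hscrp", "fasting_glucose")

# soft plausibility bounds -> warnings, never hard errors
_PLAUSIBILITY = {"bmi": (10.0, 80.0), "hba1c": (3.0, 20.0)}

_ENUM_FIELDS = {"group": Group, "sex": Sex, "treatment": Treatment}


@dataclass(frozen=True)
class PatientRecord:
    """One subject: group label plus clinical/biomarker measurements.

    Units: age/duration in years, BMI kg/m², creatinine μmol/l, HbA1c % (NGSP),
    fasting glucose mmol/l, C-peptide ng/ml, hsCRP mg/l, 1,5-AG μg/ml.
    All numeric fields are optional (``None`` when missing) but must be
    strictly positive when present.
    """

    id: str
    group: Group | None = None
    sex: Sex | None = None
    age: float | None = None
    diabetes_duration: float | None = None
    age_at_diagnosis: float | None = None
    bmi: float | None = None
    creatinine: float | None = None
    hba1c: float | None = None
    fasting_glucose: float | None = None
    c_peptide: float | None = None
    hscrp: float | None = None
    ag15: float | None = None
    treatment: Treatment | None = None

    def validation_errors(
        self,
        require_group: bool = True,
        c_peptide_floor: float | None = None,
    ) -> list[str]:
        """Return hard-invariant violations for this record (empty = valid)."""
        errs: list[str] = []
        if not self.id:
            errs.append("empty id")
        if require_group and self.group is None:
            errs.append("missing group label")
        for name in NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                errs.append(f"{name} is not finite")
            elif v <= 0:
                errs.append(f"{name} must be strictly positive, got {v!r}")
        if (
            c_peptide_floor is not None
            and self.c_peptide is not None
            and self.c_peptide < c_peptide_floor
        ):
            errs.append(
                f"c_peptide {self.c_peptide!r} below detection floor {c_peptide_floor!r}"
            )
        return errs

    def plausibility_warnings(self) -> list[str]:
        out = []
        for name, (lo, hi) in _PLAUSIBILITY.items():
            v = getattr(self, name)
            if v is not None and not (lo < v < hi):
                out.append(f"{name}={v!r} outside plausible range ({lo}, {hi})")
        return out


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(
                [(-1, f"duplicate patient id(s): {', '.join(dupes)}")]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def groups(self) -> set[Group]:
        return {r.group for r in self.records if r.group is not None}

    def group_sizes(self) -> dict[Group, int]:
        out: dict[Group, int] = {}
        for r in self.records:
            if r.group is not None:
                out[r.group] = out.get(r.group, 0) + 1
        return out

    def subset(self, keep) -> "Cohort":
        """New cohort with records for which ``keep(record)`` is true."""
        return Cohort([r for r in self.records if keep(r)], provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {}
            for name in COLUMNS:
                v = getattr(r, name)
                row[name] = v.value if isinstance(v, enum.Enum) else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COLUMNS))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        provenance: str = "",
        require_group: bool = True,
        c_peptide_floor: float | None = None,
        on_invalid: str = "raise",
    ) -> "Cohort":
        """Build a validated cohort from a data frame with the fixed columns.

        ``on_invalid`` is ``"raise"`` (aggregate all row diagnostics into one
        :class:`CohortValidationError`) or ``"drop"`` (drop offending rows with
        a warning each).
        """
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
        records: list[PatientRecord] = []
        diagnostics: list[tuple[int, str]] = []
        for i, (_, row) in enumerate(df.iterrows()):
            try:
                rec = _record_from_row(row)
            except ValueError as exc:
                diagnostics.append((i, str(exc)))
                continue
            errs = rec.validation_errors(
                require_group=require_group, c_peptide_floor=c_peptide_floor
            )
            if errs:
                diagnostics.append((i, "; ".join(errs)))
                continue
            for w in rec.plausibility_warnings():
                warnings.warn(f"row {i}: {w}", stacklevel=3)
            records.append(rec)
        if diagnostics:
            if on_invalid == "raise":
                raise CohortValidationError(diagnostics)
            for i, msg in diagnostics:
                warnings.warn(f"dropped row {i}: {msg}", stacklevel=3)
        return cls(records, provenance=provenance)


def _parse_cell(name: str, value) -> object:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if name in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[name](str(value))
        except ValueError:
            raise ValueError(f"unrecognized {name} value {value!r}") from None
    if name in NUMERIC_FIELDS:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ValueError(f"unparseable numeric in column {name!r}: {value!r}") from None
    return str(value)


def _record_from_row(row: pd.Series) -> PatientRecord:
    kwargs = {name: _parse_cell(name, row[name]) for name in COLUMNS}
    if kwargs["id"] is None:
        raise ValueError("empty id")
    return PatientRecord(**kwargs)  # type: ignore[arg-type]


def read_cohort(
    path,
    require_group: bool = True,
    c_peptide_floor: float | None = None,
    on_invalid: str = "raise",
) -> Cohort:
    """Read and validate a cohort CSV.

    Set ``require_group=False`` in classification mode, where the ground-truth
    label column may be empty.
    """
    try:
        df = pd.read_csv(
            path, dtype={"id": str}, keep_default_na=True, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CohortFormatError(f"could not parse {path}: {exc}") from exc
    return Cohort.from_dataframe(
        df,
        provenance=str(path),
        require_group=require_group,
        c_peptide_floor=c_peptide_floor,
        on_invalid=on_invalid,
    )


def write_cohort(cohort: Cohort, path) -> str:
    """Write the cohort as CSV (fixed column order, full float precision)."""
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    df = cohort.to_dataframe()
    # str(float) is the shortest round-trip representation in py3
    df.to_csv(path, index=False)
    return str(path)


def marker_frame(records: Sequence[PatientRecord] | Cohort, markers: Iterable[str]) -> pd.DataFrame:
    """Extract a complete marker matrix; raises on any missing value."""
    from .exceptions import MissingMarkerError

    markers = list(markers)
    if isinstance(records, Cohort):
        records = records.records
    data = {m: [] for m in markers}
    for r in records:
        for m in markers:
            v = getattr(r, m, None)
            if v is None:
                raise MissingMarkerError(m, r.id)
            data[m].append(float(v))
    return pd.DataFrame(data, columns=markers)
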