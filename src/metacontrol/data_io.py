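"""Study-level data model, CSV interchange, validation and subset filtering.

The unit of analysis is one control-arm comparison from a large-animal
myocardial-infarction experiment: a raw-mean percentage outcome (infarct size
as % of area at risk, infarct size as % of left ventricle, or ejection
fraction) together with the design moderators (species, sex, occlusion type,
occluded vessel, surgical approach, co-medication, immunosuppression,
quantification method, follow-up, ischemia duration, quality score, weight,
age) and per-phase mortality counts.

CSV layout: one row per control-arm comparison; the column dictionary is
shipped in ``docs/column_dictionary.md``.  Unreported categorical values are a
first-class level (``"unknown"`` / ``"unreported"``), never dropped.  Optional
continuous moderators encode missing as an empty cell (0 is a legal value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .exceptions import ConfigurationError, DataValidationError, SchemaError

logger = logging.getLogger(__name__)

OUTCOMES = ("IS_AAR", "IS_LV", "EF")
SPECIES = ("dog", "pig", "sheep")
STRAINS = ("regular_pig", "minipig", "unreported")
SEXES = ("male", "female", "both", "unknown")
OCCLUSIONS = ("permanent", "temporary", "unknown")
VESSELS = ("LAD", "LCX", "LAD_LCX", "RCA", "unknown")
APPROACHES = ("open", "closed", "unknown")
PHASES = ("peri", "post")

#: categorical moderators with a closed level set (quantification is free text)
CATEGORICAL_LEVELS = {
    "species": SPECIES,
    "strain": STRAINS,
    "sex": SEXES,
    "occlusion": OCCLUSIONS,
    "vessel": VESSELS,
    "approach": APPROACHES,
}

#: moderators treated as categorical in regression models
CATEGORICAL_MODERATORS = (
    "species",
    "strain",
    "sex",
    "occlusion",
    "vessel",
    "approach",
    "comedication",
    "immunosuppression",
    "quantification",
)

#: moderators entered untransformed in their canonical unit
#: (hours / minutes / points / kg / weeks — chosen so regression coefficients
#: read directly as points-per-unit)
CONTINUOUS_MODERATORS = (
    "follow_up_hours",
    "ischemia_minutes",
    "quality_score",
    "weight_kg",
    "age_weeks",
)


def hours_from_days(days: float) -> float:
    """Convert follow-up days to the canonical storage unit (hours)."""
    return float(days) * 24.0


def minutes_from_hours(hours: float) -> float:
    """Convert ischemia hours to the canonical storage unit (minutes)."""
    return float(hours) * 60.0


@dataclass
class Moderators:
    """The moderator set shared by outcome arms and mortality records."""

    species: str = "pig"
    strain: Optional[str] = None  # pigs only
    sex: str = "unknown"
    occlusion: str = "temporary"
    vessel: str = "LAD"
    approach: str = "open"
    comedication: bool = False
    immunosuppression: bool = False
    quantification: str = "TTC"
    follow_up_hours: float = 168.0
    ischemia_minutes: Optional[float] = None  # only when occlusion is temporary
    quality_score: int = 5
    weight_kg: Optional[float] = None
    age_weeks: Optional[float] = None
    vf_excluded_untreated: bool = False

    def _validate_moderators(self) -> list:
        msgs = []
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if name == "strain":
                if self.species == "pig":
                    if value not in STRAINS:
                        msgs.append(f"strain {value!r} not in {STRAINS}")
                elif value is not None:
                    msgs.append("strain is only defined for pigs")
                continue
            if value not in levels:
                msgs.append(f"{name} {value!r} not in {levels}")
        if self.follow_up_hours is None or self.follow_up_hours < 0:
            msgs.append("follow_up_hours must be a nonnegative real")
        if self.ischemia_minutes is not None:
            if self.occlusion != "temporary":
                msgs.append("ischemia_minutes present requires occlusion = temporary")
            elif self.ischemia_minutes < 0:
                msgs.append("ischemia_minutes must be nonnegative")
        if self.quality_score is None or self.quality_score < 0:
            msgs.append("quality_score must be a nonnegative integer")
        if self.weight_kg is not None and self.weight_kg <= 0:
            msgs.append("weight_kg must be positive when present")
        if self.age_weeks is not None and self.age_weeks <= 0:
            msgs.append("age_weeks must be positive when present")
        return msgs


@dataclass
class StudyArm(Moderators):
    """One control-arm comparison for one percentage outcome."""

    study_id: str = ""
    outcome: str = "IS_AAR"
    mean: float = 0.0
    sd: float = 0.0
    n_animals: int = 1

    def validate(self) -> list:
        msgs = self._validate_moderators()
        if not self.study_id:
            msgs.append("study_id is required")
        if self.outcome not in OUTCOMES:
            msgs.append(f"outcome {self.outcome!r} not in {OUTCOMES}")
        if not (0.0 <= self.mean <= 100.0):
            msgs.append(f"mean {self.mean} outside [0, 100] (outcomes are percentages)")
        if self.sd < 0:
            msgs.append("sd must be >= 0")
        if self.n_animals < 1:
            msgs.append("n_animals must be a positive integer")
        if self.n_animals > 1 and not self.sd > 0:
            msgs.append("sd must be > 0 whenever n_animals > 1")
        return msgs


@dataclass
class MortalityRecord(Moderators):
    """Per-phase death counts for one comparison.

    ``second_stage`` holds a (deaths, total) pair when mortality was reported
    twice in the same procedural setting (e.g. before and after
    randomization); the two proportions are combined downstream via
    1 - p_total = (1 - p1)(1 - p2).
    """

    study_id: str = ""
    phase: str = "peri"
    deaths: int = 0
    total: int = 1
    second_stage: Optional[tuple] = None  # (deaths2, total2)

    def validate(self) -> list:
        msgs = self._validate_moderators()
        if not self.study_id:
            msgs.append("study_id is required")
        if self.phase not in PHASES:
            msgs.append(f"phase {self.phase!r} not in {PHASES}")
        if self.total < 1:
            msgs.append("total must be a positive integer")
        if not (0 <= self.deaths <= self.total):
            msgs.append(f"deaths ({self.deaths}) must satisfy 0 <= deaths <= total ({self.total})")
        if self.second_stage is not None:
            d2, t2 = self.second_stage
            if t2 < 1:
                msgs.append("second-stage total must be a positive integer")
            elif not (0 <= d2 <= t2):
                msgs.append(f"second-stage deaths ({d2}) must satisfy 0 <= deaths <= total ({t2})")
        return msgs


MODERATOR_FIELDS = tuple(f.name for f in fields(Moderators))
ARM_FIELDS = tuple(f.name for f in fields(StudyArm))

#: CSV column order: arm columns followed by per-phase mortality count columns
ARM_COLUMNS = (
    "study_id",
    "outcome",
    "mean",
    "sd",
    "n_animals",
) + MODERATOR_FIELDS
MORTALITY_COLUMNS = (
    "peri_deaths",
    "peri_total",
    "peri_deaths2",
    "peri_total2",
    "post_deaths",
    "post_total",
    "post_deaths2",
    "post_total2",
)
ALL_COLUMNS = ARM_COLUMNS + MORTALITY_COLUMNS

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class Dataset:
    """An ordered collection of study arms plus mortality records."""

    arms: list = field(default_factory=list)
    mortality: list = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> list:
        msgs = []
        seen = set()
        for arm in self.arms:
            key = (arm.study_id, arm.outcome)
            if key in seen:
                msgs.append(f"duplicate study_id/outcome pair {key}")
            seen.add(key)
        seen = set()
        for rec in self.mortality:
            key = (rec.study_id, rec.phase)
            if key in seen:
                msgs.append(f"duplicate study_id/phase pair {key}")
            seen.add(key)
        return msgs

    def to_frame(self, outcome: Optional[str] = None) -> pd.DataFrame:
        """Arms as a DataFrame (optionally restricted to one outcome)."""
        rows = [a for a in self.arms if outcome is None or a.outcome == outcome]
        return pd.DataFrame([{f: getattr(a, f) for f in ARM_FIELDS} for a in rows])

    def mortality_frame(self, phase: Optional[str] = None) -> pd.DataFrame:
        recs = [r for r in self.mortality if phase is None or r.phase == phase]
        cols = ("study_id", "phase", "deaths", "total", "second_stage") + MODERATOR_FIELDS
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in recs])


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _parse_bool(token: str, column: str):
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"{column}: {token!r} is not a boolean")


def _parse_float(token: str, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{column}: {token!r} is not numeric")


def _parse_int(token: str, column: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"{column}: {token!r} is not an integer")


def _row_to_records(row: Mapping, errors: list, row_no: int):
    """Parse one CSV row into an optional StudyArm and 0-2 MortalityRecords."""
    arm = None
    mortality = []

    def get(col):
        return str(row.get(col, "")).strip()

    try:
        mods = dict(
            species=get("species"),
            strain=get("strain") or None,
            sex=get("sex"),
            occlusion=get("occlusion"),
            vessel=get("vessel"),
            approach=get("approach"),
            comedication=_parse_bool(get("comedication"), "comedication"),
            immunosuppression=_parse_bool(get("immunosuppression"), "immunosuppression"),
            quantification=get("quantification"),
            follow_up_hours=_parse_float(get("follow_up_hours"), "follow_up_hours"),
            ischemia_minutes=(
                _parse_float(get("ischemia_minutes"), "ischemia_minutes")
                if get("ischemia_minutes")
                else None
            ),
            quality_score=_parse_int(get("quality_score"), "quality_score"),
            weight_kg=_parse_float(get("weight_kg"), "weight_kg") if get("weight_kg") else None,
            age_weeks=_parse_float(get("age_weeks"), "age_weeks") if get("age_weeks") else None,
            vf_excluded_untreated=_parse_bool(get("vf_excluded_untreated"), "vf_excluded_untreated"),
        )
        if get("outcome"):
            arm = StudyArm(
                study_id=get("study_id"),
                outcome=get("outcome"),
                mean=_parse_float(get("mean"), "mean"),
                sd=_parse_float(get("sd"), "sd"),
                n_animals=_parse_int(get("n_animals"), "n_animals"),
                **mods,
            )
        for phase in PHASES:
            if get(f"{phase}_total"):
                second = None
                if get(f"{phase}_total2"):
                    second = (
                        _parse_int(get(f"{phase}_deaths2"), f"{phase}_deaths2"),
                        _parse_int(get(f"{phase}_total2"), f"{phase}_total2"),
                    )
                mortality.append(
                    MortalityRecord(
                        study_id=get("study_id"),
                        phase=phase,
                        deaths=_parse_int(get(f"{phase}_deaths"), f"{phase}_deaths"),
                        total=_parse_int(get(f"{phase}_total"), f"{phase}_total"),
                        second_stage=second,
                        **mods,
                    )
                )
    except ValueError as exc:
        errors.append(f"row {row_no}: {exc}")
        return None, []

    for rec in ([arm] if arm is not None else []) + mortality:
        for msg in rec.validate():
            errors.append(f"row {row_no}: {msg}")
    return arm, mortality


def read_dataset(path, schema_version: str = "1") -> Dataset:
    """Read and validate a study-level CSV.

    Rows violating the data-model invariants are rejected collectively with
    row-indexed messages; a header-only file yields an empty Dataset with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema_version != "1":
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ARM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")

    ds = Dataset(provenance=f"read from {path.name}")
    errors: list = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        arm, mortality = _row_to_records(row, errors, i)
        if arm is not None:
            ds.arms.append(arm)
        ds.mortality.extend(mortality)
    errors.extend(ds.validate())
    if errors:
        raise DataValidationError("\n".join(errors))
    if not ds.arms and not ds.mortality:
        logger.warning("%s: header only, no data rows", path.name)
    return ds


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return format(value, ".12g")
    return str(value)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset to the documented CSV layout (UTF-8, comma, '.' decimal).

    Mortality records are merged onto the arm row with the same study_id;
    records without a matching arm get their own outcome-less row.
    """
    by_study: dict = {}
    for rec in dataset.mortality:
        by_study.setdefault(rec.study_id, []).append(rec)

    def mortality_cells(recs):
        cells = {c: "" for c in MORTALITY_COLUMNS}
        for rec in recs:
            cells[f"{rec.phase}_deaths"] = _fmt(rec.deaths)
            cells[f"{rec.phase}_total"] = _fmt(rec.total)
            if rec.second_stage is not None:
                cells[f"{rec.phase}_deaths2"] = _fmt(rec.second_stage[0])
                cells[f"{rec.phase}_total2"] = _fmt(rec.second_stage[1])
        return cells

    rows = []
    emitted = set()
    for arm in dataset.arms:
        cells = {c: _fmt(getattr(arm, c)) for c in ARM_COLUMNS}
        recs = by_study.get(arm.study_id, []) if arm.study_id not in emitted else []
        cells.update(mortality_cells(recs))
        emitted.add(arm.study_id)
        rows.append(cells)
    for study_id, recs in by_study.items():
        if study_id in emitted:
            continue
        rec = recs[0]
        cells = {c: "" for c in ARM_COLUMNS}
        cells["study_id"] = study_id
        cells.update({c: _fmt(getattr(rec, c)) for c in MODERATOR_FIELDS})
        cells.update(mortality_cells(recs))
        rows.append(cells)

    frame = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Subset filtering for sensitivity analyses
# ---------------------------------------------------------------------------

Predicate = Mapping[str, Union[object, Sequence, Callable]]


def _matches(record, spec: Predicate) -> bool:
    for name, want in spec.items():
        if not hasattr(record, name):
            # field not defined for this record type (e.g. outcome on a
            # mortality record): the clause does not constrain it
            continue
        value = getattr(record, name)
        if callable(want):
            if not want(value):
                return False
        elif isinstance(want, (set, frozenset, list, tuple)):
            if value not in want:
                return False
        elif value != want:
            return False
    return True


def filter_subset(data: Dataset, predicate_spec: Predicate) -> Dataset:
    """Return the rows satisfying a declarative filter; the input is untouched.

    ``predicate_spec`` maps field names to a scalar (equality), a collection
    (membership) or a callable.  Referencing a field that exists on neither
    record type raises :class:`ConfigurationError`.  Used for the predefined
    sensitivity analyses: excluding comparisons where untreated ventricular
    fibrillation led to early exclusion, and the pig-strain subset analysis.
    """
    known = set(ARM_FIELDS) | {"phase", "deaths", "total"}
    unknown = [k for k in predicate_spec if k not in known]
    if unknown:
        raise ConfigurationError(f"unknown filter field(s): {', '.join(sorted(unknown))}")
    return Dataset(
        arms=[replace(a) for a in data.arms if _matches(a, predicate_spec)],
        mortality=[replace(r) for r in data.mortality if _matches(r, predicate_spec)],
        provenance=data.provenance,
    )
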