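"""Cohort ingestion, recoding and per-variable count tables.

The analysis operates on mother-child pairs from Japanese pregnancy
notification forms: categorical questionnaire responses plus a binary
outcome (registration with a Regional Council for Children Requiring Care,
RCCRC, by age 3 — the study's proxy for a child-maltreatment case).

Two kinds of missingness are distinguished throughout:

* ``not_answered`` — the respondent left the question blank; treated as a
  category of its own, but folded into the reference category when fewer
  than five respondents skipped the question (too small a cell to carry
  its own odds ratio);
* ``not_investigated`` — the municipality never digitized the field, so it
  is structurally missing for everyone registered there.  These rows are
  never merged.

Because events are rare, each crude regression depends on the data only
through per-category (n_total, n_events) counts; the published summary
table ships as a packaged fixture so every crude fit is reproducible
without individual-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PregnancyRecord",
    "CodedVariable",
    "CategoryCountTable",
    "FixtureIntegrityError",
    "RAW_ENUMS",
    "RECODED_CATEGORIES",
    "VARIABLES",
    "recode_record",
    "recode_frame",
    "merge_small_not_answered",
    "build_count_table",
    "load_published_counts",
    "load_cohort_csv",
    "write_cohort_csv",
    "load_municipality_config",
]

NOT_ANSWERED = "not_answered"
NOT_INVESTIGATED = "not_investigated"

# Raw questionnaire enums (CSV cell values).  Missing cells become
# not_answered unless the (municipality, variable) pair is flagged
# not_investigated in the companion config.
RAW_ENUMS: dict[str, frozenset[str]] = {
    "marital_status": frozenset({"married", "unmarried", NOT_ANSWERED, NOT_INVESTIGATED}),
    "pregnancy_progress": frozenset({"good", "not_good", NOT_ANSWERED, NOT_INVESTIGATED}),
    "birth_order": frozenset({"first", "subsequent", NOT_ANSWERED}),
    "abortion_history": frozenset({"yes", "no", NOT_ANSWERED}),
    "infertility_treatment": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "feeling_at_pregnancy": frozenset(
        {
            "happy",
            "unexpected_happy",
            "unexpected_puzzled",
            "dont_know_what_to_do",
            "no_feeling",
            "other",
            NOT_ANSWERED,
        }
    ),
    "return_to_parents_home": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "has_helper": frozenset({"yes", "no", NOT_ANSWERED}),
    "worries_anxiety": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "smoking": frozenset({"no", "stopped_after_confirmation", "yes", NOT_ANSWERED}),
    "passive_smoking": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "alcohol": frozenset({"yes", "no", NOT_ANSWERED}),
    "disease_history": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "mental_illness_history": frozenset({"yes", "no", NOT_ANSWERED, NOT_INVESTIGATED}),
    "depressive_symptoms": frozenset({"yes", "no", NOT_ANSWERED}),
}

# Analysis categories after recoding, reference category first.
RECODED_CATEGORIES: dict[str, tuple[str, ...]] = {
    "marital_status": ("married", "unmarried", NOT_ANSWERED, NOT_INVESTIGATED),
    "maternal_age": ("25-39", "<20", "20-24", ">=40"),
    "late_registration": ("no", "yes", NOT_ANSWERED),
    "pregnancy_progress": ("good", "not_good", NOT_ANSWERED, NOT_INVESTIGATED),
    "birth_order": ("subsequent", "first", NOT_ANSWERED),
    "abortion_history": ("no", "yes", NOT_ANSWERED),
    "infertility_treatment": ("no", "yes", NOT_ANSWERED, NOT_INVESTIGATED),
    "feeling_at_pregnancy": ("happy", "unexpected_happy", "unexpected_other", NOT_ANSWERED),
    "return_to_parents_home": ("yes", "no", NOT_ANSWERED, NOT_INVESTIGATED),
    "has_helper": ("yes", "no", NOT_ANSWERED),
    "worries_anxiety": ("no", "yes", NOT_ANSWERED, NOT_INVESTIGATED),
    "smoking": ("no", "stopped", "yes", NOT_ANSWERED),
    "passive_smoking": ("no", "yes", NOT_ANSWERED, NOT_INVESTIGATED),
    "alcohol": ("no", "yes", NOT_ANSWERED),
    "disease_history": ("no", "yes", NOT_ANSWERED, NOT_INVESTIGATED),
    "mental_illness_history": ("no", "yes", NOT_ANSWERED, NOT_INVESTIGATED),
    "depressive_symptoms": ("no", "yes", NOT_ANSWERED),
}

VARIABLES: tuple[str, ...] = tuple(RECODED_CATEGORIES)

# Unintended-and-unhappy feelings pooled into one analysis category.
_FEELING_POOL = {"unexpected_puzzled", "dont_know_what_to_do", "no_feeling", "other"}

MAX_PLAUSIBLE_AGE = 60
LATE_REGISTRATION_WEEKS = 12  # registration at >= 12 weeks counts as late


class FixtureIntegrityError(RuntimeError):
    """Packaged count fixture fails its internal consistency checks."""


@dataclass(frozen=True)
class PregnancyRecord:
    """One mother-child pair's raw questionnaire responses plus outcome."""

    household_id: str
    municipality_id: str
    marital_status: str
    maternal_age_years: int | None
    gestational_weeks_at_registration: int | str
    pregnancy_progress: str
    birth_order: str
    abortion_history: str
    infertility_treatment: str
    feeling_at_pregnancy: str
    return_to_parents_home: str
    has_helper: str
    worries_anxiety: str
    smoking: str
    passive_smoking: str
    alcohol: str
    disease_history: str
    mental_illness_history: str
    depressive_symptoms: str
    outcome_rccrc: bool


@dataclass(frozen=True)
class CodedVariable:
    """A recoded analysis variable: ordered categories, reference first."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate categories")


@dataclass(frozen=True)
class CategoryCountTable:
    """Per-category (n_total, n_events) for one variable — the sufficient
    input for its crude exact regression."""

    variable_name: str
    rows: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for label, n, e in self.rows:
            if not (0 <= e <= n):
                raise ValueError(f"{self.variable_name}/{label}: events {e} > total {n}")

    @property
    def n_total(self) -> int:
        return sum(n for _, n, _ in self.rows)

    @property
    def n_events(self) -> int:
        return sum(e for _, _, e in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "n_total", "n_events"]).assign(
            variable=self.variable_name
        )[["variable", "category", "n_total", "n_events"]]


def _age_band(age: int) -> str:
    if age < 0 or age > MAX_PLAUSIBLE_AGE:
        raise ValueError(f"implausible maternal age {age}")
    if age < 20:
        return "<20"
    if age < 25:
        return "20-24"
    if age < 40:
        return "25-39"
    return ">=40"


def recode_record(record: PregnancyRecord) -> dict[str, str]:
    """Map a raw record onto the analysis categories.

    Maternal age becomes one of four bands; gestational weeks become the
    late-registration indicator (12 weeks or later counts as late); the
    unintended-pregnancy feelings are pooled; smoking labels shorten; all
    other variables pass through after enum validation.
    """
    out: dict[str, str] = {}
    for var in RAW_ENUMS:
        value = getattr(record, var)
        if value not in RAW_ENUMS[var]:
            raise ValueError(f"{var}: unknown label {value!r}")
    if record.maternal_age_years is None:
        raise ValueError("maternal age is required")
    out["maternal_age"] = _age_band(int(record.maternal_age_years))
    weeks = record.gestational_weeks_at_registration
    if weeks == NOT_ANSWERED:
        out["late_registration"] = NOT_ANSWERED
    else:
        w = int(weeks)
        if w < 0:
            raise ValueError(f"negative gestational weeks {w}")
        out["late_registration"] = "yes" if w >= LATE_REGISTRATION_WEEKS else "no"
    feeling = record.feeling_at_pregnancy
    out["feeling_at_pregnancy"] = (
        "unexpected_other" if feeling in _FEELING_POOL else feeling
    )
    out["smoking"] = (
        "stopped" if record.smoking == "stopped_after_confirmation" else record.smoking
    )
    for var in RAW_ENUMS:
        if var in ("feeling_at_pregnancy", "smoking"):
            continue
        out[var] = getattr(record, var)
    for var, cat in out.items():
        if cat not in RECODED_CATEGORIES[var]:
            raise ValueError(f"{var}: recoded label {cat!r} not recognised")
    return out


def recode_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`recode_record` over a cohort frame.

    Returns a frame with one column per analysis variable plus
    ``outcome_rccrc``; index is preserved.
    """
    recoded = pd.DataFrame(index=cohort.index)
    age = pd.to_numeric(cohort["maternal_age_years"])
    if (age < 0).any() or (age > MAX_PLAUSIBLE_AGE).any():
        raise ValueError("implausible maternal age in cohort")
    recoded["maternal_age"] = pd.cut(
        age, bins=[-0.5, 19.5, 24.5, 39.5, MAX_PLAUSIBLE_AGE + 0.5],
        labels=["<20", "20-24", "25-39", ">=40"],
    ).astype(str)
    weeks = cohort["gestational_weeks_at_registration"]
    is_na = weeks.astype(str) == NOT_ANSWERED
    num = pd.to_numeric(weeks.where(~is_na, other=0))
    recoded["late_registration"] = pd.Series(
        ["yes" if w >= LATE_REGISTRATION_WEEKS else "no" for w in num], index=cohort.index
    ).where(~is_na, other=NOT_ANSWERED)
    for var in RAW_ENUMS:
        col = cohort[var].astype(str)
        bad = ~col.isin(RAW_ENUMS[var])
        if bad.any():
            raise ValueError(f"{var}: unknown labels {sorted(col[bad].unique())}")
        if var == "feeling_at_pregnancy":
            col = col.where(~col.isin(_FEELING_POOL), other="unexpected_other")
        elif var == "smoking":
            col = col.replace({"stopped_after_confirmation": "stopped"})
        recoded[var] = col
    recoded["outcome_rccrc"] = cohort["outcome_rccrc"].astype(bool)
    return recoded


def merge_small_not_answered(
    table: CategoryCountTable, threshold: int = 5
) -> CategoryCountTable:
    """Fold a small ``not_answered`` row into the reference category.

    If fewer than ``threshold`` participants skipped the question, the
    not_answered counts join the reference row, whose label becomes
    ``"<ref>/not_answered"``; otherwise the table is returned unchanged.
    Structurally missing (``not_investigated``) rows are never merged, and
    an empty not_answered row is left alone.
    """
    rows = list(table.rows)
    na_idx = next(
        (i for i, (lab, _, _) in enumerate(rows) if lab == NOT_ANSWERED), None
    )
    if na_idx is None:
        return table
    _, na_n, na_e = rows[na_idx]
    if na_n == 0 or na_n >= threshold:
        return table
    ref_label, ref_n, ref_e = rows[0]
    rows[0] = (f"{ref_label}/{NOT_ANSWERED}", ref_n + na_n, ref_e + na_e)
    del rows[na_idx]
    return replace(table, rows=tuple(rows))


def build_count_table(
    recoded: pd.DataFrame | Iterable[Mapping[str, str]],
    variable: CodedVariable,
    outcomes: Sequence[bool] | None = None,
) -> CategoryCountTable:
    """Tally one variable's per-category totals and event counts.

    Accepts either a recoded frame (with an ``outcome_rccrc`` column) or an
    iterable of recoded mappings plus a parallel outcome sequence.
    """
    if isinstance(recoded, pd.DataFrame):
        frame = recoded
    else:
        frame = pd.DataFrame(list(recoded))
        frame["outcome_rccrc"] = [bool(v) for v in outcomes]  # type: ignore[union-attr]
    if len(frame) == 0:
        raise ValueError("empty cohort")
    seen = set(frame[variable.name].unique())
    unknown = seen - set(variable.categories)
    if unknown:
        raise ValueError(f"{variable.name}: categories {sorted(unknown)} not in coding")
    rows = []
    for cat in variable.categories:
        mask = frame[variable.name] == cat
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append((cat, n, int(frame.loc[mask, "outcome_rccrc"].sum())))
    return CategoryCountTable(variable_name=variable.name, rows=tuple(rows))


def load_published_counts() -> dict[str, CategoryCountTable]:
    """Load the packaged published per-category count summary.

    Every variable's table must sum to the full cohort (893 mothers, 11
    events); any deviation raises :class:`FixtureIntegrityError`.
    """
    with resources.files("prenatal_risk").joinpath("data/published_counts.csv").open() as fh:
        frame = pd.read_csv(fh)
    tables: dict[str, CategoryCountTable] = {}
    for var, grp in frame.groupby("variable", sort=False):
        tables[var] = CategoryCountTable(
            variable_name=str(var),
            rows=tuple(
                (str(r.category), int(r.n_total), int(r.n_events))
                for r in grp.itertuples()
            ),
        )
    for var, table in tables.items():
        if (table.n_total, table.n_events) != (893, 11):
            raise FixtureIntegrityError(
                f"{var}: totals {(table.n_total, table.n_events)} != (893, 11)"
            )
    return tables


def load_municipality_config(path) -> dict[str, frozenset[str]]:
    """Read the municipality field-availability config (YAML or JSON).

    Maps municipality_id to the set of variables that municipality never
    digitized (``not_investigated`` for all of its records).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, frozenset[str]] = {}
    for muni, variables in (raw or {}).items():
        vars_ = frozenset(variables or [])
        unknown = vars_ - set(RAW_ENUMS)
        if unknown:
            raise ValueError(f"municipality {muni}: unknown variables {sorted(unknown)}")
        out[str(muni)] = vars_
    return out


_RECORD_COLUMNS = [
    "household_id",
    "municipality_id",
    "marital_status",
    "maternal_age_years",
    "gestational_weeks_at_registration",
    "pregnancy_progress",
    "birth_order",
    "abortion_history",
    "infertility_treatment",
    "feeling_at_pregnancy",
    "return_to_parents_home",
    "has_helper",
    "worries_anxiety",
    "smoking",
    "passive_smoking",
    "alcohol",
    "disease_history",
    "mental_illness_history",
    "depressive_symptoms",
    "outcome_rccrc",
]


def load_cohort_csv(
    path, municipality_config: Mapping[str, frozenset[str]] | None = None
) -> pd.DataFrame:
    """Read a cohort CSV (one row per mother-child pair).

    Empty cells become ``not_answered``, unless the record's municipality
    flags that variable as not digitized, in which case they become
    ``not_investigated``.
    """
    cohort = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_RECORD_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns {sorted(missing)}")
    cohort = cohort[_RECORD_COLUMNS].copy()
    for var in RAW_ENUMS:
        blank = cohort[var] == ""
        cohort.loc[blank, var] = NOT_ANSWERED
        if municipality_config:
            for muni, vars_ in municipality_config.items():
                if var in vars_:
                    cohort.loc[cohort["municipality_id"] == muni, var] = NOT_INVESTIGATED
    blank_w = cohort["gestational_weeks_at_registration"] == ""
    cohort.loc[blank_w, "gestational_weeks_at_registration"] = NOT_ANSWERED
    cohort["outcome_rccrc"] = cohort["outcome_rccrc"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    if cohort["outcome_rccrc"].isna().any():
        raise ValueError("outcome_rccrc must be 0/1 or True/False for every record")
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[_RECORD_COLUMNS].to_csv(path, index=False)
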