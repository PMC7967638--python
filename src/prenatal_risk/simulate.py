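"""Synthetic cohorts with the structure of a pregnancy-notification study.

The generator emulates a sparse-event administrative cohort: ~900
mother-child pairs, categorical questionnaire covariates drawn
independently from the published marginal frequencies, municipality-level
structural missingness ("not investigated" fields), and a rare binary
outcome (~1.2% prevalence) driven by a logistic model whose default
coefficients are the study's adjusted odds ratios.  It exists so that
every pipeline stage — recoding, exact fits, score derivation, ROC — can
be exercised and validated (parameter recovery, CI coverage) without any
individual-level data, which were never published.

What it deliberately does not emulate: the real joint dependence between
questionnaire items (only marginals are known), and the unknown split of
merged "not answered" cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import cohort as _cohort
from .exact import DegenerateDistributionError, GroupedDesign, fit_exact_logit

__all__ = ["GeneratorConfig", "calibrate_intercept", "generate_cohort",
           "recovery_experiment"]

_NA = _cohort.NOT_ANSWERED
_NI = _cohort.NOT_INVESTIGATED

# Published marginal counts on the analysis categories, with structurally
# missing ("not investigated") mass removed: masking is applied separately
# by municipality so the post-masking marginals reproduce the study's.
_DEFAULT_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "marital_status": {"married": 423, "unmarried": 27, _NA: 26},
    "maternal_age": {"25-39": 753, "<20": 13, "20-24": 94, ">=40": 33},
    "late_registration": {"no": 812, "yes": 55, _NA: 26},
    "pregnancy_progress": {"good": 557, "not_good": 10},
    "birth_order": {"subsequent": 495, "first": 398},
    "abortion_history": {"no": 834, "yes": 59},
    "infertility_treatment": {"no": 696, "yes": 67, _NA: 6},
    "feeling_at_pregnancy": {
        "happy": 647, "unexpected_happy": 185, "unexpected_other": 54, _NA: 7
    },
    "return_to_parents_home": {"yes": 317, "no": 440, _NA: 12},
    "has_helper": {"yes": 870, "no": 13, _NA: 10},
    "worries_anxiety": {"no": 418, "yes": 264, _NA: 9},
    "smoking": {"no": 776, "stopped": 94, "yes": 23},
    "passive_smoking": {"no": 481, "yes": 86},
    "alcohol": {"no": 874, "yes": 8, _NA: 11},
    "disease_history": {"no": 476, "yes": 91},
    "mental_illness_history": {"no": 310, "yes": 25, _NA: 434},
    "depressive_symptoms": {"no": 820, "yes": 66, _NA: 7},
}

# Five municipalities whose masking sets reproduce the study's
# "not investigated" totals (417/893 marital, 326/893 pregnancy progress /
# passive smoking / disease history, 202/893 worries, 124/893 infertility /
# satogaeri / mental illness).
_MASK_A = frozenset(
    {
        "marital_status", "pregnancy_progress", "passive_smoking",
        "disease_history", "worries_anxiety", "infertility_treatment",
        "return_to_parents_home", "mental_illness_history",
    }
)
_MASK_B = frozenset(
    {"marital_status", "pregnancy_progress", "passive_smoking",
     "disease_history", "worries_anxiety"}
)
_MASK_C = frozenset(
    {"marital_status", "pregnancy_progress", "passive_smoking", "disease_history"}
)
_DEFAULT_MUNICIPALITIES: tuple[tuple[float, frozenset[str]], ...] = (
    (124 / 893, _MASK_A),
    (78 / 893, _MASK_B),
    (124 / 893, _MASK_C),
    (91 / 893, frozenset({"marital_status"})),
    (476 / 893, frozenset()),
)

# Default outcome model: log odds ratios of the adjusted multiple fit.
_DEFAULT_LOG_ODDS: dict[tuple[str, str], float] = {
    ("marital_status", "unmarried"): math.log(12.14),
    ("marital_status", _NA): math.log(8.76),
    ("marital_status", _NI): math.log(3.10),
    ("abortion_history", "yes"): math.log(5.82),
    ("smoking", "stopped"): math.log(3.35),
    ("smoking", "yes"): math.log(5.30),
}


def _normalize(counts: Mapping[str, int | float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def _default_probs() -> dict[str, dict[str, float]]:
    return {v: _normalize(c) for v, c in _DEFAULT_CATEGORY_COUNTS.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    ``category_probs`` are pre-masking category probabilities per analysis
    variable; ``municipality_patterns`` are (weight, masked-variable set)
    pairs; ``true_log_odds`` drives the outcome model on the post-masking
    categories; the intercept is calibrated so the expected event
    prevalence equals ``target_prevalence``.
    """

    n: int = 893
    category_probs: dict[str, dict[str, float]] = field(default_factory=_default_probs)
    municipality_patterns: tuple[tuple[float, frozenset[str]], ...] = (
        _DEFAULT_MUNICIPALITIES
    )
    true_log_odds: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_ODDS)
    )
    target_prevalence: float = 11 / 893
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target prevalence must be in (0, 1)")
        for var, probs in self.category_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{var}: category probabilities do not sum to 1")
        w = sum(w for w, _ in self.municipality_patterns)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("municipality weights do not sum to 1")
        for var, _cat in self.true_log_odds:
            if var not in self.category_probs:
                raise ValueError(f"true_log_odds refers to ungenerated variable {var!r}")


def _masked_probs(
    config: GeneratorConfig, mask: frozenset[str], var: str
) -> dict[str, float]:
    if var in mask:
        return {_NI: 1.0}
    return config.category_probs[var]


def calibrate_intercept(config: GeneratorConfig) -> float:
    """Intercept making the expected prevalence hit the target.

    The expectation is exact: it enumerates the joint distribution of the
    (independent) variables carrying nonzero coefficients, mixed over
    municipalities, and solves for the intercept by bracketed
    root-finding.
    """
    variables = sorted({var for var, _ in config.true_log_odds})

    def prevalence(alpha: float) -> float:
        total = 0.0
        for w, mask in config.municipality_patterns:
            if w == 0.0:
                continue
            dists = [
                list(_masked_probs(config, mask, var).items()) for var in variables
            ]
            for combo in product(*dists):
                p = w
                lp = alpha
                for var, (cat, prob) in zip(variables, combo):
                    p *= prob
                    lp += config.true_log_odds.get((var, cat), 0.0)
                total += p * float(expit(lp))
        return total

    lo, hi = -30.0, 10.0
    if not prevalence(lo) < config.target_prevalence < prevalence(hi):
        raise ValueError(
            f"target prevalence {config.target_prevalence} unattainable under model"
        )
    return float(
        brentq(lambda a: prevalence(a) - config.target_prevalence, lo, hi, xtol=1e-12)
    )


# Raw-field refinements for recoded categories drawn by the generator.
_AGE_RANGES = {"<20": (17, 20), "20-24": (20, 25), "25-39": (25, 40), ">=40": (40, 46)}
_FEELING_POOL = sorted(_cohort._FEELING_POOL)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one synthetic cohort as a raw-record frame.

    Municipality first, then covariate categories independently per
    variable, then masking, then the Bernoulli outcome from the logistic
    model with the calibrated intercept.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    intercept = calibrate_intercept(config)

    weights = np.array([w for w, _ in config.municipality_patterns])
    muni_idx = rng.choice(len(weights), size=n, p=weights / weights.sum())
    masks = [mask for _, mask in config.municipality_patterns]

    # Post-masking analysis categories per generated variable.
    recoded: dict[str, np.ndarray] = {}
    for var in config.category_probs:
        probs = config.category_probs[var]
        cats = np.array(list(probs), dtype=object)
        draw = cats[rng.choice(len(cats), size=n, p=np.array(list(probs.values())))]
        for j, mask in enumerate(masks):
            if var in mask:
                draw = np.where(muni_idx == j, _NI, draw)
        recoded[var] = draw

    lp = np.full(n, intercept)
    for (var, cat), beta in config.true_log_odds.items():
        lp += beta * (recoded[var] == cat)
    outcome = rng.random(n) < expit(lp)

    # Expand recoded categories back into raw questionnaire fields.
    raw = pd.DataFrame(index=range(n))
    raw["household_id"] = [f"H{i:06d}" for i in range(n)]
    raw["municipality_id"] = [f"M{j + 1}" for j in muni_idx]

    def _column(var: str, default: str) -> np.ndarray:
        return recoded.get(var, np.full(n, default, dtype=object))

    age_band = _column("maternal_age", "25-39")
    ages = np.empty(n, dtype=int)
    for band, (lo, hi) in _AGE_RANGES.items():
        m = age_band == band
        ages[m] = rng.integers(lo, hi, size=int(m.sum()))
    raw["maternal_age_years"] = ages

    late = _column("late_registration", "no")
    weeks = np.empty(n, dtype=object)
    early = late == "no"
    weeks[early] = rng.integers(5, 12, size=int(early.sum()))
    lat = late == "yes"
    weeks[lat] = rng.integers(12, 21, size=int(lat.sum()))
    weeks[late == _NA] = _NA
    raw["gestational_weeks_at_registration"] = weeks

    feeling = _column("feeling_at_pregnancy", "happy").copy()
    pooled = feeling == "unexpected_other"
    feeling[pooled] = rng.choice(_FEELING_POOL, size=int(pooled.sum()))
    raw["feeling_at_pregnancy"] = feeling

    smoking = _column("smoking", "no")
    raw["smoking"] = np.where(smoking == "stopped", "stopped_after_confirmation", smoking)

    for var in _cohort.RAW_ENUMS:
        if var in ("feeling_at_pregnancy", "smoking"):
            continue
        default = _cohort.RECODED_CATEGORIES[var][0]
        raw[var] = _column(var, default)

    raw["outcome_rccrc"] = outcome
    return raw[_cohort._RECORD_COLUMNS]


def _crude_design(
    recoded: pd.DataFrame, var: str, merge_threshold: int = 5
) -> GroupedDesign:
    coded = _cohort.CodedVariable(var, _cohort.RECODED_CATEGORIES[var] + (_NI,))
    table = _cohort.build_count_table(recoded, coded)
    table = _cohort.merge_small_not_answered(table, threshold=merge_threshold)
    return GroupedDesign.one_variable(var, table.rows)


def recovery_experiment(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int,
    include_multiple: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """Parameter-recovery harness over replicate synthetic cohorts.

    For each replicate: generate a cohort, recode it, run crude exact fits
    for every variable carrying a true coefficient (and, optionally, the
    joint multiple fit), and record estimates and CI coverage of the true
    odds ratios.  Returns one summary row per (fit kind, parameter):
    median estimated OR, median log-scale bias, coverage among informative
    replicates, and the number of degenerate replicates (flagged, never
    fatal).
    """
    from .pipeline import design_from_frame  # local import: avoids a cycle

    true_or = {f"{v}={c}": math.exp(b) for (v, c), b in config.true_log_odds.items()}
    variables = sorted({var for var, _ in config.true_log_odds})
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = generate_cohort(replace(config, seed=rep_seed))
        recoded = _cohort.recode_frame(cohort)
        if recoded["outcome_rccrc"].sum() == 0:
            rows.append({"replicate": rep, "fit": "none", "parameter": None,
                         "flag": "zero_events"})
            continue
        designs = [("crude:" + v, _crude_design(recoded, v)) for v in variables]
        if include_multiple and len(variables) > 1:
            designs.append(("multiple", design_from_frame(recoded, variables)))
        for kind, design in designs:
            try:
                fits = fit_exact_logit(design, level=level)
            except DegenerateDistributionError:
                rows.append({"replicate": rep, "fit": kind, "parameter": None,
                             "flag": "degenerate"})
                continue
            for f in fits:
                if f.parameter_name not in true_or:
                    continue
                truth = true_or[f.parameter_name]
                rows.append(
                    {
                        "replicate": rep,
                        "fit": kind,
                        "parameter": f.parameter_name,
                        "estimate_kind": f.estimate_kind,
                        "odds_ratio": f.odds_ratio,
                        "covered": (
                            None
                            if not f.informative
                            else bool(f.ci_lower <= truth <= f.ci_upper)
                        ),
                        "flag": None if f.informative else "non_informative",
                    }
                )
    detail = pd.DataFrame(rows)
    informative = detail[detail["parameter"].notna() & detail["flag"].isna()]
    summaries = []
    for (kind, param), grp in informative.groupby(["fit", "parameter"]):
        truth = true_or[param]
        summaries.append(
            {
                "fit": kind,
                "parameter": param,
                "true_or": truth,
                "n_replicates": len(grp),
                "n_flagged": int(
                    (detail["fit"].eq(kind) & detail["flag"].notna()).sum()
                ),
                "median_or": float(grp["odds_ratio"].median()),
                "median_log_bias": float(
                    np.median(np.log(grp["odds_ratio"]) - math.log(truth))
                ),
                "coverage": float(grp["covered"].mean()),
            }
        )
    return pd.DataFrame(summaries)
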