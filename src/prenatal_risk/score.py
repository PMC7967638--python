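"""Prenatal risk score: factor selection, OR discretization, scoring.

The score is an integer sum of weights over a mother's risk categories.
Weights discretize the adjusted odds ratios of a multiple exact logistic
fit: 3 points when OR >= 10, 2 points when 5 <= OR < 10, and 1 point for
any other non-reference category of a selected factor (reference
categories score 0).  Factors enter the multiple model when their crude
fit shows at least one category whose 95% exact CI excludes 1.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .exact import ExactParameterInference

__all__ = ["WeightRule", "ScoreFormula", "select_factors", "derive_weights",
           "compute_score", "score_distribution"]


@dataclass(frozen=True)
class WeightRule:
    """Ordered (lower OR bound, weight) bands, highest band first.

    The default ``[(10, 3), (5, 2), (0, 1)]`` gives 3 points at OR >= 10,
    2 points at 5 <= OR < 10 and 1 point below 5.
    """

    thresholds: tuple[tuple[float, int], ...] = ((10.0, 3), (5.0, 2), (0.0, 1))

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.thresholds]
        if any(b1 <= b2 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("band bounds must be strictly decreasing")
        if any(w < 0 or int(w) != w for _, w in self.thresholds):
            raise ValueError("weights must be nonnegative integers")

    def weight_for(self, odds_ratio: float) -> int:
        if odds_ratio != odds_ratio:  # NaN
            raise ValueError("cannot weight a missing odds ratio")
        if odds_ratio < 1.0:
            warnings.warn(
                f"odds ratio {odds_ratio:.3g} < 1 receives the minimum band weight",
                stacklevel=2,
            )
        for bound, weight in self.thresholds:
            if odds_ratio >= bound:
                return int(weight)
        return 0


@dataclass(frozen=True)
class ScoreFormula:
    """Integer score formula: one (variable, category, weight) per term."""

    terms: tuple[tuple[str, str, int], ...]
    max_score: int = field(init=False)

    def __post_init__(self) -> None:
        keys = [(v, c) for v, c, _ in self.terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (variable, category) term")
        per_var: dict[str, int] = {}
        for v, _, w in self.terms:
            per_var[v] = max(per_var.get(v, 0), int(w))
        object.__setattr__(self, "max_score", sum(per_var.values()))

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v, _, _ in self.terms:
            seen.setdefault(v)
        return tuple(seen)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {"variable": v, "category": c, "weight": w}
                    for v, c, w in self.terms
                ],
                "max_score": self.max_score,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreFormula":
        data = json.loads(text)
        return cls(
            tuple(
                (t["variable"], t["category"], int(t["weight"]))
                for t in data["terms"]
            )
        )


def _split(parameter_name: str) -> tuple[str, str]:
    if "=" not in parameter_name:
        raise ValueError(
            f"parameter {parameter_name!r} is not of the form 'variable=category'"
        )
    var, cat = parameter_name.split("=", 1)
    return var, cat


def select_factors(
    crude_fits: Mapping[str, Sequence[ExactParameterInference]],
) -> list[str]:
    """Variables whose crude fit has a category with 95% CI excluding 1.

    This operationalizes "statistically significant in the crude
    regression" from printed output alone; under the matching p-value
    convention it coincides with exact p < 0.05.
    """
    return [
        var
        for var, fits in crude_fits.items()
        if any(f.significant for f in fits)
    ]


def derive_weights(
    adjusted_fit: Sequence[ExactParameterInference],
    rule: WeightRule = WeightRule(),
) -> ScoreFormula:
    """Discretize adjusted odds ratios into an integer score formula.

    Every non-reference category of the multiple fit gets the weight of
    its OR band; a missing/non-informative OR is an error rather than a
    silent zero.
    """
    terms = []
    for f in adjusted_fit:
        var, cat = _split(f.parameter_name)
        if not f.informative or f.odds_ratio != f.odds_ratio:
            raise ValueError(f"{f.parameter_name}: no odds ratio to weight")
        terms.append((var, cat, rule.weight_for(f.odds_ratio)))
    return ScoreFormula(tuple(terms))


def compute_score(recoded: Mapping[str, str], formula: ScoreFormula) -> int:
    """Integer risk score of one recoded record under a formula."""
    for var in formula.variables:
        if var not in recoded:
            raise ValueError(f"record lacks formula variable {var!r}")
    return sum(
        w for var, cat, w in formula.terms if recoded[var] == cat
    )


def score_distribution(scores: Sequence[int]) -> dict[int, tuple[int, float]]:
    """Score -> (count, percent to 1 dp) over a scored cohort."""
    counts = Counter(int(s) for s in scores)
    n = sum(counts.values())
    return {
        s: (c, round(100.0 * c / n, 1)) for s, c in sorted(counts.items())
    }
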