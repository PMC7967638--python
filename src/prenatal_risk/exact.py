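"""Exact conditional logistic regression for sparse binary cohorts.

Inference on log odds ratios uses the exact distribution of each
parameter's sufficient statistic conditional on all the others (and on the
total event count, which is the intercept's sufficient statistic).  For a
binary indicator covariate the sufficient statistic T is the number of
events among exposed subjects; its conditional distribution is an
(extended) noncentral hypergeometric law

    P(T = t | beta) = c_t exp(beta t) / sum_s c_s exp(beta s),

whose integer weights c_t are enumerated exactly by multiplying per-group
generating polynomials in arbitrary-precision arithmetic.  This is the
standard route to odds ratios and confidence intervals when events are far
too rare for asymptotic logistic regression (here: cohorts with ~1% event
prevalence).

Estimates follow the usual exact-inference conventions:

* conditional MLE (CMLE) solves E[T | beta] = t_obs, a strictly
  increasing score equation;
* when t_obs sits on the boundary of its support the CMLE is infinite and
  the median unbiased estimate (MUE) is reported instead, solving a 50%
  tail equation;
* equal-tail exact confidence limits invert P(T >= t | beta) and
  P(T <= t | beta) at alpha/2, with a zero lower (infinite upper) limit
  when t_obs is at the minimum (maximum) of the support;
* the default two-sided p-value is the "probability method": the total
  null probability of outcomes no more likely than the observed one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "GroupedDesign",
    "ConditionalDistribution",
    "ExactParameterInference",
    "DegenerateDistributionError",
    "conditional_distribution",
    "brute_force_fit",
    "cmle",
    "mue",
    "exact_ci",
    "exact_p",
    "fit_exact_logit",
]

# Log odds ratios are searched on [-BETA_MAX, BETA_MAX]; OR in [e^-35, e^35]
# comfortably covers anything estimable from a finite table.
BETA_MAX = 35.0
_BETA_TOL = 1e-10


class DegenerateDistributionError(ValueError):
    """Conditional support is empty or a single point: no information."""


@dataclass(frozen=True)
class GroupedDesign:
    """Grouped binary-covariate design for exact logistic regression.

    Parameters
    ----------
    patterns
        One entry per distinct covariate pattern: ``(x, m, y)`` where ``x``
        is the 0/1 indicator vector over the ``p`` non-reference dummies,
        ``m`` the number of subjects with that pattern and ``y`` the number
        of events observed among them.
    parameter_names
        Names of the ``p`` dummy parameters, in the order used by ``x``.
    """

    patterns: tuple[tuple[tuple[int, ...], int, int], ...]
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        p = len(self.parameter_names)
        for x, m, y in self.patterns:
            if len(x) != p:
                raise ValueError(f"pattern {x} has {len(x)} entries, expected {p}")
            if any(v not in (0, 1) for v in x):
                raise ValueError(f"pattern {x} is not an indicator vector")
            if not (0 <= y <= m):
                raise ValueError(f"invalid group counts m={m}, y={y}")

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[tuple[Sequence[int], int, int]],
        parameter_names: Sequence[str],
    ) -> "GroupedDesign":
        return cls(
            tuple((tuple(int(v) for v in x), int(m), int(y)) for x, m, y in rows),
            tuple(parameter_names),
        )

    @classmethod
    def one_variable(
        cls, variable: str, rows: Sequence[tuple[str, int, int]]
    ) -> "GroupedDesign":
        """Design for one categorical variable's crude fit.

        ``rows`` are (category, n_total, n_events) with the reference
        category first; each non-reference category becomes a dummy named
        ``"<variable>=<category>"``.
        """
        p = len(rows) - 1
        if p < 1:
            raise ValueError(f"{variable}: need at least two categories")
        patterns = []
        for j, (_, m, y) in enumerate(rows):
            x = tuple(1 if i == j - 1 else 0 for i in range(p))
            patterns.append((x, int(m), int(y)))
        names = tuple(f"{variable}={cat}" for cat, _, _ in rows[1:])
        return cls(tuple(patterns), names)

    @property
    def n_subjects(self) -> int:
        return sum(m for _, m, _ in self.patterns)

    @property
    def n_events(self) -> int:
        return sum(y for _, _, y in self.patterns)

    def sufficient_statistics(self) -> tuple[int, ...]:
        """Observed T_i = sum_j y_j x_ji for each parameter."""
        p = len(self.parameter_names)
        t = [0] * p
        for x, _, y in self.patterns:
            for i in range(p):
                t[i] += y * x[i]
        return tuple(t)


@dataclass
class ConditionalDistribution:
    """Exact conditional distribution of one sufficient statistic.

    ``coefficients[i]`` is the exact integer weight c_t at
    ``support[i]``; the tilt parameter beta is the log odds ratio.
    ``conditioning`` records the fixed values of the other sufficient
    statistics, including ``"_total_events"``.
    """

    parameter_name: str
    support: np.ndarray
    coefficients: list[int]
    conditioning: dict[str, int]
    log_coeff: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        if self.support.size == 0:
            raise DegenerateDistributionError(
                f"empty conditional support for {self.parameter_name!r}"
            )
        if any(c <= 0 for c in self.coefficients):
            raise ValueError("all conditional coefficients must be positive")
        if not np.all(np.diff(self.support) > 0):
            raise ValueError("support must be strictly increasing")
        self.log_coeff = np.array([math.log(c) for c in self.coefficients])

    @property
    def t_min(self) -> int:
        return int(self.support[0])

    @property
    def t_max(self) -> int:
        return int(self.support[-1])

    @property
    def informative(self) -> bool:
        return self.support.size > 1

    def logpmf(self, beta: float) -> np.ndarray:
        w = self.log_coeff + beta * self.support
        return w - logsumexp(w)

    def pmf(self, beta: float) -> np.ndarray:
        return np.exp(self.logpmf(beta))

    def mean(self, beta: float) -> float:
        return float(np.sum(self.pmf(beta) * self.support))

    def prob_le(self, t: int, beta: float) -> float:
        """P(T <= t | beta), computed in the log domain."""
        w = self.log_coeff + beta * self.support
        mask = self.support <= t
        if not mask.any():
            return 0.0
        return float(np.exp(logsumexp(w[mask]) - logsumexp(w)))

    def prob_ge(self, t: int, beta: float) -> float:
        """P(T >= t | beta)."""
        w = self.log_coeff + beta * self.support
        mask = self.support >= t
        if not mask.any():
            return 0.0
        return float(np.exp(logsumexp(w[mask]) - logsumexp(w)))


def _joint_coefficients(
    design: GroupedDesign, n_events: int
) -> dict[tuple[int, tuple[int, ...]], int]:
    """Multiply per-group generating polynomials in exact integers.

    Each group contributes sum_{k=0..m_j} C(m_j, k) u^k z^(k x_j); the
    accumulated state maps (total events, joint sufficient statistic) to
    its big-integer coefficient.  Terms with more than ``n_events`` total
    events can never satisfy the conditioning and are pruned as we go.
    """
    p = len(design.parameter_names)
    states: dict[tuple[int, tuple[int, ...]], int] = {(0, (0,) * p): 1}
    for x, m, _ in design.patterns:
        kmax = min(m, n_events)
        binoms = [comb(m, k) for k in range(kmax + 1)]
        new: dict[tuple[int, tuple[int, ...]], int] = defaultdict(int)
        for (k, tv), c in states.items():
            for kk in range(min(kmax, n_events - k) + 1):
                nt = tuple(tv[i] + kk * x[i] for i in range(p)) if kk else tv
                new[(k + kk, nt)] += c * binoms[kk]
        states = dict(new)
    return states


def conditional_distribution(
    design: GroupedDesign, target_index: int
) -> ConditionalDistribution:
    """Exact conditional distribution of one parameter's sufficient statistic.

    Conditions on the observed values of every other parameter's sufficient
    statistic and on the total number of events; the weights c_t are exact
    integers (binomial-coefficient products survive unrounded, e.g.
    C(834, 11)-scale values that would overflow doubles).
    """
    t_obs = design.sufficient_statistics()
    n_events = design.n_events
    joint = _joint_coefficients(design, n_events)
    others = [i for i in range(len(design.parameter_names)) if i != target_index]
    weights: dict[int, int] = {}
    for (k, tv), c in joint.items():
        if k != n_events:
            continue
        if any(tv[i] != t_obs[i] for i in others):
            continue
        weights[tv[target_index]] = weights.get(tv[target_index], 0) + c
    support = sorted(weights)
    conditioning = {"_total_events": n_events}
    conditioning.update({design.parameter_names[i]: t_obs[i] for i in others})
    dist = ConditionalDistribution(
        parameter_name=design.parameter_names[target_index],
        support=np.array(support),
        coefficients=[weights[t] for t in support],
        conditioning=conditioning,
    )
    if not dist.informative:
        warnings.warn(
            f"conditional distribution of {dist.parameter_name!r} has a "
            "single support point: non-informative",
            stacklevel=2,
        )
    return dist


def brute_force_fit(
    covariates: Sequence[Sequence[int]],
    outcomes: Sequence[int],
    target_index: int,
    max_subjects: int = 25,
) -> ConditionalDistribution:
    """Conditional distribution by direct enumeration (test oracle).

    Enumerates every assignment of the observed number of events to
    subjects, keeps those matching the non-target sufficient statistics,
    and tallies c_t.  Exponential in cohort size; refuses n > ``max_subjects``.
    """
    n = len(covariates)
    if n > max_subjects:
        raise ValueError(f"brute force limited to {max_subjects} subjects, got {n}")
    if len(outcomes) != n:
        raise ValueError("covariates and outcomes disagree in length")
    p = len(covariates[0])
    x = [tuple(int(v) for v in row) for row in covariates]
    y = [int(v) for v in outcomes]
    n_events = sum(y)
    t_obs = tuple(sum(y[j] * x[j][i] for j in range(n)) for i in range(p))
    others = [i for i in range(p) if i != target_index]
    weights: dict[int, int] = defaultdict(int)
    for chosen in itertools.combinations(range(n), n_events):
        tv = [0] * p
        for j in chosen:
            for i in range(p):
                tv[i] += x[j][i]
        if any(tv[i] != t_obs[i] for i in others):
            continue
        weights[tv[target_index]] += 1
    support = sorted(weights)
    conditioning = {"_total_events": n_events}
    conditioning.update({f"x{i}": t_obs[i] for i in others})
    return ConditionalDistribution(
        parameter_name=f"x{target_index}",
        support=np.array(support),
        coefficients=[weights[t] for t in support],
        conditioning=conditioning,
    )


def _solve_increasing(f, target: float) -> float:
    """Root of the increasing map f on [-BETA_MAX, BETA_MAX]; clamps at the
    bracket ends (with a warning) when the root lies outside."""
    lo, hi = f(-BETA_MAX) - target, f(BETA_MAX) - target
    if lo >= 0:
        warnings.warn("solution at or below lower search bound", stacklevel=3)
        return -BETA_MAX
    if hi <= 0:
        warnings.warn("solution at or above upper search bound", stacklevel=3)
        return BETA_MAX
    return float(brentq(lambda b: f(b) - target, -BETA_MAX, BETA_MAX, xtol=_BETA_TOL))


def cmle(dist: ConditionalDistribution, t_observed: int) -> float:
    """Conditional maximum likelihood estimate of the log odds ratio.

    Solves the conditional score equation E[T | beta] = t_obs; the map is
    strictly increasing in beta so a bracketed Brent search is exact to
    ``_BETA_TOL``.
    """
    if not dist.informative:
        raise DegenerateDistributionError(
            f"{dist.parameter_name!r}: single-point support, no CMLE"
        )
    if t_observed <= dist.t_min or t_observed >= dist.t_max:
        raise ValueError(
            f"t_observed={t_observed} is on the support boundary "
            f"[{dist.t_min}, {dist.t_max}]; the CMLE is infinite — use mue()"
        )
    return _solve_increasing(dist.mean, float(t_observed))


def mue(dist: ConditionalDistribution, t_observed: int) -> float:
    """Median unbiased estimate of the log odds ratio.

    At the support minimum solves P(T <= t | beta) = 1/2; at the maximum
    solves P(T >= t | beta) = 1/2; for interior t returns the midpoint of
    the two tail solutions.  This is the standard estimate when zero (or
    all) events fall in a category and the CMLE does not exist.
    """
    if not dist.informative:
        raise DegenerateDistributionError(
            f"{dist.parameter_name!r}: single-point support, no MUE"
        )
    # P(T <= t | beta) decreases in beta, P(T >= t | beta) increases.
    if t_observed == dist.t_min:
        return _solve_increasing(lambda b: -dist.prob_le(t_observed, b), -0.5)
    if t_observed == dist.t_max:
        return _solve_increasing(lambda b: dist.prob_ge(t_observed, b), 0.5)
    b1 = _solve_increasing(lambda b: -dist.prob_le(t_observed, b), -0.5)
    b2 = _solve_increasing(lambda b: dist.prob_ge(t_observed, b), 0.5)
    return 0.5 * (b1 + b2)


def exact_ci(
    dist: ConditionalDistribution, t_observed: int, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tail exact confidence interval on the odds-ratio scale.

    The lower limit exponentiates the beta with P(T >= t | beta) = alpha/2
    (0 when t is at the support minimum); the upper limit the beta with
    P(T <= t | beta) = alpha/2 (+inf at the maximum).  This convention
    yields the familiar "0 – U" intervals for zero-event categories.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if not dist.informative:
        raise DegenerateDistributionError(
            f"{dist.parameter_name!r}: single-point support, no CI"
        )
    a2 = (1.0 - level) / 2.0
    if t_observed == dist.t_min:
        lower = 0.0
    else:
        lower = math.exp(
            _solve_increasing(lambda b: dist.prob_ge(t_observed, b), a2)
        )
    if t_observed == dist.t_max:
        upper = math.inf
    else:
        upper = math.exp(
            _solve_increasing(lambda b: -dist.prob_le(t_observed, b), -a2)
        )
    return lower, upper


def exact_p(
    dist: ConditionalDistribution,
    t_observed: int,
    method: Literal["probability", "twice_smaller_tail"] = "probability",
) -> float:
    """Two-sided exact p-value at the null (odds ratio 1).

    ``probability`` (default) sums the null probabilities of all support
    points no more probable than the observed one; ``twice_smaller_tail``
    doubles the smaller of the two tail probabilities.  Both are clipped
    to [0, 1].
    """
    probs = dist.pmf(0.0)
    idx = np.flatnonzero(dist.support == t_observed)
    if idx.size == 0:
        raise ValueError(f"t_observed={t_observed} not in support")
    p_obs = probs[idx[0]]
    if method == "probability":
        p = float(np.sum(probs[probs <= p_obs * (1.0 + 1e-12)]))
    elif method == "twice_smaller_tail":
        p = 2.0 * min(dist.prob_le(t_observed, 0.0), dist.prob_ge(t_observed, 0.0))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return min(1.0, max(0.0, p))


@dataclass
class ExactParameterInference:
    """Odds ratio, exact CI and p-value for one dummy parameter."""

    parameter_name: str
    estimate_kind: Literal["cmle", "median_unbiased", "non_informative"]
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    t_observed: int
    t_min: int
    t_max: int

    @property
    def informative(self) -> bool:
        return self.estimate_kind != "non_informative"

    @property
    def significant(self) -> bool:
        """95% CI excludes an odds ratio of 1."""
        return self.informative and (self.ci_lower > 1.0 or self.ci_upper < 1.0)


def fit_exact_logit(
    design: GroupedDesign,
    level: float = 0.95,
    p_method: Literal["probability", "twice_smaller_tail"] = "probability",
) -> list[ExactParameterInference]:
    """Exact conditional inference for every parameter of a grouped design.

    Serves both crude fits (one variable's dummies, each conditioned on the
    variable's other dummies) and multiple fits (all selected variables'
    dummies jointly).  Boundary statistics get median unbiased estimates;
    parameters whose conditional support collapses to a point are flagged
    ``non_informative`` rather than dropped silently.
    """
    if not design.parameter_names:
        raise ValueError("design has no non-reference parameters")
    t_obs = design.sufficient_statistics()
    results: list[ExactParameterInference] = []
    for i, name in enumerate(design.parameter_names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = conditional_distribution(design, i)
        if not dist.informative:
            results.append(
                ExactParameterInference(
                    parameter_name=name,
                    estimate_kind="non_informative",
                    odds_ratio=math.nan,
                    ci_lower=math.nan,
                    ci_upper=math.nan,
                    p_value=math.nan,
                    t_observed=t_obs[i],
                    t_min=dist.t_min,
                    t_max=dist.t_max,
                )
            )
            continue
        t = t_obs[i]
        if t == dist.t_min or t == dist.t_max:
            kind = "median_unbiased"
            beta = mue(dist, t)
        else:
            kind = "cmle"
            beta = cmle(dist, t)
        lo, hi = exact_ci(dist, t, level=level)
        results.append(
            ExactParameterInference(
                parameter_name=name,
                estimate_kind=kind,
                odds_ratio=math.exp(beta),
                ci_lower=lo,
                ci_upper=hi,
                p_value=exact_p(dist, t, method=p_method),
                t_observed=t,
                t_min=dist.t_min,
                t_max=dist.t_max,
            )
        )
    return results
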