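"""Exact conditional inference: closed forms, oracles, and invariants."""

import math
import warnings
from collections import defaultdict
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prenatal_risk.exact import (
    DegenerateDistributionError,
    GroupedDesign,
    brute_force_fit,
    cmle,
    conditional_distribution,
    exact_ci,
    exact_p,
    fit_exact_logit,
    mue,
)

# A small unbalanced two-group design used by several grid-search oracles.
TINY = GroupedDesign.from_rows([((0,), 4, 1), ((1,), 3, 2)], ["x"])


def grid_argmax_loglik(dist, t_obs, lo=-10.0, hi=10.0, step=1e-4):
    """Independent CMLE oracle: grid search of the conditional likelihood."""
    betas = np.arange(lo, hi + step, step)
    w = dist.log_coeff[:, None] + np.outer(dist.support, betas)
    idx = int(np.flatnonzero(dist.support == t_obs)[0])
    loglik = w[idx] - np.logaddexp.reduce(w, axis=0)
    return betas[int(np.argmax(loglik))]


def grid_tail_root(dist, t_obs, tail, target, lo=-10.0, hi=10.0, step=1e-4):
    """Independent CI oracle: first beta whose tail probability crosses target."""
    betas = np.arange(lo, hi + step, step)
    probs = np.array([getattr(dist, tail)(t_obs, b) for b in betas])
    crossing = np.flatnonzero(np.diff(np.sign(probs - target)))
    assert crossing.size, "oracle bracket too small"
    return betas[crossing[0]]


class TestConditionalDistribution:
    def test_two_by_two_weights_are_hypergeometric(self):
        # exposed 59 of 893, 11 events total: c_t = C(59,t) C(834,11-t)
        design = GroupedDesign.from_rows([((0,), 834, 7), ((1,), 59, 4)], ["yes"])
        dist = conditional_distribution(design, 0)
        assert list(dist.support) == list(range(12))
        assert dist.coefficients == [comb(59, t) * comb(834, 11 - t) for t in range(12)]

    def test_multicategory_conditioning_reduces_to_two_groups(self):
        # conditioning the unmarried dummy on the other dummies' observed
        # event counts leaves 4 events split between married and unmarried
        design = GroupedDesign.one_variable(
            "marital_status",
            [("married", 423, 2), ("unmarried", 27, 2),
             ("not_answered", 26, 1), ("not_investigated", 417, 6)],
        )
        dist = conditional_distribution(design, 0)
        assert list(dist.support) == [0, 1, 2, 3, 4]
        # proportional to C(27,t) C(423,4-t); the conditioned groups only
        # contribute a constant factor, which cancels in the distribution
        for t in range(5):
            assert (
                dist.coefficients[t] * comb(27, 0) * comb(423, 4)
                == dist.coefficients[0] * comb(27, t) * comb(423, 4 - t)
            )

    def test_null_matches_central_hypergeometric_moments(self):
        m1, m0, k = 30, 70, 12
        design = GroupedDesign.from_rows([((0,), m0, 8), ((1,), m1, 4)], ["x"])
        dist = conditional_distribution(design, 0)
        n = m0 + m1
        assert dist.mean(0.0) == pytest.approx(k * m1 / n, rel=1e-12)
        var = float(np.sum(dist.pmf(0.0) * dist.support**2) - dist.mean(0.0) ** 2)
        assert var == pytest.approx(
            k * (m1 / n) * (m0 / n) * (n - k) / (n - 1), rel=1e-12
        )

    def test_single_point_support_is_flagged(self):
        design = GroupedDesign.from_rows([((0,), 5, 0), ((1,), 5, 0)], ["x"])
        with pytest.warns(UserWarning, match="non-informative"):
            dist = conditional_distribution(design, 0)
        assert not dist.informative


class TestBruteForceEquivalence:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_generating_function_equals_enumeration(self, data):
        n = data.draw(st.integers(4, 14))
        p = data.draw(st.integers(1, 3))
        cov = [
            tuple(data.draw(st.integers(0, 1)) for _ in range(p)) for _ in range(n)
        ]
        y = [data.draw(st.integers(0, 1)) for _ in range(n)]
        if not 0 < sum(y) < n:
            y[0], y[-1] = 1, 0
        groups = defaultdict(lambda: [0, 0])
        for c, yy in zip(cov, y):
            groups[c][0] += 1
            groups[c][1] += yy
        design = GroupedDesign.from_rows(
            [(k, v[0], v[1]) for k, v in groups.items()],
            [f"x{i}" for i in range(p)],
        )
        for target in range(p):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fast = conditional_distribution(design, target)
                slow = brute_force_fit(cov, y, target)
            assert list(fast.support) == list(slow.support)
            assert fast.coefficients == slow.coefficients

    def test_single_subject_support_is_forced(self):
        dist = brute_force_fit([(1,)], [1], 0)
        assert list(dist.support) == [1]

    def test_refuses_large_cohorts(self):
        with pytest.raises(ValueError, match="limited"):
            brute_force_fit([(0,)] * 30, [0] * 30, 0)


class TestCmle:
    def test_matches_grid_search_oracle(self):
        dist = conditional_distribution(TINY, 0)
        assert cmle(dist, 2) == pytest.approx(grid_argmax_loglik(dist, 2), abs=2e-4)

    def test_symmetric_design_gives_unit_odds_ratio(self):
        design = GroupedDesign.from_rows([((0,), 10, 3), ((1,), 10, 3)], ["x"])
        assert math.exp(cmle(conditional_distribution(design, 0), 3)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_mean_is_increasing_in_beta(self):
        dist = conditional_distribution(TINY, 0)
        means = [dist.mean(b) for b in np.linspace(-8, 8, 33)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_boundary_statistic_directs_to_mue(self):
        dist = conditional_distribution(TINY, 0)
        with pytest.raises(ValueError, match="mue"):
            cmle(dist, dist.t_min)


class TestMue:
    def test_solves_half_tail_equation(self):
        design = GroupedDesign.from_rows([((0,), 40, 5), ((1,), 10, 0)], ["x"])
        dist = conditional_distribution(design, 0)
        beta = mue(dist, 0)
        assert dist.prob_le(0, beta) == pytest.approx(0.5, abs=1e-9)

    def test_mirrored_designs_give_reciprocal_estimates(self):
        d1 = GroupedDesign.from_rows([((0,), 20, 4), ((1,), 20, 0)], ["x"])
        d2 = GroupedDesign.from_rows([((0,), 20, 0), ((1,), 20, 4)], ["x"])
        b1 = mue(conditional_distribution(d1, 0), 0)
        b2 = mue(conditional_distribution(d2, 0), 4)
        assert b1 == pytest.approx(-b2, abs=1e-8)


class TestExactCi:
    def test_matches_tail_inversion_oracle(self):
        dist = conditional_distribution(TINY, 0)
        lo, hi = exact_ci(dist, 2)
        assert math.log(lo) == pytest.approx(
            grid_tail_root(dist, 2, "prob_ge", 0.025), abs=2e-4
        )
        assert math.log(hi) == pytest.approx(
            grid_tail_root(dist, 2, "prob_le", 0.025), abs=2e-4
        )

    def test_zero_event_category_gets_zero_lower_limit(self):
        design = GroupedDesign.from_rows([((0,), 40, 5), ((1,), 10, 0)], ["x"])
        lo, hi = exact_ci(conditional_distribution(design, 0), 0)
        assert lo == 0.0 and 0 < hi < math.inf

    def test_interval_brackets_the_cmle_and_nests_by_level(self):
        dist = conditional_distribution(TINY, 0)
        beta = cmle(dist, 2)
        lo95, hi95 = exact_ci(dist, 2, level=0.95)
        lo90, hi90 = exact_ci(dist, 2, level=0.90)
        assert lo95 < math.exp(beta) < hi95
        assert lo95 < lo90 < hi90 < hi95

    def test_invalid_level_rejected(self):
        dist = conditional_distribution(TINY, 0)
        with pytest.raises(ValueError, match="level"):
            exact_ci(dist, 2, level=1.5)


class TestExactP:
    def test_matches_exhaustive_summation(self):
        dist = conditional_distribution(TINY, 0)
        probs = dist.pmf(0.0)
        for i, t in enumerate(dist.support):
            expected = float(probs[probs <= probs[i] + 1e-15].sum())
            assert exact_p(dist, int(t)) == pytest.approx(expected, abs=1e-12)

    def test_mode_of_symmetric_distribution_gives_p_one(self):
        design = GroupedDesign.from_rows([((0,), 10, 2), ((1,), 10, 2)], ["x"])
        assert exact_p(conditional_distribution(design, 0), 2) == pytest.approx(1.0)

    def test_twice_smaller_tail_variant(self):
        dist = conditional_distribution(TINY, 0)
        expected = 2 * min(dist.prob_le(2, 0.0), dist.prob_ge(2, 0.0))
        assert exact_p(dist, 2, method="twice_smaller_tail") == pytest.approx(
            min(1.0, expected)
        )


class TestFitExactLogit:
    def test_published_crude_fits_reproduced(self, published_crude_fits):
        by_name = {
            f.parameter_name: f
            for fits in published_crude_fits.values()
            for f in fits
        }
        unmarried = by_name["marital_status=unmarried"]
        assert unmarried.odds_ratio == pytest.approx(16.54, abs=0.01)
        assert unmarried.estimate_kind == "cmle"
        assert by_name["smoking=yes"].odds_ratio == pytest.approx(12.10, abs=0.01)
        assert by_name["smoking=stopped"].odds_ratio == pytest.approx(4.22, abs=0.01)

    def test_zero_events_everywhere_is_non_informative(self):
        design = GroupedDesign.from_rows([((0,), 10, 0), ((1,), 5, 0)], ["x"])
        (fit,) = fit_exact_logit(design)
        assert fit.estimate_kind == "non_informative"
        assert math.isnan(fit.odds_ratio)

    def test_boundary_parameters_get_median_unbiased_estimates(self):
        design = GroupedDesign.one_variable(
            "infertility_treatment",
            [("no", 696, 10), ("yes", 67, 0), ("not_answered", 6, 0),
             ("not_investigated", 124, 1)],
        )
        fits = {f.parameter_name: f for f in fit_exact_logit(design)}
        yes = fits["infertility_treatment=yes"]
        assert yes.estimate_kind == "median_unbiased"
        assert yes.t_observed == yes.t_min == 0
        assert yes.ci_lower == 0.0


class TestCoverage:
    def test_exact_ci_covers_true_odds_ratio_conservatively(self):
        """95% equal-tail exact CIs on 2x2 cohorts with true OR 5 should
        cover in >= 93% of replicates (exact intervals are conservative)."""
        rng = np.random.default_rng(42)
        true_or = 5.0
        p0 = 0.05
        p1 = true_or * p0 / (1 - p0 + true_or * p0)
        m0 = m1 = 100
        covered = total = 0
        for _ in range(500):
            y0 = rng.binomial(m0, p0)
            y1 = rng.binomial(m1, p1)
            if y0 + y1 == 0 or y0 + y1 == m0 + m1:
                continue
            design = GroupedDesign.from_rows([((0,), m0, y0), ((1,), m1, y1)], ["x"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = conditional_distribution(design, 0)
                if not dist.informative:
                    continue
                lo, hi = exact_ci(dist, y1)
            total += 1
            covered += lo <= true_or <= hi
        assert total >= 490
        assert covered / total >= 0.93
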