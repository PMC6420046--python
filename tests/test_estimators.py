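import itertools
import math

import numpy as np
import pytest

from huntsurvey import (
    PhaseData,
    PhasePlan,
    StrataSummary,
    eb_estimate,
    eb_variance_estimate,
    eb_variance_true,
    hh_estimate,
    hh_variance_estimate,
    hh_variance_true,
    nrbias_index_theoretical,
    nrbias_theoretical,
)
from huntsurvey.errors import (
    ConsistencyError,
    DegenerateSizeWarning,
    DomainError,
    EstimationError,
)
from huntsurvey.estimators import (
    eb_estimate_nu_form,
    impute_last_phase_nulls,
    read_survey_tables,
    write_estimate_record,
)


def make_two_phase(rng, full_response=True):
    """Random valid two-phase dataset (full follow-up response by default)."""
    N = int(rng.integers(50, 500))
    n_s1 = int(rng.integers(10, N))
    n_r1 = int(rng.integers(2, n_s1 - 2))
    n_m1 = n_s1 - n_r1
    n_s2 = int(rng.integers(2, n_m1 + 1))
    y1 = rng.poisson(2.0, n_r1).astype(float)
    n_r2 = n_s2 if full_response else int(rng.integers(2, n_s2 + 1))
    y2 = rng.poisson(1.0, n_r2).astype(float)
    p1 = PhaseData(i=1, n_s=n_s1, n_r=n_r1, n_m=n_m1, y_r=y1)
    p2 = PhaseData(i=2, n_s=n_s2, n_r=n_r2, n_m=n_s2 - n_r2, y_r=y2)
    return p1, p2, N


def make_chain(rng, L):
    """Random valid L-phase dataset with full last-phase response."""
    N = int(rng.integers(200, 800))
    phases = []
    pool = N
    for i in range(1, L + 1):
        n_s = int(rng.integers(max(4, pool // 3), max(5, (2 * pool) // 3)))
        n_s = min(n_s, pool)
        if i < L:
            n_r = int(rng.integers(2, n_s - 2)) if n_s >= 5 else n_s
            n_m = n_s - n_r
        else:
            n_r, n_m = n_s, 0
        phases.append(
            PhaseData(i=i, n_s=n_s, n_r=n_r, n_m=n_m,
                      y_r=rng.poisson(1.5, n_r).astype(float))
        )
        pool = n_m
        if pool < 5 and i < L:
            return None  # too short a chain for the requested L
    return phases, N


class TestHansenHurwitz:
    def test_hand_worked_example(self):
        # n_s1=10, respondents [2,0,0,1]; follow-up bags [0,0,1]
        p1 = PhaseData(i=1, n_s=10, n_r=4, n_m=6, y_r=np.array([2.0, 0, 0, 1]))
        p2 = PhaseData(i=2, n_s=3, n_r=3, n_m=0, y_r=np.array([0.0, 0, 1]))
        res = hh_estimate(p1, p2, N=40)
        assert res.mean_hat == pytest.approx((4 * 0.75 + 6 * (1 / 3)) / 10)
        assert res.mean_hat == pytest.approx(0.5)
        assert res.total_hat == pytest.approx(20.0)
        assert res.phase_weights == pytest.approx((0.4, 0.6))

    def test_full_response_reduces_to_srswor(self):
        y = np.array([3.0, 0, 1, 0, 2, 0, 0, 4])
        p1 = PhaseData(i=1, n_s=8, n_r=8, n_m=0, y_r=y)
        p2 = PhaseData(i=2, n_s=0, n_r=0, n_m=0, y_r=np.empty(0))
        res = hh_estimate(p1, p2, N=50)
        assert res.mean_hat == pytest.approx(y.mean())
        expected_var = (1 / 8 - 1 / 50) * y.var(ddof=1)
        assert res.var_hat_mean == pytest.approx(expected_var, rel=1e-12)

    def test_empty_first_phase_rejected(self):
        p1 = PhaseData(i=1, n_s=0, n_r=0, n_m=0, y_r=np.empty(0))
        p2 = PhaseData(i=2, n_s=0, n_r=0, n_m=0, y_r=np.empty(0))
        with pytest.raises(EstimationError):
            hh_estimate(p1, p2, N=10)

    def test_broken_nesting_rejected(self):
        p1 = PhaseData(i=1, n_s=10, n_r=6, n_m=4, y_r=np.zeros(6))
        p2 = PhaseData(i=2, n_s=5, n_r=5, n_m=0, y_r=np.zeros(5))
        with pytest.raises(ConsistencyError):
            hh_estimate(p1, p2, N=100)

    def test_degenerate_sizes_yield_nan_with_warning(self):
        p1 = PhaseData(i=1, n_s=6, n_r=4, n_m=2, y_r=np.array([1.0, 0, 2, 0]))
        p2 = PhaseData(i=2, n_s=1, n_r=1, n_m=0, y_r=np.array([3.0]))
        with pytest.warns(DegenerateSizeWarning):
            v = hh_variance_estimate(p1, p2, N=30)
        assert math.isnan(v)

    def test_variance_estimator_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            p1, p2, N = make_two_phase(rng)
            assert hh_variance_estimate(p1, p2, N) >= 0.0


class TestDesignSpaceEnumeration:
    """Exhaustive design-space oracles on toy populations.

    Every possible sample path is enumerated with its exact probability,
    so expectations and variances are exact (up to float rounding) and the
    unbiasedness of both the point and the variance estimator is checked
    without Monte Carlo error.
    """

    def test_census_first_phase_exact_unbiasedness(self):
        y = np.array([0, 0, 0, 1, 3, 0, 2, 5], dtype=float)
        N = len(y)
        M = [3, 4, 5, 6, 7]
        R = [0, 1, 2]
        n_s2 = 2
        totals, vhats = [], []
        for s2 in itertools.combinations(M, n_s2):
            p1 = PhaseData(i=1, n_s=N, n_r=len(R), n_m=len(M), y_r=y[R])
            p2 = PhaseData(i=2, n_s=n_s2, n_r=n_s2, n_m=0, y_r=y[list(s2)])
            res = hh_estimate(p1, p2, N)
            totals.append(res.total_hat)
            vhats.append(res.var_hat_total)
        totals, vhats = np.array(totals), np.array(vhats)
        assert totals.mean() == pytest.approx(y.sum(), abs=1e-12)
        assert vhats.mean() == pytest.approx(totals.var(), abs=1e-9)
        # and both agree with the theoretical variance formula
        strata = StrataSummary.from_nested_strata(y, [np.arange(N), np.array(M)])
        v_theory = hh_variance_true(
            strata, float(y.var(ddof=1)), N, N, n_s2 / len(M)
        ) * N * N
        assert totals.var() == pytest.approx(v_theory, abs=1e-9)

    def test_two_phase_with_randomized_rounding_exact_unbiasedness(self):
        # full enumeration including the rounding branches of n_s2
        y = np.array([0, 0, 0, 1, 3, 0, 2, 5, 1], dtype=float)
        N = len(y)
        M = [4, 5, 6, 7, 8]
        Rset = {0, 1, 2, 3}
        nu_m, n_s1 = 2 / 3, 7
        acc = []
        for s1 in itertools.combinations(range(N), n_s1):
            p_s1 = 1 / math.comb(N, n_s1)
            r1 = [k for k in s1 if k in Rset]
            m1 = [k for k in s1 if k not in Rset]
            n_m1 = len(m1)
            alpha = nu_m * n_m1
            lo = math.floor(alpha)
            om = alpha - lo
            branches = [(lo, 1.0)] if om < 1e-12 else [(lo, 1 - om), (lo + 1, om)]
            for n_s2, p_round in branches:
                for s2 in itertools.combinations(m1, n_s2):
                    p = p_s1 * p_round / math.comb(n_m1, n_s2)
                    p1 = PhaseData(i=1, n_s=n_s1, n_r=len(r1), n_m=n_m1, y_r=y[r1])
                    p2 = PhaseData(i=2, n_s=n_s2, n_r=n_s2, n_m=0, y_r=y[list(s2)])
                    res = hh_estimate(p1, p2, N)
                    acc.append((p, res.total_hat, res.var_hat_total))
        probs, totals, vhats = (np.array(v) for v in zip(*acc))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        e_t = (probs * totals).sum()
        var_t = (probs * totals**2).sum() - e_t**2
        assert e_t == pytest.approx(y.sum(), abs=1e-10)
        # the variance estimator stays exactly unbiased under randomized sizes
        assert (probs * vhats).sum() == pytest.approx(var_t, rel=1e-12)


class TestElBadry:
    def test_three_phase_matches_direct_form(self):
        # independent evaluation of the L=3 closed form
        # ybar = (n_r1 ybar_r1 + n_r2/nu2 ybar_r2 + n_m2/nu2 ybar_r3)/n_s1
        rng = np.random.default_rng(9)
        N = 600
        p1 = PhaseData(i=1, n_s=300, n_r=60, n_m=240, y_r=rng.poisson(2, 60).astype(float))
        p2 = PhaseData(i=2, n_s=120, n_r=30, n_m=90, y_r=rng.poisson(1, 30).astype(float))
        p3 = PhaseData(i=3, n_s=45, n_r=45, n_m=0, y_r=rng.poisson(1, 45).astype(float))
        nu2 = p2.n_s / p1.n_m
        direct = (
            p1.n_r * p1.ybar_r + p2.n_r / nu2 * p2.ybar_r + p2.n_m / nu2 * p3.ybar_r
        ) / p1.n_s
        res = eb_estimate([p1, p2, p3], N)
        assert res.mean_hat == pytest.approx(direct, rel=1e-12)

    def test_reduces_to_hh_on_random_datasets(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            p1, p2, N = make_two_phase(rng)
            hh = hh_estimate(p1, p2, N)
            eb = eb_estimate([p1, p2], N)
            assert eb.total_hat == pytest.approx(hh.total_hat, rel=1e-10)
            assert eb.var_hat_total == pytest.approx(
                hh.var_hat_mean * N * N, rel=1e-10
            )

    def test_nu_form_agrees_under_exact_sizes(self):
        # when realized sizes equal the design sizes the two algebraic
        # forms of the estimator coincide
        N = 800
        p1 = PhaseData(i=1, n_s=400, n_r=100, n_m=300, y_r=np.ones(100))
        p2 = PhaseData(i=2, n_s=150, n_r=50, n_m=100, y_r=np.full(50, 2.0))
        p3 = PhaseData(i=3, n_s=50, n_r=50, n_m=0, y_r=np.full(50, 3.0))
        plan = PhasePlan(nu=(0.5, 0.5, 0.5))
        total_nu = eb_estimate_nu_form([p1, p2, p3], N, plan)
        total_sz = eb_estimate([p1, p2, p3], N).total_hat
        assert total_nu == pytest.approx(total_sz, rel=1e-12)

    def test_full_response_first_phase(self):
        y = np.array([1.0, 0, 2, 0])
        p1 = PhaseData(i=1, n_s=4, n_r=4, n_m=0, y_r=y)
        p2 = PhaseData(i=2, n_s=0, n_r=0, n_m=0, y_r=np.empty(0))
        res = eb_estimate([p1, p2], 20)
        assert res.mean_hat == pytest.approx(y.mean())

    def test_broken_nesting_rejected(self):
        p1 = PhaseData(i=1, n_s=10, n_r=6, n_m=4, y_r=np.zeros(6))
        p2 = PhaseData(i=2, n_s=6, n_r=6, n_m=0, y_r=np.zeros(6))
        with pytest.raises(ConsistencyError):
            eb_estimate([p1, p2], 100)

    def test_variance_estimator_nonnegative_random_chains(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 200:
            out = make_chain(rng, L=int(rng.integers(2, 5)))
            if out is None:
                continue
            phases, N = out
            v = eb_variance_estimate(phases, N)
            assert v >= 0.0
            checked += 1


@pytest.fixture(scope="module")
def nested():
    rng = np.random.default_rng(1)
    y = rng.poisson(1.2, 40).astype(float)
    perm = rng.permutation(40)
    return y, [np.arange(40), perm[:25], perm[:12]]


class TestVarianceTrue:
    def test_l2_reduction_to_two_phase_form(self, nested):
        y, strata_sets = nested
        st = StrataSummary.from_nested_strata(y, strata_sets[:2])
        nu = (0.5, 0.4)
        v_general, _ = eb_variance_true(st, PhasePlan(nu), len(y))
        v_two_phase = hh_variance_true(
            st, float(y.var(ddof=1)), int(len(y) * nu[0]), len(y), nu[1]
        )
        assert v_general == pytest.approx(v_two_phase, rel=1e-12)

    def test_l3_matches_literal_sum(self, nested):
        y, strata_sets = nested
        N = len(y)
        st = StrataSummary.from_nested_strata(y, strata_sets)
        nu = (0.5, 0.4, 0.8)
        v_general, v_total = eb_variance_true(st, PhasePlan(nu), N)
        # literal three-phase sum, coded independently
        n_s1 = N * nu[0]
        M1, M2 = strata_sets[1], strata_sets[2]
        W1, W2 = len(M1) / N, len(M2) / N
        v_lit = (
            (1 / n_s1 - 1 / N) * y.var(ddof=1)
            + 1 / n_s1 * (1 / nu[1] - 1) * W1 * y[M1].var(ddof=1)
            + 1 / n_s1 * (1 / nu[1]) * (1 / nu[2] - 1) * W2 * y[M2].var(ddof=1)
        )
        assert v_general == pytest.approx(v_lit, rel=1e-12)
        assert v_total == pytest.approx(v_lit * N * N, rel=1e-12)

    def test_no_subsampling_limit_is_srswor(self, nested):
        y, strata_sets = nested
        st = StrataSummary.from_nested_strata(y, strata_sets[:2])
        v = hh_variance_true(st, float(y.var(ddof=1)), 20, len(y), 1.0)
        assert v == pytest.approx((1 / 20 - 1 / len(y)) * y.var(ddof=1), rel=1e-12)

    def test_invalid_nu_rejected(self, nested):
        y, strata_sets = nested
        st = StrataSummary.from_nested_strata(y, strata_sets[:2])
        with pytest.raises(DomainError):
            hh_variance_true(st, 1.0, 20, len(y), 0.0)


class TestNrBiasTheory:
    def test_ignorable_when_pi_z_zero(self):
        assert nrbias_theoretical(0.6, 0.0, 5.0) == 0.0

    @pytest.mark.parametrize(
        "pi_m,pi_z,expected",
        [(0.85, 0.30, 1 / 0.745), (0.85, 0.20, 1 / 0.83)],
    )
    def test_implied_bias_index(self, pi_m, pi_z, expected):
        assert nrbias_index_theoretical(pi_m, pi_z) == pytest.approx(expected)

    def test_domain_validation(self):
        with pytest.raises(DomainError):
            nrbias_theoretical(1.0, 0.5, 1.0)


class TestLastPhaseImputation:
    def test_noop_under_full_response(self):
        ph = PhaseData(i=2, n_s=3, n_r=3, n_m=0, y_r=np.array([1.0, 0, 2]))
        assert impute_last_phase_nulls(ph) is ph

    def test_nonrespondents_scored_as_null(self):
        ph = PhaseData(i=2, n_s=5, n_r=2, n_m=3, y_r=np.array([4.0, 1.0]))
        imp = impute_last_phase_nulls(ph)
        assert imp.n_r == 5 and imp.n_m == 0
        assert imp.ybar_r == pytest.approx(1.0)  # 5/5


class TestSurveyTablesIO:
    def test_round_trip_and_estimate(self, tmp_path):
        import pandas as pd

        resp = pd.DataFrame(
            {
                "phase": [1, 1, 1, 1, 2, 2, 2],
                "unit_id": [0, 1, 2, 3, 10, 11, 12],
                "bag": [2, 0, 0, 1, 0, 0, 1],
            }
        )
        summ = pd.DataFrame(
            {"phase": [1, 2], "n_s": [10, 3], "n_r": [4, 3], "n_m": [6, 0]}
        )
        resp.to_csv(tmp_path / "resp.csv", index=False)
        summ.to_csv(tmp_path / "summ.csv", index=False)
        phases = read_survey_tables(tmp_path / "resp.csv", tmp_path / "summ.csv")
        res = hh_estimate(phases[0], phases[1], N=40)
        assert res.mean_hat == pytest.approx(0.5)
        write_estimate_record(res, tmp_path / "est.txt")
        text = (tmp_path / "est.txt").read_text()
        assert "mean_hat: 0.5" in text

    def test_malformed_tables_rejected(self, tmp_path):
        import pandas as pd

        from huntsurvey.errors import DataFormatError

        pd.DataFrame({"phase": [1], "bag": [0]}).to_csv(tmp_path / "r.csv", index=False)
        pd.DataFrame(
            {"phase": [1], "n_s": [2], "n_r": [1], "n_m": [1]}
        ).to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(DataFormatError):
            read_survey_tables(tmp_path / "r.csv", tmp_path / "s.csv")
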