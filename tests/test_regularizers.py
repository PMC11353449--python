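import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import pdmaxent as px
from pdmaxent.exceptions import InvalidInputError

from helpers import (
    oracle_elastic_net,
    oracle_group_lasso,
    oracle_project_l1,
    oracle_prox_linf,
    oracle_soft_threshold,
)

finite_vectors = hnp.arrays(
    np.float64,
    st.integers(min_value=1, max_value=8),
    elements=st.floats(-10, 10, allow_nan=False),
)


class TestSoftThreshold:
    def test_identity_at_zero(self, rng):
        v = rng.normal(size=5)
        np.testing.assert_array_equal(px.soft_threshold(v, 0.0), v)

    def test_dead_zone(self):
        assert px.soft_threshold(np.array([0.3]), 0.5)[0] == 0.0

    def test_hand_case_and_oracle(self):
        v = np.array([2.0, -1.2])
        got = px.soft_threshold(v, 0.5)
        np.testing.assert_allclose(got, [1.5, -0.7], atol=1e-14)
        np.testing.assert_allclose(got, oracle_soft_threshold(v, 0.5), atol=1e-7)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidInputError):
            px.soft_threshold(np.array([1.0]), -0.1)


class TestProxElasticNet:
    def test_alpha_one_reduces_to_soft_threshold(self, rng):
        v = rng.normal(size=6)
        np.testing.assert_allclose(
            px.prox_elastic_net(v, 0.7, 1.0), px.soft_threshold(v, 0.7)
        )

    def test_pure_ridge(self):
        assert px.prox_elastic_net(np.array([2.0]), 1.0, 0.0)[0] == pytest.approx(1.0)

    def test_halfway_case(self):
        assert px.prox_elastic_net(np.array([2.0]), 1.0, 0.5)[0] == pytest.approx(1.0)

    def test_matches_numeric_minimizer(self, rng):
        for _ in range(25):
            v = rng.normal(size=rng.integers(1, 8)) * 3
            lam = rng.random() * 2
            alpha = rng.random()
            np.testing.assert_allclose(
                px.prox_elastic_net(v, lam, alpha),
                oracle_elastic_net(v, lam, alpha),
                atol=1e-6,
            )

    def test_alpha_out_of_range(self):
        with pytest.raises(InvalidInputError):
            px.prox_elastic_net(np.array([1.0]), 1.0, 1.5)


class TestProxGroupLasso:
    groups = px.GroupStructure((0, 0, 1, 1, 1, 2))

    def test_dead_zone_block(self):
        v = np.array([0.1, 0.1, 0.0, 0.0, 0.0, 5.0])
        out = px.prox_group_lasso(v, 1.0, self.groups)
        np.testing.assert_array_equal(out[:2], 0.0)

    def test_hand_case(self):
        groups = px.GroupStructure((0, 0, 0, 0))
        # one group of 4, only two nonzero coords: threshold lam*sqrt(4)=2
        v = np.array([3.0, 4.0, 0.0, 0.0])
        out = px.prox_group_lasso(v, 1.0, groups)
        np.testing.assert_allclose(out[:2], [1.8, 2.4], atol=1e-14)

    def test_lambda_zero_identity(self, rng):
        v = rng.normal(size=6)
        np.testing.assert_array_equal(px.prox_group_lasso(v, 0.0, self.groups), v)

    def test_zero_block_maps_to_zero(self):
        v = np.zeros(6)
        np.testing.assert_array_equal(px.prox_group_lasso(v, 0.5, self.groups), 0.0)

    def test_matches_numeric_minimizer(self, rng):
        weights = np.sqrt(np.asarray(self.groups.sizes, dtype=float))
        for _ in range(25):
            v = rng.normal(size=6) * 2
            lam = rng.random()
            np.testing.assert_allclose(
                px.prox_group_lasso(v, lam, self.groups),
                oracle_group_lasso(v, lam, self.groups.indices, weights),
                atol=1e-6,
            )

    def test_size_mismatch(self):
        with pytest.raises(InvalidInputError):
            px.prox_group_lasso(np.ones(4), 1.0, self.groups)


class TestProjectL1Ball:
    def test_interior_point_unchanged(self):
        v = np.array([0.5, -0.5])
        np.testing.assert_array_equal(px.project_l1_ball(v, 2.0), v)

    def test_hand_kkt_case(self):
        np.testing.assert_allclose(
            px.project_l1_ball(np.array([3.0, 1.0]), 2.0), [2.0, 0.0], atol=1e-14
        )

    def test_matches_qp_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(size=6) * 3
            radius = 0.5 + rng.random() * 2
            np.testing.assert_allclose(
                px.project_l1_ball(v, radius),
                oracle_project_l1(v, radius),
                atol=1e-6,
            )

    @given(finite_vectors, st.floats(0.1, 5.0))
    def test_feasibility_and_optimality(self, v, radius):
        proj = px.project_l1_ball(v, radius)
        assert np.abs(proj).sum() <= radius + 1e-12
        rng = np.random.default_rng(0)
        d_proj = np.sum((proj - v) ** 2)
        for _ in range(200):
            cand = rng.normal(size=v.size)
            s = np.abs(cand).sum()
            if s > radius:
                cand *= radius / s
            assert d_proj <= np.sum((cand - v) ** 2) + 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            px.project_l1_ball(np.array([np.nan, 1.0]), 1.0)


class TestProxLinf:
    def test_inside_ball_gives_zero(self):
        np.testing.assert_array_equal(
            px.prox_linf(np.array([0.5, -0.5]), 2.0), 0.0
        )

    def test_hand_case(self):
        np.testing.assert_allclose(
            px.prox_linf(np.array([3.0, 1.0]), 2.0), [1.0, 1.0], atol=1e-14
        )

    @given(finite_vectors, st.floats(0.1, 5.0))
    def test_moreau_identity(self, v, lam):
        np.testing.assert_allclose(
            px.prox_linf(v, lam) + px.project_l1_ball(v, lam), v, atol=1e-12
        )

    def test_matches_numeric_minimizer(self, rng):
        for _ in range(20):
            v = rng.normal(size=5) * 3
            lam = 0.2 + rng.random() * 2
            np.testing.assert_allclose(
                px.prox_linf(v, lam), oracle_prox_linf(v, lam), atol=1e-6
            )

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(InvalidInputError):
            px.prox_linf(np.array([1.0]), 0.0)


class TestFirmNonexpansiveness:
    @pytest.mark.parametrize(
        "make_prox",
        [
            lambda: (lambda v: px.soft_threshold(v, 0.8)),
            lambda: (lambda v: px.prox_elastic_net(v, 0.8, 0.5)),
            lambda: (
                lambda v: px.prox_group_lasso(v, 0.5, px.GroupStructure((0, 0, 1, 1, 1, 2)))
            ),
            lambda: (lambda v: px.prox_linf(v, 0.7)),
            lambda: (lambda v: px.project_l1_ball(v, 1.3)),
        ],
        ids=["soft", "elastic", "group", "linf", "l1ball"],
    )
    def test_nonexpansive_on_random_pairs(self, make_prox, rng):
        op = make_prox()
        for _ in range(500):
            x = rng.normal(size=6) * 4
            y = rng.normal(size=6) * 4
            assert np.linalg.norm(op(x) - op(y)) <= np.linalg.norm(x - y) + 1e-12


class TestRegularizerValue:
    def test_zero_at_origin(self):
        for reg in [px.elastic_net(0.5), px.group_lasso([0, 1, 1]), px.linf()]:
            m = 2 if reg.kind != "group_lasso" else 3
            assert px.regularizer_value(np.zeros(m), reg) == 0.0

    def test_elastic_direct(self):
        reg = px.elastic_net(0.5)
        w = np.array([1.0, -1.0])
        assert px.regularizer_value(w, reg) == pytest.approx(1.5)

    def test_linf(self):
        assert px.regularizer_value(np.array([1.0, -3.0]), px.linf()) == 3.0

    def test_group_sqrt_weighting(self):
        reg = px.group_lasso([0, 0, 1])
        w = np.array([3.0, 4.0, 2.0])
        assert px.regularizer_value(w, reg) == pytest.approx(
            np.sqrt(2) * 5.0 + 1.0 * 2.0
        )

    def test_group_size_weighting_switch(self):
        reg = px.group_lasso([0, 0, 1], weighting="size")
        w = np.array([3.0, 4.0, 2.0])
        assert px.regularizer_value(w, reg) == pytest.approx(2 * 5.0 + 1 * 2.0)


class TestTMax:
    def test_degenerate_zero(self):
        values = np.array([[0.1, 0.9], [0.8, 0.2]])
        prior = np.array([0.5, 0.5])
        prob = px.MaxEntProblem(px.FeatureMatrix(values), prior, prior)
        for reg in [px.elastic_net(0.5), px.group_lasso([0, 1]), px.linf()]:
            assert px.t_max(prob, reg) == pytest.approx(0.0, abs=1e-15)

    @staticmethod
    def _problem_with_residual():
        # crafted so b - A prior = (0.2, -0.4)
        values = np.array([[0.0, 0.4], [0.8, 0.0]])
        prior = np.array([0.5, 0.5])
        empirical = np.array([0.0, 1.0])
        # b = (0.4, 0.0); A prior = (0.2, 0.4) -> residual (0.2, -0.4)
        return px.MaxEntProblem(px.FeatureMatrix(values), prior, empirical)

    def test_elastic_residual_case(self):
        prob = self._problem_with_residual()
        assert px.t_max(prob, px.elastic_net(0.5)) == pytest.approx(0.8)

    def test_linf_residual_case(self):
        prob = self._problem_with_residual()
        assert px.t_max(prob, px.linf()) == pytest.approx(0.6)

    def test_group_weighting(self):
        prob = self._problem_with_residual()
        reg = px.group_lasso([0, 0])
        expected = np.hypot(0.2, 0.4) / np.sqrt(2)
        assert px.t_max(prob, reg) == pytest.approx(expected)


class TestOptimalityResidual:
    def test_equality_at_tmax(self, small_problem):
        for reg in [px.elastic_net(0.6), px.group_lasso([0, 0, 1, 1, 2, 2]), px.linf()]:
            tm = px.t_max(small_problem, reg)
            check = px.optimality_residual(
                small_problem.prior, np.zeros(6), small_problem, reg, tm
            )
            assert check.satisfied
            assert check.residual == pytest.approx(check.threshold / (1 + 1e-5), rel=1e-9)

    def test_slack_above_tmax(self, small_problem):
        reg = px.elastic_net(0.6)
        tm = px.t_max(small_problem, reg)
        check = px.optimality_residual(
            small_problem.prior, np.zeros(6), small_problem, reg, 2.0 * tm
        )
        assert check.satisfied
        assert check.residual < check.threshold * 0.75

    def test_converged_solution_passes_and_perturbation_fails(self, small_problem):
        reg = px.elastic_net(0.6)
        t = 0.5 * px.t_max(small_problem, reg)
        res = px.solve(small_problem, reg, t)
        assert res.converged
        assert px.optimality_residual(res.p, res.w, small_problem, reg, t).satisfied
        bad = res.w.copy()
        bad[0] += 10.0
        assert not px.optimality_residual(res.p, bad, small_problem, reg, t).satisfied

    def test_t_nonpositive(self, small_problem):
        with pytest.raises(InvalidInputError):
            px.optimality_residual(
                small_problem.prior, np.zeros(6), small_problem, px.linf(), 0.0
            )


class TestSolveAtOrAboveTmax:
    def test_trivial_solution(self, small_problem):
        for reg in [px.elastic_net(0.6), px.group_lasso([0, 0, 1, 1, 2, 2]), px.linf()]:
            tm = px.t_max(small_problem, reg)
            res = px.solve(small_problem, reg, 1.01 * tm)
            assert res.converged
            assert np.max(np.abs(res.w)) <= 1e-6
            assert 0.5 * np.abs(res.p - small_problem.prior).sum() <= 1e-6
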