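import numpy as np
import pytest

from fitloop.estimator import apply_component, make_component
from fitloop.inversion import (
    GenericOperator,
    InversionConfig,
    analytic_linear_oracle,
    invert_dynamical,
    invert_fixed_point,
    operator_from_component,
    stability_map,
)


def scalar_op(s):
    return GenericOperator(forward=lambda q: s * q, m_in=1, m_out=1)


class TestFixedPoint:
    def test_identity_operator_closed_form(self):
        # Loop equilibrium for S = identity: q = g p / (1 + g).
        res = invert_fixed_point(
            scalar_op(1.0), np.array([3.0]), InversionConfig(gain=100.0)
        )
        assert res.converged
        assert res.q[0] == pytest.approx(300.0 / 101.0, rel=1e-9)
        assert res.residual == pytest.approx(3.0 / 101.0, rel=1e-6)

    def test_scalar_double_closed_form(self):
        res = invert_fixed_point(
            scalar_op(2.0), np.array([1.0]), InversionConfig(gain=100.0)
        )
        assert res.q[0] == pytest.approx(100.0 / 201.0, rel=1e-9)
        assert abs(res.q[0] - 0.5) == pytest.approx(1.0 / 402.0, rel=1e-6)

    def test_zero_operator_converges_to_g_p(self):
        res = invert_fixed_point(
            GenericOperator(forward=lambda q: 0.0 * q, m_in=1, m_out=1),
            np.array([0.5]),
            InversionConfig(gain=10.0),
        )
        assert res.converged
        assert res.q[0] == pytest.approx(5.0, rel=1e-8)

    def test_gain_law_error_scales_inverse_with_gain(self):
        # Deviation from the true inverse p/s is p / (s (1 + g s)).
        p, s = 1.0, 2.0
        for g in (10.0, 100.0, 1000.0):
            res = invert_fixed_point(scalar_op(s), np.array([p]), InversionConfig(gain=g))
            expected = p / (s * (1 + g * s))
            assert abs(res.q[0] - p / s) == pytest.approx(expected, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            invert_fixed_point(scalar_op(1.0), np.ones(2), InversionConfig())


class TestOracle:
    def test_identity_oracle(self):
        p = np.array([0.4, -1.0])
        np.testing.assert_allclose(
            analytic_linear_oracle(np.eye(2), np.zeros(2), "identity", p), p
        )

    def test_scalar_division(self):
        np.testing.assert_allclose(
            analytic_linear_oracle(
                np.array([[2.0]]), np.zeros(1), "identity", np.array([1.0])
            ),
            [0.5],
        )

    def test_round_trip_through_forward_map(self):
        comp = make_component({"m": 5, "n": 5, "cond_cap": 1e3}, seed=3)
        p = apply_component(comp, np.array([0.5, -0.2, 1.0, 0.1, -0.7]))
        u = analytic_linear_oracle(comp.A, comp.b, comp.nonlinearity, p)
        np.testing.assert_allclose(apply_component(comp, u), p, atol=1e-10)

    def test_singular_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            analytic_linear_oracle(
                np.zeros((2, 2)), np.zeros(2), "identity", np.ones(2)
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_feedback_matches_oracle_and_improves_with_gain(self, seed):
        # ||q - oracle|| / ||oracle|| shrinks at least 5x per 10x gain.
        comp = make_component(
            {"m": 4, "n": 4, "ensemble": "gaussian", "cond_cap": 1e3}, seed=seed
        )
        S = operator_from_component(comp)
        p = apply_component(comp, np.array([0.8, -0.3, 0.5, 0.2]))
        oracle = analytic_linear_oracle(comp.A, comp.b, comp.nonlinearity, p)
        errs = []
        for g in (1000.0, 10_000.0):
            res = invert_fixed_point(S, p, InversionConfig(gain=g, max_iter=100_000))
            assert res.converged
            errs.append(np.linalg.norm(res.q - oracle) / np.linalg.norm(oracle))
        assert errs[0] < 0.25
        assert errs[1] < errs[0] / 5.0


class TestDynamical:
    def test_matches_fixed_point_without_delay(self):
        cfg = InversionConfig(gain=100.0, mode="dynamical", max_iter=50_000)
        res = invert_dynamical(scalar_op(2.0), np.array([1.0]), cfg)
        assert res.converged
        assert res.q[0] == pytest.approx(100.0 / 201.0, rel=1e-6)

    def test_zero_input_settles_at_zero(self):
        cfg = InversionConfig(gain=50.0, mode="dynamical", max_iter=50_000)
        res = invert_dynamical(scalar_op(2.0), np.array([0.0]), cfg)
        assert res.converged
        assert abs(res.q[0]) <= 1e-8

    def test_large_delay_destabilizes_high_gain_loop(self):
        cfg = InversionConfig(
            gain=100.0, mode="dynamical", delay_steps=300, max_iter=50_000
        )
        res = invert_dynamical(scalar_op(2.0), np.array([1.0]), cfg)
        assert res.diverged and not res.converged
        assert np.all(np.isfinite(res.q))

    def test_trajectory_recorded_on_request(self):
        cfg = InversionConfig(gain=10.0, mode="dynamical", max_iter=5000)
        res = invert_dynamical(
            scalar_op(1.0), np.array([1.0]), cfg, record_trajectory=True
        )
        assert len(res.trajectory) == res.iterations


class TestStabilityMap:
    def test_zero_delay_converges_below_gain_limit(self):
        # relax_step (1 + g s) < 2 keeps the undelayed loop stable.
        table = stability_map(
            scalar_op(2.0),
            gains=[5.0, 50.0],
            delays=[0],
            cfg=InversionConfig(mode="dynamical", relax_step=0.002, max_iter=20_000),
        )
        assert not table["diverged"].any()

    def test_tiny_gain_never_diverges_but_leaves_residual(self):
        table = stability_map(
            scalar_op(2.0),
            gains=[0.001],
            delays=[0, 10, 100],
            cfg=InversionConfig(mode="dynamical", relax_step=0.002, max_iter=20_000),
        )
        assert not table["diverged"].any()
        assert (table["residual"] > 0.5).all()

    def test_duplicated_grid_point_is_deterministic(self):
        cfg = InversionConfig(mode="dynamical", relax_step=0.002, max_iter=20_000)
        t = stability_map(scalar_op(2.0), gains=[50.0, 50.0], delays=[5], cfg=cfg)
        assert t.iloc[0]["diverged"] == t.iloc[1]["diverged"]
        assert t.iloc[0]["settle_steps"] == t.iloc[1]["settle_steps"]

    def test_divergence_monotone_in_delay(self):
        table = stability_map(
            scalar_op(2.0),
            gains=[5.0, 50.0, 200.0],
            delays=[0, 1, 2, 5, 10, 20, 50, 100, 200],
            cfg=InversionConfig(mode="dynamical", relax_step=0.002, max_iter=20_000),
        )
        assert int(table["monotone_violation"].sum()) == 0
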