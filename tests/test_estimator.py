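import numpy as np
import pytest

from fitloop.estimator import (
    NONLINEARITIES,
    EstimatorBank,
    aggregate_estimate,
    apply_component,
    drift_parameters,
    make_component,
)
from fitloop.rng import stream


class TestMakeComponent:
    def test_identity_ensemble_is_identity(self):
        comp = make_component({"m": 1, "n": 1, "ensemble": "identity"}, seed=0)
        np.testing.assert_array_equal(comp.A, [[1.0]])
        np.testing.assert_array_equal(comp.b, [0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_square_components_respect_cond_cap(self, seed):
        comp = make_component(
            {"m": 5, "n": 5, "ensemble": "gaussian", "cond_cap": 1e3}, seed=seed
        )
        assert np.linalg.cond(comp.A) <= 1e3

    def test_deterministic_given_seed(self):
        spec = {"m": 3, "n": 3, "ensemble": "gaussian"}
        a, b = make_component(spec, seed=9), make_component(spec, seed=9)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.b, b.b)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            make_component({"m": 0, "n": 1}, seed=0)


class TestApplyComponent:
    def test_identity_map(self, identity_component):
        u = np.array([0.3, -1.2])
        np.testing.assert_allclose(apply_component(identity_component, u), u)

    def test_scalar_linear(self, scalar_double):
        np.testing.assert_allclose(
            apply_component(scalar_double, np.array([1.0])), [2.0]
        )

    def test_blackbox_matches_structured_reference(self):
        # A blackbox component must agree with the structured map it wraps.
        spec = {"m": 3, "n": 3, "ensemble": "gaussian"}
        ref = make_component(spec, seed=4)
        bb = make_component(spec | {"kind": "blackbox"}, seed=4)
        rng = stream(0, "t")
        for _ in range(100):
            u = rng.normal(size=3)
            np.testing.assert_allclose(
                apply_component(bb, u), apply_component(ref, u)
            )

    def test_dimension_mismatch_rejected(self, scalar_double):
        with pytest.raises(ValueError):
            apply_component(scalar_double, np.array([1.0, 2.0]))

    def test_injective_on_random_inputs(self, square_component):
        rng = stream(2, "inj")
        inputs = rng.normal(size=(50, 4))
        outputs = np.array([apply_component(square_component, u) for u in inputs])
        d_in = np.linalg.norm(inputs[:, None] - inputs[None], axis=-1)
        d_out = np.linalg.norm(outputs[:, None] - outputs[None], axis=-1)
        mask = d_in > 1e-8
        assert np.all(d_out[mask] > 0)


class TestAggregate:
    def bank(self, comp, output_map="relu"):
        return EstimatorBank(components=(comp,), output_map=output_map)

    def test_zero_input_gives_documented_constant(self, identity_component):
        bank = self.bank(identity_component, output_map="softplus")
        x = aggregate_estimate(bank, [np.zeros(2)])
        assert x == pytest.approx(np.log(2.0))

    def test_pass_through_in_linear_regime(self, identity_component):
        bank = self.bank(identity_component, output_map="relu")
        assert aggregate_estimate(bank, [np.array([0.7, 0.7])]) == pytest.approx(0.7)

    def test_doubling_weights_doubles_presquash_sum(self, identity_component):
        b1 = EstimatorBank(
            components=(identity_component,),
            weights=np.array([1.0]),
            output_map="relu",
        )
        b2 = EstimatorBank(
            components=(identity_component,),
            weights=np.array([2.0]),
            output_map="relu",
        )
        out = [np.array([0.4, 0.8])]
        assert aggregate_estimate(b2, out) == pytest.approx(
            2 * aggregate_estimate(b1, out)
        )

    def test_nonnegative_for_any_input(self, square_component):
        bank = self.bank(square_component, output_map="softplus")
        rng = stream(3, "agg")
        for _ in range(50):
            x = aggregate_estimate(bank, [rng.normal(size=4, scale=10)])
            assert x >= 0

    def test_mismatched_outputs_rejected(self, identity_component):
        with pytest.raises(ValueError):
            aggregate_estimate(self.bank(identity_component), [])


class TestDrift:
    def drifting(self, sd):
        from dataclasses import replace

        comp = make_component({"m": 3, "n": 3, "cond_cap": 1e3}, seed=11)
        return replace(comp, drift_sd=sd, drift_timescale=1.0)

    def test_zero_drift_sd_is_noop(self):
        comp = self.drifting(0.0)
        out = drift_parameters(comp, 0.01, stream(0, "d"))
        np.testing.assert_array_equal(out.A, comp.A)

    def test_cond_cap_preserved_under_drift(self):
        comp = self.drifting(0.5)
        rng = stream(1, "d")
        for _ in range(200):
            comp = drift_parameters(comp, 0.01, rng)
            assert np.linalg.cond(comp.A) <= comp.cond_cap * (1 + 1e-9)

    def test_identical_streams_give_identical_drift(self):
        comp = self.drifting(0.3)
        a = drift_parameters(comp, 0.01, stream(7, "d"))
        b = drift_parameters(comp, 0.01, stream(7, "d"))
        np.testing.assert_array_equal(a.A, b.A)

    def test_stationary_bank_repeats_output(self):
        comp = self.drifting(0.0)
        bank = EstimatorBank(components=(comp,))
        u = np.array([0.1, -0.4, 0.9])
        vals = {
            aggregate_estimate(bank, [apply_component(comp, u)]) for _ in range(5)
        }
        assert len(vals) == 1


class TestNonlinearities:
    @pytest.mark.parametrize("name", list(NONLINEARITIES))
    def test_strictly_increasing_and_invertible(self, name):
        phi, phi_inv = NONLINEARITIES[name]
        z = np.linspace(-20, 20, 401)
        y = np.asarray(phi(z))
        assert np.all(np.diff(y) > 0)
        np.testing.assert_allclose(np.asarray(phi_inv(y)), z, atol=1e-8)
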