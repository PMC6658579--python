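from dataclasses import replace
from itertools import repeat

import numpy as np
import pytest

from fitloop.estimator import make_component
from fitloop.inversion import InversionConfig
from fitloop.loop import (
    LoopBuffers,
    LoopConfig,
    run_external,
    run_internal_dialogue,
    run_stage1,
    run_stage2,
)
from fitloop.rng import stream


def loop_cfg(**inv):
    return LoopConfig(inversion=InversionConfig(**inv))


class TestStages:
    def test_stage1_writes_x_buffer_only(self, identity_component):
        buffers = LoopBuffers(u_buf=np.array([9.0, 9.0]))
        out = run_stage1(identity_component, np.array([1.0, 2.0]), buffers)
        np.testing.assert_array_equal(out.x_buf, [1.0, 2.0])
        np.testing.assert_array_equal(out.u_buf, [9.0, 9.0])

    def test_stage1_idempotent(self, identity_component):
        u = np.array([0.4, -0.1])
        a = run_stage1(identity_component, u, LoopBuffers())
        b = run_stage1(identity_component, u, a)
        np.testing.assert_array_equal(a.x_buf, b.x_buf)

    def test_stage2_inverts_identity(self, identity_component):
        buffers = run_stage1(identity_component, np.array([1.0, 2.0]), LoopBuffers())
        buffers, res = run_stage2(
            identity_component, buffers, InversionConfig(gain=1e6, max_iter=50_000)
        )
        assert res.converged
        np.testing.assert_allclose(buffers.u_buf, [1.0, 2.0], rtol=1e-5)
        np.testing.assert_array_equal(buffers.x_buf, [1.0, 2.0])

    def test_stage2_scalar_closed_form(self, scalar_double):
        buffers = run_stage1(scalar_double, np.array([0.5]), LoopBuffers())
        buffers, _ = run_stage2(scalar_double, buffers, InversionConfig(gain=100.0))
        assert buffers.u_buf[0] == pytest.approx(100.0 / 201.0, rel=1e-8)

    def test_stage2_holds_u_buffer_on_divergence(self, scalar_double):
        # A dynamical inversion with huge delay diverges; the u buffer
        # must keep its previous value.
        held = np.array([0.123])
        buffers = LoopBuffers(x_buf=np.array([1.0]), u_buf=held.copy())
        cfg = InversionConfig(
            gain=100.0, mode="dynamical", delay_steps=500, max_iter=20_000
        )
        buffers, res = run_stage2(scalar_double, buffers, cfg)
        assert res.diverged
        np.testing.assert_array_equal(buffers.u_buf, held)

    def test_stage2_requires_populated_x_buffer(self, scalar_double):
        with pytest.raises(ValueError):
            run_stage2(scalar_double, LoopBuffers(), InversionConfig())


class TestExternalLoop:
    def test_empty_trace_for_zero_cycles(self, scalar_double):
        trace = run_external(scalar_double, repeat(np.ones(1)), 0, loop_cfg())
        assert trace.records == []

    def test_stationary_loop_cycles_identical(self, square_component):
        u = np.array([0.3, -0.2, 0.5, 0.1])
        trace = run_external(
            square_component, repeat(u), 10, loop_cfg(gain=1000.0, max_iter=50_000)
        )
        u_hats = [r["u_hat"] for r in trace.records]
        for later in u_hats[1:]:
            np.testing.assert_array_equal(u_hats[0], later)

    def test_roundtrip_error_small_at_high_gain(self, square_component):
        u = np.array([0.3, -0.2, 0.5, 0.1])
        trace = run_external(
            square_component, repeat(u), 5, loop_cfg(gain=10_000.0, max_iter=100_000)
        )
        for r in trace.records:
            assert r["converged"]
            assert r["roundtrip_error"] < 1e-3

    def test_single_instance_constraint(self, square_component):
        # Both stages of a cycle must see byte-identical parameters even
        # while the component drifts between cycles.
        comp = replace(square_component, drift_sd=0.05, drift_timescale=1.0)
        trace = run_external(
            comp,
            repeat(np.array([0.3, -0.2, 0.5, 0.1])),
            20,
            loop_cfg(gain=1000.0, max_iter=50_000),
            rng=stream(0, "loop"),
        )
        hashes = [r["param_hash"] for r in trace.records]
        assert len(set(hashes)) > 1  # drift happened across cycles


class TestInternalDialogue:
    def internal_cfg(self, **inv):
        return LoopConfig(mode="internal_dialogue", inversion=InversionConfig(**inv))

    def test_identity_component_fixes_input(self, identity_component):
        trace = run_internal_dialogue(
            identity_component,
            np.array([0.5, 0.5]),
            3,
            self.internal_cfg(gain=1e8, max_iter=100_000),
        )
        np.testing.assert_allclose(
            trace.records[0]["u_hat"], [0.5, 0.5], rtol=1e-6
        )

    def test_changes_shrink_monotonically_for_stationary_component(self):
        comp = make_component({"m": 2, "n": 2, "cond_cap": 1e2}, seed=5)
        trace = run_internal_dialogue(
            comp,
            np.array([0.5, -0.2]),
            60,
            self.internal_cfg(gain=50.0, max_iter=50_000),
        )
        u_hats = [r["u_hat"] for r in trace.records]
        changes = [
            np.linalg.norm(b - a) for a, b in zip(u_hats[:-1], u_hats[1:])
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(changes[:-1], changes[1:]))

    def test_drift_makes_u_hat_wander(self):
        comp = make_component({"m": 2, "n": 2, "cond_cap": 1e2}, seed=5)
        comp = replace(comp, drift_sd=0.1, drift_timescale=1.0)
        trace = run_internal_dialogue(
            comp,
            np.array([0.5, -0.2]),
            50,
            self.internal_cfg(gain=50.0, max_iter=50_000),
            rng=stream(3, "drift"),
        )
        u_hats = np.array([r["u_hat"] for r in trace.records])
        tail = u_hats[20:]
        assert np.linalg.norm(tail.max(axis=0) - tail.min(axis=0)) > 1e-6

    def test_change_variance_scales_with_drift_sd_squared(self):
        # The self-feeding loop's exact fixed point (the origin) does not
        # move under parameter drift, so the drift response lives in the
        # trajectory's deviation from the paired stationary baseline.
        # That deviation's per-cycle change variance must grow linearly
        # in drift_sd^2 (log-log slope ~ 1 over 4 drift levels).
        base = make_component({"m": 2, "n": 2, "cond_cap": 1e2}, seed=5)
        cfg = self.internal_cfg(gain=50.0, max_iter=50_000)
        u0 = np.array([0.5, -0.2])
        baseline = np.array(
            [r["u_hat"] for r in run_internal_dialogue(base, u0, 60, cfg).records]
        )
        levels = [0.005, 0.01, 0.02, 0.04]
        variances = []
        for sd in levels:
            comp = replace(base, drift_sd=sd, drift_timescale=1.0)
            per_seed = []
            for s in range(6):
                trace = run_internal_dialogue(
                    comp, u0, 60, cfg, rng=stream(s, "var")
                )
                dev = np.array([r["u_hat"] for r in trace.records]) - baseline
                per_seed.append(np.mean(np.sum(np.diff(dev, axis=0) ** 2, axis=1)))
            variances.append(np.mean(per_seed))
        v = np.asarray(variances)
        sd2 = np.asarray(levels) ** 2
        assert np.all(np.diff(v) > 0)
        slope = np.polyfit(np.log(sd2), np.log(v), 1)[0]
        assert 0.7 < slope < 1.3
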