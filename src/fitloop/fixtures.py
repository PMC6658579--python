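"""Canonical scenario fixtures.

Each fixture is a fully specified, deterministic scenario used by the
test suite, the examples and the acceptance script.  They are generated
programmatically — no data files — and `generate_fixture(name, seed)`
always returns the identical config for identical arguments.
"""

from __future__ import annotations

from .config import ScenarioConfig

__all__ = ["FIXTURE_NAMES", "generate_fixture"]

FIXTURE_NAMES = (
    "scalar_linear",
    "square_monotone",
    "blackbox",
    "delayed_loop",
    "two_bump_drive",
    "dialogue_pair",
    "internal_dialogue",
)

# The landscape used by the drift scenarios: two Gaussian peaks of
# unequal height in a 2-d form space, start near the origin between them.
_TWO_BUMP_WORLD = {
    "dim_form": 2,
    "landscape": [
        {"center": [2.0, 2.0], "height": 1.0, "width": 1.0},
        {"center": [-2.0, -2.0], "height": 0.6, "width": 1.0},
    ],
    "init_scale": 1.0,
    "dt": 0.01,
}


def generate_fixture(name: str, seed: int = 0) -> ScenarioConfig:
    """Return a canonical scenario config by name; deterministic."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "scalar_linear":
        # The s = 2 scalar inversion: closed form q = g p / (1 + g s).
        return ScenarioConfig(
            scenario="invert",
            id="scalar_linear",
            seed=seed,
            bank={
                "components": [
                    {
                        "id": "scalar",
                        "m": 1,
                        "n": 1,
                        "ensemble": "identity",
                        "nonlinearity": "identity",
                        "A": [[2.0]],
                        "b": [0.0],
                    }
                ]
            },
            gains=[10.0, 100.0, 1000.0],
            probe=[1.0],
        )
    if name in ("square_monotone", "blackbox"):
        return ScenarioConfig(
            scenario="invert",
            id=name,
            seed=seed,
            bank={
                "components": [
                    {
                        "id": name,
                        "m": 4,
                        "n": 4,
                        "kind": "blackbox" if name == "blackbox" else "linear_monotone",
                        "ensemble": "gaussian",
                        "nonlinearity": "softplus_floor",
                        "cond_cap": 1e3,
                    }
                ]
            },
            gains=[10.0, 100.0, 1000.0],
            probe=[1.0, 0.5, -0.3, 1.2],
        )
    if name == "delayed_loop":
        return ScenarioConfig(
            scenario="stability",
            id="delayed_loop",
            seed=seed,
            bank={
                "components": [
                    {
                        "id": "scalar",
                        "m": 1,
                        "n": 1,
                        "ensemble": "identity",
                        "nonlinearity": "identity",
                        "A": [[2.0]],
                        "b": [0.0],
                    }
                ]
            },
            inversion={"mode": "dynamical", "relax_step": 0.002, "max_iter": 20000},
            gains=[5.0, 50.0, 200.0],
            delays=[0, 1, 2, 5, 10, 20, 50, 100, 200, 400],
            probe=[1.0],
        )
    if name == "two_bump_drive":
        return ScenarioConfig(
            scenario="drive",
            id="two_bump_drive",
            seed=seed,
            world=_TWO_BUMP_WORLD,
            drive={
                "sigma_max": 0.25,
                "modulation_family": "hill",
                "x_half": 0.15,
                "steepness": 4.0,
                "horizon_steps": 4000,
                "n_seeds": 20,
                "control": "matched_mean_sigma",
            },
            n_seeds=20,
        )
    if name == "dialogue_pair":
        return ScenarioConfig(
            scenario="dialogue",
            id="dialogue_pair",
            seed=seed,
            bank={
                "components": [
                    {
                        "id": "talk",
                        "m": 3,
                        "n": 3,
                        "ensemble": "gaussian",
                        "nonlinearity": "softplus_floor",
                        "cond_cap": 10.0,
                    }
                ]
            },
            inversion={"gain": 1e5, "max_iter": 50000},
            n_turns=12,
            u_init=[0.8, -0.4, 0.5],
        )
    # internal_dialogue
    return ScenarioConfig(
        scenario="internal_dialogue",
        id="internal_dialogue",
        seed=seed,
        bank={
            "components": [
                {
                    "id": "inner",
                    "m": 2,
                    "n": 2,
                    "ensemble": "gaussian",
                    "nonlinearity": "softplus_floor",
                    "cond_cap": 1e2,
                }
            ]
        },
        loop={"mode": "internal_dialogue"},
        inversion={"gain": 50.0},
        n_cycles=2000,
        u_init=[0.5, -0.2],
    )
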