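"""Shared fixtures.

The expensive end-to-end chains (Lotka–Volterra small/large noise and the
FitzHugh–Nagumo pipeline) are session-scoped and shared between the
acceptance tests and the module-level property tests, so each study
condition is sampled exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import fgpgm
from fgpgm import experiments


@pytest.fixture(scope="session")
def lv_system():
    return fgpgm.registry_get("lotka_volterra")


@pytest.fixture(scope="session")
def fhn_system():
    return fgpgm.registry_get("fitzhugh_nagumo")


@pytest.fixture(scope="session")
def protein_system():
    return fgpgm.registry_get("protein_transduction")


@pytest.fixture(scope="session")
def lv_scheme_x1(lv_system):
    return fgpgm.ObservationScheme.from_names(lv_system, ["x1"], ["x2"])


@pytest.fixture(scope="session")
def lv_dataset_small_noise(lv_system, lv_scheme_x1):
    """One LV dataset at the small-noise study conditions."""
    return fgpgm.generate_dataset(
        lv_system, (2, 1, 4, 1), (5, 3), (20, 0.0, 2.0),
        fgpgm.NoiseSpec(sd=0.1), lv_scheme_x1, seed=1,
    )


@pytest.fixture(scope="session")
def lv_gp_small_noise(lv_dataset_small_noise):
    d = lv_dataset_small_noise
    return {0: fgpgm.fit_state_gp(d.times, d.values[:, 0], "rbf",
                                  n_restarts=10, seed=0)}


@pytest.fixture(scope="session")
def lv_small_noise_runs():
    """Full pipeline (FGPGM + least-squares polish) at sd 0.1, 10 seeds."""
    return [experiments.lv_partial(seed=s, noise_sd=0.1) for s in range(1, 11)]


@pytest.fixture(scope="session")
def lv_large_noise_runs():
    """Full pipeline at sd 0.5; both observation schemes, 5 seeds each."""
    runs = [experiments.lv_partial(seed=s, noise_sd=0.5, observed="x1")
            for s in range(1, 6)]
    runs += [experiments.lv_partial(seed=s, noise_sd=0.5, observed="x2")
             for s in range(1, 6)]
    return runs


@pytest.fixture(scope="session")
def fhn_pipeline_runs():
    """FHN with x2 latent (reduced-sampling set-up) + LM refinement, 10 seeds."""
    return [
        experiments.fhn_strategy(seed=s, strategy="full_integration", refine=True)
        for s in range(1, 11)
    ]
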