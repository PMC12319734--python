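"""Shared fixtures.

The two expensive session fixtures run the full desk-scale pipeline once —
``desk_results`` on the default heterogeneous cohort (subject fingerprints
present) and ``null_results`` on an information-free cohort
(between-subject variance zero) — and are shared by the statistical and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from megfingerprint.geometry import build_array, build_source_space, compute_leadfield
from megfingerprint.pipeline import RunConfig, run


@pytest.fixture(scope="session")
def desk_config() -> RunConfig:
    return RunConfig.desk_scale(seed=1)


@pytest.fixture(scope="session")
def desk_results(desk_config):
    """Full pipeline on the default 15-subject desk-scale cohort."""
    return run(desk_config)


@pytest.fixture(scope="session")
def null_results():
    """Same pipeline with between-subject variance forced to zero."""
    return run(RunConfig.desk_scale(seed=1, between_subject_scale=0.0))


@pytest.fixture(scope="session")
def equivalent_results():
    """Quick platform-equivalent cohort (equal sensor noise floors) for the
    group-level exchangeability check."""
    cfg = RunConfig.desk_scale(
        seed=1,
        n_trials=4,
        source_spacing_m=0.015,
        tfs_centres_hz=(18.5, 26.5, 4.0),
        n_perm_matrix=1000,
        n_chance_sim=1000,
        noise_floor_override_fT=8.0,
    )
    return run(cfg)


@pytest.fixture(scope="session")
def opm_array():
    return build_array("opm")


@pytest.fixture(scope="session")
def squid_array():
    return build_array("squid")


@pytest.fixture(scope="session")
def fine_space():
    """5 mm source grid for localisation-accuracy tests."""
    return build_source_space(radius_m=0.08, spacing_m=0.005)


@pytest.fixture(scope="session")
def fine_leadfield_opm(fine_space, opm_array):
    return compute_leadfield(fine_space, opm_array)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
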