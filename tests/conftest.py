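"""Shared fixtures: small synthetic configurations and reusable full runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from coastvuln.config import (
    CLIMATE_VARIABLES,
    GridSpec,
    RunConfig,
    ScenarioSpec,
    SyntheticConfig,
)
from coastvuln.pipeline import generate_bundle, run_pipeline


def small_synth(seed: int = 11, **overrides) -> SyntheticConfig:
    """A fast configuration: 4 species on a 12x20 grid, 8 communities."""
    params = dict(
        seed=seed,
        grid=GridSpec(n_lon=12, n_lat=20),
        n_species=4,
        n_port_groups=3,
        n_communities=8,
        n_tracts_per_community=2,
        n_years=2,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_synth()


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    cfg = RunConfig(seed=11, synthetic=small_cfg)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_run(small_cfg):
    cfg = RunConfig(seed=11, synthetic=small_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg, write=False)


def designed_scenario(n_species: int = 20, n_communities: int = 25) -> ScenarioSpec:
    """Strictly increasing per-species shifts; the last community fishes the
    top-shift species exclusively, with maximal reliance and worst social
    conditions."""
    mult = np.linspace(0.2, 3.0, n_species)
    target = f"C{n_communities:02d}"
    top_species = f"sp{n_species:02d}"
    return ScenarioSpec(
        species_shift_multipliers=list(mult),
        revenue_concentration={target: {top_species: 1.0}},
        reliance_values={target: 50.0},
        social_metric_levels={target: 1.0},
    )


@pytest.fixture(scope="session")
def designed_run():
    scen = designed_scenario()
    cfg = RunConfig(output_dir="scratch/test_designed", seed=3,
                    synthetic=SyntheticConfig(seed=3), scenario=scen)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, run_pipeline(cfg, write=False)


@pytest.fixture(scope="session")
def zero_shift_run():
    synth = SyntheticConfig(
        seed=2, climate_shift={v: 0.0 for v in CLIMATE_VARIABLES})
    cfg = RunConfig(output_dir="scratch/test_zero", seed=2, synthetic=synth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, run_pipeline(cfg, write=False)
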