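"""Shared fixtures: small deterministic datasets built by the synthetic module."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regulonscope.config import RunConfig
from regulonscope.models import StrandedCoverage
from regulonscope.synthetic import Scenario, SyntheticDataset, simulate_scenario


@pytest.fixture(scope="session")
def default_dataset() -> SyntheticDataset:
    """The default 100 kb study-shaped scenario at a fixed seed."""
    return simulate_scenario(Scenario(), seed=7)


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    """A 30 kb scenario for fast end-to-end tests."""
    sc = Scenario(
        genome_length=30_000,
        n_genes=18,
        n_sites=8,
        n_intergenic=6,
        n_strong_repressed=1,
        n_mild_repressed=1,
        n_repressed=1,
        n_activated=1,
        n_indirect=2,
        n_acid_responsive=2,
        mean_depth=5e5,
    )
    return simulate_scenario(sc, seed=11)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default scenario (seed 7), shared."""
    from regulonscope import pipeline

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    manifest = pipeline.run_all(outdir, seed=7)
    return manifest, outdir


def make_coverage(
    length: int,
    plus_spikes: dict[int, int] | None = None,
    minus_spikes: dict[int, int] | None = None,
    name: str = "toy",
) -> StrandedCoverage:
    """Hand-built coverage track for arithmetic peak-calling examples."""
    plus = np.zeros(length, dtype=np.int64)
    minus = np.zeros(length, dtype=np.int64)
    for pos, v in (plus_spikes or {}).items():
        plus[pos] = v
    for pos, v in (minus_spikes or {}).items():
        minus[pos] = v
    return StrandedCoverage(genome_name=name, plus=plus, minus=minus)
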