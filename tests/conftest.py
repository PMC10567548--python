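"""Shared fixtures: one small synthetic fixture set and two simulations
(error-free and noisy), generated once per session."""

from __future__ import annotations

import pytest

from spatialcite import ReadLayout, load_panel, load_whitelist
from spatialcite.fixtures import make_fixtures
from spatialcite.simulate import ErrorModel, TissueModel, simulate_run


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    return make_fixtures(tmp_path_factory.mktemp("fx"), seed=11, scale="small")


@pytest.fixture(scope="session")
def panel(fixture_set):
    return load_panel(fixture_set.panel)


@pytest.fixture(scope="session")
def whitelists(fixture_set):
    return (
        load_whitelist(fixture_set.whitelist_a, "A"),
        load_whitelist(fixture_set.whitelist_b, "B"),
    )


@pytest.fixture(scope="session")
def layout():
    return ReadLayout()


@pytest.fixture(scope="session")
def tissue(fixture_set):
    return TissueModel.from_yaml(fixture_set.tissue)


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory, tissue, panel, fixture_set, whitelists, layout):
    """Error-free, duplication-free simulation: pipeline must reproduce
    ground truth exactly."""
    outdir = tmp_path_factory.mktemp("sim_clean")
    return simulate_run(
        tissue, panel, fixture_set.transcriptome, whitelists, layout,
        ErrorModel(substitution_rate=0.0, pcr_duplication=1.0, seed=101), outdir,
    )


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory, tissue, panel, fixture_set, whitelists, layout):
    """Simulation with sequencing errors and PCR duplicates."""
    outdir = tmp_path_factory.mktemp("sim_noisy")
    return simulate_run(
        tissue, panel, fixture_set.transcriptome, whitelists, layout,
        ErrorModel(substitution_rate=0.005, pcr_duplication=3.0, seed=202), outdir,
    )
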