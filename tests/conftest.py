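"""Shared fixtures: bench materials, cell geometry, fitted benchmark cone."""

import numpy as np
import pytest

import torquecell as tc


@pytest.fixture(scope="session")
def polymer() -> tc.Material:
    return tc.Material(elastic_modulus_gpa=3.76, poisson_ratio=0.34,
                       yield_strength_mpa=40.0)


@pytest.fixture(scope="session")
def bench_cell() -> tc.UnitCell:
    return tc.UnitCell(width_um=3.15, length_um=6.3, substrate_depth_um=6.0)


@pytest.fixture(scope="session")
def bench_spec() -> tc.RoughnessSpec:
    return tc.RoughnessSpec(sa_nm=849.0, sdq_deg=50.0, sdr_pct=40.0)


@pytest.fixture(scope="session")
def bench_fit(bench_spec, bench_cell) -> tc.ConeFit:
    """The packaged benchmark cone: slope and developed-area matched."""
    return tc.fit_cone(bench_spec, bench_cell, "sdq+sdr")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20180630)
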