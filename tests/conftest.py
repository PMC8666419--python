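"""Shared fixtures: small simulated libraries, parsed once per session."""

import numpy as np
import pytest

from umierr._template import DEFAULT_TEMPLATE
from umierr.ingest import TemplateSpec, read_pairs
from umierr.simulate import SimConfig, simulate_library


@pytest.fixture(scope="session")
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def spec(template):
    return TemplateSpec.from_layout(template)


@pytest.fixture(scope="session")
def small_library(template, tmp_path_factory):
    """A small noisy library with substitutions injected, written to SAM."""
    cfg = SimConfig(
        template=template,
        n_molecules=150,
        substitution_rate=1e-3,
        deletion_rate=2e-4,
        insertion_rate=2e-4,
        product_length_mean=240.0,
        product_length_sd=8.0,
        phred_mean=30.0,
        phred_sd=0.0,
        seed=42,
    )
    lib = simulate_library(cfg)
    sam = tmp_path_factory.mktemp("sim") / "small.sam"
    lib.write_sam(str(sam))
    return lib, str(sam)


@pytest.fixture(scope="session")
def small_obs(small_library, spec):
    _, sam = small_library
    return read_pairs(sam, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
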