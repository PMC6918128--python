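"""Shared fixtures: a full synthetic characterization campaign (session
scoped — simulation plus deconvolution of 5 compounds × 7 dilutions is
the expensive part of the suite) and small fast runs for unit tests."""

from __future__ import annotations

import pytest

from aiflib import synthgen
from aiflib.chem import parse_formula
from aiflib.pipeline import PipelineConfig, characterize_campaign

#: One fixed seed for the whole stated world of the test suite.
SEED = 7


@pytest.fixture(scope="session")
def campaign():
    """5 compounds x 5 tIS x 7-level dilution series at full scale."""
    return synthgen.simulate_characterization_campaign(
        synthgen.default_compounds(), synthgen.default_tis(), seed=SEED
    )


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def library(campaign, config):
    """Curated records + stage log from the full campaign."""
    return characterize_campaign(campaign, config)


def make_tiny_compound(**overrides):
    """A single fast compound on a short gradient for unit tests."""
    kw = dict(
        name="probe",
        formula=parse_formula("C7H7NO2"),
        rt=1.0,
        response=5000.0,
        adduct_abundances={"[M+H]+": 1.0},
        fragments={
            10.0: [("C7H6NO", 40.0)],
            30.0: [("C6H8N", 100.0), ("C5H6N", 40.0)],
        },
    )
    kw.update(overrides)
    return synthgen.SyntheticCompound(**kw)


@pytest.fixture
def tiny_compound():
    return make_tiny_compound()


@pytest.fixture
def tiny_run(tiny_compound):
    """2-minute gradient, one compound at 200 fmol."""
    run, manifest = synthgen.simulate_run(
        [tiny_compound], [200.0], seed=SEED, gradient_min=2.0, run_id="tiny"
    )
    return run, manifest, tiny_compound
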