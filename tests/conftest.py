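"""Shared fixtures: session-scoped phantoms and cohorts (generation is ~1 s)."""
import numpy as np
import pytest

from pulmopet import synthetic_data as synth


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size phantom with all artifacts enabled."""
    return synth.generate_phantom(synth.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Full-size phantom without cardiac/tumor/cold-spot artifacts."""
    return synth.generate_phantom(synth.PhantomSpec(
        seed=3, include_cardiac_spillover=False, include_tumor=False,
        include_diaphragm_coldspot=False))


@pytest.fixture(scope="session")
def cohort100():
    return synth.simulate_cohort(synth.CohortConfig(n_patients=100, seed=1))


@pytest.fixture(scope="session")
def phantom_case_dir(tmp_path_factory, clean_phantom):
    """Clean phantom written to disk in the per-case file layout."""
    outdir = tmp_path_factory.mktemp("cases")
    synth.save_phantom(clean_phantom, outdir, case_id="case01")
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
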