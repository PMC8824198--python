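import numpy as np
import pytest

from scgscreen import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20220207)


@pytest.fixture(scope="session")
def asv_dataset():
    """Small planted triage dataset shared across tests."""
    return fixtures.gen_asv_dataset(
        n_community_asvs=12,
        cells_per_category={"PASS": 8, "CONTAMINANT": 5, "MIXTURE": 4, "RARE_UNMATCHED": 3},
        contaminant_genera=["Ralstonia", "Pseudomonas", "Sphingomonas"],
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_curves():
    ranges = fixtures.CurveParamRanges(noise_frac=0.0)
    return fixtures.gen_mda_curves(6, 4, param_ranges=ranges, seed=7)
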