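"""Shared fixtures: one small synthetic study reused across test modules."""
import numpy as np
import pytest

from mousefc import synth

SMALL_DIMS = (24, 12, 6)
SMALL_REGIONS = 20


@pytest.fixture(scope="session")
def small_study():
    """Small atlas + region table + cohort templates (desk-size)."""
    atlas, table = synth.build_synthetic_atlas(
        dims=SMALL_DIMS, n_regions=SMALL_REGIONS, rng_seed=7)
    templates = synth.cohort_templates(table)
    return atlas, table, templates


@pytest.fixture(scope="session")
def control_run(small_study):
    """One clean control BOLD run in atlas space (T=120, mild noise)."""
    atlas, _, templates = small_study
    return synth.simulate_bold_run(atlas, templates["control"], T=120,
                                   noise_sd=0.5, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
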