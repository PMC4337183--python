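import numpy as np
import pandas as pd
import pytest

from bulb2de.catalog import generate_catalog
from bulb2de.cohort import EffectDesign, generate_cohort, plant_effects
from bulb2de.gel_analysis import GelSpotTable


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """A small noisy cohort with a few planted effects of every class."""
    design = EffectDesign(comparison="P7-vs-P90", n_up=6, n_down=5,
                          n_absent_cmp=2, n_absent_p90=2, seed=11)
    truth = plant_effects(small_catalog, design)
    cmp_gels, ref_gels = generate_cohort(truth, design)
    return design, truth, cmp_gels, ref_gels


def make_gel(gel_id, rows):
    """Helper: build a GelSpotTable from (spot_id, x, y, volume) tuples."""
    return GelSpotTable(gel_id=gel_id, spots=pd.DataFrame(
        rows, columns=["spot_id", "x", "y", "volume"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
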