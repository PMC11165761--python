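import numpy as np
import pytest

from sesvlink.pipeline import PipelineConfig, analyze_cohort
from sesvlink.simulate import SyntheticConfig, generate_cohort

#: Reduced-size study for file-level / integration tests (fast but exercises
#: every stage; the acceptance suite runs the full default conditions).
SMALL_CONFIG = SyntheticConfig(
    n_noncaga=20,
    n_caga=8,
    n_genes=60,
    n_enhancer_sites=150,
    sv_per_sample=10.0,
    n_planted_genes=6,
    seed=7,
)

SMALL_PIPELINE = PipelineConfig(permutations=200, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    c = small_cohort
    return analyze_cohort(c.samples, c.gene_models, c.peaks, c.sv_calls,
                          c.expression, SMALL_PIPELINE)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)
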