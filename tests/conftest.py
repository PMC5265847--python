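import pytest

from omnilevel.pipeline import run_study
from omnilevel.simulate import SimulationConfig, generate_study

# A fast, reduced-cohort study used across test modules.
SMALL_SHAPES = dict(
    n_genes=400,
    n_mirnas=60,
    n_planted=20,
    n_pairs_expression=20,
    n_pairs_cnv=20,
    me_a_tumor=12,
    me_a_normal=12,
    me_b_tumor=10,
    me_b_normal=15,
    mirna_tumor=15,
    mirna_normal=30,
    n_case_maf=30,
    n_background_maf=200,
)

# Fully null version (no planted effects) of the same shapes.
NULL_SHAPES = dict(
    n_genes=500,
    n_mirnas=100,
    n_planted=0,
    n_pairs_expression=20,
    n_pairs_cnv=20,
    me_a_tumor=15,
    me_a_normal=15,
    me_b_tumor=12,
    me_b_normal=20,
    mirna_tumor=20,
    mirna_normal=40,
    n_case_maf=30,
    n_background_maf=200,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SimulationConfig(seed=11, **SMALL_SHAPES))


@pytest.fixture(scope="session")
def small_result(small_study):
    return run_study(small_study)
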