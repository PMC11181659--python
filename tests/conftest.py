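import pytest

from armsl import CohortSpec, generate_cohort


def small_spec(**overrides) -> CohortSpec:
    """A fast desk-scale cohort: 80 lines x 400 genes, same planted structure."""
    base = dict(
        n_lines=80,
        n_genes=400,
        n_arm_genes=30,
        n_lineages=5,
        program_expr_size=60,
        program_fit_size=100,
        n_variable_background=20,
        n_moderate_essential=40,
        n_pan_essential=20,
        n_decoy_pairs=3,
        n_dep_arm_genes=3,
        n_dep_offarm_genes=1,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(), seed=7)
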