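import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          max_examples=60, deadline=None)
settings.load_profile("deterministic")

from pparpipe.simulate import (
    ExpressionSimSpec,
    bladder_narrative_variants,
    make_toy_heterodimer,
    simulate_expression,
)
from pparpipe.variants import pparg2_domain_map


@pytest.fixture(scope="session")
def narrative_variants():
    """Miniature cohort reproducing the published mutation narrative:
    21 unique PPARG changes, 6 cohort-recurrent, 2 more recurrent only
    after pooling external-database occurrences."""
    return bladder_narrative_variants()


@pytest.fixture(scope="session")
def domain_map():
    return pparg2_domain_map()


@pytest.fixture(scope="session")
def toy_dimer():
    """Two parallel poly-alanine helices with a 4 A closest gap plus the
    brute-force interface truth at 5 A."""
    return make_toy_heterodimer(n_residues_per_chain=20, inter_chain_gap=4.0,
                                seed=0, truth_cutoff=5.0)


@pytest.fixture(scope="session")
def sim_expression():
    """Synthetic log-expression matrix: 10 signature genes shifted +2 SD in
    the activation-high quarter of 200 samples."""
    spec = ExpressionSimSpec()
    return simulate_expression(spec, seed=42)
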