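import pytest

from topnet.pipeline import analyze
from topnet.synthetic import simulate_study


@pytest.fixture(scope="session")
def study():
    """The shipped synthetic study: 4 groups (5/5/5/2), planted 20-gene module
    with net log2FC = 2 in the RHD-vs-ARF contrast, HC decoy modules."""
    return simulate_study(seed=0)


@pytest.fixture(scope="session")
def study_result(study):
    """Full in-memory analysis of the shipped study under the default design."""
    return analyze(
        study.counts, study.network,
        gene_sets=study.gene_sets, clinical=study.clinical,
    )
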