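import pytest

from mcsurvey.dyad import load_default_reference
from mcsurvey.io_formats import DomainHit, load_default_annotations
from mcsurvey.simulate import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def reference():
    return load_default_reference()


@pytest.fixture(scope="session")
def annotations():
    return {a.domain_name: a for a in load_default_annotations()}


@pytest.fixture(scope="session")
def small_survey(tmp_path_factory):
    """One deterministic 60-genome synthetic survey shared across tests."""
    outdir = tmp_path_factory.mktemp("survey")
    files, truth = simulate_survey(SimulationConfig(seed=17, n_genomes=60), outdir)
    return files, truth


def make_hit(
    protein_id="p1",
    domain_name="Bac_PepC14",
    model_length=252,
    hmm_from=1,
    hmm_to=252,
    env_from=1,
    env_to=252,
    i_evalue=1e-20,
    score=150.0,
    bias=1.0,
):
    return DomainHit(
        protein_id=protein_id,
        domain_name=domain_name,
        model_length=model_length,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        env_from=env_from,
        env_to=env_to,
        i_evalue=i_evalue,
        score=score,
        bias=bias,
    )
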