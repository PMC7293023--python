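import pytest

from bioentity2vec.linkpred import DeepWalkParams, ExperimentConfig
from bioentity2vec.synthetic import SyntheticSpec, generate_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted fixture: 8 types x 50 nodes, 6 relations."""
    return generate_fixture(SyntheticSpec())


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        nodes_per_type={
            t: 20
            for t in (
                "protein", "mRNA", "miRNA", "lncRNA", "circRNA", "drug", "disease", "microbe",
            )
        },
        n_blocks=2,
        seq_lengths={"protein": 80, "mRNA": 120, "miRNA": 22, "lncRNA": 150, "circRNA": 100},
        fingerprint_bits=128,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_fixture(small_spec)


@pytest.fixture()
def fast_config():
    """Cheap protocol settings for shape/contract tests (not the stated
    evaluation defaults)."""
    return ExperimentConfig(
        seed=0, deepwalk=DeepWalkParams(gamma=2, t=20, epochs=2), rf_trees=25
    )
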