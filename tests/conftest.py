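import pytest

from hydrosom.corpus import build_atom_datasets, split_dataset
from hydrosom.models import train_dataset
from hydrosom.rules import default_rulebase
from hydrosom.synth import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()


@pytest.fixture(scope="session")
def small_corpus():
    """40-molecule synthetic corpus; ratio check off at this small n."""
    return generate_corpus(GeneratorConfig(n_molecules=40, seed=7, target_som_ratio=None))


@pytest.fixture(scope="session")
def small_datasets(small_corpus, rulebase):
    return build_atom_datasets(small_corpus.records, rulebase)


@pytest.fixture(scope="session")
def global_split(small_datasets):
    return split_dataset(
        small_datasets.tables["Global-Hydrolysis"], 0.8, seed=7,
        dataset_name="Global-Hydrolysis",
    )


@pytest.fixture(scope="session")
def mini_train(global_split):
    """Quick two-family training run shared by model/CLI-level tests."""
    return train_dataset(
        global_split, families=("dt", "lda"), folds=3, n_configs=3, seed=7
    )
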