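import pytest

from ragmerge import (
    TrainingConfig,
    TrainingSet,
    all_merges_upto,
    build_catalog,
    cross_validate,
    predict_all,
    train,
    training_vectors,
)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog(9)


@pytest.fixture(scope="session")
def merge_rows(catalog):
    return all_merges_upto(9, catalog)


@pytest.fixture(scope="session")
def training_set(catalog, merge_rows):
    return TrainingSet.from_vectors(training_vectors(catalog, merge_rows))


@pytest.fixture(scope="session")
def train_result(training_set):
    """One default-config training run shared across the suite."""
    return train(training_set, TrainingConfig())


@pytest.fixture(scope="session")
def classified_predictions(catalog, merge_rows, train_result):
    return predict_all(
        [7, 8, 9], train_result.params, catalog, merge_rows, which="classified"
    )


@pytest.fixture(scope="session")
def cv_report(training_set):
    return cross_validate(training_set, TrainingConfig())
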