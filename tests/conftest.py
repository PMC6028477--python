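import pytest

from rootmedia import ann
from rootmedia.media import load_formulations, load_reference_table, reference_ion_profiles
from rootmedia.modeling import prepare_dataset, train_response_model


@pytest.fixture(scope="session")
def formulations():
    return load_formulations()


@pytest.fixture(scope="session")
def reference_profiles():
    return reference_ion_profiles()


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def model_cache():
    """Memoized (bundle, model, fit_report) per (response, seed).

    Training is fast but many tests revisit the same configurations; caching
    keeps the suite quick without changing any result (everything is
    deterministic in (response, seed)).
    """
    cache = {}

    def get(response: str, seed: int):
        key = (response, seed)
        if key not in cache:
            bundle = prepare_dataset(response, seed=seed)
            model, report = train_response_model(bundle, ann.TrainingConfig(seed=seed + 2))
            cache[key] = (bundle, model, report)
        return cache[key]

    return get
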