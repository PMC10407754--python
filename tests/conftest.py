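import warnings

import pytest

import reproteome as rp

# small fixtures keep the default suite fast; statistical acceptance checks
# build their own study-scale data


@pytest.fixture(scope="session")
def small_params():
    return rp.SimulationParams(n_orthogroups=250, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rp.generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    from reproteome import pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_pipeline(dataset=small_dataset, config={"seed": 11})
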