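import numpy as np
import pytest

from serds import classify, pipeline, purifier, synthetic


@pytest.fixture(scope="session")
def library():
    return synthetic.build_class_library()


@pytest.fixture(scope="session")
def default_cohort():
    """Default 82-locus synthetic cohort, seed 0."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def trained_default():
    """Purifier trained at the default budget: 2000 pairs, 10 epochs."""
    return pipeline.train_default_purifier(n_pairs=2000, epochs=10, seed=0)


@pytest.fixture(scope="session")
def purifier_benchmark(trained_default):
    """Held-out synthetic benchmark shared across purifier tests."""
    return pipeline.benchmark_purifier(trained_default, n_test=150, seed=777)


@pytest.fixture(scope="session")
def purified_default_dataset(trained_default, default_cohort):
    spectra = pipeline.purify_cohort(trained_default, default_cohort)
    return classify.assemble_dataset(
        spectra, specimen_ids=[p.specimen_id for p in default_cohort])


def single_line_template(center=1004.0, fwhm=15.0, amplitude=1000.0, cv=0.0):
    """One isolated Lorentzian line; used by the SERDS physics tests."""
    return synthetic.ClassTemplate(
        "skin", peaks=(synthetic.RamanPeak(center, fwhm, amplitude, cv),))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
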