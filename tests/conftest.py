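import pytest

import grapearoma as ga


@pytest.fixture(scope="session")
def taxonomy():
    return ga.default_taxonomy()


@pytest.fixture(scope="session")
def library():
    return ga.default_compound_library()


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (seed 1): sample set + ground truth."""
    return ga.generate_cohort(ga.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(cohort):
    """Pipeline trained on the scored block of the default cohort."""
    sset, truth = cohort
    scores = truth.observed_scores.loc[truth.train_cultivars]
    return ga.train(sset, scores, ga.PipelineConfig(n_permutations=0, seed=1))


@pytest.fixture()
def tiny_library():
    """Three-compound panel with round thresholds for hand arithmetic."""
    return ga.CompoundLibrary(
        [
            ga.Compound("c1", "hexanal", "C6", 10.0, ("green", "grass")),
            ga.Compound("c2", "linalool", "terpene", 2.0, ("rose",)),
            ga.Compound("c3", "ethyl butyrate", "ester", 1.0, ("apple", "banana")),
        ]
    )
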