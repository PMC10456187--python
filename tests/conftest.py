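import numpy as np
import pytest

from aurevcorr import (
    MentalPrototype,
    ObserverModel,
    ResponseSet,
    StimulusCatalog,
    StimulusVector,
    TrialPair,
)


@pytest.fixture(scope="session")
def catalog16() -> StimulusCatalog:
    """The default 16-AU design catalog (3 AUs active per stimulus)."""
    return StimulusCatalog()


@pytest.fixture(scope="session")
def planted_prototype(catalog16) -> MentalPrototype:
    """A happy-style prototype: dominant lip-corner puller AU12, complementary
    cheek raiser AU6 and lip stretcher AU20."""
    return MentalPrototype(
        catalog=catalog16, dominant=12, complementary=frozenset({6, 20}), threshold=0.8
    )


@pytest.fixture(scope="session")
def noiseless_observer(planted_prototype) -> ObserverModel:
    return ObserverModel(true_prototype=planted_prototype, seed=0)


def make_random_responses(
    rng: np.random.Generator,
    n_aus: int = 6,
    max_trials: int = 20,
) -> ResponseSet:
    """A random small ResponseSet (arbitrary activation patterns, not
    necessarily k-active) for property tests."""
    catalog = StimulusCatalog(tuple(range(1, n_aus + 1)), k_active=0)
    m = int(rng.integers(1, max_trials + 1))
    trials = []
    for t in range(m):
        while True:
            left = tuple(int(b) for b in rng.integers(0, 2, n_aus))
            right = tuple(int(b) for b in rng.integers(0, 2, n_aus))
            if left != right:
                break
        choice = "left" if rng.random() < 0.5 else "right"
        trials.append(
            (
                TrialPair(t, StimulusVector(catalog, left), StimulusVector(catalog, right)),
                choice,
            )
        )
    return ResponseSet(trials, catalog=catalog)
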