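import warnings

import numpy as np
import pytest

from ssrsa.core_rdm import ConditionSet, RDM

# Small condition sets are deliberate at test scale; the coarse-null warning
# is itself covered by a dedicated test.
warnings.filterwarnings(
    "ignore", message="only .* conditions; permutation nulls will be coarse"
)


def conditions(n: int, prefix: str = "w") -> ConditionSet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ConditionSet([f"{prefix}{i}" for i in range(n)])


def random_rdm(n: int, rng: np.random.Generator) -> RDM:
    """A valid correlation-distance RDM from random response patterns."""
    from ssrsa.core_rdm import rdm_from_response_matrix

    return rdm_from_response_matrix(
        rng.standard_normal((n, max(8, n))), conditions(n)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cond5():
    return conditions(5)
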