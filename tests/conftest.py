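import numpy as np
import pytest

from covloc import CoverageMatrix, GeneratorParams, generate_instance


@pytest.fixture(scope="session")
def hampshire_like():
    """Default synthetic county: 278 sectors, 28 clinics, skewed demand."""
    return generate_instance(GeneratorParams())


@pytest.fixture
def gap_coverage():
    """Six unit-demand nodes where greedy (5) provably trails the optimum (6).

    s0 covers {0,1,2,3}, s1 covers {0,1,4}, s2 covers {2,3,5}: greedy opens
    s0 then s1 for 5 nodes, but {s1, s2} covers all 6.
    """
    a = np.zeros((6, 3), dtype=bool)
    a[[0, 1, 2, 3], 0] = True
    a[[0, 1, 4], 1] = True
    a[[2, 3, 5], 2] = True
    return CoverageMatrix(a=a, threshold_minutes=30.0, mode="car"), np.ones(6)


def random_coverage(rng, n_demand=40, n_sites=10, density=0.3,
                    integer_demand=True):
    """A random coverage matrix + demand vector for oracle cross-checks."""
    a = rng.random((n_demand, n_sites)) < density
    if integer_demand:
        h = rng.integers(1, 100, size=n_demand).astype(float)
    else:
        h = rng.uniform(0.5, 100.0, size=n_demand)
    return CoverageMatrix(a=a, threshold_minutes=1.0, mode="car"), h
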