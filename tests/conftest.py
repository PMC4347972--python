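import numpy as np
import pytest

from histonehmm import GenomeBins, SimulationSpec, ZinbParams


@pytest.fixture
def small_bins():
    """Two tiny chromosomes, 1 kb bins."""
    return GenomeBins(("chr1", "chr2"), (5000, 3000), 1000)


@pytest.fixture
def test_marginals():
    """A low-mean inflated and a high-mean clean ZINB, used across modules."""
    return ZinbParams(r=2.5, p=0.3, beta=0.1), ZinbParams(r=5.0, p=1 / 6, beta=0.0)


@pytest.fixture
def demo_spec():
    """The default demo world: 2 x 5000 bins, sticky 4-state chain."""
    return SimulationSpec(seed=7)


def brute_force_posteriors(log_b, transition, initial):
    """Exhaustive-path HMM oracle for tiny instances.

    Enumerates all K^T state paths, accumulates exact joint probabilities,
    and returns (gamma, loglik).  Independent of the package's scaled
    forward-backward recursion.
    """
    import itertools

    t_len, k = log_b.shape
    gamma = np.zeros((t_len, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=t_len):
        logp = np.log(initial[path[0]]) + log_b[0, path[0]]
        for t in range(1, t_len):
            logp += np.log(transition[path[t - 1], path[t]]) + log_b[t, path[t]]
        p = np.exp(logp)
        total += p
        for t, s in enumerate(path):
            gamma[t, s] += p
    return gamma / total, float(np.log(total))
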