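"""Seeded generators for binned ChIP-seq count tracks with known truth.

The generators emulate exactly the model's own assumptions: hidden states
follow a Markov chain along each chromosome (broad-domain persistence),
counts are drawn from the active state's ZINB, and in the bivariate case the
two samples' counts are coupled through a Gaussian copula — a bivariate
normal draw with the component's correlation is pushed through the normal
CDF and the ZINB count quantile function, which guarantees the stated ZINB
marginals in every state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedTrack, GenomeBins
from .copula import STATE_ORDER
from .zinb import UnivariateMixture, ZinbParams, zinb_ppf


@dataclass
class SimulationSpec:
    """Ground-truth description of a simulated experiment.

    The default demo world: 2 chromosomes of 5000 bins (1 kb each),
    self-transitions 0.95, an unmodified component with mean ~3 (10% zero
    inflation, as broad-mark background shows excess zeros) and a modified
    component with mean ~25, and copula correlation 0.5 within the
    concordant (both-unmodified / both-modified) states — sized so a full
    differential run finishes in well under a minute.
    """

    n_chromosomes: int = 2
    bins_per_chrom: int = 5000
    bin_size: int = 1000
    transition: np.ndarray | None = None  # (K, K); K=2 univariate, K=4 bivariate
    mixture_a: UnivariateMixture = field(
        default_factory=lambda: UnivariateMixture(
            alpha=0.7,
            theta0=ZinbParams(r=2.0, p=0.4, beta=0.1),   # mean ~2.7
            theta1=ZinbParams(r=5.0, p=1 / 6, beta=0.0),  # mean 25
        )
    )
    mixture_b: UnivariateMixture | None = None  # defaults to mixture_a
    # copula correlation per (a, b) pattern, in STATE_ORDER
    rho: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 0): 0.5, (1, 1): 0.5, (1, 0): 0.0, (0, 1): 0.0}
    )
    seed: int = 0

    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chrSim{i + 1}": self.bins_per_chrom * self.bin_size
            for i in range(self.n_chromosomes)
        }

    def genome_bins(self) -> GenomeBins:
        sizes = self.chrom_sizes()
        return GenomeBins(tuple(sizes), tuple(sizes.values()), self.bin_size)

    def _transition(self, k: int) -> np.ndarray:
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (k, k):
                raise ValueError(f"transition must be {k}x{k}")
            if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError("transition rows must be probability vectors")
            return t
        self_p = 0.95
        off = (1 - self_p) / (k - 1)
        return np.full((k, k), off) + np.eye(k) * (self_p - off)


def _sample_markov_states(
    rng: np.random.Generator, transition: np.ndarray, n: int
) -> np.ndarray:
    k = transition.shape[0]
    # start from the chain's stationary distribution
    evals, evecs = np.linalg.eig(transition.T)
    stat = np.real(evecs[:, np.argmax(np.real(evals))])
    stat = np.abs(stat) / np.abs(stat).sum()
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(k, p=stat)
    cum = transition.cumsum(axis=1)
    u = rng.random(n)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def _zinb_draw(rng: np.random.Generator, n: int, th: ZinbParams) -> np.ndarray:
    counts = rng.negative_binomial(th.r, th.p, size=n)
    if th.beta > 0:
        counts[rng.random(n) < th.beta] = 0
    return counts


def simulate_univariate(spec: SimulationSpec) -> tuple[BinnedTrack, np.ndarray]:
    """Simulate one sample: Markov states, per-state ZINB counts.

    Returns the track and the true per-bin state labels (0 unmodified,
    1 modified), concatenated across chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    transition = spec._transition(2)
    bins = spec.genome_bins()
    states = np.concatenate(
        [
            _sample_markov_states(rng, transition, spec.bins_per_chrom)
            for _ in range(spec.n_chromosomes)
        ]
    )
    counts = np.empty(len(states), dtype=np.int64)
    for j in range(2):
        mask = states == j
        counts[mask] = _zinb_draw(rng, int(mask.sum()), spec.mixture_a.component(j))
    return BinnedTrack(bins, counts, sample_id="simA"), states


def simulate_bivariate(
    spec: SimulationSpec,
) -> tuple[BinnedTrack, BinnedTrack, np.ndarray]:
    """Simulate a sample pair coupled by a Gaussian copula.

    Hidden 4-way states (indexing STATE_ORDER: unmod-both, mod-both,
    A-only, B-only) follow a Markov chain per chromosome; within a state a
    bivariate normal draw with the state's correlation is mapped through
    Phi and each sample's ZINB quantile function.  Returns both tracks and
    the true per-bin state indices.
    """
    from scipy.special import ndtr

    for ab, r in spec.rho.items():
        if abs(r) >= 1:
            raise ValueError(f"|rho| must be < 1, got {r} for pattern {ab}")
    rng = np.random.default_rng(spec.seed)
    transition = spec._transition(4)
    bins = spec.genome_bins()
    mix_a = spec.mixture_a
    mix_b = spec.mixture_b if spec.mixture_b is not None else spec.mixture_a
    states = np.concatenate(
        [
            _sample_markov_states(rng, transition, spec.bins_per_chrom)
            for _ in range(spec.n_chromosomes)
        ]
    )
    n = len(states)
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    for s, (a, b) in enumerate(STATE_ORDER):
        mask = states == s
        m = int(mask.sum())
        if m == 0:
            continue
        rho = spec.rho.get((a, b), 0.0)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=m)
        # clip to keep the count quantile finite at u == 1.0 (z beyond ~8)
        u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
        x[mask] = zinb_ppf(u[:, 0], mix_a.component(a)).astype(np.int64)
        y[mask] = zinb_ppf(u[:, 1], mix_b.component(b)).astype(np.int64)
    track_a = BinnedTrack(bins, x, sample_id="simA")
    track_b = BinnedTrack(bins, y, sample_id="simB")
    return track_a, track_b, states
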