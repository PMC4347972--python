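"""Generic K-state hidden Markov machinery with fixed emission densities.

The emission distributions are frozen from an upstream mixture fit and never
re-estimated; Baum-Welch updates only the transition matrix and the initial
distribution.  Chromosomes are independent sequences: the forward-backward
recursion restarts at every chromosome start, expected transition counts are
pooled into one shared transition matrix, and the total log-likelihood is
the sum over chromosomes.  All recursions use per-position scaling to avoid
underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .binning import GenomeBins

logger = logging.getLogger(__name__)

# an emission handle maps a per-chromosome observation array (T,) or (T, d)
# to a length-T vector of log densities
EmissionHandle = Callable[[np.ndarray], np.ndarray]


@dataclass
class HmmModel:
    """HMM with fixed per-state emission log-density callables."""

    transition: np.ndarray
    initial: np.ndarray
    emission_handles: Sequence[EmissionHandle]

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        k = len(self.emission_handles)
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape does not match state count")
        if self.initial.shape != (k,):
            raise ValueError("initial distribution length does not match state count")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.emission_handles)

    def log_emission_matrix(self, obs: np.ndarray) -> np.ndarray:
        """(T, K) matrix of per-state emission log densities for one sequence."""
        cols = [np.asarray(h(obs), dtype=float) for h in self.emission_handles]
        return np.stack(cols, axis=1)


def uniform_initial(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def sticky_transition(k: int, self_prob: float = 0.9) -> np.ndarray:
    """Diagonal-heavy transition start reflecting broad-domain persistence."""
    off = (1.0 - self_prob) / (k - 1) if k > 1 else 0.0
    return np.full((k, k), off) + np.eye(k) * (self_prob - off)


@dataclass
class PosteriorTrack:
    """Per-bin latent-state posteriors from the forward-backward algorithm."""

    gamma: np.ndarray  # (n_bins, K), rows sum to 1
    loglik: float
    genome_bins: GenomeBins | None = None
    seq_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2:
            raise ValueError("gamma must be (n_bins, K)")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.gamma.shape[1]

    def state_posterior(self, state: int) -> np.ndarray:
        return self.gamma[:, state]


def _forward_backward_single(
    log_b: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Scaled forward-backward for one sequence.

    Returns (gamma, loglik, xi_sum) where xi_sum[i, j] is the expected
    number of i -> j transitions in the sequence.
    """
    t_len, k = log_b.shape
    # per-row max-shift keeps the scaled recursion in range even for very
    # unlikely observations
    shift = log_b.max(axis=1, keepdims=True)
    if np.any(~np.isfinite(shift)):
        bad = int(np.argmax(~np.isfinite(shift.ravel())))
        raise ValueError(
            f"observation at position {bad} has -inf log-density in all states"
        )
    b = np.exp(log_b - shift)

    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    a = initial * b[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ transition) * b[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # expected transition counts: xi_t(i,j) = alpha_t(i) A_ij b_{t+1}(j)
    # beta_{t+1}(j) / scale_{t+1}, summed over t
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 1):
        xi_sum += np.outer(alpha[t], (b[t + 1] * beta[t + 1]) / scale[t + 1])
    xi_sum *= transition

    loglik = float(np.log(scale).sum() + shift.sum())
    return gamma, loglik, xi_sum


def _as_sequences(obs) -> list[np.ndarray]:
    if isinstance(obs, np.ndarray):
        return [obs]
    return [np.asarray(o) for o in obs]


def forward_backward(
    obs, model: HmmModel, genome_bins: GenomeBins | None = None
) -> PosteriorTrack:
    """Posterior state probabilities for one or more observation sequences.

    ``obs`` is a single array or a list of per-chromosome arrays; each
    sequence restarts from the initial distribution, and ``loglik`` sums over
    sequences.
    """
    seqs = _as_sequences(obs)
    gammas, lls = [], []
    for seq in seqs:
        log_b = model.log_emission_matrix(seq)
        g, ll, _ = _forward_backward_single(log_b, model.transition, model.initial)
        gammas.append(g)
        lls.append(ll)
    return PosteriorTrack(
        gamma=np.concatenate(gammas, axis=0),
        loglik=float(sum(lls)),
        genome_bins=genome_bins,
        seq_lengths=tuple(len(s) for s in seqs),
    )


def baum_welch(
    obs,
    model: HmmModel,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[HmmModel, list[float]]:
    """Estimate transition matrix and initial distribution by Baum-Welch.

    Emission densities stay fixed.  Expected transition counts are pooled
    across sequences into one shared matrix; the initial distribution is
    re-estimated from expected sequence-start occupancies.  Returns the
    updated model and the per-iteration log-likelihood trace.
    """
    seqs = _as_sequences(obs)
    log_bs = [model.log_emission_matrix(seq) for seq in seqs]
    k = model.n_states
    transition = model.transition.copy()
    initial = model.initial.copy()
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        xi_total = np.zeros((k, k))
        start_occ = np.zeros(k)
        ll_total = 0.0
        for log_b in log_bs:
            gamma, ll, xi = _forward_backward_single(log_b, transition, initial)
            xi_total += xi
            start_occ += gamma[0]
            ll_total += ll
        trace.append(ll_total)

        row_sums = xi_total.sum(axis=1)
        new_transition = transition.copy()
        for i in range(k):
            if row_sums[i] > 0:
                new_transition[i] = xi_total[i] / row_sums[i]
            else:
                logger.warning(
                    "state %d has zero expected occupancy; transition row kept", i
                )
        transition = new_transition
        initial = start_occ / start_occ.sum()

        if np.isfinite(prev_ll) and abs(ll_total - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll_total

    fitted = HmmModel(transition, initial, model.emission_handles)
    return fitted, trace


def decode(posterior: PosteriorTrack, rule="max") -> np.ndarray:
    """Per-bin state labels from posteriors.

    ``rule="max"`` takes the argmax state (ties to the lower index).
    ``rule=("threshold", lam, s)`` labels a bin as state ``s`` when its
    posterior exceeds ``lam``; in a 2-state model the complementary label is
    the other state, otherwise the argmax among the remaining states.
    """
    gamma = posterior.gamma
    if isinstance(rule, str):
        if rule != "max":
            raise ValueError(f"unknown decode rule {rule!r}")
        return np.argmax(gamma, axis=1)
    kind, lam, state = rule
    if kind != "threshold":
        raise ValueError(f"unknown decode rule {kind!r}")
    if not 0 <= lam < 1:
        raise ValueError(f"threshold lambda must be in [0,1), got {lam}")
    others = [s for s in range(posterior.n_states) if s != state]
    fallback = np.asarray(others)[np.argmax(gamma[:, others], axis=1)]
    return np.where(gamma[:, state] > lam, state, fallback)
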