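"""Gaussian-copula bivariate emissions for the 4-state differential HMM.

Two samples' counts (x, y) in a bin are coupled by mapping each through its
ZINB marginal CDF and the standard-normal quantile function (probability
integral transform, PIT) and giving the resulting scores a bivariate normal
law.  Because the margins are discrete, the joint pmf of a count pair is the
bivariate-normal measure of the rectangle between consecutive transformed
CDF values:

    P(X=x, Y=y) = Phi2(z_x(x), z_y(y)) - Phi2(z_x(x-1), z_y(y))
                  - Phi2(z_x(x), z_y(y-1)) + Phi2(z_x(x-1), z_y(y-1)),

with z(x) = Phi^-1(F(x)) and F(-1) = 0 mapping to a -inf bound.  One such
component exists for each of the four (a, b) modification patterns; its
covariance is estimated from the PIT scores of bins called confidently in
both samples by the univariate HMMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .binning import BinnedTrack
from .hmm import PosteriorTrack
from .zinb import PMF_FLOOR, UnivariateMixture, ZinbParams, zinb_cdf

logger = logging.getLogger(__name__)

CDF_CLIP = 1e-12  # keep PIT scores finite at the tails

# state order of the differential HMM: (a, b) = (A modified, B modified)
STATE_ORDER: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (1, 0), (0, 1))
STATE_LABELS: tuple[str, ...] = ("unmod-both", "mod-both", "mod-A-only", "mod-B-only")


def pit_transform(x, marginal: ZinbParams):
    """Standard-normal score of a count under its ZINB marginal.

    Returns Phi^-1(F(x)); CDF values are clipped into [1e-12, 1 - 1e-12]
    so scores stay finite.
    """
    u = np.clip(zinb_cdf(x, marginal), CDF_CLIP, 1.0 - CDF_CLIP)
    out = ndtri(u)
    return out if np.ndim(out) else float(out)


def _boundary_scores(max_count: int, marginal: ZinbParams) -> np.ndarray:
    """z(x) = Phi^-1(F(x)) for x = -1..max_count; z(-1) is exactly -inf."""
    x = np.arange(-1, max_count + 1)
    u = zinb_cdf(x, marginal)
    u = np.clip(u, 0.0, 1.0 - CDF_CLIP)
    with np.errstate(divide="ignore"):
        z = ndtri(u)
    z[0] = -np.inf
    return z


@dataclass
class CopulaComponent:
    """One bivariate emission component for modification pattern (a, b)."""

    a: int
    b: int
    marginal_x: ZinbParams
    marginal_y: ZinbParams
    sigma: np.ndarray
    n_support: int = 0
    _pmf_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (2, 2):
            raise ValueError("sigma must be 2x2")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ValueError("sigma must be positive definite")
        if abs(self.rho) >= 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")

    @property
    def rho(self) -> float:
        s = self.sigma
        return float(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))

    def _pmf_table(self, max_x: int, max_y: int) -> np.ndarray:
        """Dense (max_x+1, max_y+1) table of rectangle probabilities.

        The PIT margins are standard normal by construction, so sigma is
        rescaled to its correlation before CDF evaluation; sigma's scales
        only reflect estimation noise.
        """
        key = (max_x, max_y)
        cached = self._pmf_cache.get(key)
        if cached is not None:
            return cached
        zx = _boundary_scores(max_x, self.marginal_x)
        zy = _boundary_scores(max_y, self.marginal_y)
        rho = self.rho
        if abs(rho) < 1e-14:
            # independence: CDF factorises exactly into normal marginals
            cdf = np.where(np.isneginf(zx), 0.0, ndtr(zx))[:, None] * np.where(
                np.isneginf(zy), 0.0, ndtr(zy)
            )[None, :]
        else:
            cdf = np.zeros((len(zx), len(zy)))
            fin_x, fin_y = ~np.isneginf(zx), ~np.isneginf(zy)
            gx, gy = np.meshgrid(zx[fin_x], zy[fin_y], indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            mvn = multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
            cdf[np.ix_(fin_x, fin_y)] = np.asarray(mvn.cdf(pts)).reshape(gx.shape)
        pmf = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        pmf = np.maximum(pmf, 0.0)
        self._pmf_cache.clear()  # keep only the largest table
        self._pmf_cache[key] = pmf
        return pmf


def bivariate_log_pmf(x, y, component: CopulaComponent):
    """log P(X=x, Y=y) under one copula component; floored at log(1e-300).

    Vectorised over equal-shaped integer arrays; per-component tables of
    rectangle probabilities are memoized since counts are small integers
    repeated genome-wide.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    table = component._pmf_table(int(x.max()), int(y.max()))
    out = np.log(np.maximum(table[x, y], PMF_FLOOR))
    return out if out.ndim else float(out)


@dataclass
class BivariateMixture:
    """Four copula components indexed by modification pattern (a, b)."""

    components: dict[tuple[int, int], CopulaComponent]
    gamma_ab: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        if set(self.components) != set(STATE_ORDER):
            raise ValueError("need exactly the four (a, b) components")
        tot = sum(self.gamma_ab.values())
        if not np.isclose(tot, 1.0, atol=1e-9):
            raise ValueError(f"mixing weights must sum to 1, got {tot}")

    def component_list(self) -> list[CopulaComponent]:
        """Components in HMM state order (unmod-both, mod-both, A-only, B-only)."""
        return [self.components[ab] for ab in STATE_ORDER]


def estimate_component_covariance(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    post_a: PosteriorTrack,
    post_b: PosteriorTrack,
    mix_a: UnivariateMixture,
    mix_b: UnivariateMixture,
    confidence: float = 0.9,
    min_support: int = 50,
) -> BivariateMixture:
    """Estimate the four copula components from high-confidence univariate calls.

    For each pattern (a, b), bins with univariate posterior above
    ``confidence`` for state a in sample A and state b in sample B are PIT
    transformed with the matching marginals, and sigma is their sample
    covariance.  Patterns supported by fewer than ``min_support`` bins fall
    back to the identity covariance.  The mixing weights gamma_ab are the
    high-confidence bin fractions and serve as a diagnostic only; the HMM's
    transitions supersede them.
    """
    if track_a.genome_bins != track_b.genome_bins:
        raise ValueError("tracks must share the same GenomeBins")
    xa, yb = track_a.counts, track_b.counts
    components: dict[tuple[int, int], CopulaComponent] = {}
    n_sel: dict[tuple[int, int], int] = {}
    for a, b in STATE_ORDER:
        sel = (post_a.gamma[:, a] > confidence) & (post_b.gamma[:, b] > confidence)
        n = int(sel.sum())
        n_sel[(a, b)] = n
        marg_x = mix_a.component(a)
        marg_y = mix_b.component(b)
        if n >= min_support:
            z = np.column_stack(
                [pit_transform(xa[sel], marg_x), pit_transform(yb[sel], marg_y)]
            )
            sigma = np.cov(z, rowvar=False)
            if np.any(np.linalg.eigvalsh(sigma) <= 1e-12) or abs(
                sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
            ) >= 1 - 1e-9:
                logger.warning(
                    "pattern (%d,%d): near-singular covariance, shrinking", a, b
                )
                sigma = 0.99 * sigma + 0.01 * np.eye(2) * np.diag(sigma).mean()
        else:
            logger.warning(
                "pattern (%d,%d): only %d high-confidence bins (< %d); "
                "falling back to identity covariance",
                a, b, n, min_support,
            )
            sigma = np.eye(2)
        components[(a, b)] = CopulaComponent(a, b, marg_x, marg_y, sigma, n_support=n)

    total = sum(n_sel.values())
    if total == 0:
        raise ValueError(
            "no high-confidence support in any pattern; lower the confidence threshold"
        )
    gamma_ab = {ab: n_sel[ab] / total for ab in STATE_ORDER}
    return BivariateMixture(components, gamma_ab)
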