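"""Zero-inflated negative binomial (ZINB) mixture for binned ChIP-seq counts.

A single sample's bin counts are modelled as a two-component mixture

    P(x) = alpha * f(x; theta0) + (1 - alpha) * f(x; theta1)

where each component density is a ZINB

    f(x; r, p, beta) = beta * I[x = 0]
                       + (1 - beta) * Gamma(r + x) / (Gamma(r) x!) * p^r (1-p)^x.

Component 0 carries the low-occupancy (unmodified) mass, component 1 the
heavy modified tail; the mean ordering mu0 < mu1 is enforced after fitting.
Parameters are estimated by EM with a deterministic median-split start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy

PMF_FLOOR = 1e-300  # floor before logs, avoids -inf in HMM recursions


@dataclass(frozen=True)
class ZinbParams:
    """Parameters of one zero-inflated negative binomial component.

    ``r`` is the NB dispersion (> 0), ``p`` the NB success probability in
    (0, 1) so the NB mean is r(1-p)/p, and ``beta`` the extra point mass at
    zero in [0, 1).
    """

    r: float
    p: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"dispersion r must be > 0, got {self.r}")
        if not 0 < self.p < 1:
            raise ValueError(f"success probability p must be in (0,1), got {self.p}")
        if not 0 <= self.beta < 1:
            raise ValueError(f"zero inflation beta must be in [0,1), got {self.beta}")

    @property
    def mean(self) -> float:
        return (1.0 - self.beta) * self.r * (1.0 - self.p) / self.p


def zinb_pmf(x, params: ZinbParams):
    """ZINB probability mass at integer count(s) x (NB factor in log space)."""
    x = np.asarray(x)
    nb = stats.nbinom.pmf(x, params.r, params.p)
    out = np.where(x == 0, params.beta + (1 - params.beta) * nb,
                   (1 - params.beta) * nb)
    out = np.where(x < 0, 0.0, out)
    return out if out.ndim else float(out)


def zinb_logpmf(x, params: ZinbParams):
    """log ZINB pmf, floored at log(1e-300)."""
    return np.log(np.maximum(zinb_pmf(x, params), PMF_FLOOR))


def zinb_cdf(x, params: ZinbParams):
    """P(X <= x); zero below the support, -> 1 as x -> inf."""
    x = np.asarray(np.floor(x))
    nb = stats.nbinom.cdf(x, params.r, params.p)
    out = np.where(x < 0, 0.0, params.beta + (1 - params.beta) * nb)
    return out if out.ndim else float(out)


def zinb_ppf(q, params: ZinbParams):
    """Count quantile function: smallest x with F(x) >= q.

    Inverts the inflation-adjusted NB CDF exactly: F(x) >= q iff
    F_nb(x) >= (q - beta) / (1 - beta).
    """
    q = np.asarray(q, dtype=float)
    qa = np.clip((q - params.beta) / (1.0 - params.beta), 0.0, 1.0)
    out = np.maximum(stats.nbinom.ppf(qa, params.r, params.p), 0.0)
    return out if out.ndim else float(out)


@dataclass
class UnivariateMixture:
    """Fitted two-component ZINB mixture for one sample."""

    alpha: float
    theta0: ZinbParams
    theta1: ZinbParams
    loglik_trace: list[float] = field(default_factory=list)
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"mixing weight alpha must be in (0,1), got {self.alpha}")

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")

    def component(self, state: int) -> ZinbParams:
        return self.theta1 if state else self.theta0

    def mixture_pmf(self, x):
        return self.alpha * zinb_pmf(x, self.theta0) + (1 - self.alpha) * zinb_pmf(
            x, self.theta1
        )


def posterior_component(x, mixture: UnivariateMixture):
    """P(component = 1 | x), the static responsibility of the modified part."""
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(x)
    d0 = mixture.alpha * zinb_pmf(x, mixture.theta0)
    d1 = (1 - mixture.alpha) * zinb_pmf(x, mixture.theta1)
    tot = d0 + d1
    if np.any(tot <= 0):
        raise ValueError("total mixture density is zero at some x")
    out = d1 / tot
    return float(out[0]) if scalar else out


def _fit_weighted_nb(vals: np.ndarray, weights: np.ndarray,
                     r_bounds=(1e-3, 1e4)) -> tuple[float, float]:
    """Weighted NB maximum likelihood via the profile likelihood in r.

    With p profiled out at its conditional MLE p = r / (r + mean), the
    1-D profile log-likelihood in r is maximised numerically on a log scale.
    """
    wsum = weights.sum()
    if wsum <= 0:
        raise RuntimeError("NB M-step received zero total weight")
    mean = float((weights * vals).sum() / wsum)
    if mean <= 0:
        # all NB-attributed mass at zero; dispersion unidentifiable
        raise RuntimeError("NB M-step mean is zero; component degenerate")

    def neg_profile(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mean)
        return -float((weights * stats.nbinom.logpmf(vals, r, p)).sum())

    res = optimize.minimize_scalar(
        neg_profile, bounds=np.log(r_bounds), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"NB profile-likelihood solve failed: {res.message}")
    r = float(np.exp(res.x))
    return r, r / (r + mean)


def fit_mixture_em(
    counts,
    max_iter: int = 500,
    tol: float = 1e-6,
    sample_id: str = "sample",
) -> UnivariateMixture:
    """Fit the two-component ZINB mixture by EM.

    Starting responsibilities come from a median split: counts at or below
    the median get responsibility 0.9 for component 0 (0.1 for component 1)
    and vice versa above the median, followed by an ordinary M-step.  Each
    E-step also splits the x = 0 responsibility within a component between
    the inflation point mass and the NB zero (a three-way latent split),
    which is required for a consistent beta update.  Iterates until the
    relative log-likelihood change drops below ``tol``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
    vals, mult = np.unique(counts, return_counts=True)
    if len(vals) < 2:
        raise ValueError("degenerate input, cannot fit two components")
    mult = mult.astype(float)
    n = mult.sum()
    zero = vals == 0  # boolean mask of the x=0 cell (at most one True)

    # median-split start: ties at the median go to the lower group
    med = np.median(counts)
    resp1 = np.where(vals <= med, 0.1, 0.9)  # responsibility of component 1
    resp = np.stack([1.0 - resp1, resp1])  # (2, n_vals)
    # provisional inner split of the zero cell (no beta estimate yet)
    usplit = np.full(2, 0.5)

    alpha = 0.5
    thetas: list[ZinbParams] = [ZinbParams(1.0, 0.5), ZinbParams(1.0, 0.5)]
    trace: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        # ----- M-step -----
        new_thetas = []
        weights01 = []
        for j in range(2):
            w = resp[j] * mult
            nj = w.sum()
            weights01.append(nj)
            beta = float((w[zero] * usplit[j]).sum() / nj) if zero.any() else 0.0
            beta = min(max(beta, 0.0), 1.0 - 1e-12)
            w_nb = w.copy()
            if zero.any():
                w_nb[zero] *= 1.0 - usplit[j]
            try:
                r, p = _fit_weighted_nb(vals, w_nb)
            except RuntimeError as err:
                raise RuntimeError(f"M-step failed at iteration {it}: {err}") from err
            new_thetas.append(ZinbParams(r, p, beta))
        thetas = new_thetas
        alpha = float(weights01[0] / n)
        alpha = min(max(alpha, 1e-12), 1 - 1e-12)

        # ----- E-step -----
        dens = np.stack(
            [np.maximum(zinb_pmf(vals, thetas[j]), PMF_FLOOR) for j in range(2)]
        )
        wd = np.stack([alpha * dens[0], (1 - alpha) * dens[1]])
        tot = wd.sum(axis=0)
        resp = wd / tot
        # inner split of x=0 between inflation and the NB zero, per component
        for j in range(2):
            b, th = thetas[j].beta, thetas[j]
            p_nb0 = (1 - b) * stats.nbinom.pmf(0, th.r, th.p)
            usplit[j] = b / (b + p_nb0) if (b + p_nb0) > 0 else 0.0

        ll = float((mult * np.log(tot)).sum())
        trace.append(ll)
        if it > 0 and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll

    if thetas[0].mean > thetas[1].mean:
        thetas = thetas[::-1]
        alpha = 1.0 - alpha
    alpha, theta0, theta1 = _canonicalize_zero_mass(alpha, thetas[0], thetas[1])
    return UnivariateMixture(alpha, theta0, theta1, trace, sample_id=sample_id)


def _canonicalize_zero_mass(
    alpha: float, theta0: ZinbParams, theta1: ZinbParams
) -> tuple[float, ZinbParams, ZinbParams]:
    """Resolve the zero-inflation ridge by attributing it to component 0.

    The mixture likelihood depends on the inflation weights only through the
    total point mass at zero, pi0 = alpha*beta0 + (1-alpha)*beta1: moving
    point mass between the components' inflation terms (with the matching
    adjustment of alpha) leaves the likelihood exactly unchanged, so the
    split is unidentifiable from data.  The canonical representative assigns
    the whole point mass to the low-mean (unmodified) component, where excess
    zeros belong scientifically, forcing beta1 = 0.  NB shape parameters are
    ridge-invariant and untouched.
    """
    w0 = alpha * (1.0 - theta0.beta)  # identified NB weight of component 0
    w1 = (1.0 - alpha) * (1.0 - theta1.beta)
    pi0 = max(1.0 - w0 - w1, 0.0)
    new_alpha = min(max(w0 + pi0, 1e-12), 1 - 1e-12)
    beta0 = min(pi0 / new_alpha, 1.0 - 1e-12) if new_alpha > 0 else 0.0
    return (
        new_alpha,
        ZinbParams(theta0.r, theta0.p, beta0),
        ZinbParams(theta1.r, theta1.p, 0.0),
    )


def save_mixture(mix: UnivariateMixture, path: str | Path) -> None:
    """Serialize a fitted mixture to a plain-text key-value parameter file."""
    lines = [
        f"sample_id\t{mix.sample_id}",
        f"alpha\t{mix.alpha!r}",
        f"r0\t{mix.theta0.r!r}",
        f"p0\t{mix.theta0.p!r}",
        f"beta0\t{mix.theta0.beta!r}",
        f"r1\t{mix.theta1.r!r}",
        f"p1\t{mix.theta1.p!r}",
        f"beta1\t{mix.theta1.beta!r}",
        f"loglik\t{mix.loglik!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mixture(path: str | Path) -> UnivariateMixture:
    kv = dict(
        line.split("\t", 1) for line in Path(path).read_text().splitlines() if line
    )
    mix = UnivariateMixture(
        alpha=float(kv["alpha"]),
        theta0=ZinbParams(float(kv["r0"]), float(kv["p0"]), float(kv["beta0"])),
        theta1=ZinbParams(float(kv["r1"]), float(kv["p1"]), float(kv["beta1"])),
        loglik_trace=[float(kv["loglik"])] if kv.get("loglik") not in (None, "nan") else [],
        sample_id=kv.get("sample_id", "sample"),
    )
    return mix
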