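"""End-to-end single-sample and differential calling pipelines.

Single sample: fit the 2-component ZINB mixture on one training chromosome,
freeze its components as the emissions of a 2-state HMM, estimate
transitions by Baum-Welch, compute genome-wide posteriors by
forward-backward, and call a bin modified when P(modified) exceeds the
threshold lambda (default 0.5, the maximal-probability rule in a 2-state
model).

Differential: run the univariate machinery on both samples, estimate the
four Gaussian-copula components from bins called confidently in both, build
the 4-state HMM (both-unmodified, both-modified, A-only, B-only) with those
fixed bivariate emissions, and classify every bin by its maximal posterior.
Differential regions are the A-only and B-only runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .binning import BinnedTrack, GenomeBins, truncate_counts
from .copula import (
    STATE_LABELS,
    STATE_ORDER,
    BivariateMixture,
    CopulaComponent,
    bivariate_log_pmf,
    estimate_component_covariance,
)
from .hmm import (
    HmmModel,
    PosteriorTrack,
    baum_welch,
    decode,
    forward_backward,
    sticky_transition,
    uniform_initial,
)
from .zinb import UnivariateMixture, fit_mixture_em, zinb_logpmf

logger = logging.getLogger(__name__)

UNIVARIATE_LABELS = ("unmodified", "modified")


@dataclass
class CallingConfig:
    """Tunable parameters of the calling pipelines.

    ``lambda_threshold`` is the posterior cutoff for calling a bin modified
    in the 2-state model; ``confidence`` the stricter cutoff selecting bins
    that anchor the copula covariance estimates; ``train_chrom`` the single
    chromosome used for the mixture fit (largest present when None — the
    fit needs only enough bins to pin down six parameters).
    """

    bin_size: int = 1000
    lambda_threshold: float = 0.5
    confidence: float = 0.9
    train_chrom: str | None = None
    truncation_quantile: float = 0.999
    em_max_iter: int = 500
    em_tol: float = 1e-6
    bw_max_iter: int = 100
    bw_tol: float = 1e-6
    min_support: int = 50
    min_bins: int = 0  # minimum region length filter, in bins (0 = keep all)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_threshold < 1:
            raise ValueError("lambda_threshold must be in [0, 1)")
        if not self.lambda_threshold < self.confidence < 1:
            raise ValueError("confidence must be in (lambda_threshold, 1)")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of same-state bins, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    state: str
    mean_posterior: float
    max_posterior: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


def assemble_regions(
    labels: np.ndarray,
    genome_bins: GenomeBins,
    posterior: PosteriorTrack,
    state_names=None,
) -> list[RegionCall]:
    """Merge per-bin labels into maximal same-state regions per chromosome.

    Each region's mean/max posterior summarise its own state's per-bin
    probabilities; runs never extend across a chromosome boundary, and the
    returned regions partition the binned genome.
    """
    labels = np.asarray(labels)
    if len(labels) != genome_bins.n_bins:
        raise ValueError(
            f"got {len(labels)} labels for {genome_bins.n_bins} bins"
        )
    if state_names is None:
        k = posterior.n_states
        state_names = UNIVARIATE_LABELS if k == 2 else STATE_LABELS[:k]
    regions: list[RegionCall] = []
    for chrom, length in zip(genome_bins.chrom_names, genome_bins.chrom_lengths):
        sl = genome_bins.chrom_slice(chrom)
        lab = labels[sl]
        gam = posterior.gamma[sl]
        bs = genome_bins.bin_size
        run_start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[run_start]:
                s = int(lab[run_start])
                post = gam[run_start:i, s]
                regions.append(
                    RegionCall(
                        chrom=chrom,
                        start=run_start * bs,
                        end=min(i * bs, length),
                        state=state_names[s],
                        mean_posterior=float(post.mean()),
                        max_posterior=float(post.max()),
                        n_bins=i - run_start,
                    )
                )
                run_start = i
    return regions


def _training_counts(track: BinnedTrack, config: CallingConfig) -> np.ndarray:
    chrom = config.train_chrom or track.genome_bins.largest_chrom
    return track.chrom_counts(chrom)


def _univariate_model(mix: UnivariateMixture) -> HmmModel:
    handles = [
        lambda obs, th=mix.theta0: zinb_logpmf(obs, th),
        lambda obs, th=mix.theta1: zinb_logpmf(obs, th),
    ]
    return HmmModel(sticky_transition(2), uniform_initial(2), handles)


def call_single(
    track: BinnedTrack, config: CallingConfig | None = None
) -> tuple[UnivariateMixture, HmmModel, PosteriorTrack, list[RegionCall]]:
    """Segment one sample into modified / unmodified regions."""
    config = config or CallingConfig()
    if track.genome_bins.n_bins == 0:
        raise ValueError("empty genome")
    try:
        mix = fit_mixture_em(
            _training_counts(track, config),
            max_iter=config.em_max_iter,
            tol=config.em_tol,
            sample_id=track.sample_id,
        )
    except ValueError as err:
        raise ValueError(
            f"mixture fit failed for sample {track.sample_id!r}: {err}"
        ) from err
    model, _ = baum_welch(
        track.per_chrom(),
        _univariate_model(mix),
        max_iter=config.bw_max_iter,
        tol=config.bw_tol,
    )
    posterior = forward_backward(track.per_chrom(), model, track.genome_bins)
    labels = decode(posterior, ("threshold", config.lambda_threshold, 1))
    regions = assemble_regions(labels, track.genome_bins, posterior)
    if config.min_bins > 1:
        regions = [r for r in regions if r.n_bins >= config.min_bins]
    return mix, model, posterior, regions


def _bivariate_model(bmix: BivariateMixture) -> HmmModel:
    handles = [
        lambda obs, c=comp: bivariate_log_pmf(obs[:, 0], obs[:, 1], c)
        for comp in bmix.component_list()
    ]
    return HmmModel(sticky_transition(4), uniform_initial(4), handles)


def call_differential(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    config: CallingConfig | None = None,
) -> tuple[BivariateMixture, HmmModel, PosteriorTrack, list[RegionCall]]:
    """Classify every bin of a sample pair into the four modification patterns."""
    config = config or CallingConfig()
    if track_a.genome_bins != track_b.genome_bins:
        raise ValueError("both samples must share the same GenomeBins")
    mix_a, _, post_a, _ = call_single(track_a, config)
    mix_b, _, post_b, _ = call_single(track_b, config)
    bmix = estimate_component_covariance(
        track_a, track_b, post_a, post_b, mix_a, mix_b,
        confidence=config.confidence, min_support=config.min_support,
    )
    obs = [
        np.column_stack([track_a.chrom_counts(c), track_b.chrom_counts(c)])
        for c in track_a.genome_bins.chrom_names
    ]
    model, _ = baum_welch(
        obs, _bivariate_model(bmix),
        max_iter=config.bw_max_iter, tol=config.bw_tol,
    )
    posterior = forward_backward(obs, model, track_a.genome_bins)
    labels = decode(posterior, "max")
    regions = assemble_regions(
        labels, track_a.genome_bins, posterior, state_names=STATE_LABELS
    )
    if config.min_bins > 1:
        regions = [r for r in regions if r.n_bins >= config.min_bins]
    return bmix, model, posterior, regions


def differential_regions(regions: list[RegionCall]) -> list[RegionCall]:
    """Regions modified in exactly one sample (the differential calls)."""
    return [r for r in regions if r.state in ("mod-A-only", "mod-B-only")]


def megabases_per_state(regions: list[RegionCall]) -> dict[str, float]:
    """Summed Mb per state label: sum(end - start) / 1e6."""
    out: dict[str, float] = {}
    for r in regions:
        out[r.state] = out.get(r.state, 0.0) + (r.end - r.start) / 1e6
    return out


def prepare_track(track: BinnedTrack, config: CallingConfig | None = None) -> BinnedTrack:
    """Apply the standard truncation preprocessing to a binned track."""
    config = config or CallingConfig()
    return truncate_counts(track, config.truncation_quantile)
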