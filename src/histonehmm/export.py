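"""Plain-text exporters: BED, GFF3, bedGraph and parameter files.

Internal coordinates are 0-based half-open; BED and bedGraph share that
convention, GFF3 is written 1-based closed.  Output is deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import GenomeBins
from .copula import BivariateMixture
from .hmm import PosteriorTrack
from .workflows import RegionCall


def write_region_bed(
    regions: Sequence[RegionCall], path: str | Path, state: str | None = None
) -> None:
    """Write regions (optionally one state only) as a 5-column BED.

    The score column is 1000 * mean posterior of the region's own state,
    clipped to [0, 1000] as the BED spec requires.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if state is not None and r.state != state:
                continue
            score = int(min(max(round(1000 * r.mean_posterior), 0), 1000))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}_{i}\t{score}\n"
            )


def write_regions_gff3(regions: Sequence[RegionCall], path: str | Path) -> None:
    """Write all regions as GFF3 (1-based closed) with the state in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(regions):
            attrs = (
                f"ID=region_{i};state={r.state};"
                f"mean_posterior={r.mean_posterior:.6f};"
                f"max_posterior={r.max_posterior:.6f};n_bins={r.n_bins}"
            )
            fh.write(
                f"{r.chrom}\thistonehmm\tregion\t{r.start + 1}\t{r.end}\t"
                f"{r.mean_posterior:.4f}\t.\t.\t{attrs}\n"
            )


def write_posterior_bedgraph(
    posterior: PosteriorTrack,
    genome_bins: GenomeBins,
    state: int,
    path: str | Path,
    track_name: str | None = None,
) -> None:
    """Write one state's per-bin posterior probability as bedGraph."""
    gamma = posterior.gamma[:, state]
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for (chrom, start, end), value in zip(genome_bins.iter_bins(), gamma):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")


def save_bivariate_mixture(bmix: BivariateMixture, path: str | Path) -> None:
    """Serialize the four copula components to a key-value parameter file."""
    lines = []
    for (a, b), comp in sorted(bmix.components.items()):
        pre = f"comp_{a}{b}"
        s = comp.sigma
        lines += [
            f"{pre}_gamma\t{bmix.gamma_ab[(a, b)]!r}",
            f"{pre}_rx\t{comp.marginal_x.r!r}",
            f"{pre}_px\t{comp.marginal_x.p!r}",
            f"{pre}_betax\t{comp.marginal_x.beta!r}",
            f"{pre}_ry\t{comp.marginal_y.r!r}",
            f"{pre}_py\t{comp.marginal_y.p!r}",
            f"{pre}_betay\t{comp.marginal_y.beta!r}",
            f"{pre}_sxx\t{s[0, 0]!r}",
            f"{pre}_sxy\t{s[0, 1]!r}",
            f"{pre}_syy\t{s[1, 1]!r}",
            f"{pre}_n_support\t{comp.n_support}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_bivariate_mixture(path: str | Path) -> BivariateMixture:
    from .copula import STATE_ORDER, CopulaComponent
    from .zinb import ZinbParams

    kv = dict(
        line.split("\t", 1) for line in Path(path).read_text().splitlines() if line
    )
    components, gamma_ab = {}, {}
    for a, b in STATE_ORDER:
        pre = f"comp_{a}{b}"
        sigma = np.array(
            [
                [float(kv[f"{pre}_sxx"]), float(kv[f"{pre}_sxy"])],
                [float(kv[f"{pre}_sxy"]), float(kv[f"{pre}_syy"])],
            ]
        )
        components[(a, b)] = CopulaComponent(
            a, b,
            ZinbParams(float(kv[f"{pre}_rx"]), float(kv[f"{pre}_px"]),
                       float(kv[f"{pre}_betax"])),
            ZinbParams(float(kv[f"{pre}_ry"]), float(kv[f"{pre}_py"]),
                       float(kv[f"{pre}_betay"])),
            sigma,
            n_support=int(kv[f"{pre}_n_support"]),
        )
        gamma_ab[(a, b)] = float(kv[f"{pre}_gamma"])
    return BivariateMixture(components, gamma_ab)
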