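import numpy as np
import pytest

from histonehmm import (
    BinnedTrack,
    CallingConfig,
    GenomeBins,
    PosteriorTrack,
    SimulationSpec,
    assemble_regions,
    call_differential,
    call_single,
    decode,
    differential_regions,
    megabases_per_state,
    prepare_track,
    simulate_bivariate,
    simulate_univariate,
    write_posterior_bedgraph,
    write_region_bed,
    write_regions_gff3,
)


def _posterior_for(labels, k=2):
    g = np.full((len(labels), k), 0.1 / (k - 1))
    g[np.arange(len(labels)), labels] = 0.9
    return PosteriorTrack(g / g.sum(1, keepdims=True), 0.0)


class TestAssembleRegions:
    def test_basic_runs(self):
        gb = GenomeBins(("c",), (4000,), 1000)
        labels = np.array([1, 1, 0, 1])
        regions = assemble_regions(labels, gb, _posterior_for(labels))
        spans = [(r.start, r.end, r.state) for r in regions]
        assert spans == [
            (0, 2000, "modified"),
            (2000, 3000, "unmodified"),
            (3000, 4000, "modified"),
        ]
        assert regions[0].n_bins == 2

    def test_never_merges_across_chromosomes(self):
        gb = GenomeBins(("c1", "c2"), (3000, 2000), 1000)
        labels = np.ones(5, dtype=int)
        regions = assemble_regions(labels, gb, _posterior_for(labels))
        assert len(regions) == 2
        assert [r.chrom for r in regions] == ["c1", "c2"]

    def test_partition_property(self):
        rng = np.random.default_rng(40)
        gb = GenomeBins(("c1", "c2"), (50_000, 30_500), 1000)
        labels = rng.integers(0, 2, gb.n_bins)
        regions = assemble_regions(labels, gb, _posterior_for(labels))
        assert sum(r.end - r.start for r in regions) == gb.total_basepairs
        # same-state neighbours never touch
        by_chrom: dict = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            for a, b in zip(rs[:-1], rs[1:]):
                assert a.end == b.start and a.state != b.state

    def test_posterior_summaries_are_own_state(self):
        gb = GenomeBins(("c",), (3000,), 1000)
        gamma = np.array([[0.2, 0.8], [0.4, 0.6], [0.9, 0.1]])
        post = PosteriorTrack(gamma, 0.0)
        regions = assemble_regions(np.array([1, 1, 0]), gb, post)
        assert regions[0].mean_posterior == pytest.approx(0.7)
        assert regions[0].max_posterior == pytest.approx(0.8)
        assert regions[1].mean_posterior == pytest.approx(0.9)

    def test_length_mismatch(self):
        gb = GenomeBins(("c",), (3000,), 1000)
        with pytest.raises(ValueError):
            assemble_regions(np.array([0, 1]), gb, _posterior_for(np.array([0, 1])))


class TestCallSingle:
    @pytest.fixture(scope="class")
    def sim(self):
        spec = SimulationSpec(n_chromosomes=2, bins_per_chrom=4000, seed=41)
        track, states = simulate_univariate(spec)
        return prepare_track(track), states

    def test_planted_state_recovery(self, sim):
        track, states = sim
        mix, model, post, regions = call_single(track)
        labels = decode(post, ("threshold", 0.5, 1))
        assert (labels == states).mean() >= 0.95

    def test_block_boundary_accuracy(self, sim):
        """Planted block edges recovered within +-2 bins on average."""
        track, states = sim
        _, _, post, _ = call_single(track)
        labels = decode(post, ("threshold", 0.5, 1))
        true_edges = np.flatnonzero(np.diff(states) != 0)
        called_edges = np.flatnonzero(np.diff(labels) != 0)
        dists = [np.abs(called_edges - e).min() for e in true_edges]
        assert np.mean(dists) <= 2.0

    def test_lambda_monotonicity(self, sim):
        track, _ = sim
        _, _, post, _ = call_single(track)
        n_mod = [
            (decode(post, ("threshold", lam, 1)) == 1).sum()
            for lam in (0.5, 0.7, 0.9)
        ]
        assert n_mod[0] >= n_mod[1] >= n_mod[2]

    def test_all_zero_track_errors_with_context(self, small_bins):
        track = BinnedTrack(small_bins, np.zeros(8, dtype=int), sample_id="empty")
        with pytest.raises(ValueError, match="empty"):
            call_single(track)

    def test_regions_partition_genome(self, sim):
        track, _ = sim
        _, _, _, regions = call_single(track)
        assert sum(r.end - r.start for r in regions) == track.genome_bins.total_basepairs


class TestCallDifferential:
    @pytest.fixture(scope="class")
    def sim_pair(self):
        spec = SimulationSpec(seed=42)
        ta, tb, states = simulate_bivariate(spec)
        return prepare_track(ta), prepare_track(tb), states

    @pytest.fixture(scope="class")
    def called(self, sim_pair):
        ta, tb, _ = sim_pair
        return call_differential(ta, tb)

    def test_four_way_accuracy(self, sim_pair, called):
        _, _, states = sim_pair
        _, _, post, _ = called
        labels = decode(post, "max")
        assert (labels == states).mean() >= 0.90

    def test_differential_accuracy(self, sim_pair, called):
        _, _, states = sim_pair
        _, _, post, _ = called
        labels = decode(post, "max")
        assert ((labels >= 2) == (states >= 2)).mean() >= 0.95

    def test_swap_symmetry(self, sim_pair, called):
        """Swapping inputs exchanges A-only and B-only calls, both-states fixed."""
        ta, tb, _ = sim_pair
        _, _, post_ab, _ = called
        _, _, post_ba, _ = call_differential(tb, ta)
        lab_ab = decode(post_ab, "max")
        lab_ba = decode(post_ba, "max")
        swap = np.array([0, 1, 3, 2])
        assert np.array_equal(lab_ab, swap[lab_ba])

    def test_differential_regions_selector(self, called):
        _, _, _, regions = called
        diff = differential_regions(regions)
        assert diff and all(r.state in ("mod-A-only", "mod-B-only") for r in diff)

    def test_megabases_partition(self, called, sim_pair):
        ta, _, _ = sim_pair
        _, _, _, regions = called
        mb = megabases_per_state(regions)
        assert sum(mb.values()) == pytest.approx(
            ta.genome_bins.total_basepairs / 1e6
        )

    def test_mismatched_bins_rejected(self, small_bins, sim_pair):
        ta, _, _ = sim_pair
        other = BinnedTrack(small_bins, np.arange(8))
        with pytest.raises(ValueError, match="GenomeBins"):
            call_differential(ta, other)


class TestExports:
    @pytest.fixture(scope="class")
    def result(self):
        spec = SimulationSpec(n_chromosomes=2, bins_per_chrom=1500, seed=43)
        track, _ = simulate_univariate(spec)
        track = prepare_track(track)
        mix, model, post, regions = call_single(track)
        return track, post, regions

    def test_bed_scores_in_range(self, result, tmp_path):
        _, _, regions = result
        path = tmp_path / "regions.bed"
        write_region_bed(regions, path, state="modified")
        lines = path.read_text().splitlines()
        assert lines
        for line in lines:
            chrom, start, end, name, score = line.split("\t")
            assert 0 <= int(score) <= 1000
            assert int(end) > int(start)
            assert name.startswith("modified")

    def test_gff3_one_based_closed(self, result, tmp_path):
        _, _, regions = result
        path = tmp_path / "regions.gff3"
        write_regions_gff3(regions, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        fields = lines[1].split("\t")
        assert int(fields[3]) == regions[0].start + 1
        assert int(fields[4]) == regions[0].end
        assert f"state={regions[0].state}" in fields[8]

    def test_bedgraph_values_match_posteriors(self, result, tmp_path):
        track, post, _ = result
        path = tmp_path / "post.bedGraph"
        write_posterior_bedgraph(post, track.genome_bins, 1, path)
        lines = path.read_text().splitlines()
        assert len(lines) == track.genome_bins.n_bins
        vals = np.array([float(l.split("\t")[3]) for l in lines])
        np.testing.assert_allclose(vals, post.gamma[:, 1], atol=5e-7)

    def test_outputs_deterministic(self, tmp_path):
        """Identical seed and config give byte-identical export files."""
        outputs = []
        for run in range(2):
            spec = SimulationSpec(n_chromosomes=1, bins_per_chrom=1200, seed=44)
            track, _ = simulate_univariate(spec)
            track = prepare_track(track)
            _, _, post, regions = call_single(track)
            bed = tmp_path / f"r{run}.bed"
            gff = tmp_path / f"r{run}.gff3"
            bg = tmp_path / f"r{run}.bedGraph"
            write_region_bed(regions, bed)
            write_regions_gff3(regions, gff)
            write_posterior_bedgraph(post, track.genome_bins, 1, bg)
            outputs.append(
                (bed.read_bytes(), gff.read_bytes(), bg.read_bytes())
            )
        assert outputs[0] == outputs[1]


class TestCallingConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            CallingConfig(lambda_threshold=1.0)
        with pytest.raises(ValueError):
            CallingConfig(confidence=0.4)  # below lambda
        with pytest.raises(ValueError):
            CallingConfig(bin_size=0)
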