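import numpy as np
import pytest

from modmotif.motif_context import (
    DPNI,
    EnzymeProfile,
    digest,
    extension_ladder,
    ladder_frame,
    motif_mean_fraction,
    scan_sites,
)
from modmotif.simulate import SimulationConfig, simulate_genome, simulate_tracks
from modmotif.tracks_io import FractionTrack, Genome


class TestScanSites:
    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("GGATCC", "GATC", [(1, "+"), (1, "-")]),
            ("AAAA", "ATC", []),
            ("ATCATC", "ATC", [(0, "+"), (3, "+")]),
        ],
    )
    def test_examples(self, seq, pattern, expected):
        assert scan_sites(Genome("g", seq), pattern) == expected

    def test_overlapping_matches_reported(self):
        assert scan_sites(Genome("g", "AAAA"), "AA", both_strands=False) == [
            (0, "+"), (1, "+"), (2, "+"),
        ]

    def test_iupac_degeneracy(self):
        hits = scan_sites(Genome("g", "GAATCA"), "NATC", both_strands=False)
        assert hits == [(1, "+")]

    def test_circular_scan_crosses_origin(self):
        g = Genome("g", "TCGGGA", circular=True)
        assert (4, "+") in scan_sites(g, "GATC")  # GA|TC across the origin


class TestMotifMeanFraction:
    def test_uniform_adenine_track(self):
        g = Genome("g", "GATCGATC")
        track = FractionTrack.for_genome(g)
        for i, c in enumerate(g.seq):
            if c == "A":
                track.set(i, "+", 0.6)
            if c == "T":
                track.set(i, "-", 0.6)
        stat = motif_mean_fraction(g, track, "ATC", 0)
        assert stat.mean_fraction == pytest.approx(0.6)
        # both-strand scan: ATC at 1 and 5 (+), GAT footprints at 0 and 4 (-)
        assert stat.n_loci == 4

    def test_planted_motif_beats_control_motif(self, default_run):
        g, test = default_run["genome"], default_run["test"]
        atc = motif_mean_fraction(g, test, "ATC", 0)
        acc = motif_mean_fraction(g, test, "ACC", 0)
        assert atc.mean_fraction - acc.mean_fraction >= 0.5

    def test_absent_pattern_yields_null_mean(self, caplog):
        g = Genome("g", "CCCCGGGG")
        track = FractionTrack.for_genome(g)
        with caplog.at_level("WARNING"):
            stat = motif_mean_fraction(g, track, "AAAA", 0)
        assert stat.n_loci == 0 and stat.mean_fraction is None
        assert "no occurrences" in caplog.text


class TestExtensionLadder:
    def test_max_ext_zero_is_bare_core(self, default_run):
        g, diff = default_run["genome"], default_run["diff"]
        rows = extension_ladder(g, diff, "ATC", 0, 0)
        assert len(rows) == 1
        bare = motif_mean_fraction(g, diff, "ATC", 0)
        assert rows[0].stat.n_loci == bare.n_loci
        assert rows[0].stat.mean_fraction == pytest.approx(bare.mean_fraction)

    def test_context_free_planting_shows_no_upstream_preference(self, default_run):
        g, test = default_run["genome"], default_run["test"]
        rows = extension_ladder(g, test, "ATC", 0, 1)
        up = {r.base: r.stat.mean_fraction for r in rows if r.direction == "up"}
        spread = max(up.values()) - min(up.values())
        assert spread <= 0.05

    def test_gatc_only_planting_shows_g_preference(self):
        cfg = SimulationConfig(genome_length=50_000, motif="GATC", mod_offset=1, seed=6)
        g = simulate_genome(cfg.genome_length, cfg.gc, cfg.seed)
        test, _ = simulate_tracks(g, cfg)
        rows = extension_ladder(g, test, "ATC", 0, 1)
        up = {r.base: r.stat.mean_fraction for r in rows if r.direction == "up"}
        assert up["G"] >= 0.7
        for base in "ACT":
            assert up[base] <= 0.1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_extension_rows_partition_core_loci(self, seed):
        """On a circular genome the four base-specific rows at each
        distance/direction split the core's loci exactly."""
        rng = np.random.default_rng(seed)
        g = Genome("g", "".join(rng.choice(list("ACGT"), 400)), circular=True)
        track = FractionTrack.for_genome(g)
        rows = extension_ladder(g, track, "ATC", 0, 3)
        core_n = rows[0].stat.n_loci
        for direction in ("up", "down"):
            for d in (1, 2, 3):
                total = sum(
                    r.stat.n_loci
                    for r in rows
                    if r.direction == direction and r.distance == d
                )
                assert total == core_n

    def test_ladder_frame_shape(self, default_run):
        rows = extension_ladder(
            default_run["genome"], default_run["diff"], "ATC", 0, 2
        )
        frame = ladder_frame(rows)
        assert list(frame.columns) == [
            "pattern", "direction", "distance", "base", "n_loci", "mean_fraction",
        ]
        assert len(frame) == 1 + 2 * 2 * 4


class TestDigest:
    def test_fully_methylated_gatc_is_cut(self):
        g = Genome("g", "AAGATCAA")
        methylated = {(2, "+"), (2, "-")}
        assert digest(g, DPNI, methylated) == [4, 4]

    def test_unmethylated_site_not_cut(self):
        g = Genome("g", "AAGATCAA")
        assert digest(g, DPNI, set()) == [8]

    def test_hemimethylated_primary_site_not_cut(self):
        g = Genome("g", "AAGATCAA")
        assert digest(g, DPNI, {(2, "+")}) == [8]

    def test_circular_single_cut_gives_one_fragment(self):
        g = Genome("g", "GATC" + "A" * 16, circular=True)
        assert digest(g, DPNI, {(0, "+"), (0, "-")}) == [20]

    def test_secondary_sites_cut_only_when_enabled(self):
        g = Genome("g", "AACATCAA")  # CATC at 2, no GATC
        methylated = {(2, "+")}
        assert digest(g, DPNI, methylated) == [8]
        assert digest(g, DPNI, methylated, include_secondary=True) == [4, 4]

    def test_methylation_independent_enzyme_cuts_everywhere(self):
        enzyme = EnzymeProfile("blunt", ["GATC"], [], cut_offset=2)
        g = Genome("g", "GATCAGATC")
        assert digest(g, enzyme, set()) == [2, 5, 2]

    @pytest.mark.parametrize("seed", range(20))
    def test_fragment_lengths_conserve_genome_length(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(10, 120))
        g = Genome(
            "g", "".join(rng.choice(list("ACGT"), L)), circular=bool(rng.integers(2))
        )
        sites = scan_sites(g, "GATC")
        methylated = {s for s in sites if rng.random() < 0.7}
        frags = digest(g, DPNI, methylated, include_secondary=bool(rng.integers(2)))
        assert sum(frags) == L
        assert all(f > 0 for f in frags)
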