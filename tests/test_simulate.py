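"""Synthetic repeatome generator: planted truth must be recoverable."""

import numpy as np
import pytest

from repeatscape._util import revcomp
from repeatscape.asr import Phylogeny
from repeatscape.simulate import (ConfigurationError, RepeatFamilySpec,
                                  build_genome, evolve_family, sample_reads)


def _hamming_frac(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestEvolveFamily:
    def test_zero_rate_gives_identical_copies(self, two_tip_tree):
        spec = RepeatFamilySpec("f", "LINE", 200, 10, divergence_rate=0.0)
        out = evolve_family(two_tip_tree, spec, seed=3)
        for sp in ("focal", "other"):
            assert len(out[sp]) == 10
            assert len(set(out[sp])) == 1
        assert out["focal"][0] == out["other"][0]

    def test_divergence_matches_jukes_cantor_expectation(self):
        # one long branch; compare per-site mismatch counting against the
        # JC expectation 3/4 (1 - exp(-4 r v / 3))
        tree = Phylogeny.from_newick("(a:1.0,b:1.0)root;")
        r, v = 0.05, 1.0
        spec = RepeatFamilySpec("f", "LINE", 1000, 500, divergence_rate=r)
        ancestral = RepeatFamilySpec("f", "LINE", 1000, 500,
                                     divergence_rate=0.0)
        out = evolve_family(tree, spec, seed=9)
        ref = evolve_family(tree, ancestral, seed=9)[("a")][0]
        divs = [_hamming_frac(c, ref) for c in out["a"]]
        expected = 0.75 * (1.0 - np.exp(-4.0 * r * v / 3.0))
        assert np.mean(divs) == pytest.approx(expected, rel=0.05)

    def test_origin_node_restricts_clade(self):
        tree = Phylogeny.from_newick(
            "((A:0.1,B:0.1)ab:0.1,C:0.2)root;")
        spec = RepeatFamilySpec("f", "LINE", 100, 5, origin_node="ab",
                                divergence_rate=0.1)
        out = evolve_family(tree, spec, seed=1)
        assert len(out["A"]) == 5 and len(out["B"]) == 5
        assert out["C"] == []

    def test_branch_multiplier_scales_copy_number(self, two_tip_tree):
        spec = RepeatFamilySpec("f", "LINE", 100, 10,
                                branch_multipliers={"focal": 3.0,
                                                    "other": 0.5},
                                divergence_rate=0.0)
        out = evolve_family(two_tip_tree, spec, seed=1)
        assert len(out["focal"]) == 30
        assert len(out["other"]) == 5

    def test_unknown_branch_id_rejected(self, two_tip_tree):
        spec = RepeatFamilySpec("f", "LINE", 100, 5,
                                branch_multipliers={"nope": 2.0})
        with pytest.raises(ConfigurationError, match="nope"):
            evolve_family(two_tip_tree, spec, seed=1)

    def test_post_split_expansion_is_species_private(self):
        # expanded after the split: within-species divergence of the young
        # cohort is below the between-species divergence; expanded before:
        # the two are comparable
        tree = Phylogeny.from_newick("((A:0.05,B:0.05)ab:0.06,C:0.11)root;")

        def mean_divs(mults, rate):
            # single ancestral copy: every within-species pair belongs to
            # the same expansion cohort, isolating the timing contrast
            spec = RepeatFamilySpec("f", "satellite", 300, 1,
                                    branch_multipliers=mults,
                                    divergence_rate=rate)
            out = evolve_family(tree, spec, seed=5)
            within = [_hamming_frac(a, b) for cps in (out["A"], out["B"])
                      for i, a in enumerate(cps) for b in cps[i + 1:]]
            between = [_hamming_frac(a, b) for a in out["A"]
                       for b in out["B"]]
            return np.mean(within), np.mean(between)

        w_post, b_post = mean_divs({"A": 8.0, "B": 8.0}, 1.0)
        w_pre, b_pre = mean_divs({"ab": 8.0}, 1.0)
        assert w_post < 0.75 * b_post
        assert w_pre == pytest.approx(b_pre, rel=0.25)


class TestBuildGenome:
    def test_intervals_tile_genome(self, two_tip_tree, satellite_spec):
        copies = evolve_family(two_tip_tree, satellite_spec, seed=2)["focal"]
        genome = build_genome("focal", [(satellite_spec, copies)], 10_000,
                              seed=4)
        intervals = genome.truth_intervals
        assert intervals[0][0] == 0
        assert intervals[-1][1] == genome.length
        for (s1, e1, _), (s2, e2, _) in zip(intervals, intervals[1:]):
            assert e1 == s2

    def test_no_families_means_zero_repeat_fraction(self):
        genome = build_genome("sp", [], 5_000, seed=1)
        assert genome.repeat_fraction == 0.0
        assert genome.length == 5_000

    def test_planted_fraction_recomputable(self, two_tip_tree):
        spec = RepeatFamilySpec("f", "LINE", 500, 100, divergence_rate=0.0)
        copies = evolve_family(two_tip_tree, spec, seed=1)["focal"]
        genome = build_genome("focal", [(spec, copies)], 50_000, seed=1)
        assert genome.repeat_fraction == pytest.approx(0.5, abs=0.01)

    def test_satellite_copies_form_tandem_array(self, two_tip_tree,
                                                satellite_spec):
        copies = evolve_family(two_tip_tree, satellite_spec, seed=2)["focal"]
        genome = build_genome("focal", [(satellite_spec, copies)], 10_000,
                              seed=4)
        sat = [(s, e) for s, e, lab in genome.truth_intervals if lab == "satT"]
        assert len(sat) == len(copies)
        for (s1, e1), (s2, e2) in zip(sat, sat[1:]):
            assert e1 == s2  # adjacent: one uninterrupted array

    def test_min_gap_spaces_blocks(self, two_tip_tree):
        spec = RepeatFamilySpec("f", "LINE", 100, 20, divergence_rate=0.0)
        copies = evolve_family(two_tip_tree, spec, seed=1)["focal"]
        genome = build_genome("focal", [(spec, copies)], 20_000, seed=1,
                              min_gap=150)
        gaps = [e - s for s, e, lab in genome.truth_intervals
                if lab == "background"]
        assert min(gaps) >= 150

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            build_genome("sp", [], 0, seed=1)


class TestSampleReads:
    @pytest.fixture()
    def genome(self, two_tip_tree, satellite_spec):
        copies = evolve_family(two_tip_tree, satellite_spec, seed=2)["focal"]
        return build_genome("focal", [(satellite_spec, copies)], 30_000,
                            seed=4)

    def test_read_count_formula(self, genome):
        rs = sample_reads(genome, 0.2, 100, 0.0, seed=1)
        assert len(rs.reads) == round(0.2 * genome.length / 100)

    def test_same_seed_identical(self, genome):
        a = sample_reads(genome, 0.1, 100, 0.01, seed=7)
        b = sample_reads(genome, 0.1, 100, 0.01, seed=7)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert [r.provenance for r in a.reads] == [r.provenance
                                                   for r in b.reads]

    def test_error_free_reads_are_genome_substrings(self, genome):
        rs = sample_reads(genome, 0.1, 80, 0.0, seed=3)
        for read in rs.reads:
            assert (read.sequence in genome.sequence
                    or revcomp(read.sequence) in genome.sequence)

    def test_read_provenance_fraction_converges(self, genome):
        rs = sample_reads(genome, 2.0, 100, 0.0, seed=5)
        frac = np.mean([r.provenance != "background" for r in rs.reads])
        n = len(rs.reads)
        p = genome.repeat_fraction
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < tol

    def test_coverage_must_be_positive(self, genome):
        with pytest.raises(ValueError):
            sample_reads(genome, 0.0, 100, 0.0, seed=1)
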