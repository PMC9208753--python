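"""Synthetic-data generators: determinism, equilibrium behavior, planting,
kinetic integration, and gene-table layouts."""

import numpy as np
import pytest

import paraspec as ps
from paraspec.errors import InvalidArgumentError
from paraspec.simulate import integrate_phosphotransfer

import _oracles as orc


class TestEvolveAlignment:
    def test_zero_branch_lengths_copy_the_root(self, lg):
        tree = ps.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        sim = ps.evolve_alignment(tree, lg, 50, seed=1)
        root_seq = sim.ancestral_truth[tree.root_id]
        for _, seq in sim.leaf_alignment:
            assert seq == root_seq
        for seq in sim.ancestral_truth.values():
            assert seq == root_seq

    def test_deterministic_for_same_seed(self, lg_gamma):
        tree = ps.sample_tree(6, 0.2, seed=2)
        a = ps.evolve_alignment(tree, lg_gamma, 40, seed=7)
        b = ps.evolve_alignment(tree, lg_gamma, 40, seed=7)
        assert list(a.leaf_alignment) == list(b.leaf_alignment)
        assert a.ancestral_truth == b.ancestral_truth
        np.testing.assert_array_equal(a.site_rates, b.site_rates)

    def test_saturated_branches_reach_equilibrium_identity(self, poisson):
        # two leaves 50 substitutions/site apart are independent equilibrium
        # draws; expected pairwise identity is sum(pi_i^2) = 1/20
        tree = ps.parse_newick("(A:50.0,B:50.0);")
        n = 10_000
        sim = ps.evolve_alignment(tree, poisson, n, seed=11)
        a = sim.leaf_alignment.sequence("A")
        b = sim.leaf_alignment.sequence("B")
        identity = sum(x == y for x, y in zip(a, b)) / n
        p = 0.05
        se = np.sqrt(p * (1 - p) / n)
        assert abs(identity - p) < 3 * se

    def test_leaf_frequencies_match_equilibrium(self, lg):
        # chi-square goodness of fit at a saturated leaf should not reject
        from scipy.stats import chisquare

        tree = ps.parse_newick("(A:50.0,B:50.0);")
        sim = ps.evolve_alignment(tree, lg, 10_000, seed=5)
        counts = np.zeros(20)
        for ch in sim.leaf_alignment.sequence("A"):
            counts[ps.AMINO_ACIDS.index(ch)] += 1
        _, pval = chisquare(counts, 10_000 * ps.lg_model().frequencies)
        assert pval > 0.01

    def test_low_gamma_shape_creates_more_invariant_columns(self, lg):
        tree = ps.sample_tree(8, 0.3, seed=3)

        def invariant_fraction(alpha, seed):
            model = ps.lg_model(alpha, 4)
            sim = ps.evolve_alignment(tree, model, 300, seed=seed)
            aln = sim.leaf_alignment
            inv = sum(
                len(set(aln.column(c))) == 1
                for c in range(1, aln.n_columns + 1)
            )
            return inv / aln.n_columns

        lo = np.mean([invariant_fraction(0.2, s) for s in range(10)])
        hi = np.mean([invariant_fraction(10.0, s) for s in range(10)])
        assert lo > hi

    def test_site_rate_bookkeeping(self, lg_gamma):
        tree = ps.sample_tree(4, 0.1, seed=1)
        sim = ps.evolve_alignment(tree, lg_gamma, 25, seed=2)
        assert sim.site_rates.shape == (25,)
        assert np.all(sim.site_rates > 0)
        cats = set(np.round(sim.site_rates, 10))
        assert cats <= set(np.round(lg_gamma.category_rates(), 10))


class TestPlantDuplication:
    @pytest.fixture
    def scenario(self):
        tree = ps.duplication_tree(6, 0.1, 0.2, seed=9)
        return ps.DuplicationScenario.at_root(
            tree, [(5, {"R"}, {"Q"}), (11, {"D", "E"}, {"A"})]
        )

    def test_planted_columns_are_diagnostic_by_construction(self, scenario, lg):
        sim, clades = ps.plant_duplication(scenario, lg, 30, seed=4)
        aln = sim.leaf_alignment
        clade1 = [l for l, c in clades.items() if c == 1]
        clade2 = [l for l, c in clades.items() if c == 2]
        f1 = ps.position_frequencies(aln, clade1, [5, 11])
        f2 = ps.position_frequencies(aln, clade2, [5, 11])
        assert f1.frequency(5, "R") == 1.0
        assert f2.frequency(5, "R") == 0.0
        assert f1.frequency(11, {"D", "E"}) == 1.0
        assert f2.frequency(11, "A") == 1.0

    def test_no_planting_is_identical_to_plain_evolution(self, lg):
        tree = ps.duplication_tree(4, 0.1, 0.2, seed=1)
        scenario = ps.DuplicationScenario.at_root(tree, [])
        sim, _ = ps.plant_duplication(scenario, lg, 20, seed=6)
        plain = ps.evolve_alignment(tree, lg, 20, seed=6)
        assert list(sim.leaf_alignment) == list(plain.leaf_alignment)

    def test_overlapping_residue_sets_rejected(self, lg):
        tree = ps.duplication_tree(4, 0.1, 0.2, seed=1)
        scenario = ps.DuplicationScenario.at_root(
            tree, [(3, {"R", "Q"}, {"Q"})]
        )
        with pytest.raises(InvalidArgumentError, match="overlap"):
            ps.plant_duplication(scenario, lg, 10, seed=0)

    def test_planted_column_outside_alignment_rejected(self, scenario, lg):
        with pytest.raises(InvalidArgumentError):
            ps.plant_duplication(scenario, lg, 8, seed=0)  # column 11 > 8

    def test_round_trip_recovers_exactly_the_planted_columns(self, scenario, lg):
        model = ps.lg_model(1.0, 4)
        sim, clades = ps.plant_duplication(scenario, model, 30, seed=12)
        aln = sim.leaf_alignment
        clade1 = [l for l, c in clades.items() if c == 1]
        clade2 = [l for l, c in clades.items() if c == 2]
        calls = ps.paralog_specific_positions(
            ps.position_frequencies(aln, clade1),
            ps.position_frequencies(aln, clade2),
        )
        called = {c.position for c in calls if c.is_specific}
        assert {5, 11} <= called


class TestPhosphotransfer:
    def test_no_transfer_means_flat_signal(self):
        params = ps.KineticParameters(
            transfer_rate_constant=0.0, noise_sd=0.0
        )
        tc = ps.simulate_phosphotransfer(params, [0.0, 10.0, 60.0])
        np.testing.assert_array_equal(tc.intensity, 1.0)

    def test_phosphoryl_conservation_without_phosphatase(self):
        params = ps.KineticParameters(
            transfer_rate_constant=5e-3,
            phosphatase_rate_constant=0.0,
            noise_sd=0.0,
        )
        times = np.linspace(0, 600, 25)
        times[0] = 0.0
        hkp, rrp = integrate_phosphotransfer(params, times)
        np.testing.assert_allclose(hkp + rrp, params.hk_total, atol=1e-6)

    def test_matches_fine_step_integrator(self):
        params = ps.KineticParameters(
            transfer_rate_constant=0.01,
            phosphatase_rate_constant=0.0,
            noise_sd=0.0,
        )
        times = np.array([0.0, 15.0, 30.0, 60.0])
        tc = ps.simulate_phosphotransfer(params, times)
        oracle = orc.rk4_phosphotransfer(0.01, 0.0, 1.0, 4.0, times)
        assert np.max(np.abs(tc.intensity - oracle / oracle[0])) < 1e-6

    def test_phosphatase_depletes_phosphorylated_regulator(self):
        base = dict(transfer_rate_constant=5e-3, noise_sd=0.0)
        times = np.array([0.0, 300.0, 3600.0])
        _, rrp_no = integrate_phosphotransfer(
            ps.KineticParameters(phosphatase_rate_constant=0.0, **base), times
        )
        _, rrp_with = integrate_phosphotransfer(
            ps.KineticParameters(phosphatase_rate_constant=5e-3, **base), times
        )
        assert rrp_with[-1] < rrp_no[-1]

    def test_noise_is_seeded_and_multiplicative(self):
        params = dict(
            transfer_rate_constant=1e-3, noise_sd=0.05
        )
        times = [0.0, 30.0, 300.0]
        a = ps.simulate_phosphotransfer(
            ps.KineticParameters(seed=1, **params), times
        )
        b = ps.simulate_phosphotransfer(
            ps.KineticParameters(seed=1, **params), times
        )
        c = ps.simulate_phosphotransfer(
            ps.KineticParameters(seed=2, **params), times
        )
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)
        assert a.intensity[0] == 1.0

    @pytest.mark.parametrize(
        "times", [[10.0, 30.0], [0.0, 30.0, 20.0], [-5.0, 0.0, 10.0]],
        ids=["no-zero", "unsorted", "negative"],
    )
    def test_invalid_sample_times_rejected(self, times):
        params = ps.KineticParameters(transfer_rate_constant=1e-3)
        with pytest.raises(InvalidArgumentError):
            ps.simulate_phosphotransfer(params, times)

    def test_negative_rate_constants_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ps.KineticParameters(transfer_rate_constant=-1.0)


class TestGeneTable:
    def test_adjacent_pair_layout(self):
        records = ps.simulate_gene_table(
            1, ps.GenomeLayout(adjacent_pairs=1), seed=0
        )
        assert [r.role for r in records] == ["HK", "RR"]
        assert records[1].ordinal == records[0].ordinal + 1
        assert records[0].contig == records[1].contig

    def test_cluster_layout_is_dropped_by_pairing(self):
        records = ps.simulate_gene_table(
            1, ps.GenomeLayout(adjacent_pairs=0, clusters=1), seed=0
        )
        assert [r.role for r in records] == ["HK", "RR", "HK"]
        pairs, dropped = ps.match_cognate_pairs(records)
        assert pairs == []
        assert {d.reason for d in dropped} == {"cluster"}

    def test_orphan_layout(self):
        records = ps.simulate_gene_table(
            1, ps.GenomeLayout(adjacent_pairs=0, orphan_hks=1), seed=0
        )
        assert len(records) == 1
        pairs, dropped = ps.match_cognate_pairs(records)
        assert pairs == [] and dropped[0].reason == "orphan"

    def test_determinism_and_multiple_genomes(self):
        layout = ps.GenomeLayout(
            adjacent_pairs=2, clusters=1, orphan_hks=1, orphan_rrs=1
        )
        a = ps.simulate_gene_table(3, layout, seed=5)
        b = ps.simulate_gene_table(3, layout, seed=5)
        assert a == b
        assert len({r.genome for r in a}) == 3
        per_genome = 2 * 2 + 3 + 1 + 1
        assert len(a) == 3 * per_genome
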