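"""Tests for the synthetic genome, cohort and read generators."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sexscreen import synthetic
from sexscreen._seq import decode


class TestGenomeSpec:
    def test_default_truth_intervals(self, small_spec):
        truth = small_spec.truth_intervals()
        assert [e - s for _, s, e in truth] == [800, 1_200]
        assert all(contig == "W" for contig, _, _ in truth)

    def test_xy_truth_attached_to_y(self):
        spec = synthetic.build_genome_spec(
            system="XY", autosome_length=20_000, sex_shared_length=4_000,
            unique_lengths=(500,), n_traps=2, seed=3,
        )
        assert all(c == "Y" for c, _, _ in spec.truth_intervals())

    def test_colliding_trap_positions_rejected(self):
        with pytest.raises(ValueError, match="overlapping trap loci"):
            synthetic.build_genome_spec(
                autosome_length=10_000, n_traps=2,
                trap_positions=[(0, 5_000), (0, 5_000)], seed=1,
            )

    def test_deterministic_under_seed(self):
        a = synthetic.build_genome_spec(seed=5, autosome_length=10_000,
                                        sex_shared_length=2_000, n_traps=2)
        b = synthetic.build_genome_spec(seed=5, autosome_length=10_000,
                                        sex_shared_length=2_000, n_traps=2)
        assert np.array_equal(a.autosomes[0], b.autosomes[0])
        assert [l.sequence for l in a.trap_loci] == [l.sequence for l in b.trap_loci]


class TestPopulation:
    def test_karyotypes_follow_sex(self, small_population):
        assert all(f.karyotype == "ZW" for f in small_population.females)
        assert all(m.karyotype == "ZZ" for m in small_population.males)
        # pool is the homogametic sex under ZW
        assert all(p.sex == "male" for p in small_population.pool)

    def test_heterogametic_carriers_of_truth_sequence(self, small_spec,
                                                      small_population):
        truth_seqs = [decode(s) for s in small_spec.unique_seqs]
        for f in small_population.females:
            haps = dict(synthetic.individual_haplotypes(small_spec, f))
            joined = {name: decode(c) for name, c in haps.items()}
            for t in truth_seqs:
                carriers = [n for n, s in joined.items() if t in s]
                assert carriers == ["W"]
        for m in small_population.males:
            haps = synthetic.individual_haplotypes(small_spec, m)
            assert all(t not in decode(c) for t in truth_seqs for _, c in haps)

    def test_trap_absent_in_aa_individuals(self, small_spec, small_population):
        everyone = [*small_population.females, *small_population.males]
        for ind in everyone:
            haps = synthetic.individual_haplotypes(small_spec, ind)
            seqs = [decode(c) for _, c in haps]
            for locus, gt in zip(small_spec.trap_loci, ind.genotypes):
                copies = sum(s.count(locus.sequence) for s in seqs)
                assert copies == {"AA": 2, "Aa": 1, "aa": 0}[gt]

    def test_genotypes_follow_hardy_weinberg(self):
        spec = synthetic.build_genome_spec(
            autosome_length=20_000, sex_shared_length=2_000, n_traps=1,
            trap_ps=[0.5], seed=2,
        )
        pop = synthetic.simulate_population(spec, 5_000, 5_000, 0, seed=2)
        gts = [ind.genotypes[0] for ind in (*pop.females, *pop.males)]
        counts = [gts.count("AA"), gts.count("Aa"), gts.count("aa")]
        expected = [0.25 * 10_000, 0.5 * 10_000, 0.25 * 10_000]
        assert chisquare(counts, expected).pvalue > 0.01

    def test_force_trap_engineers_pseudo_marker(self, small_spec):
        pop = synthetic.simulate_population(
            small_spec, 3, 3, 8, seed=4, force_trap=0
        )
        assert all(f.genotypes[0] == "Aa" for f in pop.females)
        assert all(m.genotypes[0] == "aa" for m in pop.males)


class TestReads:
    def test_expected_read_count(self, small_spec, small_population):
        ind = small_population.females[0]
        rs = synthetic.simulate_reads(small_spec, ind, depth=10, seed=1)
        genome_len = sum(
            c.size for _, c in synthetic.individual_haplotypes(small_spec, ind)
        )
        expected = 10 * genome_len / rs.read_length
        assert abs(len(rs) - expected) / expected < 0.01

    def test_error_free_reads_are_haplotype_substrings(self, small_spec,
                                                       small_population):
        ind = small_population.males[0]
        rs = synthetic.simulate_reads(small_spec, ind, depth=0.2,
                                      error_rate=0.0, seed=6)
        haps = [decode(c) for _, c in
                synthetic.individual_haplotypes(small_spec, ind)]
        from oracles import rc

        for seq in rs.sequences():
            assert any(seq in h or rc(seq) in h for h in haps)

    def test_same_seed_reproduces_identical_fastq(self, small_spec,
                                                  small_population, tmp_path):
        ind = small_population.females[1]
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        synthetic.simulate_reads(small_spec, ind, depth=0.5, seed=9).write_fastq(p1)
        synthetic.simulate_reads(small_spec, ind, depth=0.5, seed=9).write_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_length_longer_than_contig_rejected(self):
        with pytest.raises(ValueError):
            synthetic.reads_from_sequences(["ACGT" * 20], depth=1, read_length=100)

    def test_pool_reads_sample_all_individuals(self, small_spec,
                                               small_population):
        rs = synthetic.simulate_reads(
            small_spec, small_population.pool, depth=5, seed=3, library_id="pool"
        )
        assert rs.library_id == "pool"
        # budget is per mean individual genome, not per pooled haplotype
        one = synthetic.simulate_reads(
            small_spec, small_population.pool[0], depth=5, seed=3
        )
        assert len(rs) == pytest.approx(len(one), rel=0.02)


class TestReferenceAssembly:
    def test_truth_intervals_slice_to_unique_sequence(self, small_spec,
                                                      small_population):
        ref = synthetic.reference_assembly(
            small_spec, small_population.reference_female
        )
        for (contig, s, e), uniq in zip(ref.truth_intervals,
                                        small_spec.unique_seqs):
            assert ref.sequence(contig, s, e) == decode(uniq)

    def test_trap_intervals_slice_to_insertion(self, small_spec,
                                               small_population):
        ref = synthetic.reference_assembly(
            small_spec, small_population.reference_female
        )
        for contig, s, e, locus_i in ref.trap_intervals:
            assert ref.sequence(contig, s, e) == small_spec.trap_loci[locus_i].sequence

    def test_homogametic_reference_lacks_heterosome(self, small_spec,
                                                    small_population):
        ref = synthetic.reference_assembly(
            small_spec, small_population.reference_male
        )
        assert "W" not in ref.contigs
        assert ref.truth_intervals == []


class TestTrapRemovalLaw:
    def test_removal_probability_matches_carrier_law(self):
        # removal happens iff the pool of N carries >= 1 insertion allele
        emp = synthetic.simulate_trap_removal(0.5, 5, replicates=20_000, seed=8)
        expected = 1 - 0.5**10
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(emp - expected) < 4 * se
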