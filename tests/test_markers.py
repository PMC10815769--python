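"""Tests for primer scanning, in-silico PCR, band calling and sex calls."""

import numpy as np
import pytest

from oracles import brute_force_primer_scan, rc
from sexscreen import markers as mk
from sexscreen import synthetic
from sexscreen.workflow import design_truth_markers, genotype_individuals


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestPrimerSpecificity:
    def test_planted_primer_found_once(self):
        primer = "GGATCTCATTTGTGAGCCTACATGT"
        template = _random_seq(1, 400) + primer + _random_seq(2, 400)
        sites = mk.primer_specificity(primer, [("t", template)])
        exact = [s for s in sites if s.mismatches == 0]
        assert len(exact) == 1 and exact[0].start == 400 and exact[0].strand == "+"

    def test_three_mismatches_not_reported(self):
        primer = "ACGTACGTACGTACGTACGT"
        site = list(primer)
        for i in (2, 9, 17):
            site[i] = "C" if site[i] != "C" else "G"
        template = _random_seq(3, 100) + "".join(site) + _random_seq(4, 100)
        sites = mk.primer_specificity(primer, [("t", template)], max_mismatches=2)
        assert all(s.start != 100 for s in sites)

    def test_iupac_codes_match_compatible_bases_free(self):
        # W matches A or T at zero cost (as in degenerate primer design)
        primer = "CCCACAGCTTGCTTTCCWTGTTTAG"
        for base in "AT":
            template = _random_seq(5, 50) + primer.replace("W", base) + _random_seq(6, 50)
            sites = mk.primer_specificity(primer, [("t", template)])
            assert any(s.start == 50 and s.mismatches == 0 for s in sites)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            mk.primer_specificity("ACGTACGT", [("t", "A" * 100)])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        template = _random_seq(7, 3_000)
        # plant near-matches of a primer containing an ambiguity code
        primer = "GCTAGCTAGWCTAGCTAGCT"
        t = list(template)
        t[500:520] = primer.replace("W", "T")
        t[900:920] = rc(primer.replace("W", "A"))
        mutated = list(primer.replace("W", "A"))
        mutated[3] = "C" if mutated[3] != "C" else "A"
        t[1500:1520] = "".join(mutated)
        template = "".join(t)
        got = {
            (s.contig, s.start, s.strand, s.mismatches)
            for s in mk.primer_specificity(primer, [("t", template)])
        }
        assert got == brute_force_primer_scan(primer, [("t", template)])


class TestInSilicoPcr:
    def test_constructed_amplicon_length(self):
        fwd = "ACGGATTACAGGCATGAGCC"
        rev = "TTGAGACGGAGTCTCGCTCT"
        template = (
            _random_seq(8, 100) + fwd + _random_seq(9, 360) + rc(rev) + _random_seq(10, 80)
        )
        # forward starts at 100; revcomp(reverse) ends at 100+20+360+20 = 500
        pair = mk.PrimerPair("T1", fwd, rev)
        amps = mk.in_silico_pcr(pair, [("t", template)])
        assert len(amps) == 1
        assert amps[0].start == 100 and amps[0].end == 500
        assert amps[0].length == 400

    def test_same_orientation_no_product(self):
        fwd = "ACGGATTACAGGCATGAGCC"
        rev = "TTGAGACGGAGTCTCGCTCT"
        template = _random_seq(11, 100) + fwd + _random_seq(12, 200) + rev + _random_seq(13, 100)
        assert mk.in_silico_pcr(mk.PrimerPair("T2", fwd, rev), [("t", template)]) == []

    def test_product_window_enforced(self):
        fwd = "ACGGATTACAGGCATGAGCC"
        rev = "TTGAGACGGAGTCTCGCTCT"
        template = _random_seq(14, 50) + fwd + _random_seq(15, 3_000) + rc(rev)
        pair = mk.PrimerPair("T3", fwd, rev, product_range=(50, 2_000))
        assert mk.in_silico_pcr(pair, [("t", template)]) == []

    def test_strand_symmetry(self):
        fwd = "ACGGATTACAGGCATGAGCC"
        rev = "TTGAGACGGAGTCTCGCTCT"
        template = _random_seq(16, 120) + fwd + _random_seq(17, 500) + rc(rev) + _random_seq(18, 60)
        pair = mk.PrimerPair("T4", fwd, rev)
        a = sorted(x.length for x in mk.in_silico_pcr(pair, [("t", template)]))
        b = sorted(x.length for x in mk.in_silico_pcr(pair, [("t", rc(template))]))
        assert a == b != []


class TestBandPattern:
    def test_distinct_lengths_give_two_bands(self):
        amps = [mk.Amplicon("c", 0, 400, 0, 0), mk.Amplicon("c", 0, 600, 0, 0)]
        assert mk.band_pattern(amps).bands == (400, 600)

    def test_close_lengths_merge(self):
        amps = [mk.Amplicon("c", 0, 400, 0, 0), mk.Amplicon("c", 10, 420, 0, 0)]
        assert mk.band_pattern(amps, gel_resolution=20).n_bands == 1

    def test_no_amplicons_no_bands(self):
        assert mk.band_pattern([]).bands == ()

    def test_band_spacing_invariant(self):
        rng = np.random.default_rng(19)
        lengths = sorted(int(x) for x in rng.integers(100, 1_500, size=30))
        amps = [mk.Amplicon("c", 0, l, 0, 0) for l in lengths]
        bands = mk.band_pattern(amps, gel_resolution=25).bands
        assert all(b2 - b1 > 25 for b1, b2 in zip(bands, bands[1:]))


@pytest.fixture(scope="module")
def spec():
    return synthetic.build_genome_spec(
        autosome_length=30_000, sex_shared_length=6_000,
        unique_lengths=(1_500, 900), n_traps=2, seed=29,
    )


@pytest.fixture(scope="module")
def genomes(spec):
    f = synthetic.Individual("f", "female", "ZW", ("aa", "aa"))
    m = synthetic.Individual("m", "male", "ZZ", ("aa", "aa"))
    return (
        synthetic.reference_assembly(spec, f).contigs,
        synthetic.reference_assembly(spec, m).contigs,
    )


class TestMarkerClassificationAndCalls:
    def test_truth_derived_marker_classes(self, spec, genomes):
        female, male = genomes
        pairs = design_truth_markers(spec)
        assert mk.classify_marker(pairs["dominant"], female, male) == "dominant"
        assert (
            mk.classify_marker(pairs["gametologous"], female, male) == "gametologous"
        )

    def test_autosomal_pair_is_non_specific(self, spec, genomes):
        from sexscreen._seq import decode

        female, male = genomes
        auto = decode(spec.autosomes[0])
        fwd = auto[1_000:1_020]
        rev = rc(auto[1_400:1_420])
        pair = mk.PrimerPair("AUTO", fwd, rev)
        assert mk.classify_marker(pair, female, male) == "non_specific"

    @pytest.mark.parametrize(
        "marker_class,n_bands,system,expected",
        [
            ("dominant", 1, "ZW", "female"),
            ("dominant", 0, "ZW", "male"),
            ("gametologous", 2, "ZW", "female"),
            ("gametologous", 1, "ZW", "male"),
            ("gametologous", 0, "ZW", "invalid"),
            ("dominant", 1, "XY", "male"),
            ("gametologous", 2, "XY", "male"),
            ("gametologous", 1, "XY", "female"),
        ],
    )
    def test_call_table(self, marker_class, n_bands, system, expected):
        pattern = mk.BandPattern("i1", tuple(300 + 100 * i for i in range(n_bands)))
        assert mk.call_sex(pattern, marker_class, system).call == expected

    def test_non_specific_marker_cannot_call(self):
        with pytest.raises(ValueError, match="non-specific"):
            mk.call_sex(mk.BandPattern("i", (300,)), "non_specific")

    def test_cohort_genotyping_is_fully_accurate(self, spec):
        pop = synthetic.simulate_population(spec, 20, 20, 0, seed=31)
        pairs = design_truth_markers(spec)
        df = genotype_individuals(spec, [*pop.females, *pop.males], pairs)
        assert len(df) == 80  # 40 individuals x 2 markers
        assert df["correct"].all()
        gam = df[df["marker_class"] == "gametologous"]
        assert set(gam[gam["true_sex"] == "female"]["bands"].str.count(",") + 1) == {2}
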