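"""Tests for the coverage-subtraction screen and its summaries."""

import numpy as np
import pytest

from sexscreen import screen
from sexscreen.mapping import CoverageSet
from sexscreen._seq import encode


def track(lib, contig, length, spans, depth=1):
    d = np.zeros(length, dtype=np.int32)
    for s, e in spans:
        d[s:e] += depth
    return CoverageSet(library_id=lib, depth={contig: d})


def ivs(*pairs):
    return np.asarray(pairs, dtype=np.int64) if pairs else np.empty((0, 2), np.int64)


class TestCommonRegions:
    def test_interval_mode_is_set_intersection(self):
        tracks = [
            track("a", "c", 200, [(0, 100)]),
            track("b", "c", 200, [(50, 150)]),
            track("d", "c", 200, [(80, 200)]),
        ]
        out = screen.common_regions(tracks, {"c": 200}, granularity="interval")
        assert np.array_equal(out["c"], ivs((80, 100)))

    def test_zero_coverage_library_empties_result(self):
        tracks = [track("a", "c", 100, [(0, 100)]), track("b", "c", 100, [])]
        out = screen.common_regions(tracks, {"c": 100}, granularity="interval")
        assert out["c"].size == 0

    def test_sequence_mode_keeps_well_covered_contigs(self):
        tracks = [track("a", "c", 100, [(0, 80)]), track("b", "c", 100, [(0, 60)])]
        out = screen.common_regions(tracks, {"c": 100}, covered_fraction=0.5,
                                    granularity="sequence")
        assert np.array_equal(out["c"], ivs((0, 100)))
        out2 = screen.common_regions(tracks, {"c": 100}, covered_fraction=0.7,
                                     granularity="sequence")
        assert out2["c"].size == 0

    def test_mismatched_reference_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            screen.common_regions([track("a", "other", 50, [])], {"c": 100})


class TestSubtraction:
    def test_interval_subtraction_splits_candidates(self):
        cand = {"c": ivs((0, 100))}
        opp = [track("m1", "c", 200, [(40, 60)])]
        out = screen.subtract_covered(cand, opp, granularity="interval")
        assert np.array_equal(out["c"], ivs((0, 40), (60, 100)))

    def test_empty_opposite_tracks_is_identity(self):
        cand = {"c": ivs((10, 90))}
        assert screen.subtract_covered(cand, [], granularity="interval") == cand

    def test_sequence_mode_single_read_kills_contig(self):
        cand = {"c": ivs((0, 500))}
        opp = [track("m1", "c", 500, [(250, 350)])]
        out = screen.subtract_covered(cand, opp, granularity="sequence")
        assert out["c"].size == 0

    def test_stage_monotonicity(self):
        cand = {"c": ivs((0, 300))}
        out1 = screen.subtract_covered(
            cand, [track("m", "c", 300, [(0, 50)])], granularity="interval"
        )
        pool = track("p", "c", 300, [(100, 120)])
        out2 = screen.pool_filter(out1, pool, "female", "male",
                                  granularity="interval")
        assert screen.total_bp(cand) >= screen.total_bp(out1) >= screen.total_bp(out2)


class TestPoolFilter:
    def test_same_sex_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            screen.pool_filter({"c": ivs((0, 10))},
                               track("p", "c", 10, []), "female", "female")

    def test_empty_pool_track_is_identity(self):
        cand = {"c": ivs((5, 50))}
        out = screen.pool_filter(cand, track("p", "c", 50, []), "female", "male",
                                 granularity="interval")
        assert np.array_equal(out["c"], cand["c"])


class TestCompositionFilters:
    def test_n_rich_region_dropped(self):
        seq = encode("A" * 850 + "N" * 150)
        kept, dropped = screen.composition_filters(
            {"c": ivs((0, 1_000))}, {"c": seq}, "female"
        )
        assert kept == [] and dropped[0].dropped_by == "N-content"

    def test_repeat_copy_of_reference_segment_dropped(self):
        rng = np.random.default_rng(3)
        segment = rng.integers(0, 4, 500).astype(np.uint8)
        auto = np.concatenate([rng.integers(0, 4, 2_000).astype(np.uint8), segment])
        ref = {"auto": auto, "w": segment.copy()}
        kept, dropped = screen.composition_filters(
            {"w": ivs((0, 500))}, ref, "female"
        )
        assert kept == [] and dropped[0].dropped_by == "repeat"

    def test_clean_unique_region_retained(self):
        rng = np.random.default_rng(4)
        ref = {"w": rng.integers(0, 4, 2_000).astype(np.uint8)}
        kept, dropped = screen.composition_filters({"w": ivs((0, 2_000))}, ref,
                                                   "female")
        assert dropped == [] and len(kept) == 1
        assert kept[0].provenance[-1] == "composition"

    def test_short_region_dropped(self):
        rng = np.random.default_rng(5)
        ref = {"w": rng.integers(0, 4, 400).astype(np.uint8)}
        kept, dropped = screen.composition_filters(
            {"w": ivs((0, 100))}, ref, "female", min_length=200
        )
        assert kept == [] and dropped[0].dropped_by == "min-length"


class TestSummaryAndSystemCall:
    def _regions(self, count, length, sex="female"):
        return [
            screen.CandidateRegion("c", i * (length + 1), i * (length + 1) + length,
                                   sex)
            for i in range(count)
        ]

    def test_totals_are_exact_arithmetic(self):
        summary = screen.summarize(self._regions(1883, 2131),
                                   self._regions(151, 1733, "male"))
        assert summary.female.total_bp == 1883 * 2131
        assert summary.female.mean_bp == pytest.approx(2131)
        assert summary.male.total_bp == 151 * 1733

    def test_large_female_excess_calls_zw(self):
        summary = screen.summarize(self._regions(1735, 2951),
                                   self._regions(151, 1733, "male"))
        call = screen.infer_system(summary, ratio_threshold=5)
        assert call.system == "ZW"
        assert call.ratio == pytest.approx(
            (1735 * 2951 + 1) / (151 * 1733 + 1)
        )

    def test_mirror_calls_xy(self):
        summary = screen.summarize(self._regions(10, 300),
                                   self._regions(100, 2_000, "male"))
        assert screen.infer_system(summary).system == "XY"

    def test_empty_both_sides_undetermined(self):
        summary = screen.summarize([], [])
        call = screen.infer_system(summary)
        assert call.system == "undetermined" and call.ratio == 1.0

    def test_balanced_yields_undetermined(self):
        summary = screen.summarize(self._regions(5, 1_000),
                                   self._regions(4, 1_000, "male"))
        assert screen.infer_system(summary).system == "undetermined"


class TestExport:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        ref = {"w": rng.integers(0, 4, 3_000).astype(np.uint8)}
        cands = [
            screen.CandidateRegion("w", 100, 600, "female", ["common"]),
            screen.CandidateRegion("w", 1_000, 1_400, "female", ["common"]),
        ]
        paths = screen.export(cands, ref, tmp_path / "out")
        bed = (tmp_path / "out.bed").read_text().splitlines()
        assert bed == ["w\t100\t600", "w\t1000\t1400"]
        from Bio import SeqIO

        recs = {r.id: str(r.seq) for r in SeqIO.parse(paths["fasta"], "fasta")}
        from sexscreen._seq import decode

        for c in cands:
            assert recs[f"w:{c.start}-{c.end}"] == decode(ref["w"][c.start:c.end])

    def test_empty_set_writes_valid_files(self, tmp_path):
        paths = screen.export([], {"w": np.zeros(10, np.uint8)}, tmp_path / "e")
        assert (tmp_path / "e.bed").read_text() == ""
        assert (tmp_path / "e.fa").read_text() == ""


class TestJaccard:
    def test_identical_sets(self):
        a = {"c": ivs((0, 100))}
        assert screen.jaccard(a, a) == 1.0

    def test_partial_overlap(self):
        a = {"c": ivs((0, 100))}
        b = {"c": ivs((50, 150))}
        assert screen.jaccard(a, b) == pytest.approx(50 / 150)
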