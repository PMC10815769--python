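"""Coverage-subtraction screening for sex-specific sequence.

The screen takes per-library coverage tracks over a per-sex reference and
applies, in order:

1. ``common_regions`` -- keep sequence covered in every same-sex library;
2. ``subtract_covered`` -- discard every base (or whole contig) touched by
   any read from any opposite-sex library (strict zero-coverage rule);
3. ``pool_filter`` -- the same strict subtraction against a large
   single-sex pool of the homogametic sex, which removes autosomal
   pseudo-markers that survived the small-group screen;
4. ``composition_filters`` -- drop candidates that are N-rich, repetitive
   within the reference, or too short to design a PCR marker on.

Run in both directions (female-specific on the female reference,
male-specific on the male reference), the relative yield decides the
sex-determination system: a large excess of female-specific sequence means
female heterogamety (ZW), the mirror means XY.

Intervals are 0-based half-open throughout, as dicts mapping contig name to
an (m, 2) array of (start, end) rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import canonical_kmer_hashes, decode
from .mapping import CoverageSet

Intervals = dict[str, np.ndarray]
Granularity = Literal["sequence", "interval"]


@dataclass
class CandidateRegion:
    contig: str
    start: int
    end: int
    target_sex: str
    provenance: list[str] = field(default_factory=list)
    dropped_by: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.contig}:{self.start}-{self.end}")


@dataclass(frozen=True)
class SexStats:
    count: int
    total_bp: int
    mean_bp: float


@dataclass
class ScreenSummary:
    female: SexStats
    male: SexStats
    attrition: pd.DataFrame | None = None


@dataclass(frozen=True)
class SystemCall:
    system: str                 # "ZW" | "XY" | "undetermined"
    female_bp: int
    male_bp: int
    ratio: float
    ratio_threshold: float


def intervals_to_mask(intervals: np.ndarray, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> np.ndarray:
    if mask.size == 0 or not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return np.column_stack([starts, ends]).astype(np.int64)


def total_bp(intervals: Intervals) -> int:
    return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in intervals.values()))


def _check_refs(tracks: Sequence[CoverageSet], lengths: dict[str, int]) -> None:
    for t in tracks:
        for contig, d in t.depth.items():
            if contig not in lengths or d.size != lengths[contig]:
                raise ValueError(
                    f"coverage track {t.library_id!r} does not match the "
                    f"reference (contig {contig!r})"
                )


def common_regions(
    tracks: Sequence[CoverageSet],
    contig_lengths: dict[str, int],
    min_depth: int = 1,
    covered_fraction: float = 0.5,
    granularity: Granularity = "sequence",
) -> Intervals:
    """Sequence shared by all same-sex libraries.

    ``sequence`` granularity keeps whole contigs in which every library
    covers at least ``covered_fraction`` of bases at depth >= ``min_depth``;
    ``interval`` granularity intersects the per-base covered positions of
    all libraries and emits maximal intervals.
    """
    if not tracks:
        raise ValueError("at least one coverage track required")
    _check_refs(tracks, contig_lengths)
    out: Intervals = {}
    for contig, L in contig_lengths.items():
        if granularity == "sequence":
            ok = all(
                np.count_nonzero(t.depth[contig] >= min_depth) >= covered_fraction * L
                for t in tracks
            )
            out[contig] = (
                np.array([[0, L]], dtype=np.int64) if ok else np.empty((0, 2), np.int64)
            )
        elif granularity == "interval":
            mask = np.ones(L, dtype=bool)
            for t in tracks:
                mask &= t.depth[contig] >= min_depth
            out[contig] = mask_to_intervals(mask)
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    return out


def _subtract(
    intervals: Intervals,
    tracks: Sequence[CoverageSet],
    granularity: Granularity,
    min_reads: int,
) -> Intervals:
    out: Intervals = {}
    for contig, ivs in intervals.items():
        if ivs.size == 0:
            out[contig] = ivs
            continue
        covered = np.zeros(int(ivs[:, 1].max()), dtype=bool)
        for t in tracks:
            if contig in t.depth:
                d = t.depth[contig][: covered.size]
                covered[: d.size] |= d >= min_reads
        if granularity == "sequence":
            # strict rule: any opposite coverage anywhere on the contig
            any_cov = any(
                contig in t.depth and bool(np.any(t.depth[contig] >= min_reads))
                for t in tracks
            )
            out[contig] = np.empty((0, 2), np.int64) if any_cov else ivs
        else:
            mask = intervals_to_mask(ivs, covered.size)
            mask &= ~covered
            out[contig] = mask_to_intervals(mask)
    return out


def subtract_covered(
    intervals: Intervals,
    opposite_tracks: Sequence[CoverageSet],
    granularity: Granularity = "sequence",
    min_reads: int = 1,
) -> Intervals:
    """Remove every base covered by >= ``min_reads`` in ANY opposite-sex library.

    With ``sequence`` granularity a contig is discarded as soon as a single
    opposite-sex read maps anywhere on it.
    """
    if not opposite_tracks:
        return intervals
    return _subtract(intervals, opposite_tracks, granularity, min_reads)


def pool_filter(
    intervals: Intervals,
    pool_track: CoverageSet,
    target_sex: str,
    pool_sex: str,
    granularity: Granularity = "sequence",
    min_reads: int = 1,
) -> Intervals:
    """Strict zero-coverage subtraction against the single-sex pool.

    The pool must be of the homogametic sex relative to the target:
    female-specific candidates are screened against a male pool and vice
    versa.
    """
    if target_sex == pool_sex:
        raise ValueError(
            f"pool sex {pool_sex!r} cannot validate {target_sex}-specific "
            "candidates; the pool must be the opposite (homogametic) sex"
        )
    return _subtract(intervals, [pool_track], granularity, min_reads)


def composition_filters(
    intervals: Intervals,
    reference: dict[str, np.ndarray],
    target_sex: str,
    max_n_fraction: float = 0.1,
    max_repeat_fraction: float = 0.5,
    repeat_k: int = 21,
    min_length: int = 200,
    provenance: Sequence[str] = (),
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Final composition screen; returns (kept, dropped) candidate regions.

    A region is dropped when its N fraction exceeds ``max_n_fraction``, when
    more than ``max_repeat_fraction`` of its ``repeat_k``-mers occur more
    than once in the whole reference (canonical, both strands), or when it
    is shorter than ``min_length``.  ``dropped_by`` on the region names the
    filter that fired.
    """
    # multiplicity of every canonical k-mer in the reference
    all_hashes = [
        canonical_kmer_hashes(codes, repeat_k) for codes in reference.values()
    ]
    ref_hashes = np.concatenate(all_hashes) if all_hashes else np.empty(0, np.uint64)
    uniq, counts = np.unique(ref_hashes, return_counts=True)

    kept: list[CandidateRegion] = []
    dropped: list[CandidateRegion] = []
    base_prov = list(provenance)
    for contig, ivs in intervals.items():
        codes = reference[contig]
        for s, e in ivs:
            region = CandidateRegion(
                contig=contig,
                start=int(s),
                end=int(e),
                target_sex=target_sex,
                provenance=base_prov.copy(),
            )
            if region.length < min_length:
                region.dropped_by = "min-length"
                dropped.append(region)
                continue
            seg = codes[s:e]
            n_frac = np.count_nonzero(seg >= 4) / seg.size
            if n_frac > max_n_fraction:
                region.dropped_by = "N-content"
                dropped.append(region)
                continue
            h = canonical_kmer_hashes(seg, repeat_k)
            if h.size:
                idx = np.searchsorted(uniq, h)
                idx = np.minimum(idx, uniq.size - 1)
                mult = np.where(uniq[idx] == h, counts[idx], 0)
                repeat_frac = np.count_nonzero(mult > 1) / h.size
                if repeat_frac > max_repeat_fraction:
                    region.dropped_by = "repeat"
                    dropped.append(region)
                    continue
            region.provenance.append("composition")
            kept.append(region)
    return kept, dropped


def candidates_from_intervals(
    intervals: Intervals, target_sex: str, provenance: Sequence[str] = ()
) -> list[CandidateRegion]:
    out = []
    for contig, ivs in sorted(intervals.items()):
        for s, e in ivs:
            out.append(
                CandidateRegion(
                    contig=contig,
                    start=int(s),
                    end=int(e),
                    target_sex=target_sex,
                    provenance=list(provenance),
                )
            )
    return out


def _stats(candidates: Sequence[CandidateRegion]) -> SexStats:
    total = sum(c.length for c in candidates)
    n = len(candidates)
    return SexStats(count=n, total_bp=total, mean_bp=total / n if n else 0.0)


def summarize(
    female_candidates: Sequence[CandidateRegion],
    male_candidates: Sequence[CandidateRegion],
    attrition: pd.DataFrame | None = None,
) -> ScreenSummary:
    """Exact per-sex candidate counts, total and mean lengths."""
    return ScreenSummary(
        female=_stats(female_candidates),
        male=_stats(male_candidates),
        attrition=attrition,
    )


def infer_system(
    summary: ScreenSummary,
    ratio_threshold: float = 5.0,
    pseudocount: float = 1.0,
) -> SystemCall:
    """Decide ZW vs XY from the relative sex-specific sequence yield.

    ratio = (female bp + pseudocount) / (male bp + pseudocount); a ratio at
    or above the threshold calls ZW (female heterogamety), at or below its
    reciprocal calls XY, anything between is undetermined.  The pseudocount
    keeps the ratio finite when one side yields nothing (the expected final
    state for the homogametic sex).
    """
    f = summary.female.total_bp
    m = summary.male.total_bp
    ratio = (f + pseudocount) / (m + pseudocount)
    if f == 0 and m == 0:
        system = "undetermined"
    elif ratio >= ratio_threshold:
        system = "ZW"
    elif ratio <= 1.0 / ratio_threshold:
        system = "XY"
    else:
        system = "undetermined"
    return SystemCall(
        system=system,
        female_bp=f,
        male_bp=m,
        ratio=ratio,
        ratio_threshold=ratio_threshold,
    )


def export(
    candidates: Sequence[CandidateRegion],
    reference: dict[str, np.ndarray],
    out_prefix,
) -> dict[str, str]:
    """Write BED, FASTA and a TSV report; returns the written paths.

    BED is 0-based half-open; FASTA records are named ``contig:start-end``
    and hold the exact reference slice.
    """
    out_prefix = str(out_prefix)
    paths = {
        "bed": out_prefix + ".bed",
        "fasta": out_prefix + ".fa",
        "tsv": out_prefix + ".tsv",
    }
    with open(paths["bed"], "w") as fh:
        for c in candidates:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\n")
    records = [
        SeqRecord(
            Seq(decode(reference[c.contig][c.start : c.end])),
            id=f"{c.contig}:{c.start}-{c.end}",
            description="",
        )
        for c in candidates
    ]
    SeqIO.write(records, paths["fasta"], "fasta")
    df = pd.DataFrame(
        [
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "target_sex": c.target_sex,
                "provenance": ",".join(c.provenance),
            }
            for c in candidates
        ],
        columns=["contig", "start", "end", "length", "target_sex", "provenance"],
    )
    df.to_csv(paths["tsv"], sep="\t", index=False)
    return paths


def jaccard(intervals_a: Intervals, intervals_b: Intervals) -> float:
    """Base-level Jaccard index between two interval sets."""
    contigs = set(intervals_a) | set(intervals_b)
    inter = union = 0
    for contig in contigs:
        a = intervals_a.get(contig, np.empty((0, 2), np.int64))
        b = intervals_b.get(contig, np.empty((0, 2), np.int64))
        hi = int(max(a[:, 1].max() if a.size else 0, b[:, 1].max() if b.size else 0))
        if hi == 0:
            continue
        ma = intervals_to_mask(a, hi)
        mb = intervals_to_mask(b, hi)
        inter += int(np.count_nonzero(ma & mb))
        union += int(np.count_nonzero(ma | mb))
    return inter / union if union else 1.0
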