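"""Read quality control and k-mer genome-size estimation.

QC applies the two pre-assembly filters used throughout this workflow: a
read is discarded when more than 10% of its bases are N, or when more than
half of its bases have Phred quality <= 5 (both thresholds strict
inequalities and configurable).  Genome size is estimated from the
canonical k-mer multiplicity spectrum (k = 21 by default): total k-mer
occurrences above the error trough divided by the depth of the homozygous
coverage peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._seq import canonical_kmer_hashes, encode

FastqRecord = tuple[str, str, str]  # (id, sequence, quality string)


@dataclass(frozen=True)
class QcReport:
    input: int
    removed_polyN: int
    removed_lowq: int
    retained: int
    max_n_fraction: float
    lowq_fraction: float
    q_threshold: int

    def __post_init__(self) -> None:
        assert self.removed_polyN + self.removed_lowq + self.retained == self.input


def read_fastq(path) -> Iterator[FastqRecord]:
    """Yield (id, sequence, quality) records from a FASTQ file."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations["phred_quality"]
        yield rec.id, str(rec.seq), "".join(chr(q + 33) for q in quals)


def _as_records(reads) -> Iterable[FastqRecord]:
    if hasattr(reads, "records"):  # ReadSet
        return reads.records()
    return reads


def filter_reads(
    reads,
    max_n_fraction: float = 0.10,
    lowq_fraction: float = 0.50,
    q_threshold: int = 5,
) -> tuple[list[FastqRecord], QcReport]:
    """Drop N-rich then low-quality reads; survivors keep input order.

    ``reads`` is a :class:`~sexscreen.synthetic.ReadSet` or an iterable of
    ``(id, sequence, quality)`` tuples.  A read is removed as poly-N when its
    N fraction is strictly greater than ``max_n_fraction``, otherwise as
    low-quality when the fraction of bases at Phred <= ``q_threshold`` is
    strictly greater than ``lowq_fraction``.
    """
    if not (0.0 < max_n_fraction <= 1.0 and 0.0 < lowq_fraction <= 1.0):
        raise ValueError("fraction thresholds must lie in (0, 1]")
    kept: list[FastqRecord] = []
    n_in = n_polyn = n_lowq = 0
    for idx, rec in enumerate(_as_records(reads)):
        try:
            rid, seq, qual = rec
            if len(seq) != len(qual) or not seq:
                raise ValueError("length mismatch or empty read")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
        n_in += 1
        n_count = seq.count("N") + seq.count("n")
        if n_count / len(seq) > max_n_fraction:
            n_polyn += 1
            continue
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
        if np.count_nonzero(q <= q_threshold) / len(seq) > lowq_fraction:
            n_lowq += 1
            continue
        kept.append((rid, seq, qual))
    report = QcReport(
        input=n_in,
        removed_polyN=n_polyn,
        removed_lowq=n_lowq,
        retained=len(kept),
        max_n_fraction=max_n_fraction,
        lowq_fraction=lowq_fraction,
        q_threshold=q_threshold,
    )
    return kept, report


@dataclass
class KmerHistogram:
    k: int
    multiplicities: np.ndarray  # multiplicities[m] = number of distinct k-mers seen m times; index 0 unused
    total_distinct: int
    total_occurrences: int

    def __post_init__(self) -> None:
        occ = int(np.sum(np.arange(self.multiplicities.size) * self.multiplicities))
        assert occ == self.total_occurrences


@dataclass(frozen=True)
class GenomeSizeEstimate:
    size_bp: int | None
    peak_depth: float | None
    modal_multiplicity: int | None
    trough: int
    total_occurrences_used: int

    @property
    def determined(self) -> bool:
        return self.size_bp is not None


def kmer_histogram(reads, k: int = 21) -> KmerHistogram:
    """Canonical k-mer multiplicity spectrum of a read set.

    k must be odd (no self-complementary k-mers) and within [11, 31].
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    chunks: list[np.ndarray] = []
    if hasattr(reads, "codes"):  # ReadSet: hash the whole matrix at once
        mat = reads.codes
        sep = np.full((mat.shape[0], 1), 4, dtype=np.uint8)
        flat = np.hstack([mat, sep]).ravel()
        chunks.append(canonical_kmer_hashes(flat, k))
    else:
        buf: list[str] = []
        for rec in _as_records(reads):
            seq = rec[1] if isinstance(rec, tuple) else str(rec)
            if len(seq) >= k:
                buf.append(seq)
            if len(buf) >= 10_000:
                chunks.append(_hash_batch(buf, k))
                buf = []
        if buf:
            chunks.append(_hash_batch(buf, k))
    if not chunks or sum(c.size for c in chunks) == 0:
        raise ValueError("no k-mers: reads empty or shorter than k")
    hashes = np.concatenate(chunks)
    _, counts = np.unique(hashes, return_counts=True)
    hist = np.bincount(counts)
    return KmerHistogram(
        k=k,
        multiplicities=hist,
        total_distinct=int(counts.size),
        total_occurrences=int(hashes.size),
    )


def _hash_batch(seqs: list[str], k: int) -> np.ndarray:
    joined = ("N" * k).join(seqs)
    return canonical_kmer_hashes(encode(joined), k)


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Spectrum-based genome size: occurrences above the error trough over
    the homozygous peak depth.

    The trough is the first local minimum of the spectrum; the peak is the
    modal multiplicity beyond it, refined to the spectrum-weighted mean
    multiplicity within [0.6, 1.6] x mode so that an integer-rate coverage
    peak does not quantise the estimate.  A spectrum with no rise after the
    trough yields an undetermined result.
    """
    c = hist.multiplicities.astype(float)
    if c.size < 3:
        return GenomeSizeEstimate(None, None, None, 0, 0)
    # first local minimum: first m >= 1 with c[m] <= c[m+1]
    trough = 0
    for m in range(1, c.size - 1):
        if c[m] <= c[m + 1]:
            trough = m
            break
    else:
        return GenomeSizeEstimate(None, None, None, 0, 0)
    tail = c[trough + 1 :]
    if tail.size == 0 or tail.max() <= 0:
        return GenomeSizeEstimate(None, None, None, trough, 0)
    mode = trough + 1 + int(np.argmax(tail))
    if mode <= trough or c[mode] <= c[trough]:
        return GenomeSizeEstimate(None, None, None, trough, 0)
    # two-pass peak refinement: a coarse centroid around the mode, then a
    # centroid over +-4 sd of that estimate, which is symmetric about the
    # true coverage rate and so does not quantise to the integer mode
    peak = float(mode)
    for half_width in (0.4 * mode, 4.0 * math.sqrt(mode)):
        lo = max(trough + 1, int(np.floor(peak - half_width)))
        hi = min(c.size - 1, int(np.ceil(peak + half_width)))
        m_range = np.arange(lo, hi + 1)
        weights = c[lo : hi + 1]
        if weights.sum() <= 0:
            break
        peak = float(np.sum(m_range * weights) / np.sum(weights))
    m_all = np.arange(c.size)
    used = float(np.sum(m_all[trough + 1 :] * c[trough + 1 :]))
    size = int(round(used / peak))
    return GenomeSizeEstimate(
        size_bp=size,
        peak_depth=peak,
        modal_multiplicity=mode,
        trough=trough,
        total_occurrences_used=int(used),
    )
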