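"""Ungapped seed-and-extend read mapping and coverage tracks.

The subtraction screen only needs presence/absence of read coverage, so the
mapper is deliberately simple and exhaustively specified: a read is
reported at every reference position (both strands) where at least one
exact ``seed_k``-mer of the read matches the reference and the full-length
ungapped extension has at most ``max_mismatches`` substitutions.
Multi-mapping reads are reported at every such site.  The seed rule is part
of the public contract -- a brute-force scan with the same seed-visibility
rule reproduces the output exactly, blind spots included.

SAM import is provided for interoperability with external aligners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pysam
from Bio import SeqIO

from ._seq import INVALID, encode, kmer_hashes, revcomp_hashes


class Alignment(NamedTuple):
    read_id: str
    contig: str
    start: int          # 0-based
    strand: str         # '+' or '-'
    mismatches: int
    length: int


@dataclass
class AlignmentSet:
    """Column-oriented container of ungapped alignments."""

    read_ids: list[str]
    contig_names: list[str]
    read_index: np.ndarray
    contig_index: np.ndarray
    start: np.ndarray
    strand: np.ndarray          # bool, True = '-'
    mismatches: np.ndarray
    length: np.ndarray
    skipped_short: int = 0

    def __len__(self) -> int:
        return self.start.size

    def __iter__(self) -> Iterator[Alignment]:
        for i in range(len(self)):
            yield Alignment(
                read_id=self.read_ids[self.read_index[i]],
                contig=self.contig_names[self.contig_index[i]],
                start=int(self.start[i]),
                strand="-" if self.strand[i] else "+",
                mismatches=int(self.mismatches[i]),
                length=int(self.length[i]),
            )

    def total_aligned_bases(self) -> int:
        return int(self.length.sum())


def _empty_alignments(read_ids, contig_names, skipped=0) -> AlignmentSet:
    z = np.empty(0, dtype=np.int64)
    return AlignmentSet(
        read_ids=list(read_ids),
        contig_names=list(contig_names),
        read_index=z,
        contig_index=z.copy(),
        start=z.copy(),
        strand=np.empty(0, bool),
        mismatches=z.copy(),
        length=z.copy(),
        skipped_short=skipped,
    )


class ReferenceIndex:
    """Exact seed_k-mer index over a set of reference contigs."""

    def __init__(self, contigs, seed_k: int = 31):
        if isinstance(contigs, (str,)) or hasattr(contigs, "__fspath__"):
            contigs = [
                (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(contigs), "fasta")
            ]
        elif isinstance(contigs, dict):
            contigs = list(contigs.items())
        self.seed_k = int(seed_k)
        self.names: list[str] = []
        codes: list[np.ndarray] = []
        for name, seq in contigs:
            c = encode(seq) if isinstance(seq, str) else np.asarray(seq, np.uint8)
            if c.size < seed_k:
                raise ValueError(
                    f"contig {name!r} shorter than seed_k={seed_k}"
                )
            self.names.append(name)
            codes.append(c)
        if not codes:
            raise ValueError("reference has no contigs")
        pad = np.full(self.seed_k, INVALID, dtype=np.uint8)
        parts: list[np.ndarray] = []
        offsets: list[int] = []
        pos = 0
        for c in codes:
            offsets.append(pos)
            parts.append(c)
            parts.append(pad)
            pos += c.size + pad.size
        self.concat = np.concatenate(parts)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([c.size for c in codes], dtype=np.int64)
        self.ends = self.offsets + self.lengths

        hashes, valid = kmer_hashes(self.concat, self.seed_k)
        pos_arr = np.nonzero(valid)[0].astype(np.int64)
        h = hashes[valid]
        order = np.argsort(h, kind="stable")
        h_sorted = h[order]
        self._seed_positions = pos_arr[order]
        self._uniq_hashes, first = np.unique(h_sorted, return_index=True)
        self._csr = np.append(first, h_sorted.size).astype(np.int64)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(zip(self.names, (int(l) for l in self.lengths)))

    def contig_of(self, global_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, global_pos, side="right") - 1


def _reads_to_matrix(reads):
    """Return (ids, list of (length, codes-matrix, row->read-index))."""
    if hasattr(reads, "codes"):  # ReadSet
        ids = [f"{reads.library_id}:{i}" for i in range(len(reads))]
        return ids, [(reads.read_length, reads.codes, np.arange(len(reads)))]
    ids = []
    seqs = []
    for rec in reads:
        if isinstance(rec, tuple):
            rid, seq = rec[0], rec[1]
        else:  # SeqRecord
            rid, seq = rec.id, str(rec.seq)
        ids.append(rid)
        seqs.append(seq)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    groups = []
    for L, idxs in sorted(by_len.items()):
        mat = np.empty((len(idxs), L), dtype=np.uint8)
        for r, i in enumerate(idxs):
            mat[r] = encode(seqs[i])
        groups.append((L, mat, np.asarray(idxs)))
    return ids, groups


def map_reads(
    reads,
    index: ReferenceIndex,
    max_mismatches: int = 5,
    batch_size: int = 25_000,
) -> AlignmentSet:
    """Map reads against an indexed reference, reporting all sites.

    Reads shorter than ``index.seed_k`` are skipped (and counted), not
    fatal.  Accepts a :class:`~sexscreen.synthetic.ReadSet`, an iterable of
    ``(id, sequence, ...)`` tuples, or Biopython ``SeqRecord`` objects.
    """
    ids, groups = _reads_to_matrix(reads)
    k = index.seed_k
    skipped = 0
    out_read: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    out_mm: list[np.ndarray] = []
    out_len: list[np.ndarray] = []

    for L, mat, row_ids in groups:
        if L < k:
            skipped += mat.shape[0]
            continue
        for b0 in range(0, mat.shape[0], batch_size):
            sub = mat[b0 : b0 + batch_size]
            rows = row_ids[b0 : b0 + batch_size]
            rc_sub = None
            hv = _window_hashes(sub, k)
            for is_minus in (False, True):
                cand_read, cand_start = _seed_candidates(hv, index, L, is_minus)
                if cand_read.size == 0:
                    continue
                if is_minus:
                    if rc_sub is None:
                        rev = sub[:, ::-1]
                        rc_sub = np.where(rev < 4, 3 - rev, rev)
                    oriented = rc_sub
                else:
                    oriented = sub
                # verify full-length ungapped extension
                win = index.concat[cand_start[:, None] + np.arange(L)]
                mm = np.count_nonzero(win != oriented[cand_read], axis=1)
                ok = mm <= max_mismatches
                if not ok.any():
                    continue
                out_read.append(rows[cand_read[ok]])
                out_start.append(cand_start[ok])
                out_strand.append(np.full(int(ok.sum()), is_minus))
                out_mm.append(mm[ok])
                out_len.append(np.full(int(ok.sum()), L, dtype=np.int64))

    if not out_read:
        return _empty_alignments(ids, index.names, skipped)
    read_idx = np.concatenate(out_read)
    gstart = np.concatenate(out_start)
    strand = np.concatenate(out_strand)
    mism = np.concatenate(out_mm).astype(np.int64)
    length = np.concatenate(out_len)
    contig_idx = index.contig_of(gstart)
    start_local = gstart - index.offsets[contig_idx]
    order = np.lexsort((strand, start_local, contig_idx, read_idx))
    return AlignmentSet(
        read_ids=ids,
        contig_names=list(index.names),
        read_index=read_idx[order],
        contig_index=contig_idx[order],
        start=start_local[order],
        strand=strand[order],
        mismatches=mism[order],
        length=length[order],
        skipped_short=skipped,
    )


def _window_hashes(mat: np.ndarray, k: int):
    """Flat per-(row, offset) k-mer hashes of a read matrix, plus validity."""
    n, L = mat.shape
    n_off = L - k + 1
    sep = np.full((n, 1), INVALID, dtype=np.uint8)
    flat = np.hstack([mat, sep]).ravel()
    hashes, valid = kmer_hashes(flat, k)
    stride = L + 1
    win_idx = (np.arange(n)[:, None] * stride + np.arange(n_off)).ravel()
    return hashes[win_idx], valid[win_idx], n_off


def _seed_candidates(hv, index: ReferenceIndex, L: int, is_minus: bool):
    """Unique (row, global start) placements with at least one exact seed.

    For the minus strand the forward-read k-mer hashes are
    reverse-complemented arithmetically: the k-mer at forward offset o is
    the k-mer at offset (n_off - 1 - o) of the reverse-complemented read.
    """
    h, v, n_off = hv
    k = index.seed_k
    if is_minus:
        h = revcomp_hashes(h, k)
    # which k-mers exist in the reference
    loc = np.searchsorted(index._uniq_hashes, h)
    loc_c = np.minimum(loc, index._uniq_hashes.size - 1)
    hit = v & (index._uniq_hashes[loc_c] == h)
    if not hit.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    hit_idx = np.nonzero(hit)[0]
    rows = hit_idx // n_off
    offs = hit_idx % n_off
    if is_minus:
        offs = n_off - 1 - offs
    u = loc_c[hit_idx]
    counts = index._csr[u + 1] - index._csr[u]
    rep_rows = np.repeat(rows, counts)
    rep_offs = np.repeat(offs, counts)
    # expand CSR ranges into flat position-array indices
    pos_idx = _expand_ranges(index._csr[u], counts)
    seed_pos = index._seed_positions[pos_idx]
    cand = seed_pos - rep_offs
    # candidate window must lie fully inside one contig
    contig = index.contig_of(np.maximum(cand, 0))
    ok = (cand >= index.offsets[contig]) & (cand + L <= index.ends[contig])
    cand = cand[ok]
    rep_rows = rep_rows[ok]
    if cand.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    key = rep_rows.astype(np.int64) * np.int64(index.concat.size) + cand
    uniq = np.unique(key)
    return (uniq // index.concat.size).astype(np.int64), (
        uniq % index.concat.size
    ).astype(np.int64)


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for each (s, c) pair, vectorised."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64)
    out = np.ones(total, dtype=np.int64)
    ends = np.cumsum(counts)
    out[0] = starts[0]
    out[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1] - 1)
    return np.cumsum(out)


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageSet:
    """Per-contig depth arrays for one library."""

    library_id: str
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def total_depth_mass(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))

    def covered_mask(self, contig: str, min_depth: int = 1) -> np.ndarray:
        return self.depth[contig] >= min_depth


def coverage_track(
    alignments: AlignmentSet,
    contig_lengths: dict[str, int],
    library_id: str = "",
) -> CoverageSet:
    """Per-base depth from ungapped alignments (depth over [start, start+length))."""
    cov = CoverageSet(library_id=library_id)
    name_to_i = {n: i for i, n in enumerate(alignments.contig_names)}
    for contig, L in contig_lengths.items():
        diff = np.zeros(L + 1, dtype=np.int64)
        ci = name_to_i.get(contig)
        if ci is not None:
            sel = alignments.contig_index == ci
            starts = alignments.start[sel]
            ends = starts + alignments.length[sel]
            if np.any(starts < 0) or np.any(ends > L):
                bad = np.nonzero((starts < 0) | (ends > L))[0][0]
                raise ValueError(
                    f"alignment overhangs contig {contig!r}: "
                    f"[{starts[bad]}, {ends[bad]}) vs length {L}"
                )
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        cov.depth[contig] = np.cumsum(diff[:-1]).astype(np.int32)
    return cov


def import_alignments(
    path,
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> AlignmentSet:
    """Load mapped records from SAM/BAM into the internal alignment form.

    Primary mapped records only by default; mismatch counts come from the
    NM tag when present.  Aligned length is the reference span of the
    record, which for the ungapped alignments this package emits equals the
    read length.
    """
    read_ids: list[str] = []
    rid_of: dict[str, int] = {}
    rows = {"read": [], "contig": [], "start": [], "strand": [], "mm": [], "len": []}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        contig_names = list(fh.references)
        cidx = {n: i for i, n in enumerate(contig_names)}
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_secondary and not include_secondary:
                continue
            if rec.is_supplementary and not include_supplementary:
                continue
            rid = rec.query_name
            if rid not in rid_of:
                rid_of[rid] = len(read_ids)
                read_ids.append(rid)
            rows["read"].append(rid_of[rid])
            rows["contig"].append(cidx[rec.reference_name])
            rows["start"].append(rec.reference_start)
            rows["strand"].append(rec.is_reverse)
            rows["mm"].append(rec.get_tag("NM") if rec.has_tag("NM") else 0)
            rows["len"].append(rec.reference_length or rec.query_length)
    return AlignmentSet(
        read_ids=read_ids,
        contig_names=contig_names,
        read_index=np.asarray(rows["read"], dtype=np.int64),
        contig_index=np.asarray(rows["contig"], dtype=np.int64),
        start=np.asarray(rows["start"], dtype=np.int64),
        strand=np.asarray(rows["strand"], dtype=bool),
        mismatches=np.asarray(rows["mm"], dtype=np.int64),
        length=np.asarray(rows["len"], dtype=np.int64),
    )
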