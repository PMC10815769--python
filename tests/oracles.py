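"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals beyond the
plain base-encoding helpers: mapping and primer scanning are re-derived by
exhaustive sliding-window comparison.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def rc_iupac(seq: str) -> str:
    return seq.translate(IUPAC_COMP)[::-1]


def brute_force_map(
    reads: list[tuple[str, str]],
    contigs: list[tuple[str, str]],
    seed_k: int = 31,
    max_mismatches: int = 5,
) -> set[tuple[str, str, int, str, int]]:
    """All (read_id, contig, start, strand, mismatches) placements where the
    oriented read has <= max_mismatches substitutions AND at least one exact
    seed_k-mer in common with the window (the mapper's seed-visibility rule).
    """
    out = set()
    for rid, seq in reads:
        if len(seq) < seed_k:
            continue
        for strand, s in (("+", seq), ("-", rc(seq))):
            L = len(s)
            for cname, cseq in contigs:
                for st in range(0, len(cseq) - L + 1):
                    win = cseq[st : st + L]
                    mm = sum(a != b for a, b in zip(win, s))
                    if mm > max_mismatches:
                        continue
                    if any(
                        win[o : o + seed_k] == s[o : o + seed_k]
                        for o in range(L - seed_k + 1)
                    ):
                        out.add((rid, cname, st, strand, mm))
    return out


def _mm_iupac(primer: str, window: str) -> int:
    return sum(w not in IUPAC[p] for p, w in zip(primer, window))


def brute_force_primer_scan(
    primer: str,
    contigs: list[tuple[str, str]],
    max_mismatches: int = 2,
) -> set[tuple[str, int, str, int]]:
    """All (contig, start, strand, mismatches) primer binding sites by
    exhaustive Hamming scan with IUPAC expansion."""
    out = set()
    m = len(primer)
    for strand, p in (("+", primer), ("-", rc_iupac(primer))):
        for cname, cseq in contigs:
            for st in range(0, len(cseq) - m + 1):
                mm = _mm_iupac(p, cseq[st : st + m])
                if mm <= max_mismatches:
                    out.add((cname, st, strand, mm))
    return out


def random_reads_from(
    rng: np.random.Generator,
    ref: str,
    n: int,
    min_len: int = 40,
    max_len: int = 120,
    max_mut: int = 6,
) -> list[tuple[str, str]]:
    """Reads drawn from a reference with random substitutions and strands."""
    bases = "ACGT"
    reads = []
    for i in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        st = int(rng.integers(0, len(ref) - ln + 1))
        s = list(ref[st : st + ln])
        for _ in range(int(rng.integers(0, max_mut + 1))):
            j = int(rng.integers(0, ln))
            s[j] = bases[(bases.index(s[j]) + int(rng.integers(1, 4))) % 4]
        seq = "".join(s)
        if rng.random() < 0.5:
            seq = rc(seq)
        reads.append((f"r{i}", seq))
    return reads
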