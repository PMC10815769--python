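"""Primer specificity, in-silico PCR, band patterns and genetic-sex calls.

A validated sex marker is a primer pair amplifying from the sex-specific
sequence.  Two marker classes occur in practice:

* dominant -- the pair targets heterosome-unique sequence; a band is
  present in the heterogametic sex and absent in the other;
* gametologous -- the pair spans a region present on both gametologs, with
  a length difference between them; the heterogametic sex shows two bands
  (one per gametolog) and the homogametic sex one, so the shared band acts
  as an internal amplification control.

Primer matching uses a uniform Hamming mismatch budget (default <= 2, both
strands).  IUPAC ambiguity codes in primers match every compatible base at
zero cost.  3'-end chemistry, melting temperature and dimer formation are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_MASK = np.zeros(256, dtype=np.uint8)
for _b, _m in IUPAC_MASK.items():
    _BASE_MASK[ord(_b)] = _m
    _BASE_MASK[ord(_b.lower())] = _m


def _seq_masks(seq: str) -> np.ndarray:
    m = _BASE_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(m == 0):
        bad = seq[int(np.nonzero(m == 0)[0][0])]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return m


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    product_range: tuple[int, int] = (50, 2000)

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(seq) <= 35:
                raise ValueError(
                    f"{label} primer of {self.name} must be 15-35 nt, got {len(seq)}"
                )
            _seq_masks(seq)  # validates the alphabet
        lo, hi = self.product_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid product size window {self.product_range}")


class BindingSite(NamedTuple):
    contig: str
    start: int          # 0-based start of the matched window on the plus strand
    strand: str         # '+': primer as given matches; '-': its revcomp matches
    mismatches: int


class Amplicon(NamedTuple):
    contig: str
    start: int
    end: int            # half-open; length = end - start
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BandPattern:
    individual_id: str
    bands: tuple[int, ...]        # merged distinct sizes, ascending
    marker_class: str = ""

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    call: Literal["female", "male", "invalid"]
    rule: str


def _scan(template_masks: np.ndarray, primer_masks: np.ndarray) -> np.ndarray:
    """Mismatch counts of the primer at every window start of the template."""
    m = primer_masks.size
    L = template_masks.size
    if L < m:
        return np.empty(0, dtype=np.int32)
    n = L - m + 1
    mm = np.zeros(n, dtype=np.int32)
    for j in range(m):
        mm += (template_masks[j : j + n] & primer_masks[j]) == 0
    return mm


def _as_contigs(reference) -> list[tuple[str, str]]:
    from ._seq import decode

    if isinstance(reference, dict):
        out = []
        for name, seq in reference.items():
            out.append((name, decode(seq) if isinstance(seq, np.ndarray) else seq))
        return out
    if isinstance(reference, str):
        return [("template", reference)]
    out = []
    for item in reference:
        name, seq = item
        out.append((name, decode(seq) if isinstance(seq, np.ndarray) else seq))
    return out


def primer_specificity(
    primer: str,
    reference,
    max_mismatches: int = 2,
) -> list[BindingSite]:
    """All binding sites of a primer on both strands of a reference.

    ``reference`` may be a dict of contig name to sequence (str or code
    array), an iterable of (name, sequence), or a bare sequence string.
    """
    if len(primer) < 15:
        raise ValueError(f"primer shorter than 15 nt: {primer!r}")
    pm = _seq_masks(primer)
    pm_rc = _seq_masks(reverse_complement(primer))
    sites: list[BindingSite] = []
    for name, seq in _as_contigs(reference):
        tm = _seq_masks(seq)
        for strand, masks in (("+", pm), ("-", pm_rc)):
            mm = _scan(tm, masks)
            for pos in np.nonzero(mm <= max_mismatches)[0]:
                sites.append(BindingSite(name, int(pos), strand, int(mm[pos])))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def in_silico_pcr(
    pair: PrimerPair,
    templates,
    max_mismatches: int = 2,
) -> list[Amplicon]:
    """Predicted amplicons of a primer pair over a set of templates.

    An amplicon spans from the 5' end of a plus-strand primer site to the
    5' end of a downstream minus-strand site of the partner primer,
    inclusive of both primer footprints; its length must fall inside the
    pair's product window.  Both primer orderings are considered, so the
    prediction is invariant under reverse-complementing the template.
    """
    lo, hi = pair.product_range
    amplicons: list[Amplicon] = []
    for name, seq in _as_contigs(templates):
        tm = _seq_masks(seq)
        combos = (
            (pair.forward, pair.reverse, False),
            (pair.reverse, pair.forward, True),
        )
        for left, right, swapped in combos:
            lm = _seq_masks(left)
            rm_rc = _seq_masks(reverse_complement(right))
            left_mm = _scan(tm, lm)
            right_mm = _scan(tm, rm_rc)
            left_pos = np.nonzero(left_mm <= max_mismatches)[0]
            right_pos = np.nonzero(right_mm <= max_mismatches)[0]
            if left_pos.size == 0 or right_pos.size == 0:
                continue
            right_end = right_pos + len(right)  # half-open end of the site
            for f in left_pos:
                # product window bounds on the 3' site
                lo_end = f + lo
                hi_end = f + hi
                i0, i1 = np.searchsorted(right_end, [lo_end, hi_end + 1])
                for j in range(i0, i1):
                    if right_pos[j] < f + len(left):
                        continue  # sites must not precede/overlap in reverse order
                    fm, rmm = int(left_mm[f]), int(right_mm[right_pos[j]])
                    if swapped:
                        fm, rmm = rmm, fm
                    amplicons.append(
                        Amplicon(
                            contig=name,
                            start=int(f),
                            end=int(right_end[j]),
                            forward_mismatches=fm,
                            reverse_mismatches=rmm,
                        )
                    )
    # the two orderings can describe the same product twice (palindromic
    # sites); keep unique spans
    uniq = {}
    for a in amplicons:
        uniq.setdefault((a.contig, a.start, a.end), a)
    return sorted(uniq.values(), key=lambda a: (a.contig, a.start, a.end))


def band_pattern(
    amplicons: Iterable[Amplicon],
    individual_id: str = "",
    gel_resolution: int = 20,
    marker_class: str = "",
) -> BandPattern:
    """Merge amplicon lengths into distinguishable gel bands.

    Lengths are single-linkage clustered: a new band starts whenever the
    gap to the previous length exceeds ``gel_resolution``; the reported
    band size is the rounded cluster mean.
    """
    lengths = sorted(a.length for a in amplicons)
    bands: list[int] = []
    cluster: list[int] = []
    for x in lengths:
        if cluster and x - cluster[-1] > gel_resolution:
            bands.append(int(round(sum(cluster) / len(cluster))))
            cluster = []
        cluster.append(x)
    if cluster:
        bands.append(int(round(sum(cluster) / len(cluster))))
    return BandPattern(
        individual_id=individual_id,
        bands=tuple(dict.fromkeys(bands)),
        marker_class=marker_class,
    )


MarkerClass = Literal["dominant", "gametologous", "non_specific"]


def classify_marker(
    pair: PrimerPair,
    female_genome,
    male_genome,
    system: str = "ZW",
    max_mismatches: int = 2,
    gel_resolution: int = 20,
) -> MarkerClass:
    """Classify a primer pair by its band patterns in the two sexes.

    dominant: bands only in the heterogametic sex; gametologous: both sexes
    amplify but the heterogametic sex shows more bands; anything else
    (identical patterns, or no amplification at all) is non_specific.
    """
    f_bands = band_pattern(
        in_silico_pcr(pair, female_genome, max_mismatches),
        gel_resolution=gel_resolution,
    ).bands
    m_bands = band_pattern(
        in_silico_pcr(pair, male_genome, max_mismatches),
        gel_resolution=gel_resolution,
    ).bands
    het, hom = (f_bands, m_bands) if system == "ZW" else (m_bands, f_bands)
    if het == hom:
        return "non_specific"
    if het and not hom:
        return "dominant"
    if het and hom and len(het) > len(hom):
        return "gametologous"
    return "non_specific"


def call_sex(
    pattern: BandPattern,
    marker_class: MarkerClass,
    system: str = "ZW",
) -> SexCall:
    """Genetic-sex decision from a band pattern.

    Under ZW: a dominant marker calls female on >= 1 band and male on 0; a
    gametologous marker calls female on 2 bands, male on 1 and invalid on 0
    (the shared band is an internal control, so no band means the reaction
    failed).  XY mirrors the calls.
    """
    if marker_class == "non_specific":
        raise ValueError("a non-specific marker cannot sex this system")
    if system not in ("ZW", "XY"):
        raise ValueError(f"unknown system {system!r}")
    het_sex = "female" if system == "ZW" else "male"
    hom_sex = "male" if system == "ZW" else "female"
    n = pattern.n_bands
    if marker_class == "dominant":
        call = het_sex if n >= 1 else hom_sex
        rule = f"dominant/{system}: {'band' if n else 'no band'}"
    elif marker_class == "gametologous":
        if n >= 2:
            call, rule = het_sex, f"gametologous/{system}: two bands"
        elif n == 1:
            call, rule = hom_sex, f"gametologous/{system}: one band"
        else:
            call, rule = "invalid", "gametologous: no bands (control failure)"
    else:
        raise ValueError(f"unknown marker class {marker_class!r}")
    return SexCall(individual_id=pattern.individual_id, call=call, rule=rule)
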