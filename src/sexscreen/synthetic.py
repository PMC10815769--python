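"""Ground-truthed synthetic diploid ZW/XY genomes, cohorts and reads.

The generator emulates the situation the screening workflow is built for: a
diploid species with genotypic sex determination whose heterogametic sex
carries sequence absent from the other sex.  A genome consists of

* one or more autosomes, shared by both sexes, carrying biallelic
  presence/absence "trap" loci (insertion allele A at Hardy-Weinberg
  frequency p) that can mimic sex linkage in small samples;
* a gametologous pair: a homogametic-pair chromosome (Z or X) and a
  heterosome copy (W or Y) diverged from it by point substitutions;
* heterosome-unique insertions -- the ground-truth sex-specific intervals
  the screen is expected to recover.

Everything is deterministic under the spec seed, so read sets, references
and truth files regenerate bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import decode, encode, revcomp_codes

Sex = Literal["female", "male"]

# phred 30 for every simulated base; QC fixtures write their own strings
DEFAULT_QUAL_CHAR = chr(30 + 33)


@dataclass(frozen=True)
class TrapLocus:
    """A biallelic autosomal insertion polymorphism.

    ``position`` is the 0-based insertion point on ``autosome`` (the
    insertion sits between position-1 and position); allele A carries
    ``sequence``, allele a is the empty allele.
    """

    autosome: int
    position: int
    sequence: str
    p: float


@dataclass
class SexGenomeSpec:
    system: Literal["ZW", "XY"]
    autosomes: list[np.ndarray]          # base sequences, no insertions
    shared_core: np.ndarray              # Z (or X) gametolog sequence
    hetero_gametolog: np.ndarray         # diverged W (or Y) copy, pre-insertion
    unique_seqs: list[np.ndarray]        # heterosome-unique insertions
    unique_positions: list[int]          # insertion points in gametolog coords
    gametolog_divergence: float
    trap_loci: list[TrapLocus]
    seed: int

    @property
    def heterogametic_sex(self) -> Sex:
        return "female" if self.system == "ZW" else "male"

    @property
    def homogametic_sex(self) -> Sex:
        return "male" if self.system == "ZW" else "female"

    @property
    def pair_name(self) -> str:
        """Name of the chromosome both sexes carry (Z or X)."""
        return "Z" if self.system == "ZW" else "X"

    @property
    def hetero_name(self) -> str:
        """Name of the heterogametic-sex-specific chromosome (W or Y)."""
        return "W" if self.system == "ZW" else "Y"

    def autosome_name(self, i: int) -> str:
        return f"chr{i + 1}"

    def heterosome_codes(self) -> np.ndarray:
        """Full W (or Y) sequence: diverged gametolog + unique insertions."""
        parts: list[np.ndarray] = []
        prev = 0
        for pos, seq in zip(self.unique_positions, self.unique_seqs):
            parts.append(self.hetero_gametolog[prev:pos])
            parts.append(seq)
            prev = pos
        parts.append(self.hetero_gametolog[prev:])
        return np.concatenate(parts)

    def truth_intervals(self) -> list[tuple[str, int, int]]:
        """Unique-insertion intervals on the heterosome, 0-based half-open."""
        out = []
        shift = 0
        for pos, seq in zip(self.unique_positions, self.unique_seqs):
            start = pos + shift
            out.append((self.hetero_name, start, start + len(seq)))
            shift += len(seq)
        return out


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex
    karyotype: str                      # "ZW", "ZZ", "XX", "XY"
    genotypes: tuple[str, ...]          # per trap locus: "AA" | "Aa" | "aa"


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort."""

    intervals: list[tuple[str, int, int]]
    trap_states: dict[str, tuple[str, ...]]
    system: str

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig, start, end in self.intervals:
                fh.write(f"{contig}\t{start}\t{end}\n")

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "system": self.system,
                    "truth_intervals": [list(t) for t in self.intervals],
                    "trap_genotypes": {k: list(v) for k, v in self.trap_states.items()},
                },
                fh,
                indent=2,
            )


@dataclass
class Population:
    spec: SexGenomeSpec
    females: list[Individual]
    males: list[Individual]
    pool: list[Individual]
    truth: TruthSet

    @property
    def reference_female(self) -> Individual:
        return self.females[0]

    @property
    def reference_male(self) -> Individual:
        return self.males[0]


@dataclass
class ReadSet:
    """Simulated single-end reads held as an (n, read_length) code matrix."""

    library_id: str
    codes: np.ndarray
    read_length: int
    depth: float
    error_rate: float
    seed: int
    source: str = ""

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def ids(self):
        return (f"{self.library_id}:{i}" for i in range(len(self)))

    def sequences(self):
        for row in self.codes:
            yield decode(row)

    def records(self):
        qual = DEFAULT_QUAL_CHAR * self.read_length
        for rid, seq in zip(self.ids, self.sequences()):
            yield rid, seq, qual

    def write_fastq(self, path) -> None:
        quals = [30] * self.read_length
        records = (
            SeqRecord(
                Seq(seq),
                id=rid,
                description="",
                letter_annotations={"phred_quality": quals},
            )
            for rid, seq in zip(self.ids, self.sequences())
        )
        SeqIO.write(records, str(path), "fastq")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _diverge(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Copy with substitutions at ``rate`` (substituted base always changes)."""
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shift) % 4
    return out


def build_genome_spec(
    system: Literal["ZW", "XY"] = "ZW",
    autosome_length: int = 200_000,
    n_autosomes: int = 1,
    sex_shared_length: int = 20_000,
    unique_lengths: Sequence[int] = (2_000, 3_000, 5_000),
    gametolog_divergence: float = 0.02,
    n_traps: int = 10,
    trap_length: int = 400,
    trap_p_range: tuple[float, float] = (0.2, 0.8),
    trap_positions: Sequence[tuple[int, int]] | None = None,
    trap_ps: Sequence[float] | None = None,
    seed: int = 0,
) -> SexGenomeSpec:
    """Construct a deterministic synthetic genome layout.

    Trap insertion points are placed evenly spaced unless given explicitly as
    ``(autosome_index, position)`` pairs; explicit collisions (same point on
    the same autosome) raise with the offending loci listed.
    """
    if system not in ("ZW", "XY"):
        raise ValueError(f"system must be 'ZW' or 'XY', got {system!r}")
    if autosome_length <= 0 or sex_shared_length <= 0 or n_autosomes < 1:
        raise ValueError("genome dimensions must be positive")
    if not 0.0 <= gametolog_divergence <= 0.2:
        raise ValueError("gametolog_divergence must be in [0, 0.2]")
    if any(l <= 0 for l in unique_lengths):
        raise ValueError("unique region lengths must be positive")

    rng = _rng(seed, 0xA)
    autosomes = [_random_codes(rng, autosome_length) for _ in range(n_autosomes)]
    shared_core = _random_codes(rng, sex_shared_length)
    hetero = _diverge(rng, shared_core, gametolog_divergence)
    unique_seqs = [_random_codes(rng, l) for l in unique_lengths]
    k = len(unique_lengths)
    unique_positions = [
        int(round(sex_shared_length * (i + 1) / (k + 1))) for i in range(k)
    ]

    if trap_positions is None:
        margin = trap_length + 1_000
        positions: list[tuple[int, int]] = []
        per_auto = [n_traps // n_autosomes + (1 if i < n_traps % n_autosomes else 0)
                    for i in range(n_autosomes)]
        for a, cnt in enumerate(per_auto):
            if cnt == 0:
                continue
            span = autosome_length - 2 * margin
            if span <= 0 or span < cnt:
                raise ValueError("autosome too short for requested trap loci")
            # one locus per equal-width bin keeps loci apart deterministically
            width = span // cnt
            pts = margin + width * np.arange(cnt) + rng.integers(0, width, size=cnt)
            positions.extend((a, int(p)) for p in np.sort(pts))
        trap_positions = positions
    else:
        trap_positions = [(int(a), int(p)) for a, p in trap_positions]
        seen: dict[tuple[int, int], int] = {}
        collisions = []
        for i, key in enumerate(trap_positions):
            if key in seen:
                collisions.append((seen[key], i, key))
            seen[key] = i
        if collisions:
            msg = "; ".join(
                f"loci {i} and {j} both at autosome {a} position {p}"
                for i, j, (a, p) in collisions
            )
            raise ValueError(f"overlapping trap loci: {msg}")
        for a, p in trap_positions:
            if not (0 <= a < n_autosomes and 0 <= p <= autosome_length):
                raise ValueError(f"trap position ({a}, {p}) outside autosome bounds")
        n_traps = len(trap_positions)

    if trap_ps is None:
        lo, hi = trap_p_range
        trap_ps = rng.uniform(lo, hi, size=n_traps)
    trap_loci = [
        TrapLocus(
            autosome=a,
            position=pos,
            sequence=decode(_random_codes(rng, trap_length)),
            p=float(p),
        )
        for (a, pos), p in zip(trap_positions, trap_ps)
    ]
    return SexGenomeSpec(
        system=system,
        autosomes=autosomes,
        shared_core=shared_core,
        hetero_gametolog=hetero,
        unique_seqs=unique_seqs,
        unique_positions=unique_positions,
        gametolog_divergence=gametolog_divergence,
        trap_loci=trap_loci,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_genotypes(rng: np.random.Generator, loci: list[TrapLocus], n: int) -> np.ndarray:
    """(n, n_loci) array of genotype codes 0=AA, 1=Aa, 2=aa, HWE per locus."""
    out = np.empty((n, len(loci)), dtype=np.int8)
    for j, locus in enumerate(loci):
        p = locus.p
        freqs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
        out[:, j] = rng.choice(3, size=n, p=freqs)
    return out


_GT = ("AA", "Aa", "aa")


def simulate_population(
    spec: SexGenomeSpec,
    n_females: int = 3,
    n_males: int = 3,
    pool_size: int = 15,
    seed: int = 0,
    force_trap: int | None = None,
) -> Population:
    """Draw a cohort of genotyped individuals plus a single-sex pool.

    Pool members are of the homogametic sex (males under ZW, females under
    XY).  ``force_trap`` engineers the named trap locus into a perfect
    pseudo-marker for the screened group (heterogametic group all Aa,
    homogametic group all aa); the pool keeps Hardy-Weinberg draws.
    """
    if min(n_females, n_males, pool_size) < 0:
        raise ValueError("counts must be >= 0")
    if force_trap is not None and not 0 <= force_trap < len(spec.trap_loci):
        raise ValueError(f"force_trap index {force_trap} out of range")
    rng = _rng(spec.seed, 0xB, seed)
    het_kary = "ZW" if spec.system == "ZW" else "XY"
    hom_kary = "ZZ" if spec.system == "ZW" else "XX"

    def make(prefix: str, sex: Sex, kary: str, count: int) -> list[Individual]:
        gts = _draw_genotypes(rng, spec.trap_loci, count)
        return [
            Individual(
                id=f"{prefix}{i + 1}",
                sex=sex,
                karyotype=kary,
                genotypes=tuple(_GT[g] for g in gts[i]),
            )
            for i in range(count)
        ]

    females = make("F", "female", het_kary if spec.system == "ZW" else "XX", n_females)
    males = make("M", "male", "ZZ" if spec.system == "ZW" else het_kary, n_males)
    pool_sex = spec.homogametic_sex
    pool_kary = hom_kary
    pool = make("P", pool_sex, pool_kary, pool_size)

    if force_trap is not None:
        het_group = females if spec.heterogametic_sex == "female" else males
        hom_group = males if spec.heterogametic_sex == "female" else females
        het_group[:] = [
            Individual(ind.id, ind.sex, ind.karyotype,
                       _set_gt(ind.genotypes, force_trap, "Aa"))
            for ind in het_group
        ]
        hom_group[:] = [
            Individual(ind.id, ind.sex, ind.karyotype,
                       _set_gt(ind.genotypes, force_trap, "aa"))
            for ind in hom_group
        ]

    truth = TruthSet(
        intervals=spec.truth_intervals(),
        trap_states={
            ind.id: ind.genotypes for ind in (*females, *males, *pool)
        },
        system=spec.system,
    )
    return Population(spec=spec, females=females, males=males, pool=pool, truth=truth)


def _set_gt(gts: tuple[str, ...], idx: int, value: str) -> tuple[str, ...]:
    lst = list(gts)
    lst[idx] = value
    return tuple(lst)


def _autosome_haplotype(
    spec: SexGenomeSpec, autosome: int, carry: Sequence[bool]
) -> np.ndarray:
    """Autosome sequence with trap insertions for the loci flagged in carry."""
    base = spec.autosomes[autosome]
    parts: list[np.ndarray] = []
    prev = 0
    for locus, has in zip(spec.trap_loci, carry):
        if locus.autosome != autosome or not has:
            continue
        parts.append(base[prev:locus.position])
        parts.append(encode(locus.sequence))
        prev = locus.position
    parts.append(base[prev:])
    return np.concatenate(parts) if len(parts) > 1 else base


def individual_haplotypes(
    spec: SexGenomeSpec, individual: Individual
) -> list[tuple[str, np.ndarray]]:
    """The two haplotypes per chromosome of one individual, as code arrays.

    An Aa genotype places the insertion on the first haplotype only; aa
    individuals carry zero copies of the trap insertion.
    """
    haps: list[tuple[str, np.ndarray]] = []
    for a in range(len(spec.autosomes)):
        loci_here = [i for i, l in enumerate(spec.trap_loci) if l.autosome == a]
        carry0 = [individual.genotypes[i] in ("AA", "Aa") if i in loci_here else False
                  for i in range(len(spec.trap_loci))]
        carry1 = [individual.genotypes[i] == "AA" if i in loci_here else False
                  for i in range(len(spec.trap_loci))]
        name = spec.autosome_name(a)
        haps.append((f"{name}_hap1", _autosome_haplotype(spec, a, carry0)))
        haps.append((f"{name}_hap2", _autosome_haplotype(spec, a, carry1)))
    pair = spec.pair_name
    if individual.sex == spec.heterogametic_sex:
        haps.append((pair, spec.shared_core))
        haps.append((spec.hetero_name, spec.heterosome_codes()))
    else:
        haps.append((f"{pair}_hap1", spec.shared_core))
        haps.append((f"{pair}_hap2", spec.shared_core.copy()))
    return haps


@dataclass
class ReferenceAssembly:
    """Collapsed per-sex reference with ground-truth annotation."""

    contigs: dict[str, np.ndarray]
    truth_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    trap_intervals: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: codes.size for name, codes in self.contigs.items()}

    def sequence(self, contig: str, start: int, end: int) -> str:
        return decode(self.contigs[contig][start:end])

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(decode(codes)), id=name, description="")
            for name, codes in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def reference_assembly(spec: SexGenomeSpec, individual: Individual) -> ReferenceAssembly:
    """Collapsed haploid-style assembly of one individual.

    Each autosome appears once and carries the insertion allele wherever the
    individual has at least one A copy (a collapsed diploid assembly retains
    the insertion); the gametologous pair contributes the Z (or X) core and,
    for the heterogametic sex, the full W (or Y).
    """
    contigs: dict[str, np.ndarray] = {}
    trap_intervals: list[tuple[str, int, int, int]] = []
    for a in range(len(spec.autosomes)):
        name = spec.autosome_name(a)
        shift = 0
        carry = [False] * len(spec.trap_loci)
        for i, locus in enumerate(spec.trap_loci):
            if locus.autosome != a:
                continue
            if individual.genotypes[i] in ("AA", "Aa"):
                carry[i] = True
                start = locus.position + shift
                trap_intervals.append((name, start, start + len(locus.sequence), i))
                shift += len(locus.sequence)
        contigs[name] = _autosome_haplotype(spec, a, carry)
    contigs[spec.pair_name] = spec.shared_core
    truth: list[tuple[str, int, int]] = []
    if individual.sex == spec.heterogametic_sex:
        contigs[spec.hetero_name] = spec.heterosome_codes()
        truth = spec.truth_intervals()
    return ReferenceAssembly(
        contigs=contigs, truth_intervals=truth, trap_intervals=trap_intervals
    )


# ---------------------------------------------------------------------------
# read simulation


def reads_from_sequences(
    sequences: Sequence[np.ndarray | str],
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.001,
    seed: int = 0,
    library_id: str = "lib",
    n_reads: int | None = None,
    source: str = "",
) -> ReadSet:
    """Uniform single-end reads over a set of template sequences.

    ``depth`` is coverage per template position: the expected read count is
    ``depth * total_length / read_length`` unless ``n_reads`` overrides it.
    Reads come off either strand with equal probability; sequencing errors
    are independent substitutions at ``error_rate`` per base.
    """
    if depth <= 0 and n_reads is None:
        raise ValueError("depth must be positive")
    if read_length < 31:
        raise ValueError("read_length must be >= 31")
    codes = [encode(s) if isinstance(s, str) else np.asarray(s, np.uint8)
             for s in sequences]
    if any(c.size < read_length for c in codes):
        raise ValueError("read_length exceeds the shortest template")
    rng = _rng(seed, 0xC)
    concat = np.concatenate(codes)
    lengths = np.array([c.size for c in codes])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    valid = lengths - read_length + 1
    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    total_valid = int(cum_valid[-1])
    total_len = int(lengths.sum())
    if n_reads is None:
        n_reads = int(round(depth * total_len / read_length))
    u = rng.integers(0, total_valid, size=n_reads)
    tpl = np.searchsorted(cum_valid, u, side="right") - 1
    starts = offsets[tpl] + (u - cum_valid[tpl])
    reads = concat[starts[:, None] + np.arange(read_length)]
    flip = rng.random(n_reads) < 0.5
    if flip.any():
        rev = reads[flip, ::-1]
        reads[flip] = np.where(rev < 4, 3 - rev, rev)
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4
    return ReadSet(
        library_id=library_id,
        codes=reads,
        read_length=int(read_length),
        depth=float(depth),
        error_rate=float(error_rate),
        seed=int(seed),
        source=source,
    )


def simulate_reads(
    spec: SexGenomeSpec,
    source: Individual | Sequence[Individual],
    depth: float = 20.0,
    read_length: int = 100,
    error_rate: float = 0.001,
    seed: int = 0,
    library_id: str | None = None,
) -> ReadSet:
    """Sequence one individual, or a pooled library of several.

    For a single individual, ``depth`` is per-haplotype-position coverage.
    For a pool the same sequencing budget rule applies per mean individual
    genome: total reads = depth * mean_genome_length / read_length, spread
    uniformly over all pooled haplotypes (each pooled haplotype is therefore
    covered at roughly depth / pool_size).
    """
    if isinstance(source, Individual):
        individuals = [source]
        lib = library_id or source.id
        desc = source.id
        n_reads = None
    else:
        individuals = list(source)
        if not individuals:
            raise ValueError("empty pool")
        lib = library_id or "pool"
        desc = f"pool[{','.join(ind.id for ind in individuals)}]"
        n_reads = 0  # placeholder, computed below
    haps: list[np.ndarray] = []
    per_ind_lengths = []
    for ind in individuals:
        hs = [h for _, h in individual_haplotypes(spec, ind)]
        per_ind_lengths.append(sum(h.size for h in hs))
        haps.extend(hs)
    if n_reads is not None:
        mean_len = float(np.mean(per_ind_lengths))
        n_reads = int(round(depth * mean_len / read_length))
    return reads_from_sequences(
        haps,
        depth=depth,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
        library_id=lib,
        n_reads=n_reads,
        source=desc,
    )


def simulate_trap_removal(
    p: float, pool_size: int, replicates: int, seed: int = 0
) -> float:
    """Empirical probability that a pooled library unmasks a forced trap.

    A trap locus engineered to pass the small-group screen (heterogametic
    group all Aa, homogametic group all aa) is removed by the pool filter as
    soon as any of the 2N pooled alleles is the insertion allele A, i.e.
    whenever the Hardy-Weinberg pool contains at least one carrier; the
    closed form is 1 - q^(2N).  Pool genotypes are drawn per replicate and
    the carrier test applied, mirroring how pool coverage disqualifies the
    locus in the full pipeline.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = _rng(seed, 0xD)
    gts = rng.random((replicates, 2 * pool_size)) < p  # allele-level draws
    removed = gts.any(axis=1)
    return float(removed.mean())
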