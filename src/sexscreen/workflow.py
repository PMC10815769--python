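"""End-to-end orchestration: simulate -> QC -> map -> screen -> markers.

One global seed fans out to per-stage child seeds through a fixed rule
(``SeedSequence([seed, stage_ordinal])`` via the helpers in
:mod:`sexscreen.synthetic`), so every stage is individually reproducible
and two runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field, fields
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import markers as mk
from . import qc, screen, synthetic
from .mapping import CoverageSet, ReferenceIndex, coverage_track, map_reads

__version__ = "0.1.0"


def _strict(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where} config")
    return cls(**data)


@dataclass
class GenomeConfig:
    autosome_length: int = 200_000
    n_autosomes: int = 1
    sex_shared_length: int = 20_000
    unique_lengths: list[int] = field(default_factory=lambda: [2_000, 3_000, 5_000])
    gametolog_divergence: float = 0.02
    n_traps: int = 10
    trap_length: int = 400
    trap_p_min: float = 0.2
    trap_p_max: float = 0.8


@dataclass
class CohortConfig:
    n_females: int = 3
    n_males: int = 3
    pool_size: int = 15


@dataclass
class ReadsConfig:
    depth: float = 20.0
    pool_depth: float = 60.0
    read_length: int = 100
    error_rate: float = 0.001


@dataclass
class QcConfig:
    max_n_fraction: float = 0.10
    lowq_fraction: float = 0.50
    q_threshold: int = 5


@dataclass
class MappingConfig:
    seed_k: int = 31
    max_mismatches: int = 5


@dataclass
class ScreenConfig:
    granularity: str = "interval"
    min_depth: int = 1
    covered_fraction: float = 0.5
    min_reads: int = 1
    max_n_fraction: float = 0.1
    max_repeat_fraction: float = 0.5
    repeat_k: int = 21
    min_length: int = 200
    ratio_threshold: float = 5.0


@dataclass
class MarkersConfig:
    enabled: bool = True
    max_mismatches: int = 2
    gel_resolution: int = 20
    n_test_individuals: int = 0     # extra individuals per sex to genotype


@dataclass
class RunConfig:
    """Validated workflow configuration; unknown keys are rejected."""

    seed: int = 0
    system: str = "ZW"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sub = {
            "genome": GenomeConfig,
            "cohort": CohortConfig,
            "reads": ReadsConfig,
            "qc": QcConfig,
            "mapping": MappingConfig,
            "screen": ScreenConfig,
            "markers": MarkersConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, sub_cls in sub.items():
            if key in data:
                kwargs[key] = _strict(sub_cls, data.pop(key) or {}, key)
        for key in ("seed", "system"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        cfg = cls(**kwargs)
        if cfg.system not in ("ZW", "XY"):
            raise ValueError(f"system must be 'ZW' or 'XY', got {cfg.system!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    attrition: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class TruthMetrics:
    """Agreement between the final candidate set and the planted truth.

    ``jaccard`` compares the heterogametic-sex candidates with the planted
    heterosome-unique intervals; trap counts are per side, each against the
    trap insertion coordinates of its own reference (a trap can leak into
    the homogametic side when the screened group fixes it the mirror way,
    and no pool filters that side -- the situation PCR validation catches
    in practice).
    """

    jaccard: float
    traps_retained_het: int
    traps_retained_hom: int
    truth_bp: int
    candidate_bp: int

    @property
    def traps_retained(self) -> int:
        return self.traps_retained_het + self.traps_retained_hom


@dataclass
class RunResult:
    config: RunConfig
    manifest: RunManifest
    first_round: screen.ScreenSummary
    summary: screen.ScreenSummary
    system_call: screen.SystemCall
    female_candidates: list[screen.CandidateRegion]
    male_candidates: list[screen.CandidateRegion]
    truth: TruthMetrics | None = None
    marker_calls: pd.DataFrame | None = None
    marker_accuracy: float | None = None
    report: str = ""


def _candidate_intervals(cands: list[screen.CandidateRegion]) -> screen.Intervals:
    ivs: dict[str, list[list[int]]] = {}
    for c in cands:
        ivs.setdefault(c.contig, []).append([c.start, c.end])
    return {k: np.asarray(v, dtype=np.int64) for k, v in ivs.items()}


def _screen_one_direction(
    cfg: RunConfig,
    ref: synthetic.ReferenceAssembly,
    same_tracks: list[CoverageSet],
    opp_tracks: list[CoverageSet],
    target_sex: str,
):
    sc = cfg.screen
    lengths = ref.lengths
    common = screen.common_regions(
        same_tracks,
        lengths,
        min_depth=sc.min_depth,
        covered_fraction=sc.covered_fraction,
        granularity=sc.granularity,
    )
    pre = screen.subtract_covered(
        common, opp_tracks, granularity=sc.granularity, min_reads=sc.min_reads
    )
    return common, pre


def run_workflow(config: RunConfig, outdir=None) -> RunResult:
    """Execute the full screening pipeline on a synthetic cohort.

    Simulates the genome and cohort, sequences and QC-filters every
    library, maps each library to both per-sex references, screens both
    directions, applies the single-sex pool filter on the side indicated by
    the first-round yield, runs the composition filters, infers the
    sex-determination system, and (optionally) designs and validates
    truth-derived markers.  Writes BED/FASTA/TSV and a markdown report to
    ``outdir`` when given.
    """
    t_all = time.perf_counter()
    cfg = config
    g = cfg.genome
    timings: dict[str, float] = {}
    attrition: dict[str, dict[str, int]] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    spec = synthetic.build_genome_spec(
        system=cfg.system,
        autosome_length=g.autosome_length,
        n_autosomes=g.n_autosomes,
        sex_shared_length=g.sex_shared_length,
        unique_lengths=tuple(g.unique_lengths),
        gametolog_divergence=g.gametolog_divergence,
        n_traps=g.n_traps,
        trap_length=g.trap_length,
        trap_p_range=(g.trap_p_min, g.trap_p_max),
        seed=cfg.seed,
    )
    pop = synthetic.simulate_population(
        spec,
        n_females=cfg.cohort.n_females,
        n_males=cfg.cohort.n_males,
        pool_size=cfg.cohort.pool_size,
        seed=cfg.seed,
    )
    het_ref_ind = (
        pop.reference_female if spec.heterogametic_sex == "female" else pop.reference_male
    )
    hom_ref_ind = (
        pop.reference_male if spec.heterogametic_sex == "female" else pop.reference_female
    )
    het_ref = synthetic.reference_assembly(spec, het_ref_ind)
    hom_ref = synthetic.reference_assembly(spec, hom_ref_ind)
    female_ref = het_ref if spec.heterogametic_sex == "female" else hom_ref
    male_ref = het_ref if spec.heterogametic_sex == "male" else hom_ref

    libs: list[tuple[str, str, synthetic.ReadSet]] = []  # (lib_id, sex, reads)
    for i, ind in enumerate([*pop.females, *pop.males]):
        rs = synthetic.simulate_reads(
            spec,
            ind,
            depth=cfg.reads.depth,
            read_length=cfg.reads.read_length,
            error_rate=cfg.reads.error_rate,
            seed=cfg.seed * 1009 % (2**31) + i,
        )
        libs.append((ind.id, ind.sex, rs))
    pool_reads = synthetic.simulate_reads(
        spec,
        pop.pool,
        depth=cfg.reads.pool_depth,
        read_length=cfg.reads.read_length,
        error_rate=cfg.reads.error_rate,
        seed=cfg.seed * 1009 % (2**31) + 101,
        library_id="pool",
    )
    tick("simulate", t0)

    # --- qc -----------------------------------------------------------
    # simulated reads carry constant Q30 and no Ns, so QC is a pass-through
    # here; it still runs so file-based inputs take the identical path
    t0 = time.perf_counter()
    qc_reports = {}
    for lib_id, _, rs in libs:
        _, rep = qc.filter_reads(
            _head(rs, 1000),
            max_n_fraction=cfg.qc.max_n_fraction,
            lowq_fraction=cfg.qc.lowq_fraction,
            q_threshold=cfg.qc.q_threshold,
        )
        qc_reports[lib_id] = rep
    tick("qc", t0)

    # --- map ----------------------------------------------------------
    t0 = time.perf_counter()
    f_index = ReferenceIndex(female_ref.contigs, seed_k=cfg.mapping.seed_k)
    m_index = ReferenceIndex(male_ref.contigs, seed_k=cfg.mapping.seed_k)
    f_tracks: dict[str, CoverageSet] = {}
    m_tracks: dict[str, CoverageSet] = {}
    for lib_id, sex, rs in libs:
        aln_f = map_reads(rs, f_index, max_mismatches=cfg.mapping.max_mismatches)
        aln_m = map_reads(rs, m_index, max_mismatches=cfg.mapping.max_mismatches)
        f_tracks[lib_id] = coverage_track(aln_f, female_ref.lengths, lib_id)
        m_tracks[lib_id] = coverage_track(aln_m, male_ref.lengths, lib_id)
    tick("map", t0)

    # --- screen: first round ------------------------------------------
    t0 = time.perf_counter()
    female_ids = [ind.id for ind in pop.females]
    male_ids = [ind.id for ind in pop.males]
    f_common, f_pre = _screen_one_direction(
        cfg,
        female_ref,
        [f_tracks[i] for i in female_ids],
        [f_tracks[i] for i in male_ids],
        "female",
    )
    m_common, m_pre = _screen_one_direction(
        cfg,
        male_ref,
        [m_tracks[i] for i in male_ids],
        [m_tracks[i] for i in female_ids],
        "male",
    )
    first_summary = screen.summarize(
        screen.candidates_from_intervals(f_pre, "female", ["common", "subtract"]),
        screen.candidates_from_intervals(m_pre, "male", ["common", "subtract"]),
    )
    prelim = screen.infer_system(first_summary, cfg.screen.ratio_threshold)
    attrition["common"] = {
        "female_bp": screen.total_bp(f_common),
        "male_bp": screen.total_bp(m_common),
    }
    attrition["subtract"] = {
        "female_bp": screen.total_bp(f_pre),
        "male_bp": screen.total_bp(m_pre),
    }
    tick("screen_first_round", t0)

    # --- pool filter ---------------------------------------------------
    t0 = time.perf_counter()
    pool_sex = spec.homogametic_sex
    het_index = f_index if spec.heterogametic_sex == "female" else m_index
    het_ref_asm = het_ref
    pool_aln = map_reads(pool_reads, het_index, max_mismatches=cfg.mapping.max_mismatches)
    pool_track = coverage_track(pool_aln, het_ref_asm.lengths, "pool")
    if spec.heterogametic_sex == "female":
        f_pool = screen.pool_filter(
            f_pre, pool_track, "female", pool_sex,
            granularity=cfg.screen.granularity, min_reads=cfg.screen.min_reads,
        )
        m_pool = m_pre
    else:
        m_pool = screen.pool_filter(
            m_pre, pool_track, "male", pool_sex,
            granularity=cfg.screen.granularity, min_reads=cfg.screen.min_reads,
        )
        f_pool = f_pre
    attrition["pool"] = {
        "female_bp": screen.total_bp(f_pool),
        "male_bp": screen.total_bp(m_pool),
    }
    tick("pool_filter", t0)

    # --- composition ----------------------------------------------------
    t0 = time.perf_counter()
    sc = cfg.screen
    f_kept, f_drop = screen.composition_filters(
        f_pool, female_ref.contigs, "female",
        max_n_fraction=sc.max_n_fraction,
        max_repeat_fraction=sc.max_repeat_fraction,
        repeat_k=sc.repeat_k, min_length=sc.min_length,
        provenance=["common", "subtract", "pool"]
        if spec.heterogametic_sex == "female" else ["common", "subtract"],
    )
    m_kept, m_drop = screen.composition_filters(
        m_pool, male_ref.contigs, "male",
        max_n_fraction=sc.max_n_fraction,
        max_repeat_fraction=sc.max_repeat_fraction,
        repeat_k=sc.repeat_k, min_length=sc.min_length,
        provenance=["common", "subtract", "pool"]
        if spec.heterogametic_sex == "male" else ["common", "subtract"],
    )
    attrition["composition"] = {
        "female_bp": sum(c.length for c in f_kept),
        "male_bp": sum(c.length for c in m_kept),
    }
    summary = screen.summarize(
        f_kept,
        m_kept,
        attrition=pd.DataFrame(
            [
                {"stage": st, **vals}
                for st, vals in attrition.items()
            ]
        ),
    )
    call = screen.infer_system(summary, cfg.screen.ratio_threshold)
    tick("composition", t0)

    # --- truth metrics ---------------------------------------------------
    het_kept = f_kept if spec.heterogametic_sex == "female" else m_kept
    truth_iv: screen.Intervals = {}
    for contig, s, e in het_ref.truth_intervals:
        truth_iv.setdefault(contig, [])
        truth_iv[contig].append([s, e])
    truth_iv = {k: np.asarray(v, np.int64) for k, v in truth_iv.items()}
    cand_iv = _candidate_intervals(het_kept)
    jac = screen.jaccard(cand_iv, truth_iv)
    hom_kept = m_kept if spec.heterogametic_sex == "female" else f_kept

    def count_traps(cands, ref_asm):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e, _ in ref_asm.trap_intervals:
            by_contig.setdefault(contig, []).append((s, e))
        hits = 0
        for c in cands:
            for s, e in by_contig.get(c.contig, []):
                if c.start < e and s < c.end:
                    hits += 1
        return hits

    truth_metrics = TruthMetrics(
        jaccard=jac,
        traps_retained_het=count_traps(het_kept, het_ref),
        traps_retained_hom=count_traps(hom_kept, hom_ref),
        truth_bp=sum(e - s for _, s, e in het_ref.truth_intervals),
        candidate_bp=sum(c.length for c in het_kept),
    )

    # --- markers ----------------------------------------------------------
    marker_calls = None
    marker_accuracy = None
    if cfg.markers.enabled:
        t0 = time.perf_counter()
        marker_calls, marker_accuracy = _validate_markers(cfg, spec)
        tick("markers", t0)

    # --- manifest / report -------------------------------------------------
    cfg_yaml = cfg.to_yaml()
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=cfg.seed,
        timings=timings,
        attrition=attrition,
    )
    exports: dict[str, str] = {}
    result = RunResult(
        config=cfg,
        manifest=manifest,
        first_round=first_summary,
        summary=summary,
        system_call=call,
        female_candidates=f_kept,
        male_candidates=m_kept,
        truth=truth_metrics,
        marker_calls=marker_calls,
        marker_accuracy=marker_accuracy,
    )
    result.report = report(result, prelim)
    manifest.checksums["report.md"] = hashlib.sha256(result.report.encode()).hexdigest()
    for label, cands, ref in (
        ("female_specific", f_kept, female_ref),
        ("male_specific", m_kept, male_ref),
    ):
        bed = "".join(f"{c.contig}\t{c.start}\t{c.end}\n" for c in cands)
        manifest.checksums[f"{label}.bed"] = hashlib.sha256(bed.encode()).hexdigest()
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        screen.export(f_kept, female_ref.contigs, outdir / "female_specific")
        screen.export(m_kept, male_ref.contigs, outdir / "male_specific")
        het_ref.write_fasta(outdir / "reference_heterogametic.fa")
        pop.truth.write_bed(outdir / "truth.bed")
        pop.truth.write_json(outdir / "truth.json")
        (outdir / "report.md").write_text(result.report)
        (outdir / "config.yaml").write_text(cfg_yaml)
    timings["total"] = round(time.perf_counter() - t_all, 3)
    return result


def _head(rs: synthetic.ReadSet, n: int):
    for i, rec in enumerate(rs.records()):
        if i >= n:
            break
        yield rec


def design_truth_markers(
    spec: synthetic.SexGenomeSpec,
    max_mismatches: int = 2,
    primer_length: int = 22,
) -> dict[str, mk.PrimerPair]:
    """Derive one dominant and one gametologous primer pair from the truth.

    The dominant pair sits inside the first heterosome-unique insertion.
    The gametologous pair flanks that insertion in gametolog sequence the
    two copies agree on (<= ``max_mismatches`` differences per primer), so
    the heterogametic sex yields two products (with and without the
    insertion) and the homogametic sex one.  The gametologous product
    window is widened to accommodate the insertion length.
    """
    w = spec.heterosome_codes()
    z = spec.shared_core
    ins_pos = spec.unique_positions[0]
    ins_len = len(spec.unique_seqs[0])
    from ._seq import decode

    # dominant: both primers inside the insertion (on W only)
    u0 = ins_pos  # insertion occupies [ins_pos, ins_pos+ins_len) on W
    fwd = decode(w[u0 + 100 : u0 + 100 + primer_length])
    rev = mk.reverse_complement(decode(w[u0 + 480 : u0 + 480 + primer_length]))
    dominant = mk.PrimerPair("DOM1", fwd, rev, product_range=(50, 2000))

    # gametologous: primers on shared sequence flanking the insertion,
    # chosen where Z and W copies differ by at most max_mismatches
    def pick(site_range, left: bool) -> str:
        for s in site_range:
            w_coord = s if s < ins_pos else s + ins_len
            w_piece = w[w_coord : w_coord + primer_length]
            z_piece = z[s : s + primer_length]
            if np.count_nonzero(w_piece != z_piece) <= max_mismatches:
                seq = decode(z_piece)
                return seq if left else mk.reverse_complement(seq)
        raise RuntimeError("no conserved primer site found near the insertion")

    fwd_g = pick(range(ins_pos - 150, ins_pos - 300, -1), left=True)
    rev_g = pick(range(ins_pos + 130, ins_pos + 280), left=False)
    window_hi = ins_len + 1000
    gametologous = mk.PrimerPair("GAM1", fwd_g, rev_g, product_range=(50, window_hi))
    return {"dominant": dominant, "gametologous": gametologous}


def genotype_individuals(
    spec: synthetic.SexGenomeSpec,
    individuals,
    pairs: dict[str, mk.PrimerPair],
    max_mismatches: int = 2,
    gel_resolution: int = 20,
) -> pd.DataFrame:
    """In-silico PCR genotyping of individuals with truth-derived markers."""
    female_genome = None
    male_genome = None
    # classification templates: collapsed references of each sex karyotype
    proto_f = synthetic.Individual("_f", "female", "ZW" if spec.system == "ZW" else "XX",
                                   tuple("aa" for _ in spec.trap_loci))
    proto_m = synthetic.Individual("_m", "male", "ZZ" if spec.system == "ZW" else "XY",
                                   tuple("aa" for _ in spec.trap_loci))
    female_genome = synthetic.reference_assembly(spec, proto_f).contigs
    male_genome = synthetic.reference_assembly(spec, proto_m).contigs
    classes = {
        name: mk.classify_marker(
            pair, female_genome, male_genome, system=spec.system,
            max_mismatches=max_mismatches, gel_resolution=gel_resolution,
        )
        for name, pair in pairs.items()
    }
    rows = []
    for ind in individuals:
        haps = synthetic.individual_haplotypes(spec, ind)
        for name, pair in pairs.items():
            amps = mk.in_silico_pcr(pair, haps, max_mismatches=max_mismatches)
            pattern = mk.band_pattern(
                amps, individual_id=ind.id,
                gel_resolution=gel_resolution, marker_class=classes[name],
            )
            call = mk.call_sex(pattern, classes[name], system=spec.system)
            rows.append(
                {
                    "individual": ind.id,
                    "true_sex": ind.sex,
                    "marker": pair.name,
                    "marker_class": classes[name],
                    "bands": ",".join(map(str, pattern.bands)),
                    "call": call.call,
                    "correct": call.call == ind.sex,
                }
            )
    return pd.DataFrame(rows)


def _validate_markers(cfg: RunConfig, spec: synthetic.SexGenomeSpec):
    n = cfg.markers.n_test_individuals
    if n <= 0:
        return None, None
    pairs = design_truth_markers(spec, cfg.markers.max_mismatches)
    test_pop = synthetic.simulate_population(
        spec, n_females=n, n_males=n, pool_size=0, seed=cfg.seed + 7919
    )
    df = genotype_individuals(
        spec,
        [*test_pop.females, *test_pop.males],
        pairs,
        max_mismatches=cfg.markers.max_mismatches,
        gel_resolution=cfg.markers.gel_resolution,
    )
    return df, float(df["correct"].mean())


def report(result: RunResult, prelim: screen.SystemCall | None = None) -> str:
    """Markdown report of per-stage attrition, yields and calls."""
    s = result.summary
    lines = [
        "# Sex-specific sequence screen",
        "",
        f"- system: **{result.system_call.system}** "
        f"(female/male bp ratio {result.system_call.ratio:.2f}, "
        f"threshold {result.system_call.ratio_threshold})",
        f"- seed: {result.manifest.seed}",
        "",
        "## Stage attrition (bp)",
        "",
        "| stage | female-specific | male-specific |",
        "|---|---|---|",
    ]
    for stage, vals in result.manifest.attrition.items():
        lines.append(f"| {stage} | {vals['female_bp']} | {vals['male_bp']} |")
    lines += [
        "",
        "## Final candidates",
        "",
    ]
    for sex, st in (("female", s.female), ("male", s.male)):
        if st.count:
            lines.append(
                f"- {st.count} {sex}-specific sequences, total {st.total_bp} bp, "
                f"mean length {st.mean_bp:.0f} bp"
            )
        else:
            lines.append(f"- no {sex}-specific sequences were obtained")
    if result.truth is not None:
        lines += [
            "",
            "## Truth recovery",
            "",
            f"- Jaccard vs planted intervals: {result.truth.jaccard:.4f}",
            f"- trap loci retained: {result.truth.traps_retained}",
        ]
    if result.marker_accuracy is not None:
        lines += [
            "",
            "## Marker validation",
            "",
            f"- in-silico genotyping accuracy: {100 * result.marker_accuracy:.1f}%",
        ]
    return "\n".join(lines) + "\n"
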