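# Methods

This note records the models implemented in `sexscreen`, the defaults and
why they were chosen, and what the synthetic benchmarks do and do not show
about real data.

## 1. Pseudo-marker error models

Setting: a diploid species with genotypic sex determination; a biallelic
autosomal locus with insertion allele A at frequency p, empty allele a at
q = 1 − p, genotypes at Hardy–Weinberg proportions (p², 2pq, q²). A
presence/absence screen over n females and n males mistakes the locus for
a sex marker when every heterogametic-sex individual is Aa and every
homogametic-sex individual is the matching homozygote. The per-locus
error probability implemented in `design.pseudo_marker_rate` is

    P_E(single system) = (pq)^n · [(p²/2)^n + (q²/2)^n]
    P_E(combined)      = 2 · P_E(single system)

Two modelling notes, both deliberate:

* The heterozygote sampling term is (pq)^n, not (2pq)^n, and the
  homozygote terms carry a factor 1/2 per individual. This is the
  convention of the sampling table this model family is built on, where
  each genotype class is split evenly between the two possible sex
  assignments. The cohort simulator, by contrast, draws genotypes from
  canonical Hardy–Weinberg (p², 2pq, q²); the two conventions answer
  different questions and are both exposed.
* The combined form doubles the single-system form because, with the
  system unknown, either sex may play the heterogametic role.

With p ~ Uniform(0, 1) (and q = 1 − p, not independently drawn — an
independent q inflates the mean ~70-fold), the exact mean of the combined
form is

    E[P_E] = 2^(2−n) · B(3n + 1, n + 1)

(`design.expected_rate_closed_form`), giving 0.1, 3.97e-3, 1.75e-4,
8.08e-6, 3.84e-7 for n = 1..5. The Monte-Carlo simulators are checked
against this closed form to 3 standard errors; the n = 3 mean, 1.748e-4,
prints as 0.0176% and is the basis for recommending at least three
individuals per sex.

### Pool model and the meaning of r

Sequencing a pool of N extra homogametic individuals multiplies each
homozygote term by r^(2N): r² is the probability that one pool member has
the "pure" genotype that keeps the pseudo-marker alive, so one carrier in
the pool kills it. The identity of r is under-determined in the
formulation this follows, so three policies are implemented
(`simulate_pool_design(r_policy=...)`):

* `literal_choice` (default): r is set to p or q with equal probability,
  one draw per iteration applied to the whole expression;
* `matched`: term-wise r — the term whose group homozygote class is AA
  gets r = p, the aa term gets r = q (the pool must repeat that class);
  its exact mean is B(3n + 1 + 2N, n + 1)/4 at n = 3, used as an oracle;
* `independent_per_individual`: a fresh Uniform(0, 1) frequency per pool
  member; the mean decays geometrically by E[r²] = 1/3 per member.

Under the literal per-term readings (`literal_choice`, `matched`) the mean
decays only polynomially in N (≈ (2N)^−4 at n = 3) and never reaches
1e-10 at practical pool sizes; only `independent_per_individual` crosses
1e-10, first at N = 13. `recommend_design` therefore reports an explicit
"not reached" where a threshold is unattainable rather than an answer.
This divergence between the literal formula and the commonly quoted
"maximum below 1e-10 near N = 15" is a documented property of the model
family, not reproduced by curve-fitting; all policies do satisfy the
defensible qualitative claims (rates non-increasing in N for shared
draws, pooled rate ≤ group rate).

All simulators draw from one seeded generator keyed by (seed, n), so a
pool run at N = 0 reproduces the group run bit-for-bit and identical
seeds give identical summaries.

## 2. Synthetic genomes and cohorts

`synthetic.build_genome_spec` emulates the minimal genome on which the
screen is decidable:

| parameter | default | rationale |
|---|---|---|
| autosome | 1 × 200 kb | large enough for ten well-separated traps, small enough to map in seconds |
| gametolog pair | 20 kb | shared Z/W core; W copy diverged |
| gametolog divergence | 2% substitutions | produces realistic cross-mapping (most reads from Z still place on W), so gametologous two-band markers and near-miss subtraction both arise naturally |
| W-unique insertions | 2, 3, 5 kb | the planted truth; sub-contig scale so interval-level screening is exercised |
| trap loci | 10, insertion 400 bp, p ∈ [0.2, 0.8] | mid-frequency alleles are the ones that actually generate pseudo-markers at n = 3 |
| reads | single-end 100 bp, 20× per individual, 0.1% substitution error, constant Q30 | single-end suffices because the screen consumes only coverage presence; pairing adds nothing at this scale |
| pool | 15 males (ZW), 60× | the pool budget is defined per mean individual genome and spread uniformly over all pooled haplotypes, so each pooled haplotype sits near depth/N ≈ 4×, comfortably above the coverage needed to reveal one carrier |

Base composition is uniform random; there are no indels, no GC bias, no
adapter sequence and no real nucleotide content of any organism. Reads,
genotypes and references regenerate bit-identically from (spec, seed).

What passing the synthetic benchmarks shows: the screening logic, the
strict subtraction semantics, the pool-filter mathematics and the marker
calling are correct on a genome whose truth is known exactly. What it
does not show: robustness to assembly fragmentation, collapsed repeats,
structural variation, mapping ambiguity at real repeat content, or
library-prep artefacts — on real data the mapper would also typically be
replaced by a production aligner through the SAM import path.

## 3. QC and k-mer genome size

Reads are removed when more than 10% of bases are N, then when more than
50% of bases have Phred ≤ 5 (both strict inequalities; thresholds are
arguments). Adapter trimming is out of scope because simulated reads
carry no adapters.

Genome size is estimated from the canonical 21-mer multiplicity spectrum
as total occurrences above the error trough divided by the homozygous
coverage peak. The trough is the first local minimum; the peak is the
modal multiplicity beyond it, refined in two passes to the
count-weighted centroid (first within ±40% of the mode, then within ±4
standard deviations of the first pass). The refinement exists because
the expected k-mer coverage, depth·(L−k+1)/L, is usually non-integral
while the mode is quantised; the centroid removes a ±1-bin wobble that
would otherwise cost several percent. A spectrum with no rise after the
trough (for example all-unique k-mers) returns an explicit undetermined
result rather than a number.

## 4. Mapping

The internal mapper is ungapped and exhaustively specified: a read is
reported at every position, on either strand, where (a) at least one
exact 31-mer of the read matches the reference and (b) the full-length
extension has at most 5 substitutions. Multi-mapping reads count toward
coverage at every reported site — conservative for subtraction, since
spurious opposite-sex coverage can only remove candidates, never create
them. The seed rule is part of the public contract: tests reproduce the
mapper's output, blind spots included, with a brute-force sliding-window
scan. Coordinates are 0-based half-open everywhere except human-readable
reports. There are no mapping qualities, no gapped alignment and no BAM
writing; SAM/BAM import covers interoperability.

## 5. Subtraction screen

Stage order and semantics (`screen`):

1. `common_regions` — interval granularity intersects the positions
   covered at ≥ 1 read in every same-sex library; sequence granularity
   keeps whole contigs in which each library covers ≥ 50% of bases (the
   0.5 is a package choice, exposed as `covered_fraction`).
2. `subtract_covered` — strict zero-coverage rule: one read from any
   opposite-sex library removes a base (interval mode) or disqualifies
   the whole contig (sequence mode). A `min_reads` knob exists for noisy
   real data; the default is the strict 1.
3. `pool_filter` — the same strict subtraction against the single-sex
   pool, validated to be of the homogametic sex for the target.
4. `composition_filters` — drop regions with > 10% N, regions whose
   21-mers recur elsewhere in the reference for > 50% of positions, and
   regions shorter than 200 bp (too short to design a useful PCR marker
   on). Every region carries provenance of the stages it passed or the
   filter that dropped it.

The packaged synthetic scenario screens at **interval** granularity even
though `common_regions` defaults to sequence granularity: the synthetic
references are chromosome-scale, so whole-contig screening would stand or
fall with the single W contig (which always carries some cross-mapped
male coverage on its gametolog). On fragmented real assemblies, where a
scaffold approximates a candidate unit, sequence granularity is the
appropriate default and is what the function-level default reflects.

The ZW/XY call compares total female-specific and male-specific yield:
ratio ≥ 5 calls ZW, ≤ 1/5 calls XY, otherwise undetermined. A 1 bp
pseudocount keeps the ratio finite when one side is empty — the expected
final state for the homogametic sex. A trap locus fixed the mirror way
(all males carriers, all females empty) can survive on the homogametic
side, where no pool screens it; the truth metrics report such leaks per
side, mirroring why first-round markers are PCR-validated in practice.

## 6. Markers

Primer matching uses a uniform Hamming budget (≤ 2 mismatches, both
strands); IUPAC codes in primers match compatible bases at zero cost.
3'-end mismatch chemistry, melting temperature, dimers and hairpins are
deliberately out of scope (primer design itself is not this package's
job). Amplicon length is inclusive of both primer footprints. Gel bands
merge when lengths lie within 20 bp (single linkage; `gel_resolution`
configurable; 20 bp approximates agarose resolution at marker scale).
Classification compares band patterns between the two sex genomes:
heterogametic-only bands → dominant; more heterogametic bands with a
shared band present → gametologous; identical patterns → non-specific.
For gametologous markers a zero-band individual is called invalid, not
male/female, because the shared band doubles as an amplification control.

The truth-derived gametologous demo marker spans a multi-kb synthetic
insertion, so its product window is widened to insertion length + 1 kb;
real gametologous markers target small indels and use the default
50–2000 bp window.

## 7. Problem sizes and determinism

Default benchmark sizes (≈ 250 kb genome, 3 + 3 × 20× libraries, pool of
15 at 60×, one million Monte-Carlo iterations) were chosen so the full
test suite and the end-to-end scenarios complete in a few minutes on one
CPU while keeping every statistical check inside 3–4 standard errors of
its closed form. One global seed fans out to per-stage child seeds via
`SeedSequence([seed, stage_key])`; manifests record config hashes and
output checksums, and rerunning a configuration reproduces them exactly.

## 8. Known limitations

* Coverage-presence screening only; no small-variant or SNP-based sexing.
* No de novo assembly: per-sex references are inputs (synthetic or user
  FASTA).
* The ungapped mapper ignores indels by design; divergent gametologs
  beyond a few percent substitution would need a gapped aligner via SAM
  import.
* Multiple sex-chromosome systems (X1X2Y etc.) and multi-locus linkage
  are out of scope.
* The pool error model treats pool members as independent draws from one
  population; structured or related pools violate that.
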