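# Methods

This note documents the models and procedures implemented in
`mtb-interpret`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## Coordinates and intake

All internal coordinates are 1-based fully-closed intervals (the VCF/SEG
habit); BED input is converted at the file boundary and converted back on
write, so canonical files round-trip byte-identically. Chromosome names are
normalized by stripping a leading `chr`.

The QC gate checks the pathologist's tumor-cell-content estimate (≥ 20%)
and per-assay coverage minima (tumor WGS 80x / WES 120x, control WGS 40x /
WES 80x, RNA 30 M reads when RNA was assayed). Where a pathologist estimate
and a computational purity estimate disagree, the gate uses the pathologist
field; the computational estimate travels alongside as metadata. The gate
is a pure threshold check and therefore monotone: improving any observed
value can never turn a pass into a fail. By default the library reports
failures and continues; the CLI offers `--hard-fail` for pipeline use,
since sub-threshold samples are normally excluded before analysis.

## Scar metrics

**Ploidy** is the length-weighted mean total copy number over autosomal
segments. Sex chromosomes are excluded because their copy number reflects
sex, not tumor aneuploidy.

**LOH** requires rounded minor state 0 with rounded total state ≥ 1:
loss of one parental allele with retention of the other. Homozygous
deletions are deliberately excluded — nothing is "retained". Abutting LOH
segments merge into maximal runs regardless of their total states, since
the lost haplotype is what defines the run.

**HRD-LOH** counts merged LOH runs strictly longer than 15 Mbp that do not
span an entire chromosome (p-arm start through q-arm end, taken from the
arm table). Whole-chromosome LOH is an aneuploidy signal, not the
subchromosomal scarring characteristic of HRD. The subchromosomal test is
applied against the chromosome extent rather than the arm extent; an
arm-level run therefore still counts.

**LST** counting is per arm. Segments crossing the centromere are split at
the arm boundary, and flanks never straddle the centromere — the
centromere is a mappability desert where segmentation is unreliable.
Within an arm: same-state neighbours are merged into runs, runs shorter
than 3 Mbp are dropped, the survivors re-merged, and a transition is
counted for each adjacent pair of runs with different states and both
lengths ≥ 10 Mbp. Merging *before* the length filter makes the count
invariant to how the segmentation happens to split same-state regions — a
property the test suite asserts directly. The 3-Mbp smoothing default
exists because fragmented segmentations would otherwise manufacture
transitions out of noise, contradicting the large-scale intent of the
metric; it is configurable, as is the 10-Mbp flank. Copy-number "state" is
the (rounded total, rounded minor) pair by default — the stricter
allele-specific convention — with a total-only mode behind a flag.

**Gene-level calls** take the length-weighted CN over the segments
overlapping the gene. AMP requires CN ≥ 2ψ + 1, where ψ is average ploidy;
the offset makes the threshold ploidy-relative, so CN 8 at ψ 2 is an
amplification while CN 6 at ψ 4 is only a gain. HETLOSS is a rounded state
below rounded ploidy but ≥ 1; HOMDEL is state 0. For loss calls, the
second-hit logic declares biallelic loss only for HOMDEL, or HETLOSS plus
a truncating variant in the gene, a focal intragenic deletion, or location
inside an LOH run. A lone heterozygous deletion is flagged for cautious
interpretation rather than nominated as a loss-of-function driver.

When `minor_cn` is absent from a segment file, LOH-dependent metrics are
reported as not computable rather than guessed from total copy number.

## VICC scoring, TMB, mosaicism

The oncogenicity engine consumes *asserted* criteria — curator judgements
with free-text notes — and aggregates points: very strong 8, strong 4,
moderate 2, supporting 1, benign counterparts mirrored negative.
Automated criterion evaluation (hotspot lookups, population frequencies)
requires external knowledge bases and is upstream curation, not part of
this package. Classification bands default to ≥ 10 oncogenic, 6–9 likely
oncogenic, 0–5 VUS, −6…−1 likely benign, ≤ −7 benign, and live in
configuration, not code.

TMB divides qualifying variants by a coding footprint of 38 Mbp by
default — the approximate protein-coding exome size consistent with the
anchoring worked example (23 variants ↦ 0.6/Mbp). Synonymous and
non-coding consequences are excluded by default, with a flag to count all.

The mosaicism flag bands the control-sample allele fraction: below 2% is
treated as sequencing noise, [2%, 30%) as possible mosaicism (a 5–6%
control AF is the archetypal case, warranting genetic counseling), and
≥ 30% as consistent with germline heterozygosity. The band edges are
configuration; no published consensus band exists.

## Signature refitting

Catalogs follow the SBS-96 convention: six pyrimidine-centric substitution
classes × 16 flanking-base combinations, with purine-reference SNVs
reverse-complemented. Exposure fitting solves min‖c − S·e‖₂ subject to
e ≥ 0 via `scipy.optimize.nnls` — an active-set method that is exact and
deterministic for fixed input. The contract is the optimization problem,
not the solver. Refitting against a supplied matrix is the whole scope;
de-novo extraction is not attempted. No sparsity pruning is applied by
default because small-fraction signatures are legitimate findings; an
optional drop-and-refit for exposures under 1% is available.

The two built-in fixture signatures are synthetic 96-bin spectra with
partially overlapping support (not COSMIC copies): SBS-A weights the C>*
classes, SBS-B the T>* classes, each leaking 25%-weight bins into the
other's territory so that refitting is a genuine deconvolution. Any
COSMIC-format TSV is accepted for real use.

## Fusions

Frame assessment is junction arithmetic: L5 = coding bases of the 5'
partner retained at or upstream of its breakpoint, U3 = coding bases of
the 3' partner excluded strictly upstream of its breakpoint; the junction
is in frame iff L5 > 0, the 3' partner retains coding sequence, and
L5 ≡ U3 (mod 3). The 5' breakpoint is read as the last retained base and
the 3' breakpoint as the first retained base — the convention of common
fusion callers. Breakpoints at exon boundaries therefore retain the named
exon fully. A promoter swap is called when both breakpoints lie upstream
of their partner's transcription and coding starts, leaving the 3' gene
intact under the 5' promoter.

Kinase-domain retention maps the domain's amino-acid interval into the
retained coding portion, boundary-inclusive: a domain ending exactly at
the last retained codon counts as retained.

The decision table gates on read support first (default minimum 2 total
supporting reads — "a few reads" is not quantified anywhere authoritative,
so the floor is deliberately permissive and configurable), then: in-frame
with intact kinase domain → actionable; out of frame → non-functional;
promoter swap or in-frame without a kinase domain → oncogenic but not
druggable. One canonical transcript per gene is assumed; isoform
enumeration is the caller's responsibility.

The engineered fusion fixtures carry explicit nucleotide bookkeeping: the
3' coding sequence embeds a codon-aligned TTA-ATT-AAG motif that
translates as Leu-Ile-Lys in frame but yields a TAA stop in either shifted
frame, so a translation oracle can verify the frame logic independently.

## Expression integration

Percentiles are midrank: 100·(#below + ½·#ties)/n, so a value tied with
the whole cohort ranks 50th. The index sample is included in its own
cohort by default (stable for small cohorts; a flag excludes it).
Overexpression defaults to the 90th percentile; driver/passenger
integration for amplified genes uses 75/25. All three are qualitative
conventions exposed in configuration — the underlying biology gives no
sharp threshold. Every expression-based call carries a caveat string about
tumor-site effects, and an expressed heterozygous-loss gene is never
escalated to a loss-of-function driver verdict.

## Evidence and reporting

Entity matching is exact string equality after case/whitespace
normalization, with an optional alias table; ontology mapping is out of
scope. A knowledge entry with entity `*` matches any patient entity and
yields tier m1 — the wildcard asserts the evidence applies regardless of
histology, and demoting it to m2 would claim a cross-entity extrapolation
the entry does not make.

The level total order is m1a < m1b < m1c < m2a < m2b < m2c < m3 < m4
(strongest first): tier dominates suffix. Published level systems do not
define a comparator between, e.g., m1c and m2a; tier-first is one
defensible reading and the order is replaceable in configuration.
Evidence ranges ("m2a–m3") are stored as (best, worst) pairs and ranked by
their best level. Ranking sorts by level, then trial-before-off-label
(so a higher-level off-label therapy still outranks a trial), then
DNA+RNA-supported biomarkers before single-layer ones, then input order
(stable). Whitelist membership flags presentation priority only; it never
changes an evidence level. Resistance biomarkers are matched by the same
machinery with a polarity field and rendered in report blocks, never
ranked as therapies.

Reports are a pure function of inputs plus configuration: blocks in rank
order (biomarkers, evidence with level, trials, summary), a summary table,
germline findings filtered to ACMG classes 4 and 5 at assembly time so no
lower-class finding can reach any renderer, and a provenance stanza with a
configuration hash. JSON rendering uses sorted keys and fixed separators,
so equal inputs produce byte-identical output. Markdown templates are this
package's own design; clinical free text is passed through verbatim, never
synthesized. English only.

## Synthetic data: what it does and does not show

The generators are pure functions of (spec, seed) and every manifest
records ground truth computed by construction — from the generator's
internal piece lists, never by calling the analysis code. The toy genome
is three chromosomes (200/150/100 Mbp, arm boundaries at 90/60/40 Mbp with
a 3-Mbp centromere gap) so the whole suite runs in seconds.

Copy-number profiles place alternating LOH and heterozygous blocks with
lengths drawn across the 15-Mbp and 10-Mbp thresholds (HRD-like), a
near-diploid background with one gained region (silent), or a 2-Mbp
high-level amplicon (amplified), plus one whole-chromosome LOH chromosome
to exercise the subchromosomal exclusion. SNV fixtures draw trinucleotide
contexts multinomially from S·e and emit roughly half the variants on the
purine strand to exercise strand collapsing. Fusion fixtures are the three
engineered scenarios described above.

What passing tests therefore show: the metric definitions, junction
arithmetic, fitting, ordering and rendering are implemented correctly
against independent oracles. What they do not show: robustness to the
noise of real segmentation (purity/ploidy estimation error, subclonality,
fractional copy numbers), real trinucleotide abundance biases, or real
transcript-annotation complexity (overlapping isoforms, UTR introns).
Those belong to upstream pipelines and validation on real cases.

## Problem sizes and determinism

The signature-recovery experiment uses 20,000 SNVs — ample for ±2-pp
recovery of a 50/50 mixture under multinomial noise, and small enough to
simulate in well under a second. Fixture profiles carry tens of segments;
NNLS problems are 96 × 2. All randomness flows through
`numpy.random.default_rng` seeded from the spec, and `scripts/acceptance.py`
derives every seed from its `--seed` argument.

## Known limitations

- No segmentation, purity/ploidy fitting, or variant calling: everything
  upstream of interpretation is consumed as input.
- No telomeric allelic imbalance metric; the scar set is HRD-LOH + LST.
- No automated VICC criterion evaluation (needs external databases).
- No microsatellite-instability, methylation-classification or
  transcriptome-similarity layers.
- Entity matching is string-based; no tumor ontology.
- Indel/doublet/copy-number signature classes are out of scope.
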