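# Methods

This note documents the models and procedures implemented in `varprio`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where more than one reasonable
reading existed.

## Variant model and VCF normalization

Every multiallelic VCF record is decomposed into one variant per alternate
allele before any downstream operation; the only normalization applied is
removal of shared trailing bases (no left-alignment — auditable minimal
transformation; full normalization is out of scope). For each decomposed
allele the per-sample call carries the original AD slice `[AD_ref, AD_i]`.
Whether per-allele AD ordering survives a caller's own decomposition is not
verifiable in general; we carry the slice as-is.

When AD/DP are absent but AO/RO are present (Torrent-style callers), allele
depths become `[RO, AO_i]` and total depth `RO + Σ AO` (equal to `RO + AO`
at biallelic sites). Explicitly present AD/DP are never overwritten.

Genotype semantics: phased separators are accepted and treated as unphased;
half-calls (`./1`) are classed `other_ploidy` and never satisfy presence or
zygosity requirements; a genotype carrying only a *different* alternate
allele (e.g. `2/2` seen from allele 1) counts as not carrying this allele.
Missing genotypes count as *absent* for sharing and fail every explicit
zygosity requirement; the implicit "no other sample may be homozygous"
check of an `only_in` pattern treats a missing call as "not called
hom-alt" (an explicit requirement is a positive claim that needs evidence;
the exclusivity check is only the absence of a contradicting call).

Coordinates: VCF and GFF3 are 1-based inclusive; BED is 0-based half-open
and converted at the comparison boundary (`RegionTrack.contains_pos`).

## Per-isoform annotation

Variants are annotated against **every** transcript isoform whose flanked
span covers them; nothing is collapsed to a single representative isoform.

- `splice_window` (default 2 bp) — a variant intersecting the first/last
  window of any intron, or straddling an exon/intron boundary, is
  `splice_site` (conservative severity). 2 bp is the canonical
  donor/acceptor dinucleotide; the parameter is exposed because tools
  differ.
- `flank` (default 5000 bp) — upstream/downstream reach, strand-aware.
  Conventional; exposed as a parameter.

Coding consequences translate the affected codon(s) of the spliced,
strand-corrected CDS under the standard genetic code; precedence for
substitutions is start-loss (initiator ATG altered), stop-gain, stop-loss,
missense; identical translation is synonymous. Indels are classified by
REF/ALT length difference mod 3 (frameshift vs in-frame), regardless of
sequence context. The unit tests verify, on thousands of random SNVs and
indels on both strands, that this local-codon computation is identical to a
brute-force oracle that rebuilds and translates the entire mutant CDS.

For single-class summaries a fixed severity order is used
(stop_gain > frameshift > stop_loss > start_loss > missense >
inframe_indel > synonymous; splice_site > cds_exonic > UTR > intronic);
per-isoform lists are never reduced by it.

### mAiR

The reference-allele frequency at a known site is `1 − Σ gmaf` over all
records at the site sharing the variant's REF (multiple alternate alleles
sum; "the site's non-reference frequency" is the coherent reading). The
flag is raised when that frequency is strictly below 0.1. The subtraction
is rounded (9 decimals) so the strict inequality is exact at printed
precisions — `1 − 0.9` must equal 0.1, not fall a binary ulp below it.
Sites absent from the frequency table are never flagged.

## Trio and family logic

"Present" means carrying ≥ 1 alternate allele (het or hom-alt); "shared"
means jointly present, not genotype-identical. De novo candidates require
child-present, both parents absent **and** both parental depths ≥
`min_parent_depth` (default 10) as a dropout guard; the guard is optional
sugar and can be disabled by passing 0.

Parental origin of a child-het variant: exactly one carrier parent names
that parent; both carriers give `either`; neither gives `de_novo_like`;
non-het children or any missing call are `unresolved` (a hom-alt child
inherited from both, so per-allele origin is trivially "both").

Compound-het pairs in a gene require: child het for both variants, each
variant present in ≥ 1 parent and hom-alt in neither, and parental origins
resolving to the two different parents. Pairs in which one or both origins
are `either` cannot be phased from genotypes alone and are reported in a
separate *ambiguous* list rather than guessed. Chromosome X receives no
special-casing; hemizygous designs are expressed through zygosity criteria.

## Criteria engine

Criteria are declared in YAML (one mapping per criterion: id, section —
one of the seven query sections — field, comparator, value, weight > 0,
optional samples / scope / isoform_mode), validated against the set of
known context fields; custom annotation-table columns extend that set.
YAML was chosen over XML as the equivalent declarative structured format
native to this ecosystem.

Evaluation rules:

- each criterion is evaluated independently; results never depend on other
  criteria or on evaluation order;
- transcript-scope predicates: any-isoform OR by default (`isoform_mode:
  all` switches to AND);
- sample-scope predicates: all listed samples must satisfy when `samples`
  is given, otherwise any project (or subset) sample suffices;
- a field absent from a variant's context makes the criterion false and
  logs a deduplicated data-gap warning — never an error, so queries run on
  sparsely annotated projects;
- `score(v) = Σ w_c` over satisfied criteria; every variant is retained
  (positive selection), so results are invariant in ordering under any
  positive rescaling of the weights.

Genes are ranked by their best variant's score, ties broken by (number of
variants at that score, descending) then gene ID — score-major ordering
plus a deterministic total order. A variant inside several overlapping
genes counts fully for each gene's matrix row; the score table and the
per-criterion "total number of variants" line count each variant once
globally. Both conventions are deliberate: splitting would distort
per-gene matrices, double-counting would distort totals.

## Runs of homozygosity

Informative positions are frequency-table sites with GMAF strictly above
0.3 inside the sample's target regions: no call for the sample ⇒ inferred
`0/0`; otherwise the call's zygosity (an explicit `0/0` also counts as
hom-ref). Requesting a sample with no target track is an error that
suggests the explicit no-targets mode (`targets=None`).

Seeds are maximal hom-ref runs whose length strictly exceeds the
nearest-rank 95th percentile of the run-length distribution. Defaults,
both exposed as parameters: lengths in genomic bp (physical span is the
natural reading of "length"; position count is available) pooled
genome-wide (stabilises small chromosomes). Nearest-rank is used for
cross-platform reproducibility. Degenerate input with exactly one run
returns that run as the sole seed — under a strict "exceeds" rule the
algorithm could otherwise never start (this also means no seed can form
with ≤ 20 runs, since the 95th-percentile cutoff then equals the maximum).

Extension grows each seed to the *maximal region reachable by
single-position steps that each keep the full-region homozygosity ratio
strictly above* `min_ratio` (default 0.9; a candidate at exactly 0.9 is
rejected). Both directions are retried until a fixpoint, because a step
that fails now can become feasible after growth on the other side;
hom-ref neighbours are absorbed eagerly (adding a hom-ref position only
raises the ratio, so this provably never changes the result). Among
reachable regions the one maximizing (genomic span, hom-ref count,
leftmost start) is reported; maximality implies no single-position
extension of a reported region keeps the ratio above threshold, which the
tests verify against an exhaustive interval-reachability oracle.
Overlapping extended regions merge when the union's ratio passes the
threshold, otherwise the longer region wins.

The chromosome map flags a prioritized gene `in_roh` when its interval
lies wholly inside a reported region.

## Gene recurrence

A variant qualifies for a patient when the patient carries it and its
query score reaches `min_score` (default: the query's maximum observed
score, i.e. "the current top stratum"). Genes with qualifying variants in
≥ `min_patients` (≥ 2) distinct patients are reported with their distinct
variant count — reported, not required, since de novo designs hit the same
gene through different variants while shared variants still mean the gene
is mutated in both patients.

## Synthetic-data generator

One integer seed drives everything through independent named substreams;
identical seeds give byte-identical files. The generator writes a genome
(default 2 × 500 kb), ~30 genes of 3–5 exons with 1–2 isoforms (exon
lengths multiples of 3 and 30 bp UTR margins, so every isoform's CDS stays
in frame; start/stop codons are written into the genome at CDS
boundaries), a multi-sample trio VCF (GT:AD:DP:GQ, plus one multiallelic
record and an auxiliary single-sample GT:AO:RO file to exercise depth
derivation), a site-frequency table (80% rare U(0, 0.05), 20% high
U(0.3, 0.5)), whole-chromosome BED targets per sample and a phenotype gene
list — with machine-readable truth for every planted signal.

Key realism decisions:

- Trio genotypes are Mendelian-consistent everywhere except the planted
  de novo sites, so the de novo search recovers the planted truth
  *exactly* (no accidental de novo patterns).
- At high-GMAF sites parental genotypes are drawn carrier-dense
  (hom-ref 0.06 / het 0.52 / hom-alt 0.42) rather than from
  Hardy–Weinberg proportions: informative-marker panels are ascertained
  for heterozygosity, and a background in which homozygous-reference calls
  are the minority is precisely what makes a genuine homozygous tract
  detectable. The greedy ROH extension inevitably overshoots a tract's
  edges by roughly `(ratio_surplus)/(0.9 − background_hom_fraction)`
  positions, so a hom-ref-rich background would smear every tract well
  beyond its bounds.
- Planted ROH tracts (default 300 and 400 informative positions at
  ~100 bp pitch, 2% interior het contamination) force the tract sample
  hom-ref at every high-GMAF site inside the tract.
- Case-study qualifying variants are middle-of-codon substitutions —
  under the standard code a middle-base change of a non-stop codon is
  always protein-changing, so the planted "protein-changing" truth needs
  no translation machinery at generation time. Their depth (70–110×),
  child homozygosity with het parents, GMAF 0.01 records and
  phenotype-listed genes satisfy all six case-study criteria; distractor
  positions are disjoint from rare-frequency sites, so every distractor
  fails the GMAF criterion by construction (recorded in the audit table).

What the generator does **not** emulate: linkage disequilibrium, realistic
mutation-rate heterogeneity, sequencing error, allele-balance noise,
structural variants, gVCF blocks. Passing planted-truth tests therefore
demonstrates algorithmic correctness under clean Mendelian data, not
performance on real exomes.

## Problem sizes and numerics

The packaged project is ~1 Mb of genome, ~9,600 variant records and
~40,000 frequency records — sized so the full test suite and the
acceptance script each complete in well under a minute while still
separating two planted signals from > 9,000 distractors. Consequence
checks use 5,000 random CDS variants against the full-translation oracle;
ROH extension is verified against the exhaustive oracle on 200 random
position sets of up to 100 sites. All thresholds that are comparisons
against stated constants (GMAF > 0.3, ratio > 0.9, mAiR < 0.1, percentile
"exceeds") are strict inequalities.

## Known limitations

- HGVS output is descriptive (`REF>ALT(effect)`), not nomenclature-strict.
- No splice-strength scoring, UTR regulatory effects or non-standard
  genetic codes.
- Multigenerational pedigrees beyond the trio, statistical phasing and
  Mendelian-error rate estimation are out of scope.
- The ROH caller is the deterministic seed-and-extend procedure, not an
  HMM; no LD pruning or autozygosity-coefficient estimation.
- Compound-het pairs with double-"either" origins remain ambiguous by
  design; genotype data alone cannot phase them.
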