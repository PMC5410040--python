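# varprio

Weighted-criteria prioritization of genetic variants from multi-sample VCF
files, with per-isoform consequence annotation, trio inheritance models,
runs-of-homozygosity detection and cross-patient gene recurrence — all on
local files, no web service or database required.

## Who this is for

Clinical and research geneticists triaging exome/genome variant calls:
single patients, trios, families and cohorts. The standard workflow —
sequential hard filters, each silently discarding everything below its
threshold — risks losing a causal variant that just misses one cutoff while
clearing every other bar. `varprio` instead uses **positive selection**:
every criterion is evaluated independently for every variant, and failing a
criterion lowers a variant's rank without removing it.

## The model

A query is a set of criteria *C*, each a weighted predicate over variant,
transcript, gene or per-sample context (depth, genotype, consequence,
population frequency, gene lists, sharing patterns, …). For a variant *v*
with satisfied set *S(v) ⊆ C*:

```
score(v) = Σ_{c ∈ S(v)} w_c            (w_c > 0, default 1)
score(g) = max_{v ∈ g} score(v)        (genes ranked by their best variant)
```

Annotation is per transcript isoform — the same substitution can be
missense in one isoform and intronic in another, so transcript-scope
criteria use any-isoform semantics and nothing is collapsed onto a "major"
isoform. Two further analyses are built in:

- **Runs of homozygosity** (seed-and-extend): at known high-polymorphism
  sites (GMAF > 0.3) inside a sample's target regions, sites with no called
  variant are inferred homozygous-reference. Maximal hom-ref runs longer
  than the 95th percentile of the run-length distribution become seeds,
  then grow in both directions while the homozygosity ratio
  `n_hom_ref / (n_hom_ref + n_het + n_hom_alt)` of the whole region stays
  strictly above 0.9.
- **mAiR flags** (minor Allele in Reference): sites where the reference
  base has population frequency < 0.1, which surface as systematic
  "variants" in most individuals.

## Worked example

Generate a complete synthetic trio project (genome FASTA, GFF3 gene models,
multi-sample VCF, site-frequency table, BED targets, phenotype gene list —
with recorded ground truth for every planted signal), then run the
six-criterion recessive-trio query:

```bash
varprio fixtures --seed 7 --outdir demo
# wrote 9588 variant records and 39846 frequency records to demo

cat > demo/project.yaml <<'YAML'
vcf: variants.vcf
genome: genome.fa
gff3: genes.gff3
frequencies: frequencies.tsv
targets: targets.bed
phenotype_genes: phenotype_genes.tsv
trio: {child: CHILD, father: FATHER, mother: MOTHER}
YAML

varprio query --project demo/project.yaml --case-study --outdir demo/out
# max score 6; top gene G1_04; reports in demo/out
```

The six criteria are: total depth > 60 in all three samples, child
alternate-allele depth > 30, protein-changing consequence in ≥ 1 isoform,
GMAF < 0.05, gene on the phenotype list, homozygous only in the child.
`demo/out/score_table.tsv` summarises genes and variants per score:

```
score   n_genes n_variants
6       2       2
4       3       4
3       7       69
```

Exactly two variants reach the maximum score of 6 — the two qualifying
variants the generator planted — and `demo/out/variants_report.tsv` names
them with their satisfied criteria:

```
chrom   pos     ref alt score satisfied_criteria
chr1    61373   A   G   6     alt_coverage,deep_coverage,hom_only_in_child,phenotype_gene,protein_changing,rare
chr1    76199   C   T   6     alt_coverage,deep_coverage,hom_only_in_child,phenotype_gene,protein_changing,rare
```

ROH detection recovers the two planted homozygous tracts (~40 kb and
~50 kb) for the child:

```bash
varprio roh --project demo/project.yaml --sample CHILD --outdir demo/out
# 18 ROH regions for CHILD; reports in demo/out
```

`demo/out/roh_CHILD.tsv` contains, among short perfect-homozygosity
stretches, the two extended tracts:

```
chr1  115073  154338  546  31  29  0.900990  true
chr2  91222   142345  695  50  27  0.900259  true
```

Other subcommands: `varprio annotate` (per-isoform annotation store + mAiR
flags), `varprio genes` (genes mutated in several patients). The same
functionality is available as a library: `parse_vcf`, `annotate_all`,
`run_query`, `de_novo_candidates`, `compound_het_genes`,
`informative_positions` / `find_seeds` / `extend_seeds`,
`recurrent_genes`.

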