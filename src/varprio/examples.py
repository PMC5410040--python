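"""Reference criteria spanning the seven query sections.

The engine is generic — any declared context field can be constrained —
and these catalogs are worked examples, not an exhaustive list. The
six-criterion case-study query reproduces a classic recessive-disease
prioritization: deep confident calls, a protein-changing consequence, a
rare allele, a phenotype-matched gene and child-only homozygosity.
"""

from __future__ import annotations

from .criteria import Criterion, criteria_from_dicts
from .model import TrioSpec

__all__ = ["case_study_criteria", "eight_criterion_query", "reference_criteria"]

PROTEIN_CHANGING_EFFECTS = [
    "missense",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "frameshift",
    "inframe_indel",
]


def case_study_criteria(
    trio: TrioSpec, phenotype_set: str = "phenotype"
) -> list[Criterion]:
    """The six-criterion recessive-trio query, unit weights."""
    samples = [trio.child, trio.father, trio.mother]
    return criteria_from_dicts(
        [
            {
                "id": "deep_coverage",
                "section": "vcf_user_data",
                "field": "total_depth",
                "comparator": ">",
                "value": 60,
                "samples": samples,
            },
            {
                "id": "alt_coverage",
                "section": "vcf_user_data",
                "field": "alt_allele_depth",
                "comparator": ">",
                "value": 30,
                "samples": [trio.child],
            },
            {
                "id": "protein_changing",
                "section": "variant_annotation",
                "field": "effect",
                "comparator": "in_set",
                "value": PROTEIN_CHANGING_EFFECTS,
            },
            {
                "id": "rare",
                "section": "variant_databases",
                "field": "gmaf",
                "comparator": "<",
                "value": 0.05,
            },
            {
                "id": "phenotype_gene",
                "section": "phenotype_annotation",
                "field": "gene_id",
                "comparator": "in_set",
                "value": phenotype_set,
            },
            {
                "id": "hom_only_in_child",
                "section": "sharing_segregation",
                "field": "zygosity",
                "comparator": "matches",
                "value": {
                    "requirements": {trio.child: "hom_alt_required"},
                    "only_in": [trio.child],
                },
            },
        ]
    )


def eight_criterion_query(
    trio: TrioSpec, phenotype_set: str = "phenotype"
) -> list[Criterion]:
    """Eight unit-weight criteria: the case-study six plus call quality and
    genomic-context constraints."""
    extra = criteria_from_dicts(
        [
            {
                "id": "confident_calls",
                "section": "vcf_user_data",
                "field": "quality",
                "comparator": ">=",
                "value": 50,
                "samples": [trio.child, trio.father, trio.mother],
            },
            {
                "id": "genic_context",
                "section": "variant_annotation",
                "field": "region_class",
                "comparator": "in_set",
                "value": ["cds_exonic", "splice_site", "utr5", "utr3"],
            },
        ]
    )
    return case_study_criteria(trio, phenotype_set) + extra


def reference_criteria(
    trio: TrioSpec, phenotype_set: str = "phenotype"
) -> list[Criterion]:
    """~20 example criteria covering all seven sections."""
    samples = [trio.child, trio.father, trio.mother]
    extra = criteria_from_dicts(
        [
            # ensembl_features
            {"id": "on_chr1", "section": "ensembl_features", "field": "chrom",
             "comparator": "=", "value": "chr1"},
            {"id": "gene_prefix", "section": "ensembl_features", "field": "gene_id",
             "comparator": "matches", "value": "^G1_"},
            {"id": "isoform_t1", "section": "ensembl_features",
             "field": "transcript_id", "comparator": "matches", "value": r"\.t1$"},
            # functional_annotation
            {"id": "coding_region", "section": "functional_annotation",
             "field": "region_class", "comparator": "=", "value": "cds_exonic"},
            {"id": "splice_or_coding", "section": "functional_annotation",
             "field": "region_class", "comparator": "in_set",
             "value": ["cds_exonic", "splice_site"]},
            # variant_annotation
            {"id": "missense", "section": "variant_annotation", "field": "effect",
             "comparator": "=", "value": "missense"},
            {"id": "truncating", "section": "variant_annotation", "field": "effect",
             "comparator": "in_set", "value": ["stop_gain", "frameshift"]},
            # variant_databases
            {"id": "known_site", "section": "variant_databases", "field": "site_id",
             "comparator": "matches", "value": "."},
            {"id": "not_mair", "section": "variant_databases", "field": "is_mair",
             "comparator": "=", "value": "False"},
            {"id": "common", "section": "variant_databases", "field": "gmaf",
             "comparator": ">=", "value": 0.3},
            # sharing_segregation
            {"id": "de_novo_sharing", "section": "sharing_segregation",
             "field": "sharing", "comparator": "matches",
             "value": {trio.child: "present", trio.father: "absent",
                       trio.mother: "absent"}},
            {"id": "shared_by_all", "section": "sharing_segregation",
             "field": "sharing", "comparator": "matches",
             "value": {s: "present" for s in samples}},
            # vcf_user_data
            {"id": "child_het", "section": "vcf_user_data", "field": "gt",
             "comparator": "=", "value": "het", "samples": [trio.child]},
            {"id": "minimum_depth", "section": "vcf_user_data",
             "field": "total_depth", "comparator": ">=", "value": 20,
             "samples": samples},
        ]
    )
    return eight_criterion_query(trio, phenotype_set) + extra
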