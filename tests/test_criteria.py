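"""Criteria parsing, independent evaluation, scoring and gene ranking."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from varprio import (
    Criterion,
    Effect,
    Genotype,
    GenotypeCall,
    RegionClass,
    TranscriptAnnotation,
    TrioSpec,
    Variant,
    build_contexts,
    evaluate,
    rank_genes,
    run_query,
    score_variants,
)
from varprio.criteria import criteria_from_dicts, parse_criteria, write_criteria_yaml
from varprio.examples import case_study_criteria, eight_criterion_query
from varprio.model import UsageError


def ctx_for(variant, annotations=(), **kw):
    return build_contexts([variant], {variant.key: list(annotations)}, **kw)[0]


def numbered_criteria(n, weight=1.0):
    """Criteria c1..cn over synthetic variant-scope annotation columns."""
    return criteria_from_dicts(
        [
            {"id": f"c{i}", "field": f"f{i}", "comparator": "=", "value": 1,
             "weight": weight}
            for i in range(1, n + 1)
        ],
        extra_fields=[f"f{i}" for i in range(1, n + 1)],
    )


def variant_with_fields(pos, fields, gene="GENE1"):
    v = Variant("chr1", pos, "A", "G", annotations=dict(fields))
    ann = TranscriptAnnotation(
        transcript_id=f"{gene}.t1", region_class=RegionClass.INTRONIC, gene_id=gene
    )
    return v, {v.key: [ann]}


class TestParsing:
    def test_yaml_round_trip(self, tmp_path):
        criteria = criteria_from_dicts(
            [
                {"id": "deep", "field": "total_depth", "comparator": ">",
                 "value": 60},
                {"id": "rare", "field": "gmaf", "comparator": "<", "value": 0.05,
                 "weight": 2.5, "section": "variant_databases"},
            ]
        )
        assert criteria[0].weight == 1.0  # default weight
        path = tmp_path / "crit.yaml"
        write_criteria_yaml(criteria, path)
        assert parse_criteria(path) == criteria

    def test_negative_weight_rejected(self):
        with pytest.raises(UsageError, match="weight"):
            criteria_from_dicts(
                [{"id": "x", "field": "gmaf", "comparator": "<", "value": 1,
                  "weight": -1}]
            )

    def test_duplicate_id_rejected(self):
        entry = {"id": "maf", "field": "gmaf", "comparator": "<", "value": 0.1}
        with pytest.raises(UsageError, match="duplicate"):
            criteria_from_dicts([entry, dict(entry)])

    def test_unknown_comparator_rejected(self):
        with pytest.raises(UsageError, match="comparator"):
            criteria_from_dicts(
                [{"id": "x", "field": "gmaf", "comparator": "~", "value": 1}]
            )

    def test_unknown_field_lists_known_fields(self):
        with pytest.raises(UsageError, match="known fields"):
            criteria_from_dicts(
                [{"id": "x", "field": "wibble", "comparator": "=", "value": 1}]
            )

    def test_empty_config_rejected(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(yaml.safe_dump({"criteria": []}))
        with pytest.raises(UsageError):
            parse_criteria(path)


class TestEvaluate:
    def test_any_isoform_semantics(self):
        """Missense in one isoform satisfies the effect criterion even when
        the other isoform is intronic."""
        v = Variant("chr1", 10, "A", "G")
        anns = [
            TranscriptAnnotation("t1", RegionClass.CDS_EXONIC, Effect.MISSENSE,
                                 gene_id="G"),
            TranscriptAnnotation("t2", RegionClass.INTRONIC, gene_id="G"),
        ]
        (crit,) = criteria_from_dicts(
            [{"id": "mis", "field": "effect", "comparator": "=",
              "value": "missense"}]
        )
        assert evaluate(crit, ctx_for(v, anns))
        all_mode = Criterion(
            id="mis_all", field="effect", comparator="=", value="missense",
            isoform_mode="all",
        )
        assert not evaluate(all_mode, ctx_for(v, anns))

    def test_gmaf_threshold(self):
        (crit,) = criteria_from_dicts(
            [{"id": "rare", "field": "gmaf", "comparator": "<", "value": 0.05}]
        )
        v, _ = variant_with_fields(10, {"gmaf": 0.2})
        assert not evaluate(crit, ctx_for(v))
        v2, _ = variant_with_fields(11, {"gmaf": 0.01})
        assert evaluate(crit, ctx_for(v2))

    def test_alt_depth_boundary(self):
        """AD [30,12]: alternate depth 12 fails the > 30 requirement."""
        (crit,) = criteria_from_dicts(
            [{"id": "alt", "field": "alt_allele_depth", "comparator": ">",
              "value": 30, "samples": ["S"]}]
        )
        v = Variant(
            "chr1", 10, "A", "G",
            calls={"S": GenotypeCall("S", Genotype.HET, [30, 12], 42)},
        )
        assert not evaluate(crit, ctx_for(v))
        v2 = Variant(
            "chr1", 11, "A", "G",
            calls={"S": GenotypeCall("S", Genotype.HET, [30, 31], 61)},
        )
        assert evaluate(crit, ctx_for(v2))

    def test_missing_field_is_false_not_error(self, caplog):
        (crit,) = criteria_from_dicts(
            [{"id": "rare", "field": "gmaf", "comparator": "<", "value": 0.05}]
        )
        v, _ = variant_with_fields(10, {})
        import varprio.criteria as crit_mod

        crit_mod._warned_gaps.clear()
        with caplog.at_level("WARNING", logger="varprio.criteria"):
            assert evaluate(crit, ctx_for(v)) is False
        assert any("gmaf" in r.message for r in caplog.records)

    def test_gene_set_membership(self):
        (crit,) = criteria_from_dicts(
            [{"id": "panel", "field": "gene_id", "comparator": "in_set",
              "value": "panel"}]
        )
        v, anns = variant_with_fields(10, {}, gene="NPHS1")
        ctx = build_contexts([v], anns, gene_sets={"panel": ["NPHS1"]})[0]
        assert evaluate(crit, ctx)
        ctx2 = build_contexts([v], anns, gene_sets={"panel": ["NPHS2"]})[0]
        assert not evaluate(crit, ctx2)


class TestScoring:
    def test_unit_weights_sum(self):
        criteria = numbered_criteria(8)
        v, anns = variant_with_fields(
            10, {f"f{i}": 1 for i in range(1, 9)}
        )
        (sv,) = score_variants(
            build_contexts([v], anns), criteria
        )
        assert sv.score == 8 and len(sv.satisfied) == 8

    def test_zero_score_variant_retained(self):
        criteria = numbered_criteria(3)
        v, anns = variant_with_fields(10, {})
        (sv,) = score_variants(build_contexts([v], anns), criteria)
        assert sv.score == 0

    def test_arbitrary_weights(self):
        criteria = criteria_from_dicts(
            [
                {"id": "a", "field": "f1", "comparator": "=", "value": 1, "weight": 2},
                {"id": "b", "field": "f2", "comparator": "=", "value": 1, "weight": 3},
                {"id": "c", "field": "f3", "comparator": "=", "value": 1, "weight": 5},
            ],
            extra_fields=["f1", "f2", "f3"],
        )
        v, anns = variant_with_fields(10, {"f1": 1, "f3": 1})
        (sv,) = score_variants(build_contexts([v], anns), criteria)
        assert sv.score == 7 and sv.satisfied == {"a", "c"}


class TestRanking:
    def make_seven_of_eight_gene(self):
        """Eight variants, each failing a different one of eight criteria:
        every matrix column is populated but the best variant scores 7."""
        criteria = numbered_criteria(8)
        variants = []
        annotations = {}
        for i in range(1, 9):
            fields = {f"f{j}": 1 for j in range(1, 9) if j != i}
            v, anns = variant_with_fields(100 + i, fields, gene="BP_LIKE")
            variants.append(v)
            annotations.update(anns)
        return criteria, variants, annotations

    def test_gene_score_is_best_variant_not_matrix_row(self):
        criteria, variants, annotations = self.make_seven_of_eight_gene()
        ranking = run_query(variants, criteria, annotations)
        gene = ranking.gene("BP_LIKE")
        assert gene.gene_score == 7
        assert all(gene.criterion_counts[c.id] == 7 for c in criteria)

    def test_single_gene_single_variant_score_table(self):
        criteria = numbered_criteria(3)
        v, anns = variant_with_fields(10, {"f1": 1, "f2": 1})
        ranking = run_query([v], criteria, anns)
        assert ranking.score_table == {2.0: (1, 1)}

    def test_criterion_totals_match_column_recount(self, trio_project):
        criteria = eight_criterion_query(trio_project.trio)
        ranking = run_query(
            trio_project.variants,
            criteria,
            trio_project.annotations,
            frequency_index=trio_project.freq_index,
            gene_sets=trio_project.gene_sets,
        )
        for c in criteria:
            recount = sum(
                1 for sv in ranking.scored if c.id in sv.satisfied
            )
            assert ranking.criterion_totals[c.id] == recount

    def test_positive_selection_keeps_every_variant_and_gene(self, trio_project):
        criteria = case_study_criteria(trio_project.trio)
        ranking = run_query(
            trio_project.variants,
            criteria,
            trio_project.annotations,
            frequency_index=trio_project.freq_index,
            gene_sets=trio_project.gene_sets,
        )
        assert len(ranking.scored) == len(trio_project.variants)
        genes_with_variants = {
            a.gene_id
            for v in trio_project.variants
            for a in trio_project.annotations[v.key]
            if a.gene_id
        }
        assert {g.gene_id for g in ranking.genes} == genes_with_variants

    def test_weight_scale_invariance(self):
        criteria, variants, annotations = self.make_seven_of_eight_gene()
        doubled = [
            Criterion(
                id=c.id, field=c.field, comparator=c.comparator, value=c.value,
                weight=c.weight * 2,
            )
            for c in criteria
        ]
        r1 = run_query(variants, criteria, annotations)
        r2 = run_query(variants, doubled, annotations)
        assert [g.gene_id for g in r1.genes] == [g.gene_id for g in r2.genes]
        assert r2.gene("BP_LIKE").gene_score == 14

    def test_criterion_order_independence(self):
        criteria, variants, annotations = self.make_seven_of_eight_gene()
        rng = np.random.default_rng(0)
        shuffled = [criteria[i] for i in rng.permutation(len(criteria))]
        r1 = score_variants(build_contexts(variants, annotations), criteria)
        r2 = score_variants(build_contexts(variants, annotations), shuffled)
        assert [(sv.score, sv.satisfied) for sv in r1] == [
            (sv.score, sv.satisfied) for sv in r2
        ]

    def test_removing_criterion_is_monotone(self):
        criteria, variants, annotations = self.make_seven_of_eight_gene()
        full = score_variants(build_contexts(variants, annotations), criteria)
        reduced = score_variants(
            build_contexts(variants, annotations), criteria[:-1]
        )
        for before, after in zip(full, reduced):
            assert after.satisfied <= before.satisfied


class TestSampleSubset:
    def test_empty_subset_rejected(self):
        v, anns = variant_with_fields(10, {})
        with pytest.raises(UsageError):
            build_contexts([v], anns, sample_subset=[])

    def test_subset_restricts_sample_criteria(self):
        (crit,) = criteria_from_dicts(
            [{"id": "deep", "field": "total_depth", "comparator": ">",
              "value": 50}]
        )
        v = Variant(
            "chr1", 10, "A", "G",
            calls={
                "A": GenotypeCall("A", Genotype.HET, [10, 10], 20),
                "B": GenotypeCall("B", Genotype.HET, [40, 40], 80),
            },
        )
        anns = {v.key: []}
        assert evaluate(crit, build_contexts([v], anns)[0])  # any-sample: B passes
        restricted = build_contexts([v], anns, sample_subset=["A"])[0]
        assert not evaluate(crit, restricted)


class TestCaseStudyQuery:
    def test_exactly_two_planted_variants_at_score_six(self, trio_project):
        """The six-criterion query isolates the two planted variants among
        hundreds of distractors."""
        criteria = case_study_criteria(trio_project.trio)
        ranking = run_query(
            trio_project.variants,
            criteria,
            trio_project.annotations,
            frequency_index=trio_project.freq_index,
            gene_sets=trio_project.gene_sets,
        )
        assert ranking.max_score == 6
        top = [sv for sv in ranking.scored if sv.score == 6]
        assert {sv.variant.key for sv in top} == {
            tuple(c["key"]) for c in trio_project.truth["case_study"]
        }
        assert len(trio_project.variants) - len(top) >= 500

    def test_dropping_phenotype_criterion_grows_top_set(self, trio_project):
        criteria = [
            c
            for c in case_study_criteria(trio_project.trio)
            if c.id != "phenotype_gene"
        ]
        ranking = run_query(
            trio_project.variants,
            criteria,
            trio_project.annotations,
            frequency_index=trio_project.freq_index,
            gene_sets=trio_project.gene_sets,
        )
        top = [sv for sv in ranking.scored if sv.score == ranking.max_score]
        assert len(top) >= 2
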