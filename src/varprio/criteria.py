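"""Weighted multi-criteria scoring and gene ranking.

Prioritization is a *positive selection* process: every criterion is
evaluated independently for every variant, a variant's score is the sum of
the weights of the criteria it satisfies, and genes are ranked by their
highest-scoring variant. Failing a criterion lowers a variant's score but
never removes it from the results, so the user always sees which criteria
are and are not met.

Criteria are declared in a YAML file, one mapping per criterion::

    criteria:
      - id: deep
        section: vcf_user_data
        field: total_depth
        comparator: ">"
        value: 60
        weight: 1
        samples: [CHILD, FATHER, MOTHER]

Transcript-scope predicates use any-isoform semantics by default: a variant
satisfies ``effect = missense`` if *any* of its isoform annotations is
missense.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .io_formats import AnnotationTable, FrequencyIndex
from .model import (
    GenotypeCall,
    MairFlag,
    ScoredVariant,
    TranscriptAnnotation,
    UsageError,
    Variant,
)
from .segregation import (
    SharingPattern,
    ZygosityPattern,
    matches_sharing,
    matches_zygosity,
)
from .transcripts import flag_mair

logger = logging.getLogger(__name__)

_warned_gaps: set[tuple[str, str]] = set()


def _warn_gap(criterion_id: str, message: str) -> None:
    """Data-gap warning, deduplicated per (criterion, message) pair."""
    key = (criterion_id, message)
    if key not in _warned_gaps:
        _warned_gaps.add(key)
        logger.warning("criterion %s: %s", criterion_id, message)

__all__ = [
    "Criterion",
    "EvaluationContext",
    "GeneRanking",
    "GeneResult",
    "parse_criteria",
    "criteria_from_dicts",
    "build_contexts",
    "evaluate",
    "score_variants",
    "rank_genes",
    "run_query",
    "SECTIONS",
    "COMPARATORS",
]

SECTIONS = (
    "ensembl_features",
    "functional_annotation",
    "phenotype_annotation",
    "variant_annotation",
    "variant_databases",
    "sharing_segregation",
    "vcf_user_data",
)

COMPARATORS = ("<", "<=", "=", ">=", ">", "in_set", "matches")

#: built-in context fields per scope; annotation-table columns extend the
#: variant scope dynamically (declare them via ``extra_fields``).
VARIANT_FIELDS = {
    "chrom", "pos", "ref", "alt", "gmaf", "site_id", "vcf_id", "is_mair",
}
SAMPLE_FIELDS = {"gt", "total_depth", "alt_allele_depth", "ref_allele_depth", "quality"}
TRANSCRIPT_FIELDS = {"effect", "region_class", "transcript_id"}
GENE_FIELDS = {"gene_id"}
SEGREGATION_FIELDS = {"sharing", "zygosity"}

_SCOPE_OF = {}
for _f in VARIANT_FIELDS:
    _SCOPE_OF[_f] = "variant"
for _f in SAMPLE_FIELDS:
    _SCOPE_OF[_f] = "sample"
for _f in TRANSCRIPT_FIELDS:
    _SCOPE_OF[_f] = "transcript"
for _f in GENE_FIELDS:
    _SCOPE_OF[_f] = "gene"
for _f in SEGREGATION_FIELDS:
    _SCOPE_OF[_f] = "sample"


def known_fields(extra_fields: Iterable[str] = ()) -> set[str]:
    return (
        VARIANT_FIELDS
        | SAMPLE_FIELDS
        | TRANSCRIPT_FIELDS
        | GENE_FIELDS
        | SEGREGATION_FIELDS
        | set(extra_fields)
    )


@dataclass(frozen=True)
class Criterion:
    """A weighted, independently evaluated predicate over variant context."""

    id: str
    field: str
    comparator: str
    value: object
    weight: float = 1.0
    section: str = "vcf_user_data"
    scope: Optional[str] = None
    samples: tuple[str, ...] = ()
    isoform_mode: str = "any"  # any-isoform OR (default) vs all-isoform AND

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise UsageError(f"criterion {self.id!r}: weight must be > 0")
        if self.comparator not in COMPARATORS:
            raise UsageError(
                f"criterion {self.id!r}: unknown comparator {self.comparator!r}; "
                f"known: {COMPARATORS}"
            )
        if self.section not in SECTIONS:
            raise UsageError(
                f"criterion {self.id!r}: unknown section {self.section!r}; "
                f"known: {SECTIONS}"
            )
        if self.isoform_mode not in ("any", "all"):
            raise UsageError(
                f"criterion {self.id!r}: isoform_mode must be 'any' or 'all'"
            )
        if self.scope is None:
            object.__setattr__(self, "scope", _SCOPE_OF.get(self.field, "variant"))
        if self.field in SEGREGATION_FIELDS and self.comparator != "matches":
            raise UsageError(
                f"criterion {self.id!r}: field {self.field!r} requires the "
                "'matches' comparator with a pattern mapping"
            )
        object.__setattr__(self, "samples", tuple(self.samples))


def criteria_from_dicts(
    entries: Sequence[Mapping], extra_fields: Iterable[str] = ()
) -> list[Criterion]:
    """Validate raw criterion mappings into :class:`Criterion` objects."""
    fields = known_fields(extra_fields)
    out: list[Criterion] = []
    seen: set[str] = set()
    for entry in entries:
        entry = dict(entry)
        cid = entry.get("id")
        if not cid:
            raise UsageError("every criterion needs an 'id'")
        if cid in seen:
            raise UsageError(f"duplicate criterion id {cid!r}")
        seen.add(cid)
        fname = entry.get("field")
        if fname not in fields:
            raise UsageError(
                f"criterion {cid!r}: unknown field {fname!r}; known fields: "
                f"{sorted(fields)}"
            )
        out.append(
            Criterion(
                id=cid,
                field=fname,
                comparator=str(entry.get("comparator", "=")),
                value=entry.get("value"),
                weight=float(entry.get("weight", 1.0)),
                section=entry.get("section", "vcf_user_data"),
                scope=entry.get("scope"),
                samples=tuple(entry.get("samples", ())),
                isoform_mode=entry.get("isoform_mode", "any"),
            )
        )
    if not out:
        raise UsageError("criteria config declares no criteria")
    return out


def parse_criteria(path, extra_fields: Iterable[str] = ()) -> list[Criterion]:
    """Parse and validate a YAML criteria configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "criteria" not in doc:
        raise UsageError(f"{path}: criteria config must be a mapping with a 'criteria' list")
    entries = doc["criteria"]
    if not isinstance(entries, list) or not entries:
        raise UsageError(f"{path}: 'criteria' must be a non-empty list")
    return criteria_from_dicts(entries, extra_fields=extra_fields)


def write_criteria_yaml(criteria: Sequence[Criterion], path) -> None:
    doc = {
        "criteria": [
            {
                "id": c.id,
                "section": c.section,
                "field": c.field,
                "comparator": c.comparator,
                "value": c.value,
                "weight": c.weight,
                **({"samples": list(c.samples)} if c.samples else {}),
                **(
                    {"isoform_mode": c.isoform_mode}
                    if c.isoform_mode != "any"
                    else {}
                ),
            }
            for c in criteria
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# evaluation context
# ---------------------------------------------------------------------------

@dataclass
class EvaluationContext:
    """Everything a criterion may inspect for one variant.

    Immutable during a query: criteria read, never write.
    """

    variant: Variant
    annotations: list[TranscriptAnnotation] = field(default_factory=list)
    mair: Optional[MairFlag] = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    fields: dict[str, object] = field(default_factory=dict)
    gene_sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return {a.gene_id for a in self.annotations if a.gene_id is not None}


def build_contexts(
    variants: Sequence[Variant],
    annotations: Mapping[tuple, list[TranscriptAnnotation]],
    frequency_index: Optional[FrequencyIndex] = None,
    gene_sets: Optional[Mapping[str, Iterable[str]]] = None,
    tables: Sequence[AnnotationTable] = (),
    sample_subset: Optional[Sequence[str]] = None,
) -> list[EvaluationContext]:
    """Assemble one evaluation context per variant.

    Joins frequency records (``gmaf``, ``site_id``, mAiR flag), custom
    annotation tables and named gene sets into a read-only view; with
    ``sample_subset`` only the chosen samples' calls are visible to
    sample-scope criteria.
    """
    if sample_subset is not None and len(sample_subset) == 0:
        raise UsageError("sample_subset must not be empty")
    sets = {
        name: frozenset(str(g) for g in members)
        for name, members in (gene_sets or {}).items()
    }
    contexts = []
    for v in variants:
        if sample_subset is None:
            calls = dict(v.calls)
        else:
            unknown = [s for s in sample_subset if s not in v.calls]
            if unknown:
                raise UsageError(
                    f"unknown samples {unknown}; known: {sorted(v.calls)}"
                )
            calls = {s: v.calls[s] for s in sample_subset}
        fields: dict[str, object] = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
        }
        fields.update(v.annotations)
        mair = None
        if frequency_index is not None:
            rec = frequency_index.lookup(*v.key)
            if rec is not None:
                fields["gmaf"] = rec.gmaf
                if rec.site_id is not None:
                    fields.setdefault("site_id", rec.site_id)
            mair = flag_mair(v, frequency_index)
            fields["is_mair"] = mair.is_mair
        for table in tables:
            if table.kind == "variant_keyed":
                values = table.variant_values(v)
                if values:
                    fields.update(values)
        gene_tables = [t for t in tables if t.kind == "gene_keyed"]
        ctx = EvaluationContext(
            variant=v,
            annotations=list(annotations.get(v.key, [])),
            mair=mair,
            calls=calls,
            fields=fields,
            gene_sets=sets,
        )
        for table in gene_tables:
            for gid in sorted(ctx.gene_ids):
                values = table.gene_values(gid)
                if values:
                    for k, val in values.items():
                        ctx.fields.setdefault(k, val)
        contexts.append(ctx)
    return contexts


# ---------------------------------------------------------------------------
# predicate evaluation
# ---------------------------------------------------------------------------

def _compare(comparator: str, actual, expected, gene_sets=None) -> bool:
    if actual is None:
        return False
    if comparator == "in_set":
        if isinstance(expected, str):
            members = (gene_sets or {}).get(expected)
            if members is None:
                logger.warning("unknown named set %r", expected)
                return False
        else:
            members = {str(x) for x in expected}
        return str(actual) in members
    if comparator == "matches":
        return re.search(str(expected), str(actual)) is not None
    if comparator == "=":
        if isinstance(actual, (int, float)) and isinstance(expected, (int, float)):
            return float(actual) == float(expected)
        return str(actual) == str(expected)
    try:
        a, e = float(actual), float(expected)
    except (TypeError, ValueError):
        return False
    if comparator == "<":
        return a < e
    if comparator == "<=":
        return a <= e
    if comparator == ">=":
        return a >= e
    if comparator == ">":
        return a > e
    raise UsageError(f"unknown comparator {comparator!r}")  # pragma: no cover


def _sample_field(call: GenotypeCall, fname: str):
    if fname == "gt":
        return call.gt.value
    if fname == "total_depth":
        return call.total_depth
    if fname == "alt_allele_depth":
        return call.alt_depth
    if fname == "ref_allele_depth":
        return call.ref_depth
    if fname == "quality":
        return call.quality
    raise UsageError(f"unknown sample field {fname!r}")  # pragma: no cover


def evaluate(criterion: Criterion, ctx: EvaluationContext) -> bool:
    """Evaluate one criterion against one variant context, independently.

    A field absent from the context makes the criterion false (with a
    data-gap warning), never an error: queries must run on sparsely
    annotated projects.
    """
    c = criterion
    if c.field in SEGREGATION_FIELDS:
        try:
            if c.field == "sharing":
                pattern = SharingPattern(dict(c.value))
                view = Variant(
                    chrom=ctx.variant.chrom,
                    pos=ctx.variant.pos,
                    ref=ctx.variant.ref,
                    alt=ctx.variant.alt,
                    calls=ctx.calls,
                )
                return matches_sharing(view, pattern)
            value = dict(c.value)
            pattern = ZygosityPattern(
                requirements=value.get("requirements", {}),
                only_in=frozenset(value.get("only_in", ())),
            )
            view = Variant(
                chrom=ctx.variant.chrom,
                pos=ctx.variant.pos,
                ref=ctx.variant.ref,
                alt=ctx.variant.alt,
                calls=ctx.calls,
            )
            return matches_zygosity(view, pattern)
        except UsageError as exc:
            _warn_gap(c.id, str(exc))
            return False

    if c.scope == "sample":
        if c.samples:
            pool = []
            for s in c.samples:
                call = ctx.calls.get(s)
                if call is None:
                    _warn_gap(c.id, f"sample {s!r} not in context")
                    return False
                pool.append(call)
            mode = all
        else:
            pool = list(ctx.calls.values())
            mode = any
        if not pool:
            return False
        return mode(
            _compare(c.comparator, _sample_field(call, c.field), c.value)
            for call in pool
        )

    if c.scope == "transcript":
        values = [getattr(a, c.field, None) for a in ctx.annotations]
        values = [v.value if hasattr(v, "value") else v for v in values]
        values = [v for v in values if v is not None]
        if not values:
            _warn_gap(c.id, "no isoform annotations")
            return False
        mode = any if c.isoform_mode == "any" else all
        return mode(
            _compare(c.comparator, v, c.value, ctx.gene_sets) for v in values
        )

    if c.scope == "gene":
        genes = sorted(ctx.gene_ids)
        if not genes:
            return False
        return any(
            _compare(c.comparator, g, c.value, ctx.gene_sets) for g in genes
        )

    # variant scope
    actual = ctx.fields.get(c.field)
    if actual is None and c.field not in ctx.fields:
        _warn_gap(c.id, f"field {c.field!r} absent from context")
        return False
    return _compare(c.comparator, actual, c.value, ctx.gene_sets)


# ---------------------------------------------------------------------------
# scoring and ranking
# ---------------------------------------------------------------------------

def score_variants(
    contexts: Sequence[EvaluationContext], criteria: Sequence[Criterion]
) -> list[ScoredVariant]:
    """Score every variant: sum of weights of satisfied criteria.

    Positive selection — every input variant appears in the output, however
    low its score.
    """
    scored = []
    for ctx in contexts:
        satisfied = frozenset(c.id for c in criteria if evaluate(c, ctx))
        score = sum(c.weight for c in criteria if c.id in satisfied)
        scored.append(ScoredVariant(variant=ctx.variant, satisfied=satisfied, score=score))
    return scored


@dataclass
class GeneResult:
    """One ranked gene: best-variant score, variant keys and per-criterion counts."""

    gene_id: str
    gene_score: float
    best_variant: tuple
    variant_keys: list[tuple]
    criterion_counts: dict[str, int]

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_at_best(self) -> int:
        return self._n_at_best

    _n_at_best: int = 0


@dataclass
class GeneRanking:
    """Gene ranking plus the score table and the results matrix.

    ``score_table`` maps score → (n_genes at that gene-score, n_variants at
    that variant-score); variants are counted once globally, but a variant
    in several overlapping genes contributes fully to each gene's row of
    the matrix. ``criterion_totals`` is the bottom "total number of
    variants" line: distinct variants satisfying each criterion.
    """

    genes: list[GeneResult]
    score_table: dict[float, tuple[int, int]]
    criterion_totals: dict[str, int]
    scored: list[ScoredVariant]

    def gene(self, gene_id: str) -> GeneResult:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise UsageError(f"gene {gene_id!r} not in ranking")

    @property
    def max_score(self) -> float:
        return max((s.score for s in self.scored), default=0.0)


def rank_genes(
    scored: Sequence[ScoredVariant],
    annotations: Mapping[tuple, list[TranscriptAnnotation]],
    criteria: Sequence[Criterion],
) -> GeneRanking:
    """Rank genes by their highest-scoring variant.

    Ties are broken by (number of variants at the gene score, descending)
    then gene ID; a variant overlapping several genes counts fully for each.
    """
    by_gene: dict[str, list[ScoredVariant]] = {}
    for sv in scored:
        genes = {
            a.gene_id
            for a in annotations.get(sv.variant.key, [])
            if a.gene_id is not None
        }
        for g in genes:
            by_gene.setdefault(g, []).append(sv)

    results = []
    for gene_id, svs in by_gene.items():
        gene_score = max(sv.score for sv in svs)
        best = min(
            (sv for sv in svs if sv.score == gene_score),
            key=lambda sv: sv.variant.key,
        )
        counts = {
            c.id: sum(1 for sv in svs if c.id in sv.satisfied) for c in criteria
        }
        gr = GeneResult(
            gene_id=gene_id,
            gene_score=gene_score,
            best_variant=best.variant.key,
            variant_keys=[sv.variant.key for sv in svs],
            criterion_counts=counts,
        )
        gr._n_at_best = sum(1 for sv in svs if sv.score == gene_score)
        results.append(gr)
    results.sort(key=lambda g: (-g.gene_score, -g.n_at_best, g.gene_id))

    gene_score_counts: dict[float, int] = {}
    for g in results:
        gene_score_counts[g.gene_score] = gene_score_counts.get(g.gene_score, 0) + 1
    variant_score_counts: dict[float, int] = {}
    for sv in scored:
        variant_score_counts[sv.score] = variant_score_counts.get(sv.score, 0) + 1
    score_table = {
        s: (gene_score_counts.get(s, 0), variant_score_counts.get(s, 0))
        for s in sorted(set(gene_score_counts) | set(variant_score_counts), reverse=True)
    }
    criterion_totals = {
        c.id: sum(1 for sv in scored if c.id in sv.satisfied) for c in criteria
    }
    return GeneRanking(
        genes=results,
        score_table=score_table,
        criterion_totals=criterion_totals,
        scored=list(scored),
    )


def run_query(
    variants: Sequence[Variant],
    criteria: Sequence[Criterion],
    annotations: Mapping[tuple, list[TranscriptAnnotation]],
    frequency_index: Optional[FrequencyIndex] = None,
    gene_sets: Optional[Mapping[str, Iterable[str]]] = None,
    tables: Sequence[AnnotationTable] = (),
    sample_subset: Optional[Sequence[str]] = None,
) -> GeneRanking:
    """Full query composition: context → evaluate → score → rank.

    Deterministic given identical inputs; ``sample_subset`` restricts the
    calls visible to sample-scope and segregation criteria.
    """
    contexts = build_contexts(
        variants,
        annotations,
        frequency_index=frequency_index,
        gene_sets=gene_sets,
        tables=tables,
        sample_subset=sample_subset,
    )
    scored = score_variants(contexts, criteria)
    return rank_genes(scored, annotations, criteria)
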