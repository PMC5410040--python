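"""Cross-patient gene-level recurrence.

For unrelated cohorts and de novo designs it matters more that the same
*gene* is hit in different patients than that the patients share the same
variant. A variant qualifies for a patient when that patient carries it
(het or hom-alt) and its query score reaches the threshold; genes with
qualifying variants in enough distinct patients are reported, whether or
not the variants themselves differ.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Optional, Sequence

from .model import (
    GeneRecurrence,
    ScoredVariant,
    TranscriptAnnotation,
    UsageError,
)

__all__ = ["recurrent_genes", "summary_distribution", "write_recurrence_tsv"]


def recurrent_genes(
    scored_variants: Sequence[ScoredVariant],
    annotations: Mapping[tuple, list[TranscriptAnnotation]],
    min_patients: int,
    min_score: Optional[float] = None,
) -> list[GeneRecurrence]:
    """Genes carrying qualifying variants in at least ``min_patients`` patients.

    ``min_score`` defaults to the query's maximum observed score. Sorted by
    (n_patients desc, n_distinct_variants desc, gene_id).
    """
    if min_patients < 2:
        raise UsageError("min_patients must be >= 2 (recurrence across patients)")
    if min_score is None:
        min_score = max((sv.score for sv in scored_variants), default=0.0)

    per_gene: dict[str, dict[str, list[tuple]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for sv in scored_variants:
        if sv.score < min_score:
            continue
        genes = {
            a.gene_id
            for a in annotations.get(sv.variant.key, [])
            if a.gene_id is not None
        }
        if not genes:
            continue
        carriers = [
            s for s, call in sv.variant.calls.items() if call.carries_alt
        ]
        for gene in genes:
            for sample in carriers:
                per_gene[gene][sample].append(sv.variant.key)

    out = []
    for gene, patients in per_gene.items():
        if len(patients) < min_patients:
            continue
        out.append(
            GeneRecurrence(
                gene_id=gene,
                patients=tuple(
                    (s, tuple(sorted(set(keys))))
                    for s, keys in sorted(patients.items())
                ),
            )
        )
    out.sort(key=lambda r: (-r.n_patients, -r.n_distinct_variants, r.gene_id))
    return out


def summary_distribution(
    recurrences: Sequence[GeneRecurrence],
) -> dict[int, int]:
    """Histogram: number of genes per patient count."""
    hist: dict[int, int] = {}
    for rec in recurrences:
        hist[rec.n_patients] = hist.get(rec.n_patients, 0) + 1
    return dict(sorted(hist.items()))


def write_recurrence_tsv(recurrences: Sequence[GeneRecurrence], path) -> None:
    lines = ["gene_id\tn_patients\tn_distinct_variants\tpatients"]
    for rec in recurrences:
        patients = ";".join(
            f"{s}:" + ",".join(f"{c}:{p}:{r}:{a}" for c, p, r, a in keys)
            for s, keys in rec.patients
        )
        lines.append(
            f"{rec.gene_id}\t{rec.n_patients}\t{rec.n_distinct_variants}\t{patients}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
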