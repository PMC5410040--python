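"""Sharing, zygosity and trio inheritance logic.

"Present" means the sample demonstrably carries at least one alternate
allele (het or hom-alt); "absent" means hom-ref or missing. Missing
genotypes are conservative: they count as absent for sharing and fail every
explicit zygosity requirement. Parental origin of a child's heterozygous
variant is inferred from the trio genotypes, not from phase flags.
"""

from __future__ import annotations

import enum
import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import (
    Genotype,
    TranscriptAnnotation,
    TrioSpec,
    UsageError,
    Variant,
)

__all__ = [
    "Requirement",
    "SharingState",
    "SharingPattern",
    "ZygosityPattern",
    "Origin",
    "matches_sharing",
    "matches_zygosity",
    "de_novo_candidates",
    "parental_origin",
    "compound_het_genes",
    "CompoundHetResult",
    "DEFAULT_MIN_PARENT_DEPTH",
]

DEFAULT_MIN_PARENT_DEPTH = 10


class SharingState(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    IGNORE = "ignore"


class Requirement(str, enum.Enum):
    HOM_ALT_REQUIRED = "hom_alt_required"
    HET_REQUIRED = "het_required"
    NOT_HOM_ALT = "not_hom_alt"
    IGNORE = "ignore"


@dataclass(frozen=True)
class SharingPattern:
    """Per-sample present/absent/ignore requirements, conjoined."""

    requirements: Mapping[str, SharingState]

    def __post_init__(self) -> None:
        reqs = {k: SharingState(v) for k, v in self.requirements.items()}
        object.__setattr__(self, "requirements", reqs)
        if all(s is SharingState.IGNORE for s in reqs.values()) or not reqs:
            raise UsageError("sharing pattern must constrain at least one sample")


@dataclass(frozen=True)
class ZygosityPattern:
    """Per-sample zygosity requirements with an optional exclusivity set.

    Samples in ``only_in`` must be hom-alt while every other non-ignored
    project sample must not be.
    """

    requirements: Mapping[str, Requirement]
    only_in: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        reqs = {k: Requirement(v) for k, v in self.requirements.items()}
        object.__setattr__(self, "requirements", reqs)
        object.__setattr__(self, "only_in", frozenset(self.only_in))
        for s in self.only_in:
            if reqs.get(s, Requirement.IGNORE) is Requirement.IGNORE:
                raise UsageError(
                    f"sample {s!r} in only_in must carry a non-ignore requirement"
                )


def _check_samples_known(variant: Variant, samples: Iterable[str]) -> None:
    unknown = [s for s in samples if s not in variant.calls]
    if unknown:
        raise UsageError(
            f"samples {unknown} not called at {variant.chrom}:{variant.pos}; "
            f"known samples: {sorted(variant.calls)}"
        )


def matches_sharing(variant: Variant, pattern: SharingPattern) -> bool:
    """Whether the variant's calls satisfy every per-sample sharing requirement."""
    _check_samples_known(variant, pattern.requirements)
    for sample, state in pattern.requirements.items():
        if state is SharingState.IGNORE:
            continue
        gt = variant.calls[sample].gt
        present = gt in (Genotype.HET, Genotype.HOM_ALT)
        absent = gt in (Genotype.HOM_REF, Genotype.MISSING)
        if state is SharingState.PRESENT and not present:
            return False
        if state is SharingState.ABSENT and not absent:
            return False
    return True


def _satisfies_requirement(gt: Genotype, req: Requirement) -> bool:
    if req is Requirement.IGNORE:
        return True
    # missing/half-calls fail every explicit zygosity requirement
    if gt in (Genotype.MISSING, Genotype.OTHER_PLOIDY):
        return False
    if req is Requirement.HOM_ALT_REQUIRED:
        return gt is Genotype.HOM_ALT
    if req is Requirement.HET_REQUIRED:
        return gt is Genotype.HET
    if req is Requirement.NOT_HOM_ALT:
        return gt is not Genotype.HOM_ALT
    raise UsageError(f"unknown requirement {req}")  # pragma: no cover


def matches_zygosity(variant: Variant, pattern: ZygosityPattern) -> bool:
    """Whether the variant's calls satisfy every zygosity requirement.

    With ``only_in``, listed samples must be hom-alt and every other sample
    called on the variant (except explicitly ignored ones) must not be
    called hom-alt.
    """
    _check_samples_known(variant, pattern.requirements)
    _check_samples_known(variant, pattern.only_in)
    for sample, req in pattern.requirements.items():
        if not _satisfies_requirement(variant.calls[sample].gt, req):
            return False
    if pattern.only_in:
        for s in pattern.only_in:
            if variant.calls[s].gt is not Genotype.HOM_ALT:
                return False
        ignored = {
            s
            for s, r in pattern.requirements.items()
            if r is Requirement.IGNORE
        }
        for s, call in variant.calls.items():
            if s in pattern.only_in or s in ignored:
                continue
            if call.gt is Genotype.HOM_ALT:
                return False
    return True


def de_novo_candidates(
    variants: Iterable[Variant],
    trio: TrioSpec,
    min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH,
) -> list[Variant]:
    """Variants present in the child and confidently absent from both parents.

    Both parental calls must be hom-ref/missing *and* have total depth of at
    least ``min_parent_depth`` — the depth guard protects against allele
    dropout masquerading as a de novo event.
    """
    pattern = SharingPattern(
        {
            trio.child: SharingState.PRESENT,
            trio.father: SharingState.ABSENT,
            trio.mother: SharingState.ABSENT,
        }
    )
    out = []
    for v in variants:
        if not matches_sharing(v, pattern):
            continue
        ok = True
        for parent in (trio.father, trio.mother):
            depth = v.calls[parent].total_depth
            if depth is None or depth < min_parent_depth:
                ok = False
                break
        if ok:
            out.append(v)
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


class Origin(str, enum.Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    EITHER = "either"
    UNRESOLVED = "unresolved"
    DE_NOVO_LIKE = "de_novo_like"


def parental_origin(variant: Variant, trio: TrioSpec) -> Origin:
    """Infer which parent contributed the child's heterozygous alternate allele."""
    _check_samples_known(variant, (trio.child, trio.father, trio.mother))
    child = variant.calls[trio.child].gt
    father = variant.calls[trio.father].gt
    mother = variant.calls[trio.mother].gt
    if any(
        gt in (Genotype.MISSING, Genotype.OTHER_PLOIDY)
        for gt in (child, father, mother)
    ):
        return Origin.UNRESOLVED
    if child is not Genotype.HET:
        return Origin.UNRESOLVED
    pat = father in (Genotype.HET, Genotype.HOM_ALT)
    mat = mother in (Genotype.HET, Genotype.HOM_ALT)
    if pat and mat:
        return Origin.EITHER
    if pat:
        return Origin.PATERNAL
    if mat:
        return Origin.MATERNAL
    return Origin.DE_NOVO_LIKE


@dataclass
class CompoundHetResult:
    """Compound-heterozygous candidate pairs per gene.

    ``resolved`` pairs have one clearly paternal and one clearly maternal
    variant; ``ambiguous`` pairs involve at least one variant whose origin
    could be either parent and therefore cannot be confirmed to hit both
    haplotypes.
    """

    resolved: dict[str, list[tuple[Variant, Variant]]] = field(default_factory=dict)
    ambiguous: dict[str, list[tuple[Variant, Variant]]] = field(default_factory=dict)


def compound_het_genes(
    variants: Iterable[Variant],
    annotations: Mapping[tuple, list[TranscriptAnnotation]],
    trio: TrioSpec,
) -> CompoundHetResult:
    """Find genes with two child-het variants inherited from different parents.

    A variant is a compound-het candidate when the child is het, at least
    one parent carries it and neither parent is hom-alt for it. Pairs whose
    parental origins resolve to the two different parents are reported as
    ``resolved``; pairs where one or both origins are "either" go to
    ``ambiguous``.
    """
    by_gene: dict[str, list[Variant]] = defaultdict(list)
    for v in variants:
        genes = {
            a.gene_id for a in annotations.get(v.key, []) if a.gene_id is not None
        }
        for g in sorted(genes):
            by_gene[g].append(v)

    result = CompoundHetResult()
    for gene, vs in sorted(by_gene.items()):
        candidates = []
        for v in vs:
            if v.calls[trio.child].gt is not Genotype.HET:
                continue
            father = v.calls[trio.father].gt
            mother = v.calls[trio.mother].gt
            if Genotype.HOM_ALT in (father, mother):
                continue
            origin = parental_origin(v, trio)
            if origin in (Origin.PATERNAL, Origin.MATERNAL, Origin.EITHER):
                candidates.append((v, origin))
        for (v1, o1), (v2, o2) in itertools.combinations(candidates, 2):
            if {o1, o2} == {Origin.PATERNAL, Origin.MATERNAL}:
                result.resolved.setdefault(gene, []).append((v1, v2))
            elif Origin.EITHER in (o1, o2) and not (
                o1 == o2 != Origin.EITHER
            ):
                # one or both "either": cannot exclude a single-haplotype pair
                result.ambiguous.setdefault(gene, []).append((v1, v2))
    return result
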