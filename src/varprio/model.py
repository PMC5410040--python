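"""Shared data model for the prioritization toolkit.

Every module operates on the types defined here: normalized single-alternate
variants with per-sample genotype calls, stranded transcript models, weighted
criteria, scored variants and runs of homozygosity.

Coordinate conventions: variant and transcript positions are 1-based
inclusive (VCF/GFF3 standard); region tracks loaded from BED are 0-based
half-open and converted at comparison boundaries via
:meth:`RegionTrack.contains_pos`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class VarprioError(Exception):
    """Base class for all package errors."""


class FormatError(VarprioError):
    """A file does not conform to its declared format."""


class InputError(VarprioError):
    """Inputs are structurally valid but semantically unusable."""


class UsageError(VarprioError):
    """An operation was called with inconsistent arguments."""


class ReferenceMismatchError(VarprioError):
    """A variant's REF string disagrees with the genome sequence."""


class Genotype(str, enum.Enum):
    """Zygosity of one sample's call with respect to a single alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"
    OTHER_PLOIDY = "other_ploidy"  # half-calls like ./1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GenotypeCall:
    """One sample's genotype at one decomposed variant.

    ``allele_depths`` holds [REF depth, ALT depth] for the decomposed
    alternate allele; ``total_depth`` is the site depth (DP, or RO + sum(AO)
    when derived).
    """

    sample_id: str
    gt: Genotype
    allele_depths: Optional[list[int]] = None
    total_depth: Optional[int] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.allele_depths is not None:
            if any(d < 0 for d in self.allele_depths):
                raise InputError(
                    f"negative allele depth for sample {self.sample_id!r}"
                )
            if self.total_depth is not None and self.total_depth < max(
                self.allele_depths
            ):
                raise InputError(
                    f"total_depth {self.total_depth} < max allele depth for "
                    f"sample {self.sample_id!r}"
                )

    @property
    def ref_depth(self) -> Optional[int]:
        return self.allele_depths[0] if self.allele_depths else None

    @property
    def alt_depth(self) -> Optional[int]:
        if self.allele_depths and len(self.allele_depths) > 1:
            return self.allele_depths[1]
        return None

    @property
    def carries_alt(self) -> bool:
        """True when the call demonstrably carries >=1 alternate allele."""
        return self.gt in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class Variant:
    """One normalized alternate allele at a genomic site.

    Multiallelic VCF records are decomposed into one ``Variant`` per
    alternate allele before any downstream operation. ``annotations`` is the
    open-ended bag of per-variant columns (population frequencies,
    pathogenicity scores, custom-table joins).
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise InputError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise InputError(
                f"REF equals ALT ({self.ref}) at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def call(self, sample_id: str) -> GenotypeCall:
        try:
            return self.calls[sample_id]
        except KeyError:
            raise UsageError(
                f"sample {sample_id!r} has no call at {self.chrom}:{self.pos}; "
                f"known samples: {sorted(self.calls)}"
            ) from None


@dataclass(frozen=True)
class RegionTrack:
    """One BED4 row: a region associated with a sample (e.g. capture target)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"region start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    def contains_pos(self, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside this region."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class FrequencyRecord:
    """A known polymorphic site with the global frequency of one alternate allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gmaf: float
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gmaf <= 1.0:
            raise FormatError(
                f"gmaf must lie in [0,1], got {self.gmaf} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class RegionClass(str, enum.Enum):
    CDS_EXONIC = "cds_exonic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    NONCODING_EXONIC = "noncoding_exonic"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Effect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: Reporting severity orders (most severe first). Used only where a single
#: per-variant summary is required; per-isoform lists are never collapsed.
EFFECT_SEVERITY: tuple[Effect, ...] = (
    Effect.STOP_GAIN,
    Effect.FRAMESHIFT,
    Effect.STOP_LOSS,
    Effect.START_LOSS,
    Effect.MISSENSE,
    Effect.INFRAME_INDEL,
    Effect.SYNONYMOUS,
    Effect.NONE,
)

REGION_SEVERITY: tuple[RegionClass, ...] = (
    RegionClass.SPLICE_SITE,
    RegionClass.CDS_EXONIC,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.NONCODING_EXONIC,
    RegionClass.INTRONIC,
    RegionClass.UPSTREAM,
    RegionClass.DOWNSTREAM,
    RegionClass.INTERGENIC,
)

#: Effects that change the encoded protein ("protein-changing" in queries).
PROTEIN_CHANGING: frozenset[Effect] = frozenset(
    {
        Effect.MISSENSE,
        Effect.STOP_GAIN,
        Effect.STOP_LOSS,
        Effect.START_LOSS,
        Effect.FRAMESHIFT,
        Effect.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon/CDS structure of one transcript isoform.

    ``exons`` and ``cds`` are genomic-coordinate-sorted lists of 1-based
    inclusive (start, end) intervals; ``cds`` may be empty for non-coding
    transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise InputError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise InputError(
                    f"overlapping/unsorted exons in {self.transcript_id}"
                )
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in exons):
                raise InputError(
                    f"CDS interval {cs}-{ce} of {self.transcript_id} not "
                    "contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        )

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Consequence of one variant on one transcript isoform."""

    transcript_id: Optional[str]
    region_class: RegionClass
    effect: Effect = Effect.NONE
    gene_id: Optional[str] = None
    hgvs_like: Optional[str] = None

    def __post_init__(self) -> None:
        coding = self.region_class is RegionClass.CDS_EXONIC
        if coding != (self.effect is not Effect.NONE):
            raise InputError(
                "effect != none exactly when region_class is cds_exonic "
                f"(got {self.region_class}/{self.effect})"
            )


@dataclass(frozen=True)
class MairFlag:
    """Minor-Allele-in-Reference flag for one site.

    ``is_mair`` is true when the reference allele is itself the minor allele
    (population frequency strictly below the threshold), a situation that
    produces systematic apparent variants in most individuals.
    """

    is_mair: bool
    ref_allele_frequency: Optional[float] = None


@dataclass(frozen=True)
class TrioSpec:
    """Child/father/mother sample identifiers."""

    child: str
    father: str
    mother: str

    def __post_init__(self) -> None:
        if len({self.child, self.father, self.mother}) != 3:
            raise UsageError("trio requires three distinct sample IDs")

    def swapped(self) -> "TrioSpec":
        return TrioSpec(self.child, self.mother, self.father)


@dataclass(frozen=True)
class InformativePosition:
    """A high-GMAF known site with the sample's (possibly inferred) zygosity."""

    chrom: str
    pos: int
    state: Genotype  # HOM_REF used for the inferred-0/0 state
    source_gmaf: float


@dataclass
class ROHRegion:
    """A homozygous stretch over informative positions.

    Coordinates are the 1-based positions of the first/last informative
    position in the run; ``ratio`` is n_hom_ref / (n_hom_ref + n_het +
    n_hom_alt).
    """

    chrom: str
    start: int
    end: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    seed: bool = False

    @property
    def n_positions(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def ratio(self) -> float:
        return self.n_hom_ref / self.n_positions

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScoredVariant:
    """A variant with the set of satisfied criteria and its summed weight score."""

    variant: Variant
    satisfied: frozenset[str]
    score: float


@dataclass(frozen=True)
class GeneRecurrence:
    """A gene mutated in several patients, with each patient's qualifying variants."""

    gene_id: str
    patients: tuple[tuple[str, tuple[tuple[str, int, str, str], ...]], ...]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_distinct_variants(self) -> int:
        return len({k for _, keys in self.patients for k in keys})
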