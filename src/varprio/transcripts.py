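"""Per-isoform variant annotation.

Each variant is annotated against *every* overlapping transcript isoform —
no collapsing onto a "major" isoform — because alternative splicing lets the
same genomic change be, say, a missense substitution in one transcript and
intronic in another. Region classification, coding consequences (standard
genetic code, strand-corrected spliced CDS) and minor-allele-in-reference
flagging live here.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .io_formats import FrequencyIndex
from .model import (
    Effect,
    FormatError,
    MairFlag,
    ReferenceMismatchError,
    RegionClass,
    TranscriptAnnotation,
    TranscriptModel,
    UsageError,
    Variant,
)

__all__ = [
    "GenomeAccessor",
    "load_gff3",
    "classify_region",
    "coding_effect",
    "annotate_all",
    "flag_mair",
    "DEFAULT_FLANK",
    "DEFAULT_SPLICE_WINDOW",
]

DEFAULT_FLANK = 5000  # bp: upstream/downstream reach of a transcript
DEFAULT_SPLICE_WINDOW = 2  # bp: canonical donor/acceptor dinucleotides
MAIR_THRESHOLD = 0.1


class GenomeAccessor:
    """1-based inclusive access to an indexed FASTA genome."""

    def __init__(self, path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive."""
        if chrom not in self._fasta:
            raise UsageError(f"chromosome {chrom!r} not in genome FASTA")
        return str(self._fasta[chrom][start - 1 : end])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())


def load_gff3(path) -> list[TranscriptModel]:
    """Load transcript models from a GFF3 file.

    Expects the conventional gene/mRNA(transcript)/exon/CDS hierarchy with
    ID/Parent attributes.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for tx in list(db.features_of_type("mRNA")) + list(
        db.features_of_type("transcript")
    ):
        exons = tuple(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = tuple((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.attributes.get("Parent", [tx.id])[0]
        if not exons:
            raise FormatError(f"transcript {tx.id} has no exon features")
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
            )
        )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return models


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_region(
    variant: Variant,
    tx: TranscriptModel,
    flank: int = DEFAULT_FLANK,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> RegionClass:
    """Classify where the variant's REF span falls relative to one isoform.

    Splice-site takes precedence: a variant intersecting the first/last
    ``splice_window`` intronic bases of any intron — or straddling an
    exon/intron boundary — is ``splice_site`` regardless of exonic overlap.
    """
    if variant.chrom != tx.chrom:
        raise UsageError(
            f"variant on {variant.chrom} vs transcript {tx.transcript_id} "
            f"on {tx.chrom}"
        )
    vs, ve = variant.pos, variant.end

    if not _overlaps(vs, ve, tx.start - flank, tx.end + flank):
        return RegionClass.INTERGENIC
    if not _overlaps(vs, ve, tx.start, tx.end):
        upstream_side = vs < tx.start
        if tx.strand == "+":
            return RegionClass.UPSTREAM if upstream_side else RegionClass.DOWNSTREAM
        return RegionClass.DOWNSTREAM if upstream_side else RegionClass.UPSTREAM

    in_exon = any(_overlaps(vs, ve, s, e) for s, e in tx.exons)
    introns = tx.introns
    in_intron = any(_overlaps(vs, ve, s, e) for s, e in introns)
    if in_exon and in_intron:
        return RegionClass.SPLICE_SITE
    for s, e in introns:
        w = min(splice_window, e - s + 1)
        if w > 0 and (
            _overlaps(vs, ve, s, s + w - 1) or _overlaps(vs, ve, e - w + 1, e)
        ):
            return RegionClass.SPLICE_SITE
    if in_intron:
        return RegionClass.INTRONIC
    if not in_exon:
        # inside transcript span but neither exon nor intron can only happen
        # for zero-length oddities; treat as intronic
        return RegionClass.INTRONIC
    if not tx.is_coding:
        return RegionClass.NONCODING_EXONIC
    if any(_overlaps(vs, ve, s, e) for s, e in tx.cds):
        return RegionClass.CDS_EXONIC
    # exonic but outside CDS: 5' or 3' UTR depending on strand
    cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
    if ve < cds_start:
        return RegionClass.UTR5 if tx.strand == "+" else RegionClass.UTR3
    if vs > cds_end:
        return RegionClass.UTR3 if tx.strand == "+" else RegionClass.UTR5
    # exonic, between CDS intervals without touching them (rare): call UTR5
    return RegionClass.UTR5 if tx.strand == "+" else RegionClass.UTR3


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _cds_layout(tx: TranscriptModel, genome: GenomeAccessor):
    """Spliced CDS sequence (coding orientation) and genomic→CDS index map."""
    genomic_seq = "".join(genome.fetch(tx.chrom, s, e) for s, e in tx.cds)
    positions: list[int] = []
    for s, e in tx.cds:
        positions.extend(range(s, e + 1))
    if tx.strand == "+":
        cds_seq = genomic_seq
        index_of = {p: i for i, p in enumerate(positions)}
    else:
        cds_seq = _revcomp(genomic_seq)
        n = len(positions)
        index_of = {p: n - 1 - i for i, p in enumerate(positions)}
    return cds_seq, index_of


def _translate(seq: str) -> str:
    # truncate any trailing partial codon; standard genetic code
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def _classify_protein_change(
    ref_prot: str, mut_prot: str, changed_from: int
) -> Effect:
    """Compare reference and mutant translations of the same codon range.

    ``changed_from`` is the first affected codon index within the supplied
    strings (0 for local windows). Precedence: start-loss, stop-gain,
    stop-loss, then missense; identical translations are synonymous.
    """
    if ref_prot == mut_prot:
        return Effect.SYNONYMOUS
    if changed_from == 0 and ref_prot[:1] == "M" and mut_prot[:1] != "M":
        return Effect.START_LOSS
    for r, m in zip(ref_prot, mut_prot):
        if r != m:
            if m == "*":
                return Effect.STOP_GAIN
            if r == "*":
                return Effect.STOP_LOSS
    return Effect.MISSENSE


def coding_effect(
    variant: Variant, tx: TranscriptModel, genome: GenomeAccessor
) -> Effect:
    """Coding consequence of a CDS-overlapping variant on one isoform.

    Substitutions are resolved by translating the affected codon(s) of the
    spliced, strand-corrected CDS with the standard genetic code; indels are
    frameshift when the REF/ALT length difference is not a multiple of 3 and
    in-frame otherwise.

    Raises :class:`ReferenceMismatchError` when the variant's REF string
    disagrees with the genome.
    """
    if not tx.is_coding:
        raise UsageError(f"transcript {tx.transcript_id} has no CDS")
    genome_ref = genome.fetch(variant.chrom, variant.pos, variant.end)
    if genome_ref != variant.ref.upper():
        raise ReferenceMismatchError(
            f"variant {variant.chrom}:{variant.pos} REF={variant.ref} but "
            f"genome has {genome_ref}"
        )

    if variant.is_indel:
        shift = abs(len(variant.ref) - len(variant.alt)) % 3
        return Effect.FRAMESHIFT if shift != 0 else Effect.INFRAME_INDEL

    cds_seq, index_of = _cds_layout(tx, genome)
    # substitute every REF base that lies within the CDS
    mutant = list(cds_seq)
    touched: list[int] = []
    for offset in range(len(variant.ref)):
        gpos = variant.pos + offset
        idx = index_of.get(gpos)
        if idx is None:
            continue
        base = variant.alt[offset]
        mutant[idx] = base if tx.strand == "+" else base.translate(_COMPLEMENT)
        touched.append(idx)
    if not touched:
        raise UsageError(
            f"variant {variant.chrom}:{variant.pos} does not overlap the CDS "
            f"of {tx.transcript_id}"
        )
    first_codon = min(touched) // 3
    last_codon = max(touched) // 3
    lo, hi = first_codon * 3, (last_codon + 1) * 3
    ref_window = _translate(cds_seq[lo:hi])
    mut_window = _translate("".join(mutant[lo:hi]))
    return _classify_protein_change(ref_window, mut_window, first_codon)


def _hgvs_like(variant: Variant, effect: Effect) -> str:
    return f"{variant.ref}>{variant.alt}({effect.value})"


class TranscriptIndex:
    """Interval index over flanked transcript spans, per chromosome."""

    def __init__(self, transcripts: Iterable[TranscriptModel], flank: int):
        self.flank = flank
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for tx in transcripts:
            # IntervalTree is half-open; store [start-flank, end+flank+1)
            self._trees[tx.chrom][max(1, tx.start - flank) : tx.end + flank + 1] = tx

    def overlapping(self, variant: Variant) -> list[TranscriptModel]:
        tree = self._trees.get(variant.chrom)
        if tree is None:
            return []
        hits = tree[variant.pos : variant.end + 1]
        return sorted(
            (iv.data for iv in hits), key=lambda t: (t.start, t.transcript_id)
        )


def annotate_all(
    variants: Iterable[Variant],
    transcripts: Iterable[TranscriptModel],
    genome: GenomeAccessor,
    flank: int = DEFAULT_FLANK,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> dict[tuple, list[TranscriptAnnotation]]:
    """Annotate each variant against every isoform whose flanked span covers it.

    Returns a map from :attr:`Variant.key` to the per-isoform annotation
    list; a variant overlapping nothing gets a single ``intergenic``
    annotation. Every isoform is preserved.
    """
    index = TranscriptIndex(transcripts, flank)
    result: dict[tuple, list[TranscriptAnnotation]] = {}
    for v in variants:
        anns: list[TranscriptAnnotation] = []
        for tx in index.overlapping(v):
            region = classify_region(v, tx, flank=flank, splice_window=splice_window)
            if region is RegionClass.INTERGENIC:
                continue
            if region is RegionClass.CDS_EXONIC:
                eff = coding_effect(v, tx, genome)
                anns.append(
                    TranscriptAnnotation(
                        transcript_id=tx.transcript_id,
                        region_class=region,
                        effect=eff,
                        gene_id=tx.gene_id,
                        hgvs_like=_hgvs_like(v, eff),
                    )
                )
            else:
                anns.append(
                    TranscriptAnnotation(
                        transcript_id=tx.transcript_id,
                        region_class=region,
                        effect=Effect.NONE,
                        gene_id=tx.gene_id,
                    )
                )
        if not anns:
            anns = [
                TranscriptAnnotation(
                    transcript_id=None, region_class=RegionClass.INTERGENIC
                )
            ]
        result[v.key] = anns
    return result


def flag_mair(
    variant: Variant,
    frequency_index: FrequencyIndex,
    threshold: float = MAIR_THRESHOLD,
) -> MairFlag:
    """Flag a site whose reference allele is the population minor allele.

    The reference-allele frequency is 1 − (sum of alternate-allele GMAFs of
    all known records at the site sharing the variant's REF); the flag is
    raised when that frequency is strictly below ``threshold``. Sites absent
    from the frequency table are never flagged.
    """
    records = [
        r
        for r in frequency_index.at_site(variant.chrom, variant.pos)
        if r.ref == variant.ref
    ]
    if not records:
        return MairFlag(is_mair=False, ref_allele_frequency=None)
    # round away binary-float dust so the strict < threshold is exact at
    # printed precisions (1 - 0.9 must compare equal to 0.1, not below it)
    ref_freq = max(0.0, round(1.0 - sum(r.gmaf for r in records), 9))
    return MairFlag(is_mair=ref_freq < threshold, ref_allele_frequency=ref_freq)
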