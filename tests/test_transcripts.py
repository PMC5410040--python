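"""Per-isoform region classification, coding consequences, mAiR flags."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import StringGenome, oracle_effect
from varprio import (
    Effect,
    FrequencyIndex,
    FrequencyRecord,
    RegionClass,
    TranscriptModel,
    Variant,
    annotate_all,
    classify_region,
    coding_effect,
    flag_mair,
)
from varprio.model import ReferenceMismatchError, UsageError

# handcrafted plus-strand transcript: exons 101-160 / 301-360 / 501-560,
# CDS 131-160 / 301-360 / 501-530 (120 bp = 40 codons), UTRs 30 bp each.
CODONS = ["ATG", "TAC", "CTT"] + ["GCT"] * 36 + ["TAA"]
CDS_SEQ = "".join(CODONS)


def build_plus_genome() -> StringGenome:
    seq = list("ACGT" * 200)  # 800 bp of filler
    cds_positions = (
        list(range(131, 161)) + list(range(301, 361)) + list(range(501, 531))
    )
    for base, pos in zip(CDS_SEQ, cds_positions):
        seq[pos - 1] = base
    return StringGenome({"chrT": "".join(seq)})


PLUS_TX = TranscriptModel(
    gene_id="GT1",
    transcript_id="GT1.t1",
    chrom="chrT",
    strand="+",
    exons=((101, 160), (301, 360), (501, 560)),
    cds=((131, 160), (301, 360), (501, 530)),
)


@pytest.fixture(scope="module")
def plus_genome():
    return build_plus_genome()


def snv(pos: int, ref: str, alt: str, chrom: str = "chrT") -> Variant:
    return Variant(chrom, pos, ref, alt)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (134, RegionClass.CDS_EXONIC),
            (110, RegionClass.UTR5),
            (545, RegionClass.UTR3),
            (230, RegionClass.INTRONIC),
            (162, RegionClass.SPLICE_SITE),  # donor + 2
            (163, RegionClass.INTRONIC),  # just beyond the splice window
            (299, RegionClass.SPLICE_SITE),  # acceptor - 2
            (50, RegionClass.UPSTREAM),
            (700, RegionClass.DOWNSTREAM),
        ],
    )
    def test_single_base_classes(self, plus_genome, pos, expected):
        ref = plus_genome.base("chrT", pos)
        alt = "A" if ref != "A" else "C"
        assert classify_region(snv(pos, ref, alt), PLUS_TX) is expected

    def test_exon_intron_straddle_is_splice_site(self, plus_genome):
        ref = plus_genome.fetch("chrT", 157, 164)
        v = Variant("chrT", 157, ref, ref[0])
        assert classify_region(v, PLUS_TX) is RegionClass.SPLICE_SITE

    def test_strand_flips_upstream_downstream(self):
        minus_tx = TranscriptModel(
            "GT1", "GT1.m", "chrT", "-", PLUS_TX.exons, PLUS_TX.cds
        )
        assert classify_region(snv(50, "A", "C"), minus_tx) is RegionClass.DOWNSTREAM
        assert classify_region(snv(700, "A", "C"), minus_tx) is RegionClass.UPSTREAM

    def test_beyond_flank_is_intergenic(self):
        assert (
            classify_region(snv(3000, "A", "C"), PLUS_TX, flank=5000)
            is RegionClass.DOWNSTREAM
        )
        assert (
            classify_region(snv(3000, "A", "C"), PLUS_TX, flank=1000)
            is RegionClass.INTERGENIC
        )

    def test_chrom_mismatch_rejected(self):
        with pytest.raises(UsageError):
            classify_region(snv(134, "A", "C", chrom="chrX"), PLUS_TX)


class TestCodingEffect:
    def test_stop_gain(self, plus_genome):
        # codon 2 is TAC (Tyr) at positions 134-136; TAC->TAA
        assert (
            coding_effect(snv(136, "C", "A"), PLUS_TX, plus_genome)
            is Effect.STOP_GAIN
        )

    def test_synonymous(self, plus_genome):
        # codon 3 is CTT (Leu) at 137-139; CTT->CTG is still Leu
        assert (
            coding_effect(snv(139, "T", "G"), PLUS_TX, plus_genome)
            is Effect.SYNONYMOUS
        )

    def test_missense(self, plus_genome):
        # GCT (Ala) middle base -> GTT (Val)
        assert (
            coding_effect(snv(141, "C", "T"), PLUS_TX, plus_genome)
            is Effect.MISSENSE
        )

    def test_start_loss(self, plus_genome):
        assert (
            coding_effect(snv(131, "A", "G"), PLUS_TX, plus_genome)
            is Effect.START_LOSS
        )

    def test_stop_loss(self, plus_genome):
        # terminal TAA at 528-530 -> TAC (Tyr)
        assert (
            coding_effect(snv(530, "A", "C"), PLUS_TX, plus_genome)
            is Effect.STOP_LOSS
        )

    @pytest.mark.parametrize(
        "ref_len,alt_len,expected",
        [(1, 2, Effect.FRAMESHIFT), (1, 4, Effect.INFRAME_INDEL),
         (4, 1, Effect.INFRAME_INDEL), (3, 1, Effect.FRAMESHIFT)],
    )
    def test_indels_by_length(self, plus_genome, ref_len, alt_len, expected):
        pos = 305
        ref = plus_genome.fetch("chrT", pos, pos + ref_len - 1)
        alt = (ref[0] + "A" * (alt_len - 1))[:alt_len]
        v = Variant("chrT", pos, ref, alt)
        assert coding_effect(v, PLUS_TX, plus_genome) is expected

    def test_reference_mismatch_names_variant(self, plus_genome):
        wrong_ref = "G" if plus_genome.base("chrT", 134) != "G" else "C"
        with pytest.raises(ReferenceMismatchError, match="chrT:134"):
            coding_effect(snv(134, wrong_ref, "T"), PLUS_TX, plus_genome)


def mirror(genome: StringGenome, tx: TranscriptModel, v: Variant):
    """Reverse-complement the whole fixture, flipping coordinates and strand."""
    seq = genome.chroms[tx.chrom]
    L = len(seq)
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    flip = lambda s, e: (L - e + 1, L - s + 1)
    m_tx = TranscriptModel(
        tx.gene_id,
        tx.transcript_id + "_rc",
        tx.chrom,
        "-" if tx.strand == "+" else "+",
        tuple(flip(s, e) for s, e in tx.exons),
        tuple(flip(s, e) for s, e in tx.cds),
    )
    m_v = Variant(
        tx.chrom,
        L - v.end + 1,
        v.ref.translate(comp)[::-1],
        v.alt.translate(comp)[::-1],
    )
    return StringGenome({tx.chrom: rc}), m_tx, m_v


class TestStrandSymmetry:
    @pytest.mark.parametrize("pos", [131, 136, 139, 141, 310, 330, 510, 530])
    def test_mirrored_fixture_same_effect(self, plus_genome, pos):
        """Annotating the reverse-complemented construct gives the same class."""
        ref = plus_genome.base("chrT", pos)
        alt = {"A": "G", "C": "A", "G": "T", "T": "C"}[ref]
        v = snv(pos, ref, alt)
        forward = coding_effect(v, PLUS_TX, plus_genome)
        m_genome, m_tx, m_v = mirror(plus_genome, PLUS_TX, v)
        assert coding_effect(m_v, m_tx, m_genome) is forward


class TestOracleEquivalence:
    def test_random_cds_variants_match_full_translation(self, trio_project):
        """Local-codon classification equals full-CDS-translation brute force."""
        rng = np.random.default_rng(1234)
        coding = [t for t in trio_project.transcripts if t.is_coding]
        minus_seen = 0
        n = 600
        for _ in range(n):
            tx = coding[int(rng.integers(0, len(coding)))]
            minus_seen += tx.strand == "-"
            cds_positions = [p for s, e in tx.cds for p in range(s, e + 1)]
            if rng.random() < 0.75:  # SNV
                pos = int(cds_positions[int(rng.integers(0, len(cds_positions)))])
                ref = trio_project.genome.base(tx.chrom, pos)
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
                v = Variant(tx.chrom, pos, ref, alt)
            else:  # indel fully inside one CDS interval
                s, e = tx.cds[int(rng.integers(0, len(tx.cds)))]
                k = int(rng.integers(1, 5))
                pos = int(rng.integers(s, e - k))
                if rng.random() < 0.5:  # deletion
                    ref = trio_project.genome.fetch(tx.chrom, pos, pos + k)
                    v = Variant(tx.chrom, pos, ref, ref[0])
                else:  # insertion
                    ref = trio_project.genome.base(tx.chrom, pos)
                    ins = "".join(
                        "ACGT"[int(b)] for b in rng.integers(0, 4, size=k)
                    )
                    v = Variant(tx.chrom, pos, ref, ref + ins)
            got = coding_effect(v, tx, trio_project.genome)
            assert got.value == oracle_effect(v, tx, trio_project.genome), v.key
        assert minus_seen > 0  # both strands exercised


class TestAnnotateAll:
    def test_two_isoform_gene_gives_two_annotations(self, plus_genome):
        iso_b = TranscriptModel(
            "GT1", "GT1.t2", "chrT", "+", ((101, 160), (501, 560)),
            ((131, 160), (501, 530)),
        )
        v = snv(134, plus_genome.base("chrT", 134), "A")
        anns = annotate_all([v], [PLUS_TX, iso_b], plus_genome)[v.key]
        assert len(anns) == 2

    def test_fixture_two_isoform_disagreement(self, trio_project):
        """The planted variant is coding in one isoform, intronic in the other."""
        info = trio_project.truth["two_isoform_site"]
        anns = trio_project.annotations[tuple(info["key"])]
        by_tx = {a.transcript_id: a for a in anns}
        exonic = by_tx[info["exonic_transcript"]]
        intronic = by_tx[info["intronic_transcript"]]
        assert exonic.region_class is RegionClass.CDS_EXONIC
        assert exonic.effect is not Effect.NONE
        assert intronic.region_class is RegionClass.INTRONIC
        assert intronic.effect is Effect.NONE

    def test_far_variant_is_intergenic(self, plus_genome):
        v = snv(790, plus_genome.base("chrT", 790), "A")
        anns = annotate_all([v], [PLUS_TX], plus_genome, flank=100)[v.key]
        assert len(anns) == 1
        assert anns[0].region_class is RegionClass.INTERGENIC

    def test_isoform_completeness_and_effect_invariant(self, trio_project):
        """Annotation count equals an exhaustive flanked-span scan; effect
        is non-none exactly on coding-exonic annotations."""
        flank = 5000
        rng = np.random.default_rng(7)
        sample_idx = rng.choice(
            len(trio_project.variants), size=250, replace=False
        )
        for i in sample_idx:
            v = trio_project.variants[int(i)]
            expected = sum(
                1
                for t in trio_project.transcripts
                if t.chrom == v.chrom
                and t.start - flank <= v.end
                and v.pos <= t.end + flank
                # transcripts where the variant is classified intergenic
                # (impossible within the flank) would be dropped
            )
            anns = trio_project.annotations[v.key]
            if expected == 0:
                assert [a.region_class for a in anns] == [RegionClass.INTERGENIC]
            else:
                assert len(anns) == expected
            for a in anns:
                assert (a.effect is not Effect.NONE) == (
                    a.region_class is RegionClass.CDS_EXONIC
                )


class TestMair:
    def make_index(self, gmafs, chrom="chr1", pos=100, ref="A"):
        alts = ["G", "T", "C"]
        return FrequencyIndex(
            FrequencyRecord(chrom, pos, ref, alts[i], g)
            for i, g in enumerate(gmafs)
        )

    def test_high_alt_frequency_flags_reference(self):
        flag = flag_mair(Variant("chr1", 100, "A", "G"), self.make_index([0.95]))
        assert flag.is_mair and flag.ref_allele_frequency == pytest.approx(0.05)

    def test_boundary_is_strict(self):
        flag = flag_mair(Variant("chr1", 100, "A", "G"), self.make_index([0.90]))
        assert not flag.is_mair
        assert flag.ref_allele_frequency == pytest.approx(0.10)

    def test_multiple_alts_sum(self):
        flag = flag_mair(
            Variant("chr1", 100, "A", "G"), self.make_index([0.5, 0.45])
        )
        assert flag.is_mair and flag.ref_allele_frequency == pytest.approx(0.05)

    def test_unknown_site_never_flagged(self):
        flag = flag_mair(Variant("chr9", 1, "A", "G"), self.make_index([0.95]))
        assert not flag.is_mair and flag.ref_allele_frequency is None

    def test_fixture_planted_mair_flags(self, trio_project):
        for entry in trio_project.truth["mair"]:
            chrom, pos, ref, alt = entry["key"]
            flag = flag_mair(Variant(chrom, pos, ref, alt), trio_project.freq_index)
            assert flag.is_mair == entry["expected_is_mair"], entry
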