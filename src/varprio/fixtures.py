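"""Seeded synthetic-data generator.

Produces every input the toolkit consumes — genome FASTA, GFF3 gene models,
multi-sample VCF, site-frequency TSV, BED4 targets, phenotype gene list —
together with machine-readable truth tables for every planted signal
(de novo sites, recessive-homozygous sites, compound-het pairs, ROH tracts,
minor-allele-in-reference sites, and the six-criterion qualifying variants).
Identical seeds yield byte-identical outputs.

Trio genotypes are always Mendelian-consistent (a child allele always comes
from a parent) except at the explicitly planted de novo sites, so planted
truths are exactly recoverable. At high-GMAF sites parental genotypes are
drawn heterozygote-enriched rather than from Hardy–Weinberg proportions:
highly informative marker panels are ascertained for heterozygosity, and a
het-dense background is what makes homozygous tracts detectable at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import InputError, TranscriptModel

__all__ = ["FixtureSpec", "generate", "case_study_scenario"]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}

#: per-sample genotype distribution drawn for *parents* (and cohort samples)
#: at high-GMAF informative sites: (hom_ref, het, hom_alt). Carrier-dense —
#: at sites with alternate-allele frequency near 0.5, homozygous-reference
#: genotypes are the minority, which is exactly what makes a genuine
#: homozygous-reference tract stand out.
_HIGH_SITE_GT_P = (0.06, 0.52, 0.42)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic study.

    ``roh_tracts`` entries are (sample_id, chrom_index, start_bp,
    n_informative_positions); informative positions inside a tract are laid
    out at ~``roh_spacing_bp``. ``n_case_study`` plants variants that
    jointly satisfy the six-criterion query (deep coverage in all trio
    members, child alt depth > 30, protein-changing, GMAF < 0.05, gene on
    the phenotype list, homozygous only in the child).
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    genes_per_chrom: int = 15
    samples: tuple[str, ...] = ("CHILD", "FATHER", "MOTHER")
    trio_roles: Optional[tuple[str, str, str]] = ("CHILD", "FATHER", "MOTHER")
    background_per_kb: float = 2.5
    n_freq_sites: int = 40_000
    gmaf_rare_frac: float = 0.8  # rare U(0,0.05); rest high U(0.3,0.5)
    n_de_novo: int = 3
    n_recessive: int = 2
    n_compound_pairs: int = 1
    n_mair: int = 4
    n_case_study: int = 0
    roh_tracts: tuple[tuple[str, int, int, int], ...] = (
        ("CHILD", 0, 120_000, 300),
        ("CHILD", 1, 100_000, 400),
    )
    roh_spacing_bp: int = 100
    roh_het_contamination: float = 0.02
    n_phenotype_extra: int = 4

    def validate(self) -> None:
        if self.trio_roles is not None:
            missing = [s for s in self.trio_roles if s not in self.samples]
            if missing:
                raise InputError(f"trio roles {missing} not among samples")
        for sample, ci, start, n_pos in self.roh_tracts:
            if sample not in self.samples:
                raise InputError(f"ROH tract sample {sample!r} unknown")
            if ci >= len(self.chrom_lengths):
                raise InputError(f"ROH tract chrom index {ci} out of range")
            # jittered spacing can stretch to 1.5x the nominal pitch
            end = start + n_pos * self.roh_spacing_bp * 3 // 2
            if start < 1 or end >= self.chrom_lengths[ci] - 1000:
                raise InputError(
                    f"planted ROH tract {start}-{end} outside chr{ci + 1} "
                    f"(length {self.chrom_lengths[ci]}) — outside target regions"
                )


def case_study_scenario(seed: int) -> FixtureSpec:
    """The packaged synthetic trio: six-criterion case-study conditions.

    Plants exactly 2 variants jointly satisfying all six criteria among
    well over 500 distractors that each violate at least one, plus the
    other planted signals (de novo, recessive, compound-het, ROH tracts,
    mAiR sites) so a single project exercises every analysis.
    """
    return FixtureSpec(seed=seed, n_case_study=2)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream])


def _random_genome(rng: np.random.Generator, length: int) -> bytearray:
    idx = rng.integers(0, 4, size=length)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return bytearray(lut[idx].tobytes())


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    chrom_index: int
    strand: str
    exons: list[tuple[int, int]]
    cds_lo: int
    cds_hi: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def _build_genes(spec: FixtureSpec, rng, chrom_names) -> list[_Gene]:
    genes = []
    for ci, chrom in enumerate(chrom_names):
        cursor = 12_000
        for gi in range(spec.genes_per_chrom):
            n_ex = int(rng.integers(3, 6))
            exon_lens = [int(3 * rng.integers(40, 81)) for _ in range(n_ex)]
            intron_lens = [int(rng.integers(400, 1501)) for _ in range(n_ex - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if cursor + span > spec.chrom_lengths[ci] - 12_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = cursor
            for k, L in enumerate(exon_lens):
                exons.append((p, p + L - 1))
                p = p + L + (intron_lens[k] if k < n_ex - 1 else 0)
            gene_id = f"G{ci + 1}_{gi:02d}"
            cds_lo = exons[0][0] + 30  # 30 bp UTR at each genomic end
            cds_hi = exons[-1][1] - 30
            gene = _Gene(gene_id, chrom, ci, strand, exons, cds_lo, cds_hi)

            n_iso = 2 if (ci == 0 and gi == 0) else int(rng.integers(1, 3))
            for k in range(n_iso):
                tx_exons = list(exons)
                if k >= 1:
                    tx_exons = [e for j, e in enumerate(exons) if j != 1]
                cds = [
                    (max(s, cds_lo), min(e, cds_hi))
                    for s, e in tx_exons
                    if min(e, cds_hi) >= max(s, cds_lo)
                ]
                gene.transcripts.append(
                    TranscriptModel(
                        gene_id=gene_id,
                        transcript_id=f"{gene_id}.t{k + 1}",
                        chrom=chrom,
                        strand=strand,
                        exons=tuple(tx_exons),
                        cds=tuple(cds),
                    )
                )
            genes.append(gene)
            cursor = exons[-1][1] + int(rng.integers(6_000, 10_001))
    return genes


def _plant_codon_anchors(genomes: dict[str, bytearray], genes: list[_Gene]) -> None:
    """Write start/stop codons at every gene's CDS boundaries (strand-aware)."""
    for g in genes:
        gbuf = genomes[g.chrom]
        if g.strand == "+":
            gbuf[g.cds_lo - 1 : g.cds_lo + 2] = b"ATG"
            gbuf[g.cds_hi - 3 : g.cds_hi] = b"TAA"
        else:
            gbuf[g.cds_hi - 3 : g.cds_hi] = b"CAT"  # revcomp ATG
            gbuf[g.cds_lo - 1 : g.cds_lo + 2] = b"TTA"  # revcomp TAA


def _coding_positions(tx: TranscriptModel) -> list[int]:
    """Genomic positions of the CDS in coding (5'→3') order."""
    positions = []
    for s, e in tx.cds:
        positions.extend(range(s, e + 1))
    if tx.strand == "-":
        positions.reverse()
    return positions


def _pick_cds_middle_positions(
    gene: _Gene,
    genomes: dict[str, bytearray],
    rng,
    n: int,
    used: set[tuple[str, int]],
) -> list[tuple[int, str, str]]:
    """Choose n middle-of-codon SNV sites in the first isoform's CDS.

    Middle-base substitutions of non-stop codons are always
    protein-changing under the standard code, so no translation machinery
    is needed to guarantee a non-synonymous truth. Returns (pos, ref, alt)
    in genomic terms, at least 3 bp away from exon boundaries.
    """
    tx = gene.transcripts[0]
    coding = _coding_positions(tx)
    gbuf = genomes[gene.chrom]

    # for minus strand the coding-order positions walk right-to-left, so the
    # genome bases must be complemented to give the codon
    def codon_at(j: int) -> str:
        raw = [chr(gbuf[coding[3 * j + k] - 1]) for k in range(3)]
        if tx.strand == "-":
            raw = [b.translate(_COMPLEMENT) for b in raw]
        return "".join(raw)

    n_codons = len(coding) // 3
    candidates = []
    for j in range(2, n_codons - 2):
        pos = coding[3 * j + 1]
        if (gene.chrom, pos) in used:
            continue
        exon = next((s, e) for s, e in tx.exons if s <= pos <= e)
        if pos - exon[0] < 3 or exon[1] - pos < 3:
            continue
        if codon_at(j) in _STOPS:
            continue
        candidates.append(pos)
    if len(candidates) < n:
        raise InputError(
            f"gene {gene.gene_id} has too few usable CDS positions"
        )
    order = rng.permutation(len(candidates))
    picks = []
    for oi in order[:n]:
        pos = candidates[int(oi)]
        ref = chr(gbuf[pos - 1])
        alts = [b for b in _BASES if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        picks.append((pos, ref, alt))
        used.add((gene.chrom, pos))
    return picks


# genotype bookkeeping: gt string, [ref_depth, alt_depth], DP, GQ
_Call = tuple[str, list[int], int, int]


def _mk_call(rng, kind: str, dp_lo: int, dp_hi: int) -> _Call:
    dp = int(rng.integers(dp_lo, dp_hi + 1))
    if kind == "hom_ref":
        return "0/0", [dp, 0], dp, 99
    if kind == "het":
        alt = int(min(max(rng.binomial(dp, 0.5), 1), dp - 1)) if dp >= 2 else 1
        return "0/1", [dp - alt, alt], dp, 99
    if kind == "hom_alt":
        ref = min(int(rng.integers(0, 3)), dp - 1)
        return "1/1", [ref, dp - ref], dp, 99
    raise ValueError(kind)


def _mendelian_child(rng, father: str, mother: str) -> str:
    def transmit(kind: str) -> int:
        if kind == "hom_ref":
            return 0
        if kind == "hom_alt":
            return 1
        return int(rng.integers(0, 2))

    alleles = transmit(father) + transmit(mother)
    return ("hom_ref", "het", "hom_alt")[alleles]


def _draw_kind(rng, probs: tuple[float, float, float]) -> str:
    r = rng.random()
    if r < probs[0]:
        return "hom_ref"
    if r < probs[0] + probs[1]:
        return "het"
    return "hom_alt"


@dataclass
class _Record:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, _Call]
    kind: str  # provenance label for the truth tables

    def vcf_line(self, sample_order: Sequence[str]) -> str:
        cols = [
            self.chrom,
            str(self.pos),
            ".",
            self.ref,
            ",".join(self.alts),
            ".",
            ".",
            ".",
            "GT:AD:DP:GQ",
        ]
        for s in sample_order:
            gt, ad, dp, gq = self.calls[s]
            cols.append(f"{gt}:{','.join(str(d) for d in ad)}:{dp}:{gq}")
        return "\t".join(cols)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec, outdir) -> dict:
    """Write every input file plus truth tables; returns the manifest dict.

    Files: ``genome.fa``, ``genes.gff3``, ``variants.vcf``,
    ``aoro_sample.vcf`` (single sample, GT:AO:RO, to exercise depth
    derivation), ``frequencies.tsv``, ``targets.bed``,
    ``phenotype_genes.tsv``, ``truth/*.json`` and ``manifest.json``.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    trio = spec.trio_roles
    child, father, mother = trio if trio else (None, None, None)

    # --- genome and genes ---------------------------------------------------
    genomes = {
        chrom: _random_genome(_rng(spec, 10 + i), L)
        for i, (chrom, L) in enumerate(zip(chrom_names, spec.chrom_lengths))
    }
    genes = _build_genes(spec, _rng(spec, 20), chrom_names)
    _plant_codon_anchors(genomes, genes)

    used: set[tuple[str, int]] = set()
    records: list[_Record] = []
    freq_rows: list[tuple[str, int, str, str, float, str]] = []
    truth: dict[str, object] = {}

    def base_at(chrom: str, pos: int) -> str:
        return chr(genomes[chrom][pos - 1])

    def other_base(rng, ref: str) -> str:
        alts = [b for b in _BASES if b != ref]
        return alts[int(rng.integers(0, 3))]

    # --- ROH tracts: dense high-GMAF informative positions ------------------
    rng_roh = _rng(spec, 30)
    tract_sites: dict[tuple[str, int], str] = {}  # (chrom,pos) -> tract sample
    tract_truth = []
    for sample, ci, start, n_pos in spec.roh_tracts:
        chrom = chrom_names[ci]
        positions = []
        p = start
        for _ in range(n_pos):
            p += int(rng_roh.integers(
                max(1, spec.roh_spacing_bp // 2), spec.roh_spacing_bp * 3 // 2
            ))
            while (chrom, p) in used:
                p += 1
            positions.append(p)
            used.add((chrom, p))
            tract_sites[(chrom, p)] = sample
        n_contam = max(1, round(spec.roh_het_contamination * n_pos))
        # contamination strictly interior so tract edges stay homozygous
        interior = positions[5:-5]
        contam_idx = sorted(
            int(i)
            for i in rng_roh.choice(len(interior), size=n_contam, replace=False)
        )
        contam = {interior[i] for i in contam_idx}
        for pos in positions:
            ref = base_at(chrom, pos)
            alt = other_base(rng_roh, ref)
            gmaf = float(rng_roh.uniform(0.301, 0.5))
            freq_rows.append((chrom, pos, ref, alt, round(gmaf, 4), f"ts{len(freq_rows)}"))
            calls: dict[str, _Call] = {}
            is_contam = pos in contam
            for s in spec.samples:
                if s == sample:
                    kind = "het" if is_contam else "hom_ref"
                elif trio and s == child:
                    continue  # filled after parents below
                else:
                    kind = _draw_kind(rng_roh, _HIGH_SITE_GT_P)
                    if trio and sample == child and s in (father, mother):
                        # child 0/0 (or a single contaminating het) needs both
                        # parents able to transmit the reference allele
                        if kind == "hom_alt":
                            kind = "het"
                        if is_contam and s == father and kind == "hom_ref":
                            kind = "het"  # the het child inherits from father
                calls[s] = _mk_call(rng_roh, kind, 25, 70)
            if trio and child in spec.samples and child not in calls:
                ck = _mendelian_child(
                    rng_roh,
                    _kind_of(calls[father][0]),
                    _kind_of(calls[mother][0]),
                )
                calls[child] = _mk_call(rng_roh, ck, 25, 70)
            if any(c[0] != "0/0" for c in calls.values()):
                records.append(_Record(chrom, pos, ref, (alt,), calls, "roh_site"))
        end_bp = positions[-1]
        tract_truth.append(
            {
                "sample": sample,
                "chrom": chrom,
                "start": positions[0],
                "end": end_bp,
                "n_positions": n_pos,
                "n_contaminated": n_contam,
            }
        )
    truth["roh_tracts"] = tract_truth

    # spans of the planted tracts, so later streams keep them homozygous
    tract_spans = [
        (t["chrom"], t["start"], t["end"], t["sample"]) for t in tract_truth
    ]

    def tract_sample_at(chrom: str, pos: int) -> Optional[str]:
        for tchrom, lo, hi, sample in tract_spans:
            if chrom == tchrom and lo <= pos <= hi:
                return sample
        return None

    # --- background high-GMAF frequency sites (het-dense) --------------------
    rng_high = _rng(spec, 31)
    n_high = int(spec.n_freq_sites * (1.0 - spec.gmaf_rare_frac))
    genome_total = sum(spec.chrom_lengths)
    for _ in range(n_high):
        ci = int(rng_high.integers(0, len(chrom_names)))
        chrom = chrom_names[ci]
        pos = int(rng_high.integers(1000, spec.chrom_lengths[ci] - 1000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = base_at(chrom, pos)
        alt = other_base(rng_high, ref)
        gmaf = float(rng_high.uniform(0.301, 0.5))
        freq_rows.append((chrom, pos, ref, alt, round(gmaf, 4), f"hs{len(freq_rows)}"))
        in_tract_of = tract_sample_at(chrom, pos)
        calls = {}
        for s in spec.samples:
            if trio and s == child:
                continue
            kind = _draw_kind(rng_high, _HIGH_SITE_GT_P)
            if s == in_tract_of:
                kind = "hom_ref"  # the site falls inside this sample's ROH
            elif (
                trio
                and in_tract_of == child
                and s in (father, mother)
                and kind == "hom_alt"
            ):
                kind = "het"  # parents must be able to transmit ref
            calls[s] = _mk_call(rng_high, kind, 25, 70)
        if trio and child in spec.samples:
            if in_tract_of == child:
                ck = "hom_ref"
            else:
                ck = _mendelian_child(
                    rng_high, _kind_of(calls[father][0]), _kind_of(calls[mother][0])
                )
            calls[child] = _mk_call(rng_high, ck, 25, 70)
        if any(c[0] != "0/0" for c in calls.values()):
            records.append(_Record(chrom, pos, ref, (alt,), calls, "high_gmaf_site"))

    # --- rare frequency sites (no variant records) ---------------------------
    rng_rare = _rng(spec, 32)
    n_rare = spec.n_freq_sites - n_high
    for _ in range(n_rare):
        ci = int(rng_rare.integers(0, len(chrom_names)))
        chrom = chrom_names[ci]
        pos = int(rng_rare.integers(1000, spec.chrom_lengths[ci] - 1000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = base_at(chrom, pos)
        alt = other_base(rng_rare, ref)
        gmaf = float(rng_rare.uniform(0.0001, 0.0499))
        freq_rows.append((chrom, pos, ref, alt, round(gmaf, 4), f"rs{len(freq_rows)}"))

    # --- planted signals ------------------------------------------------------
    rng_plant = _rng(spec, 33)
    coding_genes = [g for g in genes if g.transcripts[0].cds_len >= 60]

    def fresh_intergenic_pos(rng) -> tuple[str, int]:
        while True:
            ci = int(rng.integers(0, len(chrom_names)))
            chrom = chrom_names[ci]
            pos = int(rng.integers(1000, spec.chrom_lengths[ci] - 1000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    # the two-isoform showcase: exonic+coding in isoform 1, intronic in
    # isoform 2 (which skips exon index 1)
    showcase_gene = genes[0]
    sc_exon = showcase_gene.exons[1]
    tx1 = showcase_gene.transcripts[0]
    sc_candidates = [
        (pos, base_at(showcase_gene.chrom, pos))
        for pos in range(sc_exon[0] + 5, sc_exon[1] - 5)
        if (showcase_gene.chrom, pos) not in used
        and any(s <= pos <= e for s, e in tx1.cds)
    ]
    sc_pos, sc_ref = sc_candidates[int(rng_plant.integers(0, len(sc_candidates)))]
    sc_alt = other_base(rng_plant, sc_ref)
    used.add((showcase_gene.chrom, sc_pos))
    if trio:
        fk, mk = "het", "hom_ref"
        ck = "het"
    calls = {}
    for s in spec.samples:
        if trio and s == child:
            calls[s] = _mk_call(rng_plant, ck, 30, 60)
        elif trio and s == father:
            calls[s] = _mk_call(rng_plant, fk, 30, 60)
        elif trio and s == mother:
            calls[s] = _mk_call(rng_plant, mk, 30, 60)
        else:
            calls[s] = _mk_call(rng_plant, "het", 30, 60)
    records.append(
        _Record(showcase_gene.chrom, sc_pos, sc_ref, (sc_alt,), calls, "two_isoform")
    )
    truth["two_isoform_site"] = {
        "key": [showcase_gene.chrom, sc_pos, sc_ref, sc_alt],
        "gene": showcase_gene.gene_id,
        "exonic_transcript": showcase_gene.transcripts[0].transcript_id,
        "intronic_transcript": showcase_gene.transcripts[1].transcript_id,
    }

    # de novo sites: child het, parents confidently hom-ref
    de_novo_truth = []
    if trio:
        for _ in range(spec.n_de_novo):
            chrom, pos = fresh_intergenic_pos(rng_plant)
            ref = base_at(chrom, pos)
            alt = other_base(rng_plant, ref)
            calls = {
                s: _mk_call(
                    rng_plant,
                    "het" if s == child else "hom_ref",
                    35,
                    80,
                )
                for s in spec.samples
            }
            records.append(_Record(chrom, pos, ref, (alt,), calls, "de_novo"))
            de_novo_truth.append([chrom, pos, ref, alt])
    truth["de_novo"] = sorted(de_novo_truth)

    # recessive-homozygous sites: child 1/1, parents het (inside CDS)
    recessive_truth = []
    if trio:
        gene_pool = [g for g in coding_genes if g is not showcase_gene]
        for i in range(spec.n_recessive):
            gene = gene_pool[i % len(gene_pool)]
            (pos, ref, alt) = _pick_cds_middle_positions(
                gene, genomes, rng_plant, 1, used
            )[0]
            calls = {
                s: _mk_call(
                    rng_plant,
                    "hom_alt" if s == child else "het",
                    35,
                    80,
                )
                for s in spec.samples
            }
            records.append(_Record(gene.chrom, pos, ref, (alt,), calls, "recessive"))
            recessive_truth.append(
                {"key": [gene.chrom, pos, ref, alt], "gene": gene.gene_id}
            )
    truth["recessive"] = recessive_truth

    # compound-het pairs: v1 paternal het, v2 maternal het, same gene
    compound_truth = []
    if trio:
        gene_pool = [g for g in coding_genes if g is not showcase_gene]
        for i in range(spec.n_compound_pairs):
            gene = gene_pool[(spec.n_recessive + i) % len(gene_pool)]
            picks = _pick_cds_middle_positions(gene, genomes, rng_plant, 2, used)
            pair_keys = []
            for j, (pos, ref, alt) in enumerate(picks):
                carrier = father if j == 0 else mother
                calls = {}
                for s in spec.samples:
                    if s == child or s == carrier:
                        calls[s] = _mk_call(rng_plant, "het", 35, 80)
                    else:
                        calls[s] = _mk_call(rng_plant, "hom_ref", 35, 80)
                records.append(
                    _Record(gene.chrom, pos, ref, (alt,), calls, "compound_het")
                )
                pair_keys.append([gene.chrom, pos, ref, alt])
            compound_truth.append({"gene": gene.gene_id, "pair": pair_keys})
    truth["compound_het"] = compound_truth

    # mAiR sites: the reference base is the population minor allele.
    # Alt GMAFs 0.95 / 0.9001 / 0.90 / 0.50 give ref frequencies
    # 0.05 / 0.0999 / 0.10 / 0.50 -> flags true/true/false/false.
    mair_truth = []
    mair_gmafs = [0.95, 0.9001, 0.90, 0.50]
    for i in range(spec.n_mair):
        chrom, pos = fresh_intergenic_pos(rng_plant)
        ref = base_at(chrom, pos)
        alt = other_base(rng_plant, ref)
        gmaf = mair_gmafs[i % len(mair_gmafs)]
        freq_rows.append((chrom, pos, ref, alt, gmaf, f"ms{len(freq_rows)}"))
        # ref is the minor allele, so essentially everyone carries the alt
        calls = {s: _mk_call(rng_plant, "hom_alt", 30, 60) for s in spec.samples}
        records.append(_Record(chrom, pos, ref, (alt,), calls, "mair"))
        mair_truth.append(
            {
                "key": [chrom, pos, ref, alt],
                "alt_gmaf": gmaf,
                "expected_is_mair": round(1.0 - gmaf, 6) < 0.1,
            }
        )
    truth["mair"] = mair_truth

    # case-study qualifying variants: all six criteria jointly satisfied
    case_truth = []
    phenotype_genes: list[str] = []
    if spec.n_case_study and trio:
        gene_pool = [
            g
            for g in coding_genes
            if g is not showcase_gene
            and g.gene_id not in {r["gene"] for r in recessive_truth}
            and g.gene_id not in {c["gene"] for c in compound_truth}
        ]
        for i in range(spec.n_case_study):
            gene = gene_pool[i % len(gene_pool)]
            (pos, ref, alt) = _pick_cds_middle_positions(
                gene, genomes, rng_plant, 1, used
            )[0]
            freq_rows.append((gene.chrom, pos, ref, alt, 0.01, f"cs{len(freq_rows)}"))
            calls = {}
            for s in spec.samples:
                kind = "hom_alt" if s == child else "het"
                calls[s] = _mk_call(rng_plant, kind, 70, 110)
            records.append(
                _Record(gene.chrom, pos, ref, (alt,), calls, "case_study")
            )
            phenotype_genes.append(gene.gene_id)
            case_truth.append({"key": [gene.chrom, pos, ref, alt], "gene": gene.gene_id})
    truth["case_study"] = case_truth

    # one multiallelic record to exercise decomposition
    rng_multi = _rng(spec, 34)
    chrom, pos = fresh_intergenic_pos(rng_multi)
    ref = base_at(chrom, pos)
    alt_pool = [b for b in _BASES if b != ref]
    alt1, alt2 = alt_pool[0], alt_pool[1]
    multi_calls: dict[str, _Call] = {}
    for s in spec.samples:
        dp = int(rng_multi.integers(40, 80))
        a1 = dp // 3
        a2 = dp // 3
        if trio and s == child:
            multi_calls[s] = ("1/2", [dp - a1 - a2, a1, a2], dp, 99)
        elif trio and s == father:
            multi_calls[s] = ("0/1", [dp - a1, a1, 0], dp, 99)
        elif trio and s == mother:
            multi_calls[s] = ("0/2", [dp - a2, 0, a2], dp, 99)
        else:
            multi_calls[s] = ("0/1", [dp - a1, a1, 0], dp, 99)
    records.append(_Record(chrom, pos, ref, (alt1, alt2), multi_calls, "multiallelic"))
    truth["multiallelic_site"] = {"chrom": chrom, "pos": pos, "ref": ref,
                                  "alts": [alt1, alt2]}

    # --- background rare variants (Mendelian, off the frequency table) ------
    rng_bg = _rng(spec, 35)
    n_background = int(spec.background_per_kb * genome_total / 1000)
    n_distractors = 0
    for _ in range(n_background):
        ci = int(rng_bg.integers(0, len(chrom_names)))
        chrom = chrom_names[ci]
        pos = int(rng_bg.integers(1000, spec.chrom_lengths[ci] - 1000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = base_at(chrom, pos)
        alt = other_base(rng_bg, ref)
        calls = {}
        for s in spec.samples:
            if trio and s == child:
                continue
            r = rng_bg.random()
            kind = "het" if r < 0.18 else ("hom_alt" if r < 0.22 else "hom_ref")
            calls[s] = _mk_call(rng_bg, kind, 20, 100)
        if trio and child in spec.samples:
            ck = _mendelian_child(
                rng_bg, _kind_of(calls[father][0]), _kind_of(calls[mother][0])
            )
            calls[child] = _mk_call(rng_bg, ck, 20, 100)
        if any(c[0] != "0/0" for c in calls.values()):
            records.append(_Record(chrom, pos, ref, (alt,), calls, "background"))
            n_distractors += 1

    records.sort(key=lambda r: (r.chrom, r.pos))

    # distractor audit: background and site records carry no rare-frequency
    # entry (their positions are disjoint from rare sites by construction),
    # so every non-case-study record fails the GMAF < 0.05 criterion.
    case_keys = {tuple(c["key"]) for c in case_truth}
    rare_keyed = {
        (c, p, r, a) for (c, p, r, a, g, _) in freq_rows if g < 0.05
    }
    audit_violations = 0
    for rec in records:
        for ai, alt in enumerate(rec.alts):
            key = (rec.chrom, rec.pos, rec.ref, alt)
            if key in case_keys:
                continue
            if key in rare_keyed:
                audit_violations += 1
    truth["distractor_audit"] = {
        "n_non_case_records": sum(len(r.alts) for r in records) - len(case_keys),
        "n_with_rare_frequency": audit_violations,
        "note": "every distractor fails the gmaf<0.05 criterion",
    }

    # --- phenotype gene list --------------------------------------------------
    rng_ph = _rng(spec, 36)
    other_genes = [g.gene_id for g in genes if g.gene_id not in phenotype_genes]
    extra_idx = sorted(
        int(i)
        for i in rng_ph.choice(
            len(other_genes),
            size=min(spec.n_phenotype_extra, len(other_genes)),
            replace=False,
        )
    )
    phenotype_list = phenotype_genes + [other_genes[i] for i in extra_idx]
    truth["phenotype_genes"] = phenotype_list

    # --- write files ----------------------------------------------------------
    files: dict[str, str] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = genomes[chrom].decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    files["genome"] = fasta.name

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tfixtures\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.chrom}\tfixtures\tmRNA\t{tx.start}\t{tx.end}\t.\t"
                    f"{g.strand}\t.\tID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{g.chrom}\tfixtures\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tx.transcript_id}\n"
                    )
                for s, e in tx.cds:
                    fh.write(
                        f"{g.chrom}\tfixtures\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"Parent={tx.transcript_id}\n"
                    )
    files["gff3"] = gff.name

    vcf = outdir / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in zip(chrom_names, spec.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(spec.samples)
            + "\n"
        )
        for rec in records:
            fh.write(rec.vcf_line(spec.samples) + "\n")
    files["vcf"] = vcf.name

    # auxiliary single-sample VCF in GT:AO:RO form (depth-derivation input)
    aoro = outdir / "aoro_sample.vcf"
    aoro_sample = spec.samples[0]
    aoro_records = [r for r in records if len(r.alts) == 1][:8]
    with open(aoro, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, L in zip(chrom_names, spec.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Ref obs count">\n')
        fh.write('##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alt obs count">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{aoro_sample}\n"
        )
        expected = []
        for rec in aoro_records:
            gt, ad, dp, _ = rec.calls[aoro_sample]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alts[0]}\t.\t.\t.\t"
                f"GT:RO:AO\t{gt}:{ad[0]}:{ad[1]}\n"
            )
            expected.append(
                {
                    "key": [rec.chrom, rec.pos, rec.ref, rec.alts[0]],
                    "gt": gt,
                    "allele_depths": [ad[0], ad[1]],
                    "total_depth": ad[0] + ad[1],
                }
            )
    files["aoro_vcf"] = aoro.name
    truth["aoro_expected"] = expected

    freq = outdir / "frequencies.tsv"
    freq_rows.sort(key=lambda r: (r[0], r[1]))
    with open(freq, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgmaf\tid\n")
        for chrom, pos, ref, alt, gmaf, sid in freq_rows:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gmaf}\t{sid}\n")
    files["frequencies"] = freq.name

    bed = outdir / "targets.bed"
    with open(bed, "w") as fh:
        for s in spec.samples:
            for chrom, L in zip(chrom_names, spec.chrom_lengths):
                fh.write(f"{chrom}\t0\t{L}\t{s}\n")
    files["targets"] = bed.name

    pheno = outdir / "phenotype_genes.tsv"
    with open(pheno, "w") as fh:
        fh.write("gene_id\n")
        for g in phenotype_list:
            fh.write(g + "\n")
    files["phenotype_genes"] = pheno.name

    truth_path = outdir / "truth" / "planted.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["truth"] = "truth/planted.json"

    manifest = {
        "spec": asdict(spec),
        "files": files,
        "samples": list(spec.samples),
        "trio": list(trio) if trio else None,
        "n_variant_records": len(records),
        "n_frequency_records": len(freq_rows),
        "sha256": {
            name: _sha256(outdir / rel) for name, rel in sorted(files.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _kind_of(gt: str) -> str:
    return {"0/0": "hom_ref", "0/1": "het", "1/1": "hom_alt"}[gt]
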