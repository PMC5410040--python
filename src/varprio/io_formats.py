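"""Readers and writers for the external file formats.

VCF goes through :mod:`pysam`; BED4, frequency tables and annotation tables
are plain whitespace/tab-delimited text (gzip accepted for VCF and TSV).
Every multiallelic VCF record is decomposed into one :class:`~varprio.model.Variant`
per alternate allele at parse time, and AD/DP are derived from AO/RO when a
caller (e.g. the Torrent suite) did not fill them.
"""

from __future__ import annotations

import gzip
import io
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    FormatError,
    FrequencyRecord,
    Genotype,
    GenotypeCall,
    InputError,
    RegionTrack,
    UsageError,
    Variant,
)

__all__ = [
    "parse_vcf",
    "write_vcf",
    "load_bed",
    "group_regions_by_sample",
    "load_frequency_table",
    "FrequencyIndex",
    "load_annotation_table",
    "AnnotationTable",
    "load_gene_list",
]


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _trim_trailing(ref: str, alt: str) -> tuple[str, str]:
    # Minimal normalization: drop shared trailing bases only; no left-alignment.
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt


def _classify_gt(gt: Optional[tuple], allele_index: int) -> Genotype:
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return Genotype.MISSING
    if any(a is None for a in gt):
        return Genotype.OTHER_PLOIDY
    if all(a == allele_index for a in gt):
        return Genotype.HOM_ALT
    if allele_index in gt:
        return Genotype.HET
    # does not carry this alternate allele (all-ref, or another alt)
    return Genotype.HOM_REF


def _sample_call(sample_data, sample_id: str, allele_index: int) -> GenotypeCall:
    gt = sample_data.get("GT")
    genotype = _classify_gt(gt, allele_index)

    allele_depths: Optional[list[int]] = None
    total_depth: Optional[int] = None

    ad = sample_data.get("AD")
    if ad is not None and not all(a is None for a in ad):
        # carry the original AD slice for this allele: [REF, ALT_i]
        ref_d = ad[0] or 0
        alt_d = ad[allele_index] if allele_index < len(ad) else 0
        allele_depths = [int(ref_d), int(alt_d or 0)]
    dp = sample_data.get("DP")
    if dp is not None:
        total_depth = int(dp)

    if allele_depths is None:
        ro = sample_data.get("RO")
        ao = sample_data.get("AO")
        if ro is not None and ao is not None:
            ao_tuple = ao if isinstance(ao, (tuple, list)) else (ao,)
            if not all(a is None for a in ao_tuple):
                ro = int(ro)
                ao_all = [int(a or 0) for a in ao_tuple]
                alt_d = (
                    ao_all[allele_index - 1]
                    if allele_index - 1 < len(ao_all)
                    else 0
                )
                allele_depths = [ro, alt_d]
                if total_depth is None:
                    total_depth = ro + sum(ao_all)

    if allele_depths is not None and total_depth is None:
        total_depth = sum(allele_depths)

    gq = sample_data.get("GQ")
    quality = float(gq) if gq is not None else None
    return GenotypeCall(
        sample_id=sample_id,
        gt=genotype,
        allele_depths=allele_depths,
        total_depth=total_depth,
        quality=quality,
    )


def parse_vcf(
    path, sample_subset: Optional[Sequence[str]] = None
) -> list[Variant]:
    """Parse a VCF v4.x file into decomposed single-alternate variants.

    Parameters
    ----------
    path
        Path to a plain or gzip/bgzip-compressed VCF with per-sample GT and
        either AD/DP or AO/RO fields.
    sample_subset
        Optional list of sample IDs to retain; every returned variant carries
        exactly one call per requested sample (``missing`` genotype when the
        file does not provide one).

    Raises
    ------
    FormatError
        If a record lacks the GT format field.
    InputError
        If the header declares duplicate sample names.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = pysam.VariantFile(str(path))
    header_samples = list(vcf.header.samples)
    if len(set(header_samples)) != len(header_samples):
        raise InputError(f"duplicate sample names in VCF header: {header_samples}")
    if sample_subset is None:
        samples = header_samples
    else:
        samples = list(sample_subset)
        if len(set(samples)) != len(samples):
            raise UsageError("sample_subset contains duplicates")

    variants: list[Variant] = []
    for rec in vcf:
        if rec.alts is None:
            continue
        if "GT" not in rec.format:
            raise FormatError(
                f"record {rec.chrom}:{rec.pos} has no GT in FORMAT"
            )
        for allele_index, alt in enumerate(rec.alts, start=1):
            if alt is None or alt in ("*", "."):
                continue
            ref, alt_trim = _trim_trailing(rec.ref.upper(), alt.upper())
            calls = {}
            for s in samples:
                if s in rec.samples:
                    calls[s] = _sample_call(rec.samples[s], s, allele_index)
                else:
                    calls[s] = GenotypeCall(sample_id=s, gt=Genotype.MISSING)
            annotations: dict[str, object] = {}
            if rec.id is not None:
                annotations["vcf_id"] = rec.id
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt_trim,
                    calls=calls,
                    annotations=annotations,
                )
            )
    return variants


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
    Genotype.OTHER_PLOIDY: "./1",
}


def write_vcf(
    variants: Iterable[Variant],
    path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write decomposed variants back to a biallelic VCF v4.2 file.

    One record per variant, FORMAT ``GT:AD:DP:GQ``. Parsing the written file
    with :func:`parse_vcf` round-trips the variant list field-for-field.
    """
    variants = list(variants)
    samples: list[str] = []
    for v in variants:
        for s in v.calls:
            if s not in samples:
                samples.append(s)
    chroms: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        chroms.setdefault(v.chrom, 0)
        chroms[v.chrom] = max(chroms[v.chrom], v.end + 1000)

    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in chroms.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for v in variants:
        vcf_id = v.annotations.get("vcf_id") or "."
        fields = [v.chrom, str(v.pos), str(vcf_id), v.ref, v.alt, ".", ".", ".", "GT:AD:DP:GQ"]
        for s in samples:
            call = v.calls.get(s)
            if call is None:
                fields.append("./.:.:.:.")
                continue
            ad = (
                ",".join(str(d) for d in call.allele_depths)
                if call.allele_depths
                else "."
            )
            dp = str(call.total_depth) if call.total_depth is not None else "."
            gq = str(int(call.quality)) if call.quality is not None else "."
            fields.append(f"{_GT_STRING[call.gt]}:{ad}:{dp}:{gq}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED4
# ---------------------------------------------------------------------------

def load_bed(path) -> list[RegionTrack]:
    """Load a BED4 file: chrom, start (0-based), end (exclusive), sample ID.

    Tab- or space-delimited; rows with fewer than four columns raise
    :class:`FormatError` naming the offending line.
    """
    regions: list[RegionTrack] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: BED rows need 4 columns "
                    f"(chrom, start, end, sample), got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            try:
                regions.append(RegionTrack(cols[0], start, end, cols[3]))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return regions


def group_regions_by_sample(
    regions: Iterable[RegionTrack],
) -> dict[str, list[RegionTrack]]:
    grouped: dict[str, list[RegionTrack]] = defaultdict(list)
    for r in regions:
        grouped[r.sample_id].append(r)
    for rs in grouped.values():
        rs.sort(key=lambda r: (r.chrom, r.start, r.end))
    return dict(grouped)


# ---------------------------------------------------------------------------
# Frequency table (site-frequency TSV emulating dbSNP GMAF records)
# ---------------------------------------------------------------------------

_FREQ_COLUMNS = {"chrom", "pos", "ref", "alt", "gmaf"}


def load_frequency_table(path) -> list[FrequencyRecord]:
    """Load a TSV of known-site allele frequencies.

    Header must name ``chrom, pos, ref, alt, gmaf`` (optional ``id``);
    ``gmaf`` outside [0,1] raises :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = _FREQ_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: frequency table lacks columns {sorted(missing)}"
        )
    records = []
    has_id = "id" in df.columns
    for row in df.itertuples(index=False):
        gmaf = float(row.gmaf)
        if not 0.0 <= gmaf <= 1.0:
            raise FormatError(
                f"{path}: gmaf {gmaf} outside [0,1] at {row.chrom}:{row.pos}"
            )
        site_id = getattr(row, "id", None) if has_id else None
        if site_id is not None and pd.isna(site_id):
            site_id = None
        records.append(
            FrequencyRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gmaf=gmaf,
                site_id=site_id,
            )
        )
    return records


class FrequencyIndex:
    """Frequency records indexed by full allele key and by site."""

    def __init__(self, records: Iterable[FrequencyRecord]):
        self.by_key: dict[tuple[str, int, str, str], FrequencyRecord] = {}
        self.by_site: dict[tuple[str, int], list[FrequencyRecord]] = defaultdict(list)
        for rec in records:
            self.by_key[rec.key] = rec
            self.by_site[(rec.chrom, rec.pos)].append(rec)
        self.by_site = dict(self.by_site)

    def __len__(self) -> int:
        return len(self.by_key)

    def lookup(self, chrom: str, pos: int, ref: str, alt: str):
        return self.by_key.get((chrom, pos, ref, alt))

    def at_site(self, chrom: str, pos: int) -> list[FrequencyRecord]:
        return self.by_site.get((chrom, pos), [])


# ---------------------------------------------------------------------------
# Annotation tables (gene-keyed / variant-keyed custom databases)
# ---------------------------------------------------------------------------

def load_gene_list(path) -> list[str]:
    """Load a one-column gene list TSV (header ``gene_id``), order-preserving."""
    df = pd.read_csv(path, sep="\t")
    col = _find_column(df.columns, _GENE_KEY_SYNONYMS)
    if col is None:
        raise FormatError(f"{path}: gene list lacks a gene_id column")
    return [str(g) for g in df[col]]


#: accepted spellings of the four mandatory variant-key columns
_VARIANT_KEY_SYNONYMS = {
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "position"),
    "ref": ("ref", "reference", "reference_allele", "reference allele"),
    "alt": ("alt", "alternative", "alternative_allele", "alternative allele"),
}
_GENE_KEY_SYNONYMS = ("gene_id", "gene", "ensembl_gene_id")


class AnnotationTable:
    """A custom multicolumn annotation table keyed by gene or by variant.

    ``variant_keyed`` tables must carry the four mandatory key columns
    (chromosome, position, reference allele, alternative allele); their value
    columns are joined onto :attr:`Variant.annotations`. ``gene_keyed``
    tables are joined on the gene ID into gene-level context.
    """

    def __init__(self, kind: str, df: pd.DataFrame, key_columns: list[str]):
        if kind not in ("gene_keyed", "variant_keyed"):
            raise UsageError(f"unknown annotation table kind {kind!r}")
        self.kind = kind
        self.df = df
        self.key_columns = key_columns
        self.value_columns = [c for c in df.columns if c not in key_columns]
        if kind == "variant_keyed":
            self._index = {
                (
                    str(row[key_columns[0]]),
                    int(row[key_columns[1]]),
                    str(row[key_columns[2]]),
                    str(row[key_columns[3]]),
                ): {c: row[c] for c in self.value_columns}
                for _, row in df.iterrows()
            }
        else:
            self._index = {
                str(row[key_columns[0]]): {c: row[c] for c in self.value_columns}
                for _, row in df.iterrows()
            }

    def variant_values(self, variant: Variant) -> Optional[dict]:
        if self.kind != "variant_keyed":
            raise UsageError("variant_values() requires a variant_keyed table")
        return self._index.get(variant.key)

    def gene_values(self, gene_id: str) -> Optional[dict]:
        if self.kind != "gene_keyed":
            raise UsageError("gene_values() requires a gene_keyed table")
        return self._index.get(gene_id)

    def attach(self, variants: Iterable[Variant]) -> int:
        """Join value columns onto matching variants; returns the hit count."""
        if self.kind != "variant_keyed":
            raise UsageError("attach() requires a variant_keyed table")
        hits = 0
        for v in variants:
            values = self._index.get(v.key)
            if values is not None:
                v.annotations.update(values)
                hits += 1
        return hits


def _find_column(columns, synonyms) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in columns}
    for name in synonyms:
        if name in lowered:
            return lowered[name]
    return None


def load_annotation_table(path, kind: str) -> AnnotationTable:
    """Load a custom TSV annotation table of the given kind.

    Raises :class:`FormatError` naming the first missing mandatory key
    column.
    """
    df = pd.read_csv(path, sep="\t")
    if kind == "variant_keyed":
        key_columns = []
        for canonical, synonyms in _VARIANT_KEY_SYNONYMS.items():
            col = _find_column(df.columns, synonyms)
            if col is None:
                raise FormatError(
                    f"{path}: variant-keyed table lacks mandatory column "
                    f"{canonical!r} (accepted spellings: {list(synonyms)})"
                )
            key_columns.append(col)
    elif kind == "gene_keyed":
        col = _find_column(df.columns, _GENE_KEY_SYNONYMS)
        if col is None:
            raise FormatError(
                f"{path}: gene-keyed table lacks a gene ID column "
                f"(accepted spellings: {list(_GENE_KEY_SYNONYMS)})"
            )
        key_columns = [col]
    else:
        raise UsageError(f"unknown annotation table kind {kind!r}")
    return AnnotationTable(kind, df, key_columns)
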