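"""Shared fixtures: one generated synthetic trio project per session."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pytest

from varprio import (
    FrequencyIndex,
    GenomeAccessor,
    TrioSpec,
    annotate_all,
    load_bed,
    load_frequency_table,
    load_gff3,
    parse_vcf,
)
from varprio.fixtures import case_study_scenario, generate
from varprio.io_formats import load_gene_list

FIXTURE_SEED = 11


@dataclass
class TrioProject:
    root: Path
    manifest: dict
    truth: dict
    trio: TrioSpec
    variants: list
    genome: GenomeAccessor
    transcripts: list
    annotations: dict
    freq_records: list
    freq_index: FrequencyIndex
    targets: list
    phenotype: list
    gene_sets: dict = field(default_factory=dict)

    @property
    def genome_bp(self) -> int:
        return sum(self.manifest["spec"]["chrom_lengths"])


@pytest.fixture(scope="session")
def trio_project(tmp_path_factory) -> TrioProject:
    root = tmp_path_factory.mktemp("trio_fixture")
    manifest = generate(case_study_scenario(FIXTURE_SEED), root)
    truth = json.loads((root / "truth" / "planted.json").read_text())
    variants = parse_vcf(root / "variants.vcf")
    genome = GenomeAccessor(root / "genome.fa")
    transcripts = load_gff3(root / "genes.gff3")
    annotations = annotate_all(variants, transcripts, genome)
    freq_records = load_frequency_table(root / "frequencies.tsv")
    phenotype = load_gene_list(root / "phenotype_genes.tsv")
    return TrioProject(
        root=root,
        manifest=manifest,
        truth=truth,
        trio=TrioSpec("CHILD", "FATHER", "MOTHER"),
        variants=variants,
        genome=genome,
        transcripts=transcripts,
        annotations=annotations,
        freq_records=freq_records,
        freq_index=FrequencyIndex(freq_records),
        targets=load_bed(root / "targets.bed"),
        phenotype=phenotype,
        gene_sets={"phenotype": phenotype},
    )
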