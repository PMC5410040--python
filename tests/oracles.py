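"""Independent brute-force oracles used by the test-suite.

Deliberately written without reusing the package's incremental algorithms:
the consequence oracle rebuilds and fully translates the whole mutant CDS,
the ROH oracle does exhaustive interval reachability, and the trio oracles
are hand-enumerated genotype rules.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

from varprio.model import Genotype

_COMP = str.maketrans("ACGT", "TGCA")


class StringGenome:
    """In-memory genome with the same fetch/base interface as GenomeAccessor."""

    def __init__(self, chroms: dict[str, str]):
        self.chroms = {k: v.upper() for k, v in chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])


# ---------------------------------------------------------------------------
# full-CDS-translation consequence oracle
# ---------------------------------------------------------------------------

def _translate_full(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def oracle_effect(variant, tx, genome) -> str:
    """Classify a CDS variant by rebuilding and translating the whole CDS."""
    cds_positions = [p for s, e in tx.cds for p in range(s, e + 1)]
    idx = {p: i for i, p in enumerate(cds_positions)}
    gseq = "".join(genome.fetch(tx.chrom, s, e) for s, e in tx.cds)

    if len(variant.ref) == len(variant.alt):
        glist = list(gseq)
        for k in range(len(variant.ref)):
            i = idx.get(variant.pos + k)
            if i is not None:
                glist[i] = variant.alt[k]
        mutant_genomic = "".join(glist)
    else:
        i0 = idx[variant.pos]
        i1 = idx[variant.pos + len(variant.ref) - 1]
        mutant_genomic = gseq[:i0] + variant.alt + gseq[i1 + 1 :]

    def orient(seq: str) -> str:
        return seq if tx.strand == "+" else seq.translate(_COMP)[::-1]

    ref_cds = orient(gseq)
    mut_cds = orient(mutant_genomic)
    if len(mut_cds) != len(ref_cds):
        return (
            "frameshift"
            if abs(len(mut_cds) - len(ref_cds)) % 3 != 0
            else "inframe_indel"
        )
    ref_prot = _translate_full(ref_cds)
    mut_prot = _translate_full(mut_cds)
    if ref_prot == mut_prot:
        return "synonymous"
    if ref_prot[:1] == "M" and mut_prot[:1] != "M":
        return "start_loss"
    for r, m in zip(ref_prot, mut_prot):
        if r != m:
            if m == "*":
                return "stop_gain"
            if r == "*":
                return "stop_loss"
    return "missense"


# ---------------------------------------------------------------------------
# exhaustive ROH oracle
# ---------------------------------------------------------------------------

def oracle_rohs(positions, percentile: float = 95.0, min_ratio: float = 0.9):
    """Seed selection + exhaustive-reachability extension + merge.

    Returns (chrom, start, end, n_hom_ref, n_het, n_hom_alt) tuples sorted
    by position, computed from first principles: every interval containing
    a seed is examined, and an interval counts as reachable when it can be
    grown from the seed one position at a time with the full-interval
    homozygosity ratio strictly above ``min_ratio`` at every step.
    """
    groups: dict[str, list] = {}
    for p in positions:
        groups.setdefault(p.chrom, []).append(p)
    for ps in groups.values():
        ps.sort(key=lambda p: p.pos)

    runs = []  # (chrom, a, b)
    for chrom in sorted(groups):
        ps = groups[chrom]
        a = None
        for i, p in enumerate(ps):
            if p.state is Genotype.HOM_REF:
                if a is None:
                    a = i
            else:
                if a is not None:
                    runs.append((chrom, a, i - 1))
                    a = None
        if a is not None:
            runs.append((chrom, a, len(ps) - 1))
    if not runs:
        return []
    lengths = [
        groups[chrom][b].pos - groups[chrom][a].pos + 1 for chrom, a, b in runs
    ]
    if len(runs) == 1:
        seeds = runs
    else:
        ordered = sorted(lengths)
        rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
        cutoff = ordered[min(rank, len(ordered)) - 1]
        seeds = [r for r, L in zip(runs, lengths) if L > cutoff]

    per_chrom: dict[str, list] = {}
    for chrom, a0, b0 in seeds:
        ps = groups[chrom]
        hom = [p.state is Genotype.HOM_REF for p in ps]
        n = len(ps)

        def ratio_ok(a, b):
            return sum(hom[a : b + 1]) > min_ratio * (b - a + 1)

        reach = {(a0, b0)}
        frontier = [(a0, b0)]
        while frontier:
            a, b = frontier.pop()
            for na, nb in ((a - 1, b), (a, b + 1)):
                if na < 0 or nb >= n or (na, nb) in reach:
                    continue
                if ratio_ok(na, nb):
                    reach.add((na, nb))
                    frontier.append((na, nb))
        best = max(
            reach,
            key=lambda ab: (
                ps[ab[1]].pos - ps[ab[0]].pos,
                sum(hom[ab[0] : ab[1] + 1]),
                -ab[0],
            ),
        )
        per_chrom.setdefault(chrom, []).append(best)

    result = []
    for chrom in sorted(per_chrom):
        ps = groups[chrom]
        hom = [p.state is Genotype.HOM_REF for p in ps]
        merged = []
        for a, b in sorted(set(per_chrom[chrom])):
            if merged and a <= merged[-1][1]:
                pa, pb = merged[-1]
                ua, ub = min(pa, a), max(pb, b)
                if sum(hom[ua : ub + 1]) > min_ratio * (ub - ua + 1):
                    merged[-1] = (ua, ub)
                elif ps[b].pos - ps[a].pos > ps[pb].pos - ps[pa].pos:
                    merged[-1] = (a, b)
            else:
                merged.append((a, b))
        for a, b in merged:
            states = [p.state for p in ps[a : b + 1]]
            result.append(
                (
                    chrom,
                    ps[a].pos,
                    ps[b].pos,
                    sum(s is Genotype.HOM_REF for s in states),
                    sum(s is Genotype.HET for s in states),
                    sum(s is Genotype.HOM_ALT for s in states),
                )
            )
    result.sort(key=lambda r: (r[0], r[1]))
    return result


# ---------------------------------------------------------------------------
# hand-enumerated trio rules
# ---------------------------------------------------------------------------

def oracle_recessive(child: str, father: str, mother: str) -> bool:
    """Shared by child and both parents + homozygous only in the child."""
    shared = all(g in ("het", "hom_alt") for g in (child, father, mother))
    hom_only = (
        child == "hom_alt" and father != "hom_alt" and mother != "hom_alt"
    )
    return shared and hom_only


def oracle_de_novo(child: str, father: str, mother: str) -> bool:
    """Present in the child, absent (hom-ref or uncalled) in both parents."""
    return (
        child in ("het", "hom_alt")
        and father in ("hom_ref", "missing")
        and mother in ("hom_ref", "missing")
    )
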