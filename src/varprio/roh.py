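"""Runs-of-homozygosity detection by seed-and-extend.

Informative positions are known high-polymorphism sites (GMAF > 0.3)
falling in a sample's target regions. A site with no uploaded variant call
for the sample is inferred homozygous-reference (0/0); a called site
contributes its zygosity. Maximal runs of inferred-hom-ref positions whose
length exceeds the 95th percentile of the genome-wide run-length
distribution become seeds, and each seed is extended in both directions for
as long as the homozygosity ratio — hom-ref positions over all positions in
the considered region — stays strictly above 0.9.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    FrequencyRecord,
    Genotype,
    InformativePosition,
    RegionTrack,
    ROHRegion,
    UsageError,
    Variant,
)

__all__ = [
    "informative_positions",
    "find_seeds",
    "extend_seeds",
    "chromosome_map",
    "write_roh_tsv",
    "write_chromosome_map_json",
    "DEFAULT_GMAF_MIN",
    "DEFAULT_PERCENTILE",
    "DEFAULT_MIN_RATIO",
]

DEFAULT_GMAF_MIN = 0.3
DEFAULT_PERCENTILE = 95.0
DEFAULT_MIN_RATIO = 0.9


def informative_positions(
    sample_id: str,
    variants: Iterable[Variant],
    frequency_records: Iterable[FrequencyRecord],
    targets: Optional[Sequence[RegionTrack]],
    gmaf_min: float = DEFAULT_GMAF_MIN,
) -> list[InformativePosition]:
    """Collect the sample's informative positions for ROH detection.

    For every frequency record with GMAF strictly above ``gmaf_min`` inside
    the sample's target regions: a site with no variant called for the
    sample is inferred hom-ref; otherwise the call's zygosity is used (an
    explicit 0/0 or missing call also counts as hom-ref).

    ``targets`` restricted to other samples only raises :class:`UsageError`;
    pass ``targets=None`` to deliberately scan without a target track.
    """
    sample_targets: Optional[list[RegionTrack]] = None
    if targets is not None:
        sample_targets = [t for t in targets if t.sample_id == sample_id]
        if not sample_targets:
            raise UsageError(
                f"no target regions for sample {sample_id!r}; pass "
                "targets=None to scan all known sites without a target track"
            )
        by_chrom: dict[str, list[RegionTrack]] = defaultdict(list)
        for t in sample_targets:
            by_chrom[t.chrom].append(t)

    calls_at: dict[tuple[str, int], Genotype] = {}
    for v in variants:
        call = v.calls.get(sample_id)
        if call is None:
            continue
        site = (v.chrom, v.pos)
        gt = call.gt
        # a het or hom-alt call at the site dominates any co-located record
        prev = calls_at.get(site)
        rank = {Genotype.HOM_ALT: 2, Genotype.HET: 1}
        if prev is None or rank.get(gt, 0) > rank.get(prev, 0):
            calls_at[site] = gt

    out: list[InformativePosition] = []
    seen_sites: set[tuple[str, int]] = set()
    for rec in frequency_records:
        if rec.gmaf <= gmaf_min:
            continue
        site = (rec.chrom, rec.pos)
        if site in seen_sites:
            continue
        if sample_targets is not None:
            if not any(
                t.contains_pos(rec.pos) for t in by_chrom.get(rec.chrom, [])
            ):
                continue
        seen_sites.add(site)
        gt = calls_at.get(site)
        if gt is Genotype.HET:
            state = Genotype.HET
        elif gt is Genotype.HOM_ALT:
            state = Genotype.HOM_ALT
        else:
            state = Genotype.HOM_REF  # inferred (or explicit) 0/0
        out.append(
            InformativePosition(
                chrom=rec.chrom, pos=rec.pos, state=state, source_gmaf=rec.gmaf
            )
        )
    out.sort(key=lambda p: (p.chrom, p.pos))
    return out


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def _by_chrom(
    positions: Sequence[InformativePosition],
) -> dict[str, list[InformativePosition]]:
    grouped: dict[str, list[InformativePosition]] = defaultdict(list)
    for p in positions:
        grouped[p.chrom].append(p)
    for ps in grouped.values():
        ps.sort(key=lambda p: p.pos)
    return dict(sorted(grouped.items()))


def _hom_runs(chrom_positions: Sequence[InformativePosition]):
    """Maximal runs of hom-ref positions as (start_index, end_index) pairs."""
    runs = []
    start = None
    for i, p in enumerate(chrom_positions):
        if p.state is Genotype.HOM_REF:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(chrom_positions) - 1))
    return runs


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p/100 * n)."""
    if not values:
        raise UsageError("percentile of empty sequence")
    ordered = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[min(rank, len(ordered)) - 1]


def _region_from_indices(
    chrom: str, positions: Sequence[InformativePosition], a: int, b: int, seed: bool
) -> ROHRegion:
    states = [p.state for p in positions[a : b + 1]]
    return ROHRegion(
        chrom=chrom,
        start=positions[a].pos,
        end=positions[b].pos,
        n_hom_ref=sum(s is Genotype.HOM_REF for s in states),
        n_het=sum(s is Genotype.HET for s in states),
        n_hom_alt=sum(s is Genotype.HOM_ALT for s in states),
        seed=seed,
    )


def find_seeds(
    positions: Sequence[InformativePosition],
    percentile: float = DEFAULT_PERCENTILE,
    length_unit: str = "bp",
) -> list[ROHRegion]:
    """Select seed runs: hom-ref stretches longer than the percentile cutoff.

    Run lengths (genomic bp by default, informative-position count with
    ``length_unit="count"``) are pooled genome-wide; a run seeds when its
    length *strictly exceeds* the nearest-rank percentile of that
    distribution. With exactly one run in the input the percentile equals
    the run's own length, so that run is returned as the sole seed —
    otherwise the algorithm could never start.
    """
    if length_unit not in ("bp", "count"):
        raise UsageError(f"length_unit must be 'bp' or 'count', got {length_unit!r}")
    grouped = _by_chrom(positions)
    all_runs: list[tuple[str, int, int]] = []
    for chrom, ps in grouped.items():
        for a, b in _hom_runs(ps):
            all_runs.append((chrom, a, b))
    if not all_runs:
        return []

    def run_length(chrom: str, a: int, b: int) -> float:
        ps = grouped[chrom]
        if length_unit == "bp":
            return ps[b].pos - ps[a].pos + 1
        return b - a + 1

    lengths = [run_length(*r) for r in all_runs]
    if len(all_runs) == 1:
        chrom, a, b = all_runs[0]
        return [_region_from_indices(chrom, grouped[chrom], a, b, seed=True)]
    cutoff = nearest_rank_percentile(lengths, percentile)
    seeds = [
        _region_from_indices(chrom, grouped[chrom], a, b, seed=True)
        for (chrom, a, b), length in zip(all_runs, lengths)
        if length > cutoff
    ]
    return seeds


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _extend_one(
    hom: Sequence[bool],
    prefix: Sequence[int],
    bp: Sequence[int],
    a0: int,
    b0: int,
    min_ratio: float,
) -> tuple[int, int]:
    """Maximal region reachable from [a0, b0] by single-position extensions.

    Each step must keep the full-region homozygosity ratio strictly above
    ``min_ratio``; hom-ref neighbours are absorbed eagerly (always feasible
    and never detrimental). Among reachable regions the one maximizing
    (genomic span, hom-ref count, leftmost start) is returned.
    """
    n = len(hom)

    def feasible(a: int, b: int) -> bool:
        return (prefix[b + 1] - prefix[a]) > min_ratio * (b - a + 1)

    def absorb(a: int, b: int) -> tuple[int, int]:
        while a > 0 and hom[a - 1]:
            a -= 1
        while b < n - 1 and hom[b + 1]:
            b += 1
        return a, b

    start = absorb(a0, b0)
    seen = {start}
    stack = [start]
    best = start

    def better(x: tuple[int, int], y: tuple[int, int]) -> bool:
        xa, xb = x
        ya, yb = y
        xs = (bp[xb] - bp[xa], prefix[xb + 1] - prefix[xa], -xa)
        ys = (bp[yb] - bp[ya], prefix[yb + 1] - prefix[ya], -ya)
        return xs > ys

    while stack:
        a, b = stack.pop()
        if better((a, b), best):
            best = (a, b)
        for na, nb in ((a - 1, b), (a, b + 1)):
            if na < 0 or nb >= n:
                continue
            if not feasible(na, nb):
                continue
            state = absorb(na, nb)
            if state not in seen:
                seen.add(state)
                stack.append(state)
    return best


def extend_seeds(
    seeds: Sequence[ROHRegion],
    positions: Sequence[InformativePosition],
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> list[ROHRegion]:
    """Extend each seed while the recomputed full-region ratio stays > min_ratio.

    Overlapping extended regions are merged when the union's ratio still
    exceeds ``min_ratio``; otherwise the longer region wins. Output is
    sorted by (chrom, start) with final counts.
    """
    grouped = _by_chrom(positions)
    layouts = {}
    for chrom, ps in grouped.items():
        hom = [p.state is Genotype.HOM_REF for p in ps]
        prefix = [0]
        for h in hom:
            prefix.append(prefix[-1] + int(h))
        bp = [p.pos for p in ps]
        layouts[chrom] = (hom, prefix, bp)

    extended: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for seed in seeds:
        if seed.chrom not in layouts:
            raise UsageError(
                f"seed on {seed.chrom} but no informative positions there"
            )
        hom, prefix, bp = layouts[seed.chrom]
        a0 = bisect_left(bp, seed.start)
        b0 = bisect_left(bp, seed.end)
        if a0 >= len(bp) or bp[a0] != seed.start or bp[b0] != seed.end:
            raise UsageError(
                f"seed {seed.chrom}:{seed.start}-{seed.end} does not align "
                "with the informative positions"
            )
        extended[seed.chrom].append(
            _extend_one(hom, prefix, bp, a0, b0, min_ratio)
        )

    out: list[ROHRegion] = []
    for chrom, ranges in extended.items():
        hom, prefix, bp = layouts[chrom]
        ranges = sorted(set(ranges))
        merged: list[tuple[int, int]] = []
        for a, b in ranges:
            if merged and a <= merged[-1][1]:
                pa, pb = merged[-1]
                ua, ub = min(pa, a), max(pb, b)
                if (prefix[ub + 1] - prefix[ua]) > min_ratio * (ub - ua + 1):
                    merged[-1] = (ua, ub)
                else:
                    # keep the longer region (genomic span)
                    if bp[b] - bp[a] > bp[pb] - bp[pa]:
                        merged[-1] = (a, b)
            else:
                merged.append((a, b))
        for a, b in merged:
            out.append(
                _region_from_indices(chrom, grouped[chrom], a, b, seed=True)
            )
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# ---------------------------------------------------------------------------
# chromosome map
# ---------------------------------------------------------------------------

def chromosome_map(
    rohs: Sequence[ROHRegion], ranked_genes: Sequence[Mapping]
) -> dict[str, dict]:
    """Associate prioritized genes with ROH intervals, per chromosome.

    ``ranked_genes`` rows need ``gene_id``, ``chrom``, ``start`` and ``end``
    (1-based inclusive); extra keys (e.g. ``gene_score``) are carried
    through. A gene is ``in_roh`` when its interval lies wholly inside one
    reported region.
    """
    rohs_by_chrom: dict[str, list[ROHRegion]] = defaultdict(list)
    for r in rohs:
        rohs_by_chrom[r.chrom].append(r)
    for rs in rohs_by_chrom.values():
        rs.sort(key=lambda r: r.start)

    out: dict[str, dict] = {}
    chroms = sorted(set(rohs_by_chrom) | {str(g["chrom"]) for g in ranked_genes})
    for chrom in chroms:
        regions = rohs_by_chrom.get(chrom, [])
        genes = []
        for g in ranked_genes:
            if str(g["chrom"]) != chrom:
                continue
            gs, ge = int(g["start"]), int(g["end"])
            container = next(
                (
                    i
                    for i, r in enumerate(regions)
                    if r.start <= gs and ge <= r.end
                ),
                None,
            )
            entry = dict(g)
            entry["in_roh"] = container is not None
            entry["roh_index"] = container
            genes.append(entry)
        out[chrom] = {
            "rohs": [
                {
                    "start": r.start,
                    "end": r.end,
                    "n_hom_ref": r.n_hom_ref,
                    "n_het": r.n_het,
                    "n_hom_alt": r.n_hom_alt,
                    "ratio": round(r.ratio, 6),
                    "seed": r.seed,
                }
                for r in regions
            ],
            "genes": genes,
        }
    return out


def write_roh_tsv(regions: Sequence[ROHRegion], path) -> None:
    lines = ["chrom\tstart\tend\tn_hom_ref\tn_het\tn_hom_alt\tratio\tseed"]
    for r in regions:
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_hom_ref}\t{r.n_het}\t"
            f"{r.n_hom_alt}\t{r.ratio:.6f}\t{str(r.seed).lower()}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_chromosome_map_json(chrom_map: Mapping[str, dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(chrom_map, fh, indent=2, sort_keys=True)
        fh.write("\n")
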