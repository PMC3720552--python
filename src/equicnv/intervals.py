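"""Interval algebra on CNV calls: overlap, region merging, multi-caller
consensus, state classification, pairwise caller overlap, external-list
comparison and breed-sharing summaries.

A CNV region (CNVR) is a connected component of the call overlap graph: two
calls are linked when they overlap under the chosen :class:`OverlapSpec`,
and a region's envelope is the union span of its members.  Consensus loci
are regions supported by all three detection algorithms, resolved at one of
three levels of stringency:

population
    every caller contributed at least one call anywhere in the cohort;
breed
    all three callers called the locus within at least one common breed
    (one consensus record per qualifying locus x breed pair);
individual
    all three callers called the locus in at least one common animal
    (one record per qualifying locus x sample pair).

Distinct loci are monotone across levels: any locus with individual-level
support also has breed- and population-level support.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CALLERS, CnvCall, SampleRecord, _chrom_key


@dataclass(frozen=True)
class OverlapSpec:
    """Criterion linking two intervals.

    ``any`` requires >= 1 shared bp; ``reciprocal`` additionally requires the
    shared length to be at least ``min_fraction`` of EACH interval's length.
    """

    mode: str = "any"
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("any", "reciprocal"):
            raise ValueError(f"unknown overlap mode: {self.mode!r}")
        if self.mode == "reciprocal" and not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass
class CnvRegion:
    """Union envelope of transitively overlapping calls on one chromosome."""

    chrom: str
    start: int
    end: int
    members: list[CnvCall] = field(default_factory=list)

    @property
    def carriers(self) -> set[str]:
        return {m.sample_id for m in self.members}

    @property
    def states(self) -> list[str]:
        return [m.state for m in self.members]

    @property
    def state(self) -> str:
        return classify_state(self.members) if self.members else "region"

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConsensusCnv:
    """A locus supported by all three callers at a given stringency level."""

    region: CnvRegion
    level: str
    support: dict[str, list[CnvCall]]
    state: str
    breeds: set[str]
    locus_id: int
    unit: str | None = None  # breed name or sample id at the finer levels

    @property
    def carriers(self) -> set[str]:
        return {c.sample_id for calls in self.support.values() for c in calls}


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def overlap_bp(a, b) -> int:
    """Shared base pairs of two 1-based inclusive intervals on one chromosome."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def satisfies(a, b, spec: OverlapSpec = OverlapSpec()) -> bool:
    """Whether two same-chromosome intervals overlap under ``spec``."""
    ov = overlap_bp(a, b)
    if spec.mode == "any":
        return ov >= 1
    size_a = a.end - a.start + 1
    size_b = b.end - b.start + 1
    return ov / size_a >= spec.min_fraction and ov / size_b >= spec.min_fraction


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _components(calls: Sequence[CnvCall], spec: OverlapSpec) -> list[list[CnvCall]]:
    """Connected components of the overlap graph, per chromosome.

    Calls are sorted by start; only physically overlapping pairs (the sweep's
    active set) are tested against ``spec``, which is sound because a
    reciprocal criterion implies any-overlap.
    """
    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    comps: list[list[CnvCall]] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        uf = _UnionFind(len(group))
        active: list[int] = []
        for j, c in enumerate(group):
            active = [i for i in active if group[i].end >= c.start]
            for i in active:
                if satisfies(group[i], c, spec):
                    uf.union(i, j)
            active.append(j)
        buckets: dict[int, list[CnvCall]] = defaultdict(list)
        for i, c in enumerate(group):
            buckets[uf.find(i)].append(c)
        comps.extend(sorted(buckets.values(), key=lambda ms: min(m.start for m in ms)))
    return comps


def merge_to_regions(calls: Iterable[CnvCall], spec: OverlapSpec = OverlapSpec()) -> list[CnvRegion]:
    """Merge overlapping calls into CNV regions (sorted by chrom, start)."""
    regions = [
        CnvRegion(
            chrom=ms[0].chrom,
            start=min(m.start for m in ms),
            end=max(m.end for m in ms),
            members=ms,
        )
        for ms in _components(list(calls), spec)
    ]
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start))
    return regions


def classify_state(members: Sequence[CnvCall]) -> str:
    """``loss`` if every member is a loss, ``gain`` if every member a gain, else ``both``."""
    if not members:
        raise ValueError("cannot classify an empty member list")
    states = {m.state for m in members}
    return states.pop() if len(states) == 1 else "both"


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus(
    callsets: Mapping[str, Sequence[CnvCall]],
    samples: Sequence[SampleRecord],
    level: str = "population",
    spec: OverlapSpec = OverlapSpec(),
    callers: Sequence[str] = CALLERS,
) -> list[ConsensusCnv]:
    """Loci supported by all callers at the requested stringency level.

    ``callsets`` maps caller name -> call list.  A caller with zero calls
    genome-wide yields an empty result with a warning.  At breed/individual
    level one record is emitted per qualifying (locus, breed) or
    (locus, sample) pair; ``locus_id`` identifies the underlying locus so
    distinct-locus counts can be compared across levels.
    """
    if level not in ("population", "breed", "individual"):
        raise ValueError(f"unknown consensus level: {level!r}")
    for caller in callers:
        if not callsets.get(caller):
            warnings.warn(f"caller {caller!r} contributed no calls; consensus is empty")
            return []
    breed_of = {s.sample_id: s.breed for s in samples}

    pooled: list[CnvCall] = []
    for caller in callers:
        pooled.extend(callsets[caller])

    out: list[ConsensusCnv] = []
    for locus_id, ms in enumerate(_components(pooled, spec)):
        per_caller: dict[str, list[CnvCall]] = {c: [] for c in callers}
        for m in ms:
            if m.caller in per_caller:
                per_caller[m.caller].append(m)
        if any(not v for v in per_caller.values()):
            continue

        if level == "population":
            out.append(_make_consensus(ms, per_caller, "population", None, breed_of, locus_id))
        elif level == "breed":
            common = set.intersection(
                *(set(breed_of.get(c.sample_id) for c in v) for v in per_caller.values())
            ) - {None}
            for breed in sorted(common):
                sub = {
                    k: [c for c in v if breed_of.get(c.sample_id) == breed]
                    for k, v in per_caller.items()
                }
                members = [c for v in sub.values() for c in v]
                out.append(_make_consensus(members, sub, "breed", breed, breed_of, locus_id))
        else:
            common = set.intersection(*(set(c.sample_id for c in v) for v in per_caller.values()))
            for sid in sorted(common):
                sub = {k: [c for c in v if c.sample_id == sid] for k, v in per_caller.items()}
                members = [c for v in sub.values() for c in v]
                out.append(_make_consensus(members, sub, "individual", sid, breed_of, locus_id))
    return out


def _make_consensus(members, support, level, unit, breed_of, locus_id) -> ConsensusCnv:
    region = CnvRegion(
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        members=list(members),
    )
    breeds = {breed_of[m.sample_id] for m in members if m.sample_id in breed_of}
    return ConsensusCnv(
        region=region,
        level=level,
        support=support,
        state=classify_state(members),
        breeds=breeds,
        locus_id=locus_id,
        unit=unit,
    )


def n_distinct_loci(consensus_list: Sequence[ConsensusCnv]) -> int:
    return len({c.locus_id for c in consensus_list})


# ---------------------------------------------------------------------------
# comparisons and sharing
# ---------------------------------------------------------------------------


def pairwise_overlap_fraction(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    spec: OverlapSpec = OverlapSpec(),
) -> float:
    """Fraction of calls in A with >= 1 call in B overlapping under ``spec``.

    Asymmetric by definition: A is the query set, B the reference.
    """
    if not calls_a:
        raise ValueError("empty query call set")
    b_by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for b in calls_b:
        b_by_chrom[b.chrom].append(b)
    n_hit = sum(
        1
        for a in calls_a
        if any(satisfies(a, b, spec) for b in b_by_chrom.get(a.chrom, ()))
    )
    return n_hit / len(calls_a)


def compare_external(my_regions: Sequence, external_regions: Sequence) -> pd.DataFrame:
    """Percent of external regions overlapped by our regions, per chromosome.

    Mirrors the shape of a CGH-versus-array comparison table: one row per
    chromosome carrying the external region count and the percent with any
    overlap, plus a ``total`` row.
    """
    mine: dict[str, list] = defaultdict(list)
    for r in my_regions:
        mine[r.chrom].append(r)
    ext: dict[str, list] = defaultdict(list)
    for r in external_regions:
        ext[r.chrom].append(r)

    rows = []
    total_n = total_hit = 0
    for chrom in sorted(ext, key=_chrom_key):
        n = len(ext[chrom])
        hit = sum(
            1
            for e in ext[chrom]
            if any(overlap_bp(e, m) >= 1 for m in mine.get(chrom, ()))
        )
        rows.append({"chrom": chrom, "n_external": n, "pct_overlapped": 100.0 * hit / n})
        total_n += n
        total_hit += hit
    rows.append(
        {
            "chrom": "total",
            "n_external": total_n,
            "pct_overlapped": 100.0 * total_hit / total_n if total_n else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["chrom", "n_external", "pct_overlapped"])


def breed_share_matrix(
    consensus_list: Sequence[ConsensusCnv],
    samples: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Symmetric breed x breed sharing counts over consensus CNVs.

    Off-diagonal (i, j): number of consensus CNVs with at least one carrier
    in breed i AND one in breed j.  Diagonal (i, i): number private to breed
    i.  Distinct loci are counted once even when several consensus records
    (breed/individual level) share a locus.
    """
    known = sorted({s.breed for s in samples})
    mat = pd.DataFrame(0, index=known, columns=known, dtype=int)
    seen: dict[int, set[str]] = {}
    for c in consensus_list:
        for b in c.breeds:
            if b not in mat.index:
                raise ValueError(f"unknown breed label: {b!r}")
        seen.setdefault(c.locus_id, set()).update(c.breeds)
    for breeds in seen.values():
        bl = sorted(breeds)
        if len(bl) == 1:
            mat.loc[bl[0], bl[0]] += 1
        else:
            for i, bi in enumerate(bl):
                for bj in bl[i + 1:]:
                    mat.loc[bi, bj] += 1
                    mat.loc[bj, bi] += 1
    return mat


def sharing_size_stats(
    calls: Sequence[CnvCall],
    spec: OverlapSpec = OverlapSpec(),
) -> tuple[float | None, float | None]:
    """Mean size of calls shared with >= 1 other sample vs private calls.

    A call is "shared" when some call from a different sample overlaps it
    under ``spec``.  Returns ``(shared_mean_bp, private_mean_bp)``; a class
    with no members yields ``None`` for its mean.
    """
    if len({c.sample_id for c in calls}) < 2:
        raise ValueError("sharing statistics need calls from >= 2 samples")
    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    shared_sizes: list[int] = []
    private_sizes: list[int] = []
    for c in calls:
        is_shared = any(
            o.sample_id != c.sample_id and satisfies(c, o, spec)
            for o in by_chrom[c.chrom]
        )
        (shared_sizes if is_shared else private_sizes).append(c.size)
    shared = float(np.mean(shared_sizes)) if shared_sizes else None
    private = float(np.mean(private_sizes)) if private_sizes else None
    return shared, private
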