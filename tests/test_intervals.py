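"""Interval algebra: overlap arithmetic, region merging, consensus levels,
state classification, sharing — checked against brute-force per-base and
union-find oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equicnv.intervals import (
    CnvRegion,
    OverlapSpec,
    breed_share_matrix,
    classify_state,
    compare_external,
    consensus,
    merge_to_regions,
    n_distinct_loci,
    overlap_bp,
    pairwise_overlap_fraction,
    satisfies,
    sharing_size_stats,
)
from equicnv.io import SampleRecord

from conftest import make_call, random_calls


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def overlap_oracle(a, b) -> int:
    """Shared bases by explicit set intersection (coords <= 10k only)."""
    return len(set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1)))


def components_oracle(calls, spec=OverlapSpec()):
    """O(n^2) union-find over all pairs satisfying the spec."""
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if calls[i].chrom == calls[j].chrom and satisfies(calls[i], calls[j], spec):
                parent[find(j)] = find(i)
    comps = {}
    for i in range(len(calls)):
        comps.setdefault(find(i), []).append(calls[i])
    return sorted(
        (sorted((c.chrom, c.start, c.end, c.sample_id) for c in ms) for ms in comps.values())
    )


# ---------------------------------------------------------------------------
# overlap primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((100, 200), (150, 250), 51),
        ((100, 200), (201, 300), 0),  # adjacency is not overlap (inclusive coords)
        ((100, 200), (120, 130), 11),  # nested
        ((1, 1), (1, 1), 1),
    ],
)
def test_overlap_bp_enumeration(a, b, expected):
    ca, cb = make_call(start=a[0], end=a[1]), make_call(start=b[0], end=b[1])
    assert overlap_bp(ca, cb) == expected == overlap_oracle(ca, cb)


def test_overlap_requires_same_chromosome():
    with pytest.raises(ValueError):
        overlap_bp(make_call(chrom="1"), make_call(chrom="2"))


@given(st.data())
@settings(max_examples=100, derandomize=True)
def test_overlap_matches_set_oracle_and_is_symmetric(data):
    s1 = data.draw(st.integers(1, 500))
    e1 = data.draw(st.integers(s1, 600))
    s2 = data.draw(st.integers(1, 500))
    e2 = data.draw(st.integers(s2, 600))
    a, b = make_call(start=s1, end=e1), make_call(start=s2, end=e2)
    assert overlap_bp(a, b) == overlap_oracle(a, b)
    assert overlap_bp(a, b) == overlap_bp(b, a)


@pytest.mark.parametrize(
    "a,b,frac,expected",
    [
        ((1, 100), (1, 100), 1.0, True),  # self-overlap fraction 1
        ((1, 100), (51, 150), 0.5, True),  # both fractions exactly 0.5
        ((1, 100), (51, 150), 0.51, False),  # boundary
    ],
)
def test_reciprocal_overlap_boundaries(a, b, frac, expected):
    spec = OverlapSpec(mode="reciprocal", min_fraction=frac)
    assert satisfies(make_call(start=a[0], end=a[1]), make_call(start=b[0], end=b[1]), spec) is expected


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_merge_textbook_union():
    calls = [make_call(start=1, end=10), make_call(start=5, end=20), make_call(start=30, end=40)]
    regions = merge_to_regions(calls)
    assert [(r.start, r.end) for r in regions] == [(1, 20), (30, 40)]


def test_merge_idempotent():
    rng = np.random.default_rng(0)
    calls = random_calls(rng, 50)
    regions = merge_to_regions(calls)
    as_calls = [make_call(chrom=r.chrom, start=r.start, end=r.end) for r in regions]
    again = merge_to_regions(as_calls)
    assert [(r.chrom, r.start, r.end) for r in regions] == [
        (r.chrom, r.start, r.end) for r in again
    ]


def test_merge_matches_union_find_oracle_random():
    rng = np.random.default_rng(42)
    for _ in range(20):
        calls = random_calls(rng, 200)
        got = sorted(
            sorted((c.chrom, c.start, c.end, c.sample_id) for c in r.members)
            for r in merge_to_regions(calls)
        )
        assert sorted(got) == components_oracle(calls)


def test_merge_regions_disjoint_and_conserve_coverage():
    """Merged envelopes are pairwise disjoint per chromosome and cover
    exactly the union of input base positions."""
    rng = np.random.default_rng(7)
    calls = random_calls(rng, 60, max_coord=5000)
    regions = merge_to_regions(calls)
    for chrom in {"1", "2"}:
        rs = sorted((r.start, r.end) for r in regions if r.chrom == chrom)
        for (s1, e1), (s2, e2) in zip(rs, rs[1:]):
            assert e1 < s2
        covered = set()
        for c in calls:
            if c.chrom == chrom:
                covered |= set(range(c.start, c.end + 1))
        enveloped = set()
        for s, e in rs:
            enveloped |= set(range(s, e + 1))
        assert covered <= enveloped
        # every envelope endpoint is a covered base
        for s, e in rs:
            assert s in covered and e in covered


def test_reciprocal_merge_never_coarser_than_any():
    rng = np.random.default_rng(3)
    calls = random_calls(rng, 100)
    n_any = len(merge_to_regions(calls, OverlapSpec()))
    for f in (0.1, 0.5, 0.9):
        n_rec = len(merge_to_regions(calls, OverlapSpec("reciprocal", f)))
        assert n_rec >= n_any


# ---------------------------------------------------------------------------
# state classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cns,expected",
    [([1, 1, 0], "loss"), ([3, 4], "gain"), ([1, 3], "both"), ([0], "loss")],
)
def test_classify_state(cns, expected):
    assert classify_state([make_call(cn=c) for c in cns]) == expected


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def _callsets(calls_by_caller):
    return {k: list(v) for k, v in calls_by_caller.items()}


def test_perfect_agreement_every_level(breed_samples):
    sets = _callsets(
        {c: [make_call(sample="s0", caller=c)] for c in ("cnvpartition", "penncnv", "quantisnp")}
    )
    for level in ("population", "breed", "individual"):
        cons = consensus(sets, breed_samples, level=level)
        assert len(cons) == 1
        assert cons[0].region.start == 100 and cons[0].region.end == 200


def test_level_semantics_same_breed_different_horses(breed_samples):
    # three callers hit the locus in three different Hanoverians -> consensus
    # at population and breed level, none at individual level
    sets = _callsets(
        {
            "cnvpartition": [make_call(sample="s0", caller="cnvpartition")],
            "penncnv": [make_call(sample="s1", caller="penncnv")],
            "quantisnp": [make_call(sample="s2", caller="quantisnp")],
        }
    )
    samples = [SampleRecord(f"s{i}", "Hanoverian", 160.0, 0.98) for i in range(3)]
    assert len(consensus(sets, samples, level="population")) == 1
    assert len(consensus(sets, samples, level="breed")) == 1
    assert len(consensus(sets, samples, level="individual")) == 0


def test_missing_caller_warns_and_returns_empty(breed_samples):
    sets = _callsets({"cnvpartition": [], "penncnv": [make_call()], "quantisnp": [make_call()]})
    with pytest.warns(UserWarning):
        assert consensus(sets, breed_samples) == []


def consensus_loci_oracle(callsets, samples, level):
    """Brute-force: pairwise union-find components, triple-loop support check."""
    pooled = [c for v in callsets.values() for c in v]
    parent = list(range(len(pooled)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(pooled)):
        for j in range(i + 1, len(pooled)):
            if pooled[i].chrom == pooled[j].chrom and satisfies(pooled[i], pooled[j]):
                parent[find(j)] = find(i)
    comps = {}
    for i in range(len(pooled)):
        comps.setdefault(find(i), []).append(pooled[i])

    breed_of = {s.sample_id: s.breed for s in samples}
    count = 0
    for members in comps.values():
        by_caller = {k: [c for c in members if c.caller == k] for k in callsets}
        if any(not v for v in by_caller.values()):
            continue
        if level == "population":
            count += 1
        elif level == "breed":
            ok = False
            for a in by_caller["cnvpartition"]:
                for b in by_caller["penncnv"]:
                    for c in by_caller["quantisnp"]:
                        if breed_of[a.sample_id] == breed_of[b.sample_id] == breed_of[c.sample_id]:
                            ok = True
            count += ok
        else:
            ok = False
            for a in by_caller["cnvpartition"]:
                for b in by_caller["penncnv"]:
                    for c in by_caller["quantisnp"]:
                        if a.sample_id == b.sample_id == c.sample_id:
                            ok = True
            count += ok
    return count


def test_consensus_distinct_loci_match_triple_loop_oracle():
    rng = np.random.default_rng(11)
    samples = [
        SampleRecord(f"s{i}", b, 160.0, 0.98)
        for i, b in enumerate(["Han", "Han", "Arab", "Arab", "Lus", "Lus"])
    ]
    sids = [s.sample_id for s in samples]
    for _ in range(10):
        sets = {
            caller: random_calls(rng, int(rng.integers(3, 15)), samples=sids, callers=(caller,))
            for caller in ("cnvpartition", "penncnv", "quantisnp")
        }
        for level in ("population", "breed", "individual"):
            got = n_distinct_loci(consensus(sets, samples, level=level))
            assert got == consensus_loci_oracle(sets, samples, level)


def test_consensus_level_monotonicity_random():
    rng = np.random.default_rng(2024)
    samples = [
        SampleRecord(f"s{i}", b, 160.0, 0.98)
        for i, b in enumerate(["Han", "Han", "Arab", "Lus"])
    ]
    sids = [s.sample_id for s in samples]
    for _ in range(25):
        sets = {
            caller: random_calls(rng, int(rng.integers(1, 20)), samples=sids, callers=(caller,))
            for caller in ("cnvpartition", "penncnv", "quantisnp")
        }
        n_pop = n_distinct_loci(consensus(sets, samples, level="population"))
        n_breed = n_distinct_loci(consensus(sets, samples, level="breed"))
        n_ind = n_distinct_loci(consensus(sets, samples, level="individual"))
        assert n_ind <= n_breed <= n_pop


def test_tightening_overlap_spec_is_monotone_pairwise():
    """Pair-level overlap is monotone in the criterion: any pair satisfying a
    stricter reciprocal fraction also satisfies every looser one, and the
    pairwise hit fraction can only shrink as the criterion tightens."""
    rng = np.random.default_rng(5)
    a = random_calls(rng, 40)
    b = random_calls(rng, 40, samples=("s9",))
    specs = [
        OverlapSpec("any"),
        OverlapSpec("reciprocal", 0.1),
        OverlapSpec("reciprocal", 0.5),
        OverlapSpec("reciprocal", 0.9),
    ]
    fracs = [pairwise_overlap_fraction(a, b, spec) for spec in specs]
    assert fracs == sorted(fracs, reverse=True)
    for x in a:
        for y in b:
            if x.chrom != y.chrom:
                continue
            sat = [satisfies(x, y, spec) for spec in specs]
            # once False under a looser spec, never True under a stricter one
            assert sat == sorted(sat, reverse=True)


# ---------------------------------------------------------------------------
# pairwise fractions / external / sharing
# ---------------------------------------------------------------------------


def test_pairwise_overlap_fraction_counting():
    a = [make_call(start=s, end=s + 10) for s in (100, 300, 500, 700)]
    b = [make_call(start=105, end=115, sample="s1")]
    assert pairwise_overlap_fraction(a, b) == 0.25
    assert pairwise_overlap_fraction(a, a) == 1.0
    disjoint = [make_call(start=10_000, end=10_010, sample="s1")]
    assert pairwise_overlap_fraction(a, disjoint) == 0.0
    with pytest.raises(ValueError):
        pairwise_overlap_fraction([], a)


def test_compare_external_fractions():
    mine = [CnvRegion("1", 100, 200)]
    ext = [CnvRegion("1", 150, 250), CnvRegion("1", 300, 400),
           CnvRegion("1", 500, 600), CnvRegion("1", 700, 800)]
    table = compare_external(mine, ext).set_index("chrom")
    assert table.loc["1", "pct_overlapped"] == 25.0
    assert table.loc["total", "pct_overlapped"] == 25.0
    full = compare_external(ext, ext).set_index("chrom")
    assert (full["pct_overlapped"] == 100.0).all()
    none = compare_external([], ext).set_index("chrom")
    assert (none["pct_overlapped"] == 0.0).all()


def test_breed_share_matrix_semantics(breed_samples):
    sets = _callsets(
        {
            "cnvpartition": [make_call(sample="s0", caller="cnvpartition"),
                             make_call(sample="s4", caller="cnvpartition")],
            "penncnv": [make_call(sample="s0", caller="penncnv")],
            "quantisnp": [make_call(sample="s4", caller="quantisnp")],
        }
    )
    cons = consensus(sets, breed_samples, level="population")
    mat = breed_share_matrix(cons, breed_samples)
    assert mat.loc["Hanoverian", "Lusitano"] == 1
    assert mat.loc["Lusitano", "Hanoverian"] == 1
    assert mat.loc["Hanoverian", "Hanoverian"] == 0
    assert mat.loc["Arabian"].sum() == 0


def test_breed_share_matrix_private_and_oracle():
    rng = np.random.default_rng(17)
    breeds = ["Han", "Arab", "Lus", "Mar"]
    samples = [SampleRecord(f"s{i}", breeds[i % 4], 160.0, 0.98) for i in range(12)]
    # fabricate consensus records directly: 20 loci with random carrier breeds
    from equicnv.intervals import ConsensusCnv

    cons = []
    truth_pairs = np.zeros((4, 4), dtype=int)
    for lid in range(20):
        k = int(rng.integers(1, 5))
        chosen = sorted(rng.choice(breeds, size=k, replace=False))
        cons.append(
            ConsensusCnv(
                region=CnvRegion("1", 1 + lid * 100, 50 + lid * 100),
                level="population", support={}, state="loss",
                breeds=set(chosen), locus_id=lid,
            )
        )
        if len(chosen) == 1:
            i = breeds.index(chosen[0])
            truth_pairs[i, i] += 1
        else:
            for x in range(len(chosen)):
                for y in range(x + 1, len(chosen)):
                    i, j = breeds.index(chosen[x]), breeds.index(chosen[y])
                    truth_pairs[i, j] += 1
                    truth_pairs[j, i] += 1
    mat = breed_share_matrix(cons, samples)
    for i, bi in enumerate(sorted(breeds)):
        for j, bj in enumerate(sorted(breeds)):
            oi, oj = breeds.index(bi), breeds.index(bj)
            assert mat.loc[bi, bj] == truth_pairs[oi, oj]
    assert (mat.values == mat.values.T).all()


def test_breed_share_matrix_unknown_breed_errors(breed_samples):
    from equicnv.intervals import ConsensusCnv

    bad = ConsensusCnv(region=CnvRegion("1", 1, 10), level="population",
                       support={}, state="loss", breeds={"Przewalski"}, locus_id=0)
    with pytest.raises(ValueError):
        breed_share_matrix([bad], breed_samples)


def test_sharing_size_stats_degenerate_cases():
    same = [make_call(sample="s0"), make_call(sample="s1")]
    shared, private = sharing_size_stats(same)
    assert private is None and shared == 101.0
    disjoint = [make_call(sample="s0", start=1, end=10),
                make_call(sample="s1", start=1000, end=1009)]
    shared, private = sharing_size_stats(disjoint)
    assert shared is None and private == 10.0


def test_sharing_correlates_with_length_when_shared_loci_are_longer():
    """Landscape where shared loci are drawn longer: the shared-size mean
    exceeds the private mean in nearly all seeded replicates."""
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        calls = []
        pos = 1
        for _ in range(15):  # long shared loci carried by 2 samples
            size = int(rng.integers(300, 600))
            for s in ("s0", "s1"):
                calls.append(make_call(start=pos, end=pos + size, sample=s))
            pos += size + 200
        for _ in range(15):  # short private loci
            size = int(rng.integers(20, 120))
            calls.append(make_call(start=pos, end=pos + size, sample=str(rng.choice(["s0", "s1"]))))
            pos += size + 200
        shared, private = sharing_size_stats(calls)
        wins += shared > private
    assert wins >= 95
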