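import numpy as np
import pytest

from equicnv.io import CnvCall, SampleRecord, SnpMap, SnpMarker


@pytest.fixture
def small_snp_map() -> SnpMap:
    """3 chromosomes x 10 kb with a marker every 500 bp."""
    markers = [
        SnpMarker(name=f"M{c}_{i}", chrom=str(c), pos=500 * (i + 1))
        for c in (1, 2, 3)
        for i in range(20)
    ]
    return SnpMap(markers=markers, chrom_lengths={"1": 10_000, "2": 10_000, "3": 10_000})


@pytest.fixture
def breed_samples() -> list[SampleRecord]:
    return [
        SampleRecord(f"s{i}", breed, 160.0, 0.98)
        for i, breed in enumerate(
            ["Hanoverian", "Hanoverian", "Arabian", "Arabian", "Lusitano"]
        )
    ]


def make_call(chrom="1", start=100, end=200, sample="s0", caller="penncnv",
              cn=1, n_probes=3, score=None) -> CnvCall:
    return CnvCall(sample_id=sample, caller=caller, chrom=chrom, start=start,
                   end=end, copy_number=cn, n_probes=n_probes, score=score)


def random_calls(rng: np.random.Generator, n: int, samples=("s0", "s1", "s2"),
                 callers=("penncnv",), max_coord=10_000, chroms=("1", "2")) -> list[CnvCall]:
    calls = []
    for _ in range(n):
        start = int(rng.integers(1, max_coord))
        end = int(min(start + rng.integers(0, max_coord // 5), max_coord))
        calls.append(
            make_call(
                chrom=str(rng.choice(chroms)),
                start=start,
                end=end,
                sample=str(rng.choice(samples)),
                caller=str(rng.choice(callers)),
                cn=int(rng.choice([0, 1, 3, 4])),
            )
        )
    return calls
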