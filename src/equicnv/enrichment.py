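"""Per-chromosome CNV-region coverage and enrichment.

The enrichment statistic is marker-based: the number of array SNPs covered
by CNV regions on a chromosome, divided by the chromosome length in bp.  A
chromosome is flagged enriched when this density exceeds the genome-wide
density (total covered SNPs over total autosome length).  The bp coverage
percentage of each chromosome is reported alongside, since it is the more
familiar summary, but the flag follows the SNP-density rule.

An optional permutation test (off by default in the pipeline) scatters the
observed region lengths uniformly over the genome — chromosome assignment
proportional to length, start uniform within the chromosome — and reports,
per chromosome, the fraction of placements whose SNP density meets or
exceeds the observed one (add-one corrected).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import SnpMap, _chrom_key


def coverage_table(regions: Sequence, snp_map: SnpMap) -> pd.DataFrame:
    """One row per autosome in ``snp_map``: covered-SNP density, bp coverage
    percent and the enrichment flag, plus a ``total`` row.

    Regions must be merged (disjoint per chromosome) and lie within their
    chromosome's length.
    """
    lengths = snp_map.chrom_lengths
    by_chrom: dict[str, list] = {c: [] for c in lengths}
    for r in regions:
        if r.chrom not in lengths:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")
        if r.end > lengths[r.chrom]:
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} beyond chromosome length {lengths[r.chrom]}"
            )
        by_chrom[r.chrom].append(r)

    rows = []
    for chrom in sorted(lengths, key=_chrom_key):
        n_snps = sum(snp_map.count_in(chrom, r.start, r.end) for r in by_chrom[chrom])
        bp = sum(r.end - r.start + 1 for r in by_chrom[chrom])
        rows.append(
            {
                "chrom": chrom,
                "n_snps_in_cnvr": n_snps,
                "chrom_length": lengths[chrom],
                "snp_density": n_snps / lengths[chrom],
                "bp_coverage_pct": 100.0 * bp / lengths[chrom],
            }
        )
    df = pd.DataFrame(rows)
    total_len = snp_map.total_length()
    genome_density = df["n_snps_in_cnvr"].sum() / total_len
    df["genome_snp_density"] = genome_density
    df["enriched"] = df["snp_density"] > genome_density

    total = {
        "chrom": "total",
        "n_snps_in_cnvr": int(df["n_snps_in_cnvr"].sum()),
        "chrom_length": total_len,
        "snp_density": genome_density,
        "bp_coverage_pct": 100.0
        * sum(r.end - r.start + 1 for r in regions)
        / total_len,
        "genome_snp_density": genome_density,
        "enriched": False,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def permutation_enrichment(
    regions: Sequence,
    snp_map: SnpMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-chromosome p-values for covered-SNP density.

    Each permutation re-places every region: a chromosome drawn with
    probability proportional to its length (among chromosomes the region
    fits on), then a uniform start.  p is the add-one-corrected fraction of
    permutations with chromosome SNP density >= the observed density.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    chroms = snp_map.chroms
    lengths = np.array([snp_map.chrom_lengths[c] for c in chroms], dtype=float)
    positions = {c: snp_map.positions(c) for c in chroms}

    obs = coverage_table(regions, snp_map)
    obs = obs[obs["chrom"] != "total"].set_index("chrom")["snp_density"]

    sizes = np.array([r.end - r.start + 1 for r in regions], dtype=int)
    if len(sizes) and sizes.max() > lengths.max():
        raise ValueError("a region is longer than every chromosome")

    exceed = {c: 0 for c in chroms}
    for _ in range(n_perm):
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for size in sizes:
            ok = lengths >= size
            probs = np.where(ok, lengths, 0.0)
            probs /= probs.sum()
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            start = int(rng.integers(1, snp_map.chrom_lengths[chrom] - size + 2))
            pos = positions[chrom]
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, start + size - 1, side="right"))
            if hi > lo:
                spans[chrom].append((lo, hi))
        for c in chroms:
            # count distinct covered markers (placements may overlap)
            n_cov = 0
            last = -1
            for lo, hi in sorted(spans[c]):
                lo = max(lo, last)
                if hi > lo:
                    n_cov += hi - lo
                    last = hi
                last = max(last, hi)
            if n_cov / snp_map.chrom_lengths[c] >= obs[c]:
                exceed[c] += 1

    return pd.DataFrame(
        {
            "chrom": chroms,
            "observed_snp_density": [obs[c] for c in chroms],
            "perm_p": [(1 + exceed[c]) / (n_perm + 1) for c in chroms],
        }
    )
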