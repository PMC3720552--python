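"""Synthetic SNP-array CNV study generator.

Everything the pipeline consumes can be generated here: a marker map, a
breed-structured cohort with array QC metrics, a true CNV landscape, three
caller-specific call sets with distinct error profiles, a height trait with
a planted deletion effect, and qPCR wells for validation loci.

The defaults emulate the statistical structure of an Illumina Equine SNP50
CNV survey: CNV sizes are log-normal with median ~169 kb and mean ~488 kb;
the three callers have very different yields (CNVPartition misses most
events, PennCNV and QuantiSNP are far more sensitive); breeds differ in
mean withers height (Arabian 148 cm, Lusitano 160 cm, Hanoverian 168 cm);
larger CNV loci carry higher population frequencies, so sharing correlates
with length; and one deletion locus increases height by +4 cm per deleted
copy.  The genome itself is scaled down (5 chromosomes x 10 Mb, 2,000
markers, 200 animals by default) so that a full pipeline run takes seconds;
``full_scale()`` returns a 31-chromosome / 48,860-marker / 717-animal
configuration for slow runs.

Every generator is a pure function of (config, seed): sub-streams are
derived from the configured seed with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import CnvCall, QpcrWell, SampleRecord, SnpMap, SnpMarker


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallerProfile:
    """Error profile of one detection algorithm.

    ``score_mean``/``score_sd`` parameterise the emitted confidence score
    (Log Bayes Factor for quantisnp, confidence for cnvpartition) so that
    the QC score filters have something to cut; ``None`` emits no score.
    """

    name: str
    sensitivity: float
    fp_per_sample: float
    jitter_sd: float
    score_mean: float | None = None
    score_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must be in [0,1]")
        if self.fp_per_sample < 0 or self.jitter_sd < 0:
            raise ValueError("fp_per_sample and jitter_sd must be >= 0")


#: low / mid / high yield defaults mirroring the three callers' relative
#: sensitivities (CNVPartition misses most events).
DEFAULT_PROFILES: tuple[CallerProfile, ...] = (
    CallerProfile("cnvpartition", sensitivity=0.20, fp_per_sample=0.05,
                  jitter_sd=5_000.0, score_mean=60.0, score_sd=20.0),
    CallerProfile("penncnv", sensitivity=0.70, fp_per_sample=0.20, jitter_sd=5_000.0),
    CallerProfile("quantisnp", sensitivity=0.80, fp_per_sample=0.30,
                  jitter_sd=5_000.0, score_mean=25.0, score_sd=10.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Sizes are log-normal, parameterised by (median, mean) in bp because
    those are the natural summaries of a CNV size distribution:
    mu = ln(median), sigma = sqrt(2 ln(mean/median)).
    """

    seed: int
    n_chrom: int = 5
    chrom_length: int = 10_000_000
    n_snps: int = 2_000
    # (name, n_samples, mean_height_cm)
    breeds: tuple[tuple[str, int, float], ...] = (
        ("Arabian", 50, 148.0),
        ("Hanoverian", 100, 168.0),
        ("Lusitano", 50, 160.0),
    )
    n_cnv_loci: int = 30
    size_median: float = 169_367.0
    size_mean: float = 487_562.0
    size_cap_frac: float = 0.25  # truncate draws at this fraction of a chromosome
    loss_fraction: float = 0.6
    carrier_freq_min: float = 0.02
    carrier_freq_max: float = 0.30
    hom_fraction: float = 0.10  # carriers at cn 0 (loss) or cn 4 (gain)
    causal_index: int | None = None  # None -> first loss locus
    causal_carrier_freq: float | None = 0.15
    causal_beta_cm: float = 4.0
    trait_sd_cm: float = 3.0
    min_probes: int = 3
    caller_profiles: tuple[CallerProfile, ...] = DEFAULT_PROFILES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for v in (self.n_chrom, self.chrom_length, self.n_snps, self.n_cnv_loci):
            if v <= 0:
                raise ValueError("all counts must be positive")
        if self.size_mean < self.size_median:
            raise ValueError("log-normal needs mean >= median")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n, _ in self.breeds)

    @property
    def lognorm_params(self) -> tuple[float, float]:
        mu = math.log(self.size_median)
        sigma = math.sqrt(2.0 * math.log(self.size_mean / self.size_median))
        return mu, sigma


def full_scale(seed: int) -> SimConfig:
    """Full-size configuration: 31 autosomes, 48,860 markers, 717 animals."""
    return SimConfig(
        seed=seed,
        n_chrom=31,
        chrom_length=60_000_000,
        n_snps=48_860,
        breeds=(
            ("Arabian", 87, 148.0),
            ("Hanoverian", 458, 168.0),
            ("Lusitano", 47, 160.0),
            ("Maremanno", 44, 160.0),
            ("Thoroughbred", 13, 163.0),
            ("Westphalian", 29, 168.0),
            ("Oldenburg", 11, 168.0),
            ("Holsteiner", 6, 168.0),
            ("Rhinelander", 11, 168.0),
            ("Other", 11, 165.0),
        ),
        n_cnv_loci=100,
    )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# genome and cohort
# ---------------------------------------------------------------------------


def gen_genome(config: SimConfig) -> SnpMap:
    """Uniformly scattered markers, allocated to chromosomes by length."""
    rng = _rng(config, 1)
    chroms = [str(i + 1) for i in range(config.n_chrom)]
    lengths = {c: config.chrom_length for c in chroms}
    total = sum(lengths.values())
    # multinomial allocation proportional to length, then >= 1 marker each
    counts = rng.multinomial(config.n_snps - config.n_chrom,
                             [lengths[c] / total for c in chroms])
    markers: list[SnpMarker] = []
    k = 0
    for c, extra in zip(chroms, counts):
        pos = np.sort(rng.choice(lengths[c], size=extra + 1, replace=False)) + 1
        for p in pos:
            markers.append(SnpMarker(name=f"SNP{k:06d}", chrom=c, pos=int(p)))
            k += 1
    return SnpMap(markers=markers, chrom_lengths=lengths)


def gen_cohort(config: SimConfig) -> list[SampleRecord]:
    """Breed-structured animals with array QC metrics (heights attached later).

    A few animals draw QC metrics beyond the exclusion thresholds so the
    quality filters have work to do.
    """
    rng = _rng(config, 2)
    samples: list[SampleRecord] = []
    i = 0
    for breed, n, _ in config.breeds:
        for _ in range(n):
            samples.append(
                SampleRecord(
                    sample_id=f"H{i:04d}",
                    breed=breed,
                    height_cm=None,
                    call_rate=float(np.clip(rng.normal(0.975, 0.025), 0.0, 1.0)),
                    sd_lrr=float(abs(rng.normal(0.12, 0.07))),
                    gcwf=float(rng.normal(0.0, 0.008)),
                )
            )
            i += 1
    return samples


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueLocus:
    locus_id: int
    chrom: str
    start: int
    end: int
    state: str  # loss | gain
    carrier_freq: float

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class CnvTruth:
    """Planted CNV landscape: loci plus per-sample true copy numbers."""

    loci: list[TrueLocus]
    genotypes: dict[tuple[int, str], int]  # (locus_id, sample_id) -> cn != 2
    samples: list[SampleRecord]

    def cn(self, locus_id: int, sample_id: str) -> int:
        return self.genotypes.get((locus_id, sample_id), 2)

    def carriers(self, locus_id: int) -> list[str]:
        return sorted(s for (l, s) in self.genotypes if l == locus_id)

    @property
    def causal_locus(self) -> TrueLocus | None:
        return getattr(self, "_causal", None)


def gen_truth(config: SimConfig, snp_map: SnpMap,
              samples: Sequence[SampleRecord] | None = None) -> CnvTruth:
    """Place disjoint CNV loci and assign carriers.

    Sizes are log-normal (truncated at ``size_cap_frac`` of a chromosome);
    each locus spans >= ``min_probes`` markers so detection is possible
    after the probe-count filter; carrier frequency is comonotone with
    size (larger loci are carried by more animals, so sharing correlates
    with length); each carrier is heterozygous except a ``hom_fraction``
    drawn homozygous (cn 0) or double-gain (cn 4).
    """
    rng = _rng(config, 3)
    if samples is None:
        samples = gen_cohort(config)
    mu, sigma = config.lognorm_params
    chroms = snp_map.chroms
    lengths = snp_map.chrom_lengths
    cap = config.size_cap_frac * max(lengths.values())

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    loci_intervals: list[tuple[str, int, int]] = []
    attempts = 0
    while len(loci_intervals) < config.n_cnv_loci:
        attempts += 1
        if attempts > 200 * config.n_cnv_loci:
            raise RuntimeError(
                "cannot place CNV loci disjointly; shrink size_median/size_mean "
                "or reduce n_cnv_loci"
            )
        size = int(min(rng.lognormal(mu, sigma), cap))
        size = max(size, 1000)
        fits = [c for c in chroms if lengths[c] >= size]
        weights = np.array([lengths[c] for c in fits], dtype=float)
        chrom = fits[rng.choice(len(fits), p=weights / weights.sum())]
        start = int(rng.integers(1, lengths[chrom] - size + 2))
        end = start + size - 1
        if any(not (end < s or start > e) for s, e in placed[chrom]):
            continue
        if snp_map.count_in(chrom, start, end) < config.min_probes:
            continue
        placed[chrom].append((start, end))
        loci_intervals.append((chrom, start, end))

    # larger loci get higher carrier frequency (comonotone coupling)
    sizes = np.array([e - s + 1 for _, s, e in loci_intervals])
    freqs = np.sort(rng.uniform(config.carrier_freq_min, config.carrier_freq_max,
                                size=len(sizes)))
    freq_by_locus = np.empty(len(sizes))
    freq_by_locus[np.argsort(sizes)] = freqs

    states = np.where(rng.random(len(sizes)) < config.loss_fraction, "loss", "gain")
    if not (states == "loss").any():
        states[int(rng.integers(len(states)))] = "loss"  # guarantee a causal candidate

    loci = [
        TrueLocus(locus_id=i, chrom=c, start=s, end=e,
                  state=str(states[i]), carrier_freq=float(freq_by_locus[i]))
        for i, (c, s, e) in enumerate(loci_intervals)
    ]
    loci.sort(key=lambda l: (int(l.chrom), l.start))
    loci = [replace(l, locus_id=i) for i, l in enumerate(loci)]

    ci = config.causal_index
    if ci is None:
        ci = next(i for i, l in enumerate(loci) if l.state == "loss")
    if not (0 <= ci < len(loci)):
        raise ValueError("causal locus index out of range")
    if loci[ci].state != "loss":
        raise ValueError("causal locus must be a loss locus")
    if config.causal_carrier_freq is not None:
        loci[ci] = replace(loci[ci], carrier_freq=config.causal_carrier_freq)

    genotypes: dict[tuple[int, str], int] = {}
    for locus in loci:
        for s in samples:
            if rng.random() < locus.carrier_freq:
                hom = rng.random() < config.hom_fraction
                cn = (0 if hom else 1) if locus.state == "loss" else (4 if hom else 3)
                genotypes[(locus.locus_id, s.sample_id)] = cn

    truth = CnvTruth(loci=loci, genotypes=genotypes, samples=list(samples))
    truth._causal = loci[ci]
    return truth


# ---------------------------------------------------------------------------
# caller call sets
# ---------------------------------------------------------------------------


def _snap_to_probes(chrom: str, start: int, end: int, snp_map: SnpMap,
                    min_probes: int) -> tuple[int, int, int] | None:
    """Clip to the chromosome and expand until >= min_probes markers are spanned."""
    length = snp_map.chrom_lengths[chrom]
    pos = snp_map.positions(chrom)
    if len(pos) < min_probes:
        return None
    start = max(1, min(start, length))
    end = max(start, min(end, length))
    lo = int(np.searchsorted(pos, start, side="left"))
    hi = int(np.searchsorted(pos, end, side="right"))
    while hi - lo < min_probes:
        can_lo, can_hi = lo > 0, hi < len(pos)
        if can_lo and (not can_hi or start - pos[lo - 1] <= pos[hi] - end):
            lo -= 1
        else:
            hi += 1
    start = min(start, int(pos[lo]))
    end = max(end, int(pos[hi - 1]))
    return start, end, hi - lo


def gen_caller_calls(
    truth: CnvTruth,
    snp_map: SnpMap,
    config: SimConfig,
    profiles: Sequence[CallerProfile] | None = None,
) -> dict[str, list[CnvCall]]:
    """Three caller-specific call sets with independent error profiles.

    Each true (locus, sample) genotype is detected with the caller's
    sensitivity; detected breakpoints are jittered by N(0, jitter_sd) and
    snapped so the call still spans >= min_probes markers; copy number is
    preserved on true detections.  False positives are Poisson per sample,
    placed uniformly and redrawn if they touch a true locus, so sensitivity
    and false-positive rate stay identifiable.
    """
    if profiles is None:
        profiles = config.caller_profiles
    out: dict[str, list[CnvCall]] = {}
    true_iv = {c: [] for c in snp_map.chroms}
    for l in truth.loci:
        true_iv[l.chrom].append((l.start, l.end))

    for k, prof in enumerate(profiles):
        rng = _rng(config, 10 + k)
        calls: list[CnvCall] = []
        for locus in truth.loci:
            for sid in truth.carriers(locus.locus_id):
                if rng.random() >= prof.sensitivity:
                    continue
                js, je = locus.start, locus.end
                if prof.jitter_sd > 0:
                    js = int(round(js + rng.normal(0, prof.jitter_sd)))
                    je = int(round(je + rng.normal(0, prof.jitter_sd)))
                    if js > je:
                        js, je = je, js
                snapped = _snap_to_probes(locus.chrom, js, je, snp_map, config.min_probes)
                if snapped is None:
                    continue
                s, e, nprobes = snapped
                score = None
                if prof.score_mean is not None:
                    score = float(max(0.1, rng.normal(prof.score_mean, prof.score_sd)))
                calls.append(
                    CnvCall(
                        sample_id=sid, caller=prof.name, chrom=locus.chrom,
                        start=s, end=e,
                        copy_number=truth.cn(locus.locus_id, sid),
                        n_probes=nprobes, score=score,
                    )
                )
        # false positives: uniform, never overlapping a true locus
        mu_fp, sigma_fp = config.lognorm_params
        for smp in truth.samples:
            for _ in range(rng.poisson(prof.fp_per_sample)):
                for _try in range(50):
                    size = int(min(rng.lognormal(mu_fp, sigma_fp),
                                   config.size_cap_frac * config.chrom_length))
                    size = max(size, 1000)
                    chrom = snp_map.chroms[rng.integers(len(snp_map.chroms))]
                    if size >= snp_map.chrom_lengths[chrom]:
                        continue
                    start = int(rng.integers(1, snp_map.chrom_lengths[chrom] - size + 2))
                    end = start + size - 1
                    if any(not (end < s or start > e) for s, e in true_iv[chrom]):
                        continue
                    nprobes = snp_map.count_in(chrom, start, end)
                    if nprobes < 1:
                        continue
                    score = None
                    if prof.score_mean is not None:
                        score = float(max(0.1, rng.normal(prof.score_mean, prof.score_sd)))
                    calls.append(
                        CnvCall(
                            sample_id=smp.sample_id, caller=prof.name, chrom=chrom,
                            start=start, end=end,
                            copy_number=1 if rng.random() < config.loss_fraction else 3,
                            n_probes=nprobes, score=score,
                        )
                    )
                    break
        out[prof.name] = calls
    return out


# ---------------------------------------------------------------------------
# trait and qPCR
# ---------------------------------------------------------------------------


def gen_trait(truth: CnvTruth, config: SimConfig) -> dict[str, float]:
    """Withers height per animal: breed mean + planted deletion effect + noise.

    height = breed_mean + beta_cm * (2 - cn_at_causal_locus) + N(0, trait_sd).
    """
    rng = _rng(config, 4)
    causal = truth.causal_locus
    if causal is None:
        raise ValueError("truth carries no causal locus")
    breed_mean = {name: h for name, _, h in config.breeds}
    heights: dict[str, float] = {}
    for s in truth.samples:
        if s.breed not in breed_mean:
            raise ValueError(f"no configured mean height for breed {s.breed!r}")
        cn = truth.cn(causal.locus_id, s.sample_id)
        heights[s.sample_id] = (
            breed_mean[s.breed]
            + config.causal_beta_cm * (2 - cn)
            + rng.normal(0.0, config.trait_sd_cm)
        )
    return heights


def attach_heights(samples: Sequence[SampleRecord], heights: dict[str, float]) -> list[SampleRecord]:
    return [replace(s, height_cm=heights.get(s.sample_id)) for s in samples]


def gen_qpcr(
    truth: CnvTruth,
    locus_id: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_samples: int = 20,
    base_target_ct: float = 28.0,
    base_ref_ct: float = 20.0,
    censored_ct: float = 38.0,
) -> tuple[list[QpcrWell], str]:
    """qPCR wells for one locus: target + reference assays, two replicates.

    Ct_target = base - log2(cn/2) + noise for carriers (cn=0 is censored at
    a high Ct); the returned calibrator is a diploid animal at the locus.
    Returns (wells, calibrator_sample_id).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20, int(locus_id)]))
    carriers = truth.carriers(locus_id)
    diploid = [s.sample_id for s in truth.samples if truth.cn(locus_id, s.sample_id) == 2]
    if not diploid:
        raise ValueError("no diploid calibrator available at this locus")
    calibrator = diploid[0]
    chosen = carriers[: n_samples // 2]
    chosen += [s for s in diploid if s != calibrator][: n_samples - len(chosen)]
    chosen = [calibrator] + chosen

    assay = f"region_{locus_id}"
    wells: list[QpcrWell] = []
    for sid in chosen:
        cn = truth.cn(locus_id, sid)
        for rep in (1, 2):
            if cn == 0:
                ct_t = censored_ct + rng.normal(0, noise_sd)
            else:
                ct_t = base_target_ct - math.log2(cn / 2.0) + rng.normal(0, noise_sd)
            wells.append(QpcrWell(sample_id=sid, assay=assay, ct=float(ct_t), replicate=rep))
            wells.append(
                QpcrWell(
                    sample_id=sid, assay="GAPDH",
                    ct=float(base_ref_ct + rng.normal(0, noise_sd)), replicate=rep,
                )
            )
    return wells, calibrator


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    config: SimConfig
    snp_map: SnpMap
    samples: list[SampleRecord]  # heights attached
    truth: CnvTruth
    callsets: dict[str, list[CnvCall]]


def simulate(config: SimConfig) -> SimBundle:
    """Generate the full input bundle for a pipeline run."""
    snp_map = gen_genome(config)
    cohort = gen_cohort(config)
    truth = gen_truth(config, snp_map, cohort)
    heights = gen_trait(truth, config)
    samples = attach_heights(cohort, heights)
    truth.samples = samples
    callsets = gen_caller_calls(truth, snp_map, config)
    return SimBundle(config=config, snp_map=snp_map, samples=samples,
                     truth=truth, callsets=callsets)
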