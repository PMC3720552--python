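"""File-based pipeline orchestration.

Each stage reads its inputs from, and writes its outputs to, a run
directory; cross-stage state flows only through files, so any stage can be
re-run in isolation and a run is reproducible from its manifest (config
snapshot + seed).  Stage order: simulate -> qc -> consensus -> enrich ->
share -> assoc -> qpcr -> report.  The report stage collects the result
tables as table1/table4/table5/table7 (chromosomal enrichment, per-breed
CNV counts, breed sharing, trait association).
"""

from __future__ import annotations

import hashlib

import logging
import time

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .association import CnvAssociationModel, build_genotypes
from .enrichment import coverage_table, permutation_enrichment
from .intervals import (
    CnvRegion,
    ConsensusCnv,
    OverlapSpec,
    breed_share_matrix,
    compare_external,
    consensus,
    merge_to_regions,
    pairwise_overlap_fraction,
    sharing_size_stats,
)
from .io import (
    CALLERS,
    read_calls,
    read_qpcr_wells,
    read_samples,
    read_snp_map,
    write_calls,
    write_qpcr_wells,
    write_regions_bed,
    write_samples,
    write_snp_map,
)
from .qc import QcThresholds, filter_calls, filter_samples
from .qpcr import concordance, relative_quantity, results_to_frame
from .simulate import CallerProfile, SimConfig, gen_qpcr, simulate

log = logging.getLogger("equicnv")

STAGES = ("simulate", "qc", "consensus", "enrich", "share", "assoc", "qpcr", "report")

#: optional stages not part of a default run-all (need external inputs)
EXTRA_STAGES = ("compare_external",)

_KNOWN_KEYS = {"simulate", "qc", "consensus", "enrich", "assoc", "qpcr",
               "compare_external", "seed"}


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"invalid config key(s): {sorted(unknown)}")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """One analysis run rooted at ``out_dir``."""

    def __init__(self, out_dir: str | Path, config: dict | None = None, seed: int = 0):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = config or {}
        self.seed = int(self.config.get("seed", seed))
        self.manifest: dict = {
            "tool": "equicnv",
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "stages": [],
            "outputs": {},
        }

    # -- helpers ---------------------------------------------------------

    def _require(self, filename: str, produced_by: str) -> Path:
        p = self.out / filename
        if not p.exists():
            raise FileNotFoundError(
                f"{produced_by} outputs missing: run the {produced_by!r} stage first"
            )
        return p

    def _record(self, stage: str, files: Sequence[str], t0: float, n_records: int) -> None:
        self.manifest["stages"].append(stage)
        for f in files:
            self.manifest["outputs"][f] = _digest(self.out / f)
        log.info("stage=%s wall=%.2fs records=%d", stage, time.time() - t0, n_records)

    def _spec(self) -> OverlapSpec:
        c = self.config.get("consensus", {})
        return OverlapSpec(mode=c.get("overlap_mode", "any"),
                           min_fraction=c.get("min_fraction", 0.5))

    def _qc_thresholds(self) -> QcThresholds:
        return QcThresholds(**self.config.get("qc", {}))

    # -- stages ----------------------------------------------------------

    def stage_simulate(self) -> None:
        t0 = time.time()
        sim_cfg = dict(self.config.get("simulate", {}))
        sim_cfg.setdefault("seed", self.seed)
        if "breeds" in sim_cfg:
            sim_cfg["breeds"] = tuple(
                (str(b), int(n), float(h)) for b, n, h in sim_cfg["breeds"]
            )
        if "caller_profiles" in sim_cfg:
            sim_cfg["caller_profiles"] = tuple(
                p if isinstance(p, CallerProfile) else CallerProfile(**p)
                for p in sim_cfg["caller_profiles"]
            )
        config = SimConfig(**sim_cfg)
        bundle = simulate(config)
        write_snp_map(bundle.snp_map, self.out / "snp_map.tsv",
                      self.out / "chrom_lengths.tsv")
        write_samples(bundle.samples, self.out / "samples.tsv")
        files = ["snp_map.tsv", "chrom_lengths.tsv", "samples.tsv"]
        for caller, calls in bundle.callsets.items():
            f = f"calls_{caller}.tsv"
            write_calls(calls, self.out / f)
            files.append(f)
        pd.DataFrame(
            [
                {"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start,
                 "end": l.end, "state": l.state, "carrier_freq": l.carrier_freq,
                 "causal": l.locus_id == bundle.truth.causal_locus.locus_id}
                for l in bundle.truth.loci
            ]
        ).to_csv(self.out / "truth_loci.tsv", sep="\t", index=False)
        files.append("truth_loci.tsv")
        wells, calibrator = gen_qpcr(
            bundle.truth, bundle.truth.causal_locus.locus_id,
            seed=config.seed,
        )
        write_qpcr_wells(wells, self.out / "qpcr_wells.tsv")
        (self.out / "qpcr_calibrator.txt").write_text(calibrator + "\n")
        files += ["qpcr_wells.tsv", "qpcr_calibrator.txt"]
        self._record("simulate", files, t0, sum(len(v) for v in bundle.callsets.values()))

    def stage_qc(self) -> None:
        t0 = time.time()
        thresholds = self._qc_thresholds()
        samples = read_samples(self._require("samples.tsv", "simulate"))
        kept, logr = filter_samples(samples, thresholds)
        write_samples(kept, self.out / "samples_qc.tsv")
        logr.to_frame().to_csv(self.out / "sample_exclusions.tsv", sep="\t", index=False)
        kept_ids = {s.sample_id for s in kept}
        files = ["samples_qc.tsv", "sample_exclusions.tsv"]
        n = 0
        removed_rows = []
        for caller in CALLERS:
            calls = read_calls(self._require(f"calls_{caller}.tsv", "simulate"),
                               dialect="tsv", caller=caller)
            calls = [c for c in calls if c.sample_id in kept_ids]
            kept_calls, counts = filter_calls(calls, thresholds)
            write_calls(kept_calls, self.out / f"calls_qc_{caller}.tsv")
            files.append(f"calls_qc_{caller}.tsv")
            removed_rows.append({"caller": caller, **counts})
            n += len(kept_calls)
        pd.DataFrame(removed_rows).to_csv(self.out / "call_exclusions.tsv",
                                          sep="\t", index=False)
        files.append("call_exclusions.tsv")
        self._record("qc", files, t0, n)

    def _load_qc_callsets(self):
        return {
            caller: read_calls(self._require(f"calls_qc_{caller}.tsv", "qc"),
                               dialect="tsv", caller=caller)
            for caller in CALLERS
        }

    def stage_consensus(self) -> None:
        t0 = time.time()
        callsets = self._load_qc_callsets()
        samples = read_samples(self._require("samples_qc.tsv", "qc"))
        spec = self._spec()
        files = []
        n = 0
        for level in ("population", "breed", "individual"):
            cons = consensus(callsets, samples, level=level, spec=spec)
            df = consensus_to_frame(cons)
            f = f"consensus_{level}.tsv"
            df.to_csv(self.out / f, sep="\t", index=False)
            files.append(f)
            if level == "population":
                write_regions_bed([c.region for c in cons],
                                  self.out / "consensus_regions.bed")
                files.append("consensus_regions.bed")
            n += len(cons)
        # pairwise caller overlap fractions
        rows = []
        for a in CALLERS:
            for b in CALLERS:
                if a != b and callsets[a]:
                    rows.append({"query": a, "reference": b,
                                 "fraction": pairwise_overlap_fraction(
                                     callsets[a], callsets[b], spec)})
        pd.DataFrame(rows).to_csv(self.out / "pairwise_overlap.tsv", sep="\t", index=False)
        files.append("pairwise_overlap.tsv")
        self._record("consensus", files, t0, n)

    def stage_enrich(self) -> None:
        t0 = time.time()
        snp_map = read_snp_map(self._require("snp_map.tsv", "simulate"),
                               self._require("chrom_lengths.tsv", "simulate"))
        callsets = self._load_qc_callsets()
        pooled = [c for calls in callsets.values() for c in calls]
        regions = merge_to_regions(pooled)
        table = coverage_table(regions, snp_map)
        table.to_csv(self.out / "table1.tsv", sep="\t", index=False)
        files = ["table1.tsv"]
        ecfg = self.config.get("enrich", {})
        if ecfg.get("permutation", False):
            perm = permutation_enrichment(regions, snp_map,
                                          n_perm=int(ecfg.get("n_perm", 1000)),
                                          seed=self.seed)
            perm.to_csv(self.out / "enrichment_permutation.tsv", sep="\t", index=False)
            files.append("enrichment_permutation.tsv")
        self._record("enrich", files, t0, len(regions))

    def stage_share(self) -> None:
        t0 = time.time()
        callsets = self._load_qc_callsets()
        samples = read_samples(self._require("samples_qc.tsv", "qc"))
        spec = self._spec()
        cons_pop = consensus(callsets, samples, level="population", spec=spec)
        cons_breed = consensus(callsets, samples, level="breed", spec=spec)
        cons_ind = consensus(callsets, samples, level="individual", spec=spec)

        mat = breed_share_matrix(cons_pop, samples)
        mat.to_csv(self.out / "table5.tsv", sep="\t")

        # per-breed counts in the shape of the breed-distribution table
        pooled = [c for calls in callsets.values() for c in calls]
        rows = []
        for breed in sorted({s.breed for s in samples}):
            ids = {s.sample_id for s in samples if s.breed == breed}
            rows.append(
                {
                    "breed": breed,
                    "n_animals": len(ids),
                    "n_calls": sum(1 for c in pooled if c.sample_id in ids),
                    "n_consensus_breed": sum(1 for c in cons_breed if c.unit == breed),
                    "n_consensus_individual": sum(
                        1 for c in cons_ind
                        if c.unit in ids
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(self.out / "table4.tsv", sep="\t", index=False)

        shared_mean, private_mean = sharing_size_stats(pooled, spec)
        pd.DataFrame(
            [{"shared_mean_bp": shared_mean, "private_mean_bp": private_mean}]
        ).to_csv(self.out / "sharing_sizes.tsv", sep="\t", index=False)
        self._record("share", ["table5.tsv", "table4.tsv", "sharing_sizes.tsv"],
                     t0, len(cons_pop))

    def stage_compare_external(self) -> None:
        """Overlap of an externally published CNV-region list (BED/TSV) with
        this run's merged regions, per chromosome."""
        t0 = time.time()
        ccfg = self.config.get("compare_external", {})
        path = ccfg.get("path")
        if not path:
            raise ValueError("compare_external.path must point to a BED/TSV region list")
        dialect = ccfg.get("dialect", "bed")
        external = read_calls(path, dialect=dialect)
        callsets = self._load_qc_callsets()
        pooled = [c for calls in callsets.values() for c in calls]
        regions = merge_to_regions(pooled)
        table = compare_external(regions, external)
        table.to_csv(self.out / "table3.tsv", sep="\t", index=False)
        self._record("compare_external", ["table3.tsv"], t0, len(external))

    def stage_assoc(self) -> None:
        t0 = time.time()
        self._require("consensus_population.tsv", "consensus")
        callsets = self._load_qc_callsets()
        samples = read_samples(self._require("samples_qc.tsv", "qc"))
        spec = self._spec()
        cons = consensus(callsets, samples, level="population", spec=spec)
        regions = [c.region for c in cons]
        pooled = [c for calls in callsets.values() for c in calls]
        gm = build_genotypes(regions, pooled, samples)
        acfg = self.config.get("assoc", {})
        model = CnvAssociationModel(
            gm, samples,
            coding=acfg.get("coding", "dosage"),
            min_carriers=int(acfg.get("min_carriers", 5)),
        )
        res = model.fit(n_perm=int(acfg.get("n_perm", 1000)), seed=self.seed)
        res.to_frame().to_csv(self.out / "table7.tsv", sep="\t", index=False)
        (self.out / "assoc_summary.txt").write_text(res.summary() + "\n")
        self._record("assoc", ["table7.tsv", "assoc_summary.txt"], t0, len(res.tested_idx))

    def stage_qpcr(self) -> None:
        t0 = time.time()
        wells = read_qpcr_wells(self._require("qpcr_wells.tsv", "simulate"))
        calibrator = self._require("qpcr_calibrator.txt", "simulate").read_text().strip()
        results = relative_quantity(wells, calibrator)
        results_to_frame(results).to_csv(self.out / "qpcr_results.tsv",
                                         sep="\t", index=False)

        # concordance of each caller's copy number at the validated region
        truth = pd.read_csv(self._require("truth_loci.tsv", "simulate"), sep="\t",
                            dtype={"chrom": str})
        causal = truth[truth["causal"]].iloc[0]
        region = CnvRegion(chrom=str(causal["chrom"]), start=int(causal["start"]),
                           end=int(causal["end"]))
        callsets = self._load_qc_callsets()
        samples = read_samples(self._require("samples_qc.tsv", "qc"))
        qpcr_cns = {(r.sample_id, "causal"): r.called_cn for r in results}
        caller_cns = {}
        for caller, calls in callsets.items():
            gm = build_genotypes([region], calls, samples)
            caller_cns[caller] = {
                (sid, "causal"): int(gm.cn.at[0, sid])
                for sid, _ in qpcr_cns
                if sid in gm.cn.columns
            }
        table = concordance(qpcr_cns, caller_cns)
        table.to_csv(self.out / "qpcr_concordance.tsv", sep="\t", index=False)
        self._record("qpcr", ["qpcr_results.tsv", "qpcr_concordance.tsv"],
                     t0, len(results))

    def stage_report(self) -> None:
        t0 = time.time()
        produced = [f for f in ("table1.tsv", "table4.tsv", "table5.tsv", "table7.tsv",
                                "qpcr_concordance.tsv")
                    if (self.out / f).exists()]
        lines = [f"equicnv {__version__} report", f"seed: {self.seed}", ""]
        for f in produced:
            lines.append(f"== {f} ==")
            lines.append(pd.read_csv(self.out / f, sep="\t").to_string(index=False))
            lines.append("")
        (self.out / "report.txt").write_text("\n".join(lines))
        self._record("report", ["report.txt"], t0, len(produced))

    # -- driver ----------------------------------------------------------

    def run(self, stages: Sequence[str]) -> dict:
        for s in stages:
            if s not in STAGES + EXTRA_STAGES:
                raise ValueError(f"unknown stage: {s!r}")
        for s in stages:
            getattr(self, f"stage_{s}")()
        self.manifest_path = self.out / "manifest.yaml"
        self.manifest_path.write_text(yaml.safe_dump(self.manifest, sort_keys=False))
        return self.manifest


def consensus_to_frame(cons: Sequence[ConsensusCnv]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "size": c.region.size,
                "level": c.level,
                "unit": c.unit,
                "state": c.state,
                "n_carriers": len(c.carriers),
                "breeds": ",".join(sorted(c.breeds)),
            }
            for c in cons
        ],
        columns=["locus_id", "chrom", "start", "end", "size", "level", "unit",
                 "state", "n_carriers", "breeds"],
    )


def run(config_path: str | Path | None, stages: Sequence[str], out_dir: str | Path,
        seed: int = 0) -> dict:
    """Load config, execute the requested stages, write the manifest."""
    cfg = load_config(config_path)
    runner = PipelineRun(out_dir, cfg, seed=seed)
    return runner.run(list(stages))
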