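"""Relative quantification of CNVs by the 2^-ddCt method and concordance
with array-based calls.

For each sample, replicate Ct values are averaged per assay, dCt is the
target-minus-reference Ct difference, ddCt compares the sample's dCt to a
diploid calibrator sample, and the relative quantity is rq = 2^-ddCt.
Against a two-copy calibrator the theoretical rq levels are 0, 0.5, 1 and
1.5 for 0-3 copies; classification snaps rq to the nearest level with bin
edges at the midpoints 0.25 / 0.75 / 1.25 (amplification efficiency is
assumed to be exactly 2).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import QpcrWell


@dataclass(frozen=True)
class QpcrResult:
    sample_id: str
    assay: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    called_cn: int
    out_of_range: bool = False


def relative_quantity(
    wells: Sequence[QpcrWell],
    calibrator_sample: str,
    reference_assay: str = "GAPDH",
) -> list[QpcrResult]:
    """2^-ddCt relative quantities for every (sample, target assay) pair.

    Replicates are averaged first; the calibrator sample must carry both the
    target and the reference assay.  Samples lacking reference-gene wells
    are skipped with a warning.
    """
    ct: dict[tuple[str, str], list[float]] = defaultdict(list)
    for w in wells:
        ct[(w.sample_id, w.assay)].append(w.ct)
    mean_ct = {k: float(np.mean(v)) for k, v in ct.items()}

    samples = sorted({s for s, _ in mean_ct})
    assays = sorted({a for _, a in mean_ct if a != reference_assay})
    if (calibrator_sample, reference_assay) not in mean_ct:
        raise ValueError(f"calibrator sample {calibrator_sample!r} missing reference wells")

    results: list[QpcrResult] = []
    for assay in assays:
        if (calibrator_sample, assay) not in mean_ct:
            raise ValueError(
                f"calibrator sample {calibrator_sample!r} missing assay {assay!r}"
            )
        cal_dct = mean_ct[(calibrator_sample, assay)] - mean_ct[(calibrator_sample, reference_assay)]
        for sample in samples:
            if (sample, assay) not in mean_ct:
                continue
            if (sample, reference_assay) not in mean_ct:
                warnings.warn(f"sample {sample!r} has no reference-gene wells; skipped")
                continue
            dct = mean_ct[(sample, assay)] - mean_ct[(sample, reference_assay)]
            ddct = dct - cal_dct
            rq = 2.0 ** (-ddct)
            cn, oor = classify_copy_number(rq)
            results.append(
                QpcrResult(
                    sample_id=sample,
                    assay=assay,
                    delta_ct=dct,
                    delta_delta_ct=ddct,
                    rq=rq,
                    called_cn=cn,
                    out_of_range=oor,
                )
            )
    return results


def classify_copy_number(rq: float, calibrator_cn: int = 2) -> tuple[int, bool]:
    """Copy number class for a relative quantity against a diploid calibrator.

    Expected rq for k copies is k / calibrator_cn; bins split at 0.25, 0.75
    and 1.25.  rq beyond the 3-copy level (>= 1.75) is reported as 3 with an
    out-of-range flag.
    """
    if rq <= 0:
        raise ValueError("rq must be positive")
    if calibrator_cn != 2:
        edges = [(k + 0.5) / calibrator_cn for k in range(3)]
    else:
        edges = [0.25, 0.75, 1.25]
    for cn, edge in enumerate(edges):
        if rq < edge:
            return cn, False
    return 3, rq >= (3.5 / calibrator_cn)


def results_to_frame(results: Sequence[QpcrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "assay": r.assay,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "rq": r.rq,
                "called_cn": r.called_cn,
                "out_of_range": r.out_of_range,
            }
            for r in results
        ]
    )


def concordance(
    qpcr_cns: Mapping[tuple[str, str], int],
    caller_cns: Mapping[str, Mapping[tuple[str, str], int]],
) -> pd.DataFrame:
    """Per-caller accuracy and false-negative rate against qPCR truth.

    ``qpcr_cns`` maps (sample, region) -> validated copy number;
    ``caller_cns`` maps caller -> {(sample, region) -> array copy number}
    with diploid 2 where the caller made no call.  Accuracy is the fraction
    of validated (sample, region) pairs whose caller copy number matches
    qPCR; the false-negative rate is the fraction of non-diploid qPCR pairs
    the caller left at 2.  An ``any_caller`` row gives the fraction matched
    by at least one algorithm.
    """
    if not qpcr_cns:
        raise ValueError("empty validation set")
    keys = sorted(qpcr_cns)
    non_diploid = [k for k in keys if qpcr_cns[k] != 2]

    rows = []
    matched_any = dict.fromkeys(keys, False)
    for caller, cns in caller_cns.items():
        match = [cns.get(k, 2) == qpcr_cns[k] for k in keys]
        for k, m in zip(keys, match):
            matched_any[k] = matched_any[k] or m
        fn = [cns.get(k, 2) == 2 for k in non_diploid]
        rows.append(
            {
                "caller": caller,
                "n": len(keys),
                "accuracy": float(np.mean(match)),
                "false_negative_rate": float(np.mean(fn)) if fn else float("nan"),
            }
        )
    rows.append(
        {
            "caller": "any_caller",
            "n": len(keys),
            "accuracy": float(np.mean([matched_any[k] for k in keys])),
            "false_negative_rate": float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["caller", "n", "accuracy", "false_negative_rate"])
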