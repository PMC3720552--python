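"""Sample-level and call-level quality filters.

Samples are kept when their array call rate exceeds 90%, the per-sample
standard deviation of the Log R Ratio is at most 0.3 and the absolute GC
wave factor is at most 0.02.  Calls are kept when they span at least three
probes, and additionally when the caller-specific confidence clears its
threshold: Log Bayes Factor >= 10 for QuantiSNP, confidence >= 35 for
CNVPartition.  Comparisons are boundary-inclusive for keeping except the
call-rate rule, which is strict (>).

Filtering is idempotent, and relaxing any threshold can only grow the kept
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import CnvCall, SampleRecord


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds for samples and calls.

    ``min_lbf`` applies only to quantisnp calls, ``min_confidence`` only to
    cnvpartition calls; penncnv calls are filtered on probe count alone.
    """

    min_call_rate: float = 0.90
    max_sd_lrr: float = 0.30
    max_abs_gcwf: float = 0.02
    min_probes: int = 3
    min_lbf: float = 10.0
    min_confidence: float = 35.0

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class ExclusionLog:
    """First failing rule per removed sample, plus skipped-rule notes."""

    rows: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["sample_id", "rule", "value", "threshold"])


def filter_samples(
    samples: Sequence[SampleRecord],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[SampleRecord], ExclusionLog]:
    """Keep samples passing all sample-level rules.

    A sample is kept iff ``call_rate > min_call_rate`` and
    ``sd_lrr <= max_sd_lrr`` and ``|gcwf| <= max_abs_gcwf``.  Missing
    sd_lrr/gcwf values skip the corresponding rule for that sample (logged).
    The log records the first failing rule per removed sample, in the order
    call_rate, sd_lrr, gcwf.
    """
    if not samples:
        raise ValueError("empty sample list")
    log = ExclusionLog()
    kept: list[SampleRecord] = []
    for s in samples:
        if s.call_rate <= thresholds.min_call_rate:
            log.rows.append(
                {"sample_id": s.sample_id, "rule": "call_rate", "value": s.call_rate,
                 "threshold": thresholds.min_call_rate}
            )
            continue
        if s.sd_lrr is None:
            log.skipped.append({"sample_id": s.sample_id, "rule": "sd_lrr"})
        elif s.sd_lrr > thresholds.max_sd_lrr:
            log.rows.append(
                {"sample_id": s.sample_id, "rule": "sd_lrr", "value": s.sd_lrr,
                 "threshold": thresholds.max_sd_lrr}
            )
            continue
        if s.gcwf is None:
            log.skipped.append({"sample_id": s.sample_id, "rule": "gcwf"})
        elif abs(s.gcwf) > thresholds.max_abs_gcwf:
            log.rows.append(
                {"sample_id": s.sample_id, "rule": "gcwf", "value": s.gcwf,
                 "threshold": thresholds.max_abs_gcwf}
            )
            continue
        kept.append(s)
    return kept, log


def filter_calls(
    calls: Iterable[CnvCall],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[CnvCall], dict[str, int]]:
    """Keep calls passing probe-count and caller-specific score rules.

    Returns the kept calls and per-rule removal counts; counts sum to the
    number removed (first failing rule wins, probe count checked first).
    """
    kept: list[CnvCall] = []
    counts = {"n_probes": 0, "lbf": 0, "confidence": 0}
    for c in calls:
        if c.n_probes < thresholds.min_probes:
            counts["n_probes"] += 1
            continue
        if c.caller == "quantisnp" and c.score is not None and c.score < thresholds.min_lbf:
            counts["lbf"] += 1
            continue
        if c.caller == "cnvpartition" and c.score is not None and c.score < thresholds.min_confidence:
            counts["confidence"] += 1
            continue
        kept.append(c)
    return kept, counts
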