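"""Tabular input/output for CNV call sets, SNP maps, sample metadata and qPCR wells.

All genomic coordinates are held internally as 1-based inclusive intervals,
the convention of Illumina array reports and of PennCNV/QuantiSNP output;
``size = end - start + 1``.  BED files (0-based half-open) are converted on
read and write.

Caller "dialects" are column-mapping presets over a single generic TSV
reader: the three supported callers emit tab-separated tables whose columns
differ only in naming, not in semantics.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CALLERS = ("cnvpartition", "penncnv", "quantisnp")

#: autosome labels of the horse genome (ECA1..ECA31)
AUTOSOMES = tuple(str(i) for i in range(1, 32))


class FormatError(ValueError):
    """Raised when an input table violates the documented layout or invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMarker:
    """One array marker: a named, 1-based position on an autosome."""

    name: str
    chrom: str
    pos: int


@dataclass
class SnpMap:
    """Ordered marker positions per chromosome.

    ``markers`` is sorted by ``(chrom, pos, name)``; ``chrom_lengths`` maps a
    chromosome label to its length in bp (defaulting to the last marker
    position when no sidecar is given).
    """

    markers: list[SnpMarker]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.markers = sorted(
            self.markers, key=lambda m: (_chrom_key(m.chrom), m.pos, m.name)
        )
        names = [m.name for m in self.markers]
        if len(names) != len(set(names)):
            raise FormatError("duplicate marker names in SNP map")
        for m in self.markers:
            if m.pos < 1:
                raise FormatError(f"non-positive marker position: {m.name} at {m.pos}")
            if m.pos > self.chrom_lengths.get(m.chrom, m.pos):
                raise FormatError(
                    f"marker {m.name} at {m.chrom}:{m.pos} beyond chromosome length"
                )

    def __len__(self) -> int:
        return len(self.markers)

    def positions(self, chrom: str):
        """Sorted numpy array of marker positions on ``chrom``."""
        import numpy as np

        return np.array([m.pos for m in self.markers if m.chrom == chrom], dtype=int)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of markers inside the 1-based inclusive interval."""
        import numpy as np

        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start, side="left"))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths, key=_chrom_key)

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class CnvCall:
    """A single caller's CNV event in one sample (1-based inclusive interval)."""

    sample_id: str
    caller: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_probes: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"start > end for {self.sample_id} at {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number == 2:
            raise FormatError("a CNV record must be non-diploid (copy_number != 2)")
        if self.copy_number < 0:
            raise FormatError("negative copy number")
        if self.n_probes < 1:
            raise FormatError("n_probes must be >= 1")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> str:
        return "loss" if self.copy_number < 2 else "gain"


@dataclass(frozen=True)
class SampleRecord:
    """Per-animal metadata: breed, withers height and array QC metrics."""

    sample_id: str
    breed: str
    height_cm: float | None
    call_rate: float
    sd_lrr: float | None = None
    gcwf: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.call_rate <= 1.0):
            raise FormatError(f"call_rate out of [0,1] for {self.sample_id}")
        if self.sd_lrr is not None and self.sd_lrr < 0:
            raise FormatError(f"negative sd_lrr for {self.sample_id}")


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR well: a Ct value for a (sample, assay, replicate) triple."""

    sample_id: str
    assay: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise FormatError("Ct must be positive")


def _chrom_key(chrom: str):
    """Sort key putting numeric chromosome labels in natural order."""
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


# ---------------------------------------------------------------------------
# call-set reading
# ---------------------------------------------------------------------------

# column-name presets per dialect; values are the generic column names
_DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    "tsv": {},
    "penncnv": {
        "numsnp": "n_probes",
        "cn": "copy_number",
        "sample": "sample_id",
        "conf": "score",
    },
    "quantisnp": {
        "max_log_bf": "score",
        "log_bayes_factor": "score",
        "no_probes": "n_probes",
        "copy_no": "copy_number",
    },
    "cnvpartition": {
        "confidence": "score",
        "value": "copy_number",
        "num_snps": "n_probes",
        "sampleid": "sample_id",
    },
}

_CANONICAL = ["sample_id", "caller", "chrom", "start", "end", "copy_number", "n_probes", "score"]


@dataclass
class ReadReport:
    """Counts of rows dropped while reading a call table."""

    n_read: int = 0
    n_kept: int = 0
    n_diploid_rejected: int = 0
    n_nonautosomal_dropped: int = 0


def read_calls(
    path: str | Path,
    dialect: str = "tsv",
    caller: str | None = None,
    report: ReadReport | None = None,
) -> list[CnvCall]:
    """Read a CNV call table in one of the supported dialects.

    Parameters
    ----------
    path
        TSV file (or BED when ``dialect='bed'``).
    dialect
        One of ``penncnv``, ``quantisnp``, ``cnvpartition``, ``tsv``, ``bed``.
        The caller dialects are column-name presets over the generic TSV
        layout ``sample_id  caller  chrom  start  end  copy_number  n_probes
        [score]``.  BED input is 0-based half-open and converted to 1-based
        inclusive on read.
    caller
        Overrides / supplies the caller field when the table has no column.
    report
        Optional mutable counter object; diploid (cn=2) rows are rejected
        with a warning counter rather than an error so that merged exports
        can be ingested.
    """
    dialect = dialect.lower()
    if dialect == "bed":
        return _read_bed(path, caller=caller, report=report)
    if dialect not in _DIALECT_COLUMNS:
        raise FormatError(f"unknown dialect: {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_DIALECT_COLUMNS[dialect])
    if "chr" in df.columns and "chrom" not in df.columns:
        df = df.rename(columns={"chr": "chrom"})
    return _calls_from_frame(df, dialect=dialect, caller=caller, report=report)


def _calls_from_frame(
    df: pd.DataFrame,
    dialect: str,
    caller: str | None,
    report: ReadReport | None,
) -> list[CnvCall]:
    required = {"chrom", "start", "end", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    if report is None:
        report = ReadReport()
    default_caller = caller or (dialect if dialect in CALLERS else None)

    calls: list[CnvCall] = []
    for row in df.itertuples(index=False):
        report.n_read += 1
        d = row._asdict()
        cn = int(d["copy_number"])
        if cn == 2:
            report.n_diploid_rejected += 1
            continue
        chrom = str(d["chrom"])
        if chrom not in AUTOSOMES:
            report.n_nonautosomal_dropped += 1
            continue
        row_caller = str(d.get("caller") or default_caller or "unknown")
        score = d.get("score")
        score = None if score is None or pd.isna(score) else float(score)
        calls.append(
            CnvCall(
                sample_id=str(d.get("sample_id", "NA")),
                caller=row_caller,
                chrom=chrom,
                start=int(d["start"]),
                end=int(d["end"]),
                copy_number=cn,
                n_probes=int(d.get("n_probes", 1)),
                score=score,
            )
        )
    report.n_kept = len(calls)
    return calls


def _read_bed(path, caller, report):
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if df.shape[1] < 3:
        raise FormatError("BED needs at least chrom/start/end")
    cols = ["chrom", "bed_start", "bed_end", "name", "copy_number", "sample_id"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["bed_start"].astype(int) + 1,
            "end": df["bed_end"].astype(int),
            "copy_number": df["copy_number"].astype(int) if "copy_number" in df else 1,
            "sample_id": df["sample_id"].astype(str) if "sample_id" in df else "NA",
            "n_probes": 1,
        }
    )
    return _calls_from_frame(out, dialect="bed", caller=caller, report=report)


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    """Canonical generic-TSV frame for a list of calls."""
    rows = [
        {
            "sample_id": c.sample_id,
            "caller": c.caller,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "copy_number": c.copy_number,
            "n_probes": c.n_probes,
            "score": c.score,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_CANONICAL)


def write_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP map / samples / qPCR wells
# ---------------------------------------------------------------------------


def read_snp_map(path: str | Path, lengths_path: str | Path | None = None) -> SnpMap:
    """Read a marker map TSV with columns ``name, chrom, pos``.

    Chromosome lengths come from an optional two-column sidecar
    (``chrom, length``); without one the length of each chromosome defaults
    to the largest marker position observed on it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("name", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"SNP map missing column {col!r}")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise FormatError(f"duplicate marker name: {dup!r}")
    if (df["pos"] < 1).any():
        raise FormatError("non-positive marker position")

    markers = [
        SnpMarker(name=str(r.name), chrom=str(r.chrom), pos=int(r.pos))
        for r in df.itertuples(index=False)
    ]
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", dtype={"chrom": str})
        ldf.columns = [c.strip().lower() for c in ldf.columns]
        lengths = dict(zip(ldf["chrom"].astype(str), ldf["length"].astype(int)))
    else:
        lengths = df.groupby("chrom")["pos"].max().astype(int).to_dict()
        lengths = {str(k): int(v) for k, v in lengths.items()}
    return SnpMap(markers=markers, chrom_lengths=lengths)


def write_snp_map(snp_map: SnpMap, path: str | Path, lengths_path: str | Path | None = None) -> None:
    pd.DataFrame(
        [{"name": m.name, "chrom": m.chrom, "pos": m.pos} for m in snp_map.markers]
    ).to_csv(path, sep="\t", index=False)
    if lengths_path is not None:
        pd.DataFrame(
            [{"chrom": c, "length": l} for c, l in sorted(snp_map.chrom_lengths.items(), key=lambda kv: _chrom_key(kv[0]))]
        ).to_csv(lengths_path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV: ``sample_id, breed, height_cm, call_rate, sd_lrr, gcwf``."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "breed", "call_rate"):
        if col not in df.columns:
            raise FormatError(f"sample table missing column {col!r}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = getattr(row, col)
        return None if pd.isna(v) else float(v)

    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            breed=str(r.breed),
            height_cm=_opt(r, "height_cm"),
            call_rate=float(r.call_rate),
            sd_lrr=_opt(r, "sd_lrr"),
            gcwf=_opt(r, "gcwf"),
        )
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: Iterable[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "breed": s.breed,
                "height_cm": s.height_cm,
                "call_rate": s.call_rate,
                "sd_lrr": s.sd_lrr,
                "gcwf": s.gcwf,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_qpcr_wells(path: str | Path) -> list[QpcrWell]:
    """Read a qPCR well table TSV: ``sample_id, assay, replicate, ct``."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "assay", "ct"):
        if col not in df.columns:
            raise FormatError(f"qPCR table missing column {col!r}")
    return [
        QpcrWell(
            sample_id=str(r.sample_id),
            assay=str(r.assay),
            ct=float(r.ct),
            replicate=int(getattr(r, "replicate", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def write_qpcr_wells(wells: Iterable[QpcrWell], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": w.sample_id, "assay": w.assay, "replicate": w.replicate, "ct": w.ct}
            for w in wells
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region export
# ---------------------------------------------------------------------------


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write CNV regions as BED (0-based half-open).

    The name column encodes ``state|n_carriers``; an empty region list yields
    an empty file.  The conversion is ``bed_start = start - 1``,
    ``bed_end = end`` for every 1-based inclusive interval.
    """
    lines = []
    for r in regions:
        state = getattr(r, "state", None) or "region"
        n_car = len(getattr(r, "carriers", []) or [])
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{state}|{n_car}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
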