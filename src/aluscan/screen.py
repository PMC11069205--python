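"""Short-read cohort screening by junction k-mer counting.

Streams FASTQ(.gz) or SAM-dialect records, counts reads containing any
mutant-junction probe and any wild-type-site probe (exact substring matching
after uppercasing -- the same semantics as ``grep -c`` over FASTQ sequence
lines), computes the variant allele frequency as mutant reads over
(mutant + wild-type) reads, and calls a genotype per sample.
"""

from __future__ import annotations

import glob as _glob
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .probes import ProbeSet

__all__ = [
    "ScanCounts",
    "Thresholds",
    "ScreenResult",
    "CohortReport",
    "iter_fastq_sequences",
    "iter_sam_sequences",
    "scan_stream",
    "scan_file",
    "call_genotype",
    "screen_cohort",
]


@dataclass(frozen=True)
class ScanCounts:
    mut_reads: int
    wt_reads: int
    total: int
    conflicts: int = 0


@dataclass(frozen=True)
class Thresholds:
    """Genotype-calling thresholds.

    The original screen observed zero carriers and reported no cutoffs;
    these are conventional diagnostic defaults and fully configurable.
    """

    min_total: int = 10
    min_mut_reads: int = 3
    het_vaf_min: float = 0.2
    hom_vaf_min: float = 0.8


@dataclass
class ScreenResult:
    sample_id: str
    mut_reads: int
    wt_reads: int
    vaf: Optional[float]
    genotype: str
    total_reads_scanned: int
    note: str = ""


@dataclass
class CohortReport:
    rows: list[ScreenResult]

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def n_carriers(self) -> int:
        return sum(r.genotype in ("ref/mut", "mut/mut") for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "mut_reads": r.mut_reads,
                    "wt_reads": r.wt_reads,
                    "vaf": "" if r.vaf is None else round(r.vaf, 4),
                    "genotype": r.genotype,
                    "total_reads_scanned": r.total_reads_scanned,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a 4-line FASTQ, transparently gunzipping."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record in {path}")
            yield seq.strip()


def iter_sam_sequences(path: str | Path) -> Iterator[str]:
    """Yield SEQ fields from a SAM-dialect text file (header lines skipped)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"malformed SAM line in {path}")
            yield fields[9]


def scan_stream(records: Iterable[str], probeset: ProbeSet) -> ScanCounts:
    """Count reads matching the MUT and WT probe classes.

    A read increments ``mut_reads`` if its sequence contains any validated
    MUT probe and ``wt_reads`` if it contains any validated WT probe; a read
    matching both classes increments ``conflicts`` and neither count.  Each
    read counts at most once per class.  Probes already encode both strands,
    so reads are not reverse-complemented.
    """
    mut_probes = [p.sequence for p in probeset.by_class("MUT", validated_only=True)]
    wt_probes = [p.sequence for p in probeset.by_class("WT", validated_only=True)]
    if not mut_probes or not wt_probes:
        raise ValueError("probe set must contain validated probes of both classes")
    mut = wt = total = conflicts = 0
    for seq in records:
        total += 1
        s = seq.upper()
        is_mut = any(p in s for p in mut_probes)
        is_wt = any(p in s for p in wt_probes)
        if is_mut and is_wt:
            conflicts += 1
        elif is_mut:
            mut += 1
        elif is_wt:
            wt += 1
    return ScanCounts(mut, wt, total, conflicts)


def scan_file(path: str | Path, probeset: ProbeSet, sam: bool = False) -> ScanCounts:
    records = iter_sam_sequences(path) if sam else iter_fastq_sequences(path)
    return scan_stream(records, probeset)


def call_genotype(
    mut_reads: int, wt_reads: int, thresholds: Thresholds = Thresholds()
) -> tuple[str, Optional[float]]:
    """Call a genotype from probe-class read counts.

    VAF = mut / (mut + wt); undefined (and genotype ``no_call``) when no
    informative reads were seen or fewer than ``min_total`` in total.
    """
    if mut_reads < 0 or wt_reads < 0:
        raise ValueError("read counts must be non-negative")
    denom = mut_reads + wt_reads
    vaf = mut_reads / denom if denom > 0 else None
    if denom < thresholds.min_total:
        return "no_call", vaf
    assert vaf is not None
    if vaf >= thresholds.hom_vaf_min:
        return "mut/mut", vaf
    if vaf >= thresholds.het_vaf_min and mut_reads >= thresholds.min_mut_reads:
        return "ref/mut", vaf
    return "ref/ref", vaf


def screen_cohort(
    sample_files: Sequence[str | Path] | str,
    probeset: ProbeSet,
    thresholds: Thresholds = Thresholds(),
    sam: bool = False,
) -> CohortReport:
    """Screen a cohort of per-sample read files.

    ``sample_files`` may be a glob pattern or an explicit list.  Per-sample
    I/O errors are reported in that sample's row (``no_call``) without
    aborting the cohort.  The sample id is the file name up to the first dot.
    """
    if isinstance(sample_files, str):
        files = sorted(_glob.glob(sample_files))
        if not files:
            raise FileNotFoundError(f"no files match {sample_files!r}")
    else:
        files = [str(f) for f in sample_files]
    if not files:
        raise ValueError("no sample files given")
    rows = []
    for f in files:
        sample_id = Path(f).name.split(".")[0]
        try:
            counts = scan_file(f, probeset, sam=sam)
        except (OSError, ValueError, EOFError) as exc:
            rows.append(
                ScreenResult(sample_id, 0, 0, None, "no_call", 0, note=str(exc))
            )
            continue
        genotype, vaf = call_genotype(counts.mut_reads, counts.wt_reads, thresholds)
        rows.append(
            ScreenResult(
                sample_id,
                counts.mut_reads,
                counts.wt_reads,
                vaf,
                genotype,
                counts.total,
            )
        )
    return CohortReport(rows=rows)
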