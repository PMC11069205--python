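"""Long-read SV calling: per-read signatures, clustering, consensus, repeat context.

Signatures are taken only from explicit I/D operations in the read's
alignment (no realignment or split-read rescue); same-kind signatures within
a window are merged by single-linkage on reference position, with the median
position/length as the call and the maximum deviation from the median as the
confidence interval.  Insert sequences are polished by majority vote against
the medoid (minimum summed edit distance) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .synthetic import AlignedRead

__all__ = [
    "SVSignature",
    "SVCall",
    "RepeatContext",
    "collect_signatures",
    "cluster_signatures",
    "consensus_insert",
    "annotate_repeat_context",
    "read_repeat_bed",
    "write_sv_calls_tsv",
    "write_sv_calls_vcf",
]


@dataclass(frozen=True)
class SVSignature:
    read_id: str
    kind: str  # INS or DEL
    ref_position: int  # 1-based; INS: last ref base before insert; DEL: first deleted base
    length: int
    inserted_sequence: Optional[str] = None


@dataclass
class SVCall:
    kind: str
    ref_start: int
    ref_end: int  # for INS, insert_after == ref_start == ref_end
    length: int
    support: int
    consensus_insert: Optional[str] = None
    confidence_interval: int = 0

    @property
    def insert_after(self) -> int:
        return self.ref_start


@dataclass
class RepeatContext:
    containing_repeat: Optional[tuple[str, str]] = None  # (family, class)
    nearest_upstream: Optional[tuple[str, int]] = None  # (family, distance bp)
    nearest_downstream: Optional[tuple[str, int]] = None


def collect_signatures(
    reads: Iterable[AlignedRead], min_sv_len: int = 30
) -> list[SVSignature]:
    """Extract one SV signature per I/D op of length >= ``min_sv_len``.

    The reference position is computed by walking M/D ops from
    ``mapped_start``; soft-clip-only evidence contributes nothing here.
    """
    sigs: list[SVSignature] = []
    for read in reads:
        pos = read.mapped_start
        qpos = 0
        for kind, length in read.ops:
            if kind == "M":
                pos += length
                qpos += length
            elif kind == "S":
                qpos += length
            elif kind == "I":
                if length >= min_sv_len:
                    ins_seq = read.inserted_sequences.get(
                        qpos, read.sequence[qpos:qpos + length]
                    )
                    sigs.append(
                        SVSignature(read.read_id, "INS", pos - 1, length, ins_seq)
                    )
                qpos += length
            elif kind == "D":
                if length >= min_sv_len:
                    sigs.append(SVSignature(read.read_id, "DEL", pos, length))
                pos += length
            else:
                raise ValueError(f"unknown op kind {kind!r}")
    return sigs


def cluster_signatures(
    signatures: Sequence[SVSignature], window: int = 50, min_support: int = 3
) -> list[SVCall]:
    """Merge same-kind signatures within ``window`` bp (single linkage) into calls.

    Breakpoint and length are the (integer) medians over the cluster;
    the confidence interval is the maximum |position - median|.  Clusters
    with fewer than ``min_support`` signatures are dropped.  Deterministic
    and invariant to input order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    calls: list[SVCall] = []
    for kind in ("INS", "DEL"):
        group = sorted(
            (s for s in signatures if s.kind == kind),
            key=lambda s: (s.ref_position, s.length, s.read_id),
        )
        i = 0
        while i < len(group):
            j = i + 1
            while j < len(group) and group[j].ref_position - group[j - 1].ref_position <= window:
                j += 1
            cluster = group[i:j]
            i = j
            if len(cluster) < min_support:
                continue
            positions = np.array([s.ref_position for s in cluster])
            lengths = np.array([s.length for s in cluster])
            pos = int(np.floor(np.median(positions)))
            length = int(np.floor(np.median(lengths)))
            ci = int(np.max(np.abs(positions - pos)))
            cons = None
            if kind == "INS":
                seqs = [s.inserted_sequence for s in cluster if s.inserted_sequence]
                if seqs:
                    cons = consensus_insert(seqs)
            calls.append(
                SVCall(
                    kind=kind,
                    ref_start=pos,
                    ref_end=pos if kind == "INS" else pos + length - 1,
                    length=length,
                    support=len(cluster),
                    consensus_insert=cons,
                    confidence_interval=ci,
                )
            )
    calls.sort(key=lambda c: (c.ref_start, c.kind))
    return calls


def consensus_insert(sequences: Sequence[str]) -> str:
    """Majority-polished consensus of inserted sequences.

    The medoid (minimum summed edit distance, ties to input order) is taken
    as the backbone; every sequence is aligned to it and each backbone column
    is voted per-base (gap votes delete the column; ties keep the medoid
    base).  Insertions relative to the medoid are not polished in.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return seqs[0]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j])["editDistance"]
            dist[i, j] = dist[j, i] = d
    medoid_idx = int(np.argmin(dist.sum(axis=1)))
    medoid = seqs[medoid_idx]

    votes: list[dict[str, int]] = [dict() for _ in medoid]
    ins_votes: list[dict[str, int]] = [dict() for _ in range(len(medoid) + 1)]
    for s in seqs:
        res = edlib.align(s, medoid, task="path", mode="NW")
        nice = edlib.getNiceAlignment(res, s, medoid)
        tpos = 0
        pending = ""
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":
                pending += qc  # insertion relative to the medoid
                continue
            if pending:
                ins_votes[tpos][pending] = ins_votes[tpos].get(pending, 0) + 1
                pending = ""
            votes[tpos][qc] = votes[tpos].get(qc, 0) + 1
            tpos += 1
        if pending:
            ins_votes[len(medoid)][pending] = ins_votes[len(medoid)].get(pending, 0) + 1

    out = []
    for i in range(len(medoid) + 1):
        # insertions before column i win on a strict majority of sequences
        if ins_votes[i]:
            string, count = max(ins_votes[i].items(), key=lambda kv: (kv[1], kv[0]))
            if count > n / 2:
                out.append(string)
        if i == len(medoid):
            break
        col, ref_base = votes[i], medoid[i]
        gaps = col.get("-", 0)
        bases = {b: c for b, c in col.items() if b != "-"}
        # a column is deleted only on a strict majority of gap votes;
        # otherwise the plurality base wins, ties keeping the medoid base
        if gaps > sum(bases.values()):
            continue
        best = max(bases.items(), key=lambda kv: (kv[1], kv[0] == ref_base))
        out.append(best[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# repeat context
# ---------------------------------------------------------------------------

def read_repeat_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a repeat-annotation BED (chrom, start, end, name 'family:class')."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            intervals.append((fields[0], start, end, fields[3]))
    return intervals


def _split_name(name: str) -> tuple[str, str]:
    family, _, klass = name.partition(":")
    return family, klass


def annotate_repeat_context(
    position: int,
    repeat_bed: str | Path | Sequence[tuple[str, int, int, str]],
    chrom: str | None = None,
) -> RepeatContext:
    """Locate a 1-based position relative to repeat annotations.

    Reports the repeat containing the position (distance 0) and the nearest
    repeats on each side with their gap in bp (a repeat whose last base is
    200 bp before the position has distance 200).  BED intervals are 0-based
    half-open on disk and converted here.
    """
    if isinstance(repeat_bed, (str, Path)):
        intervals = read_repeat_bed(repeat_bed)
    else:
        intervals = list(repeat_bed)
    if chrom is not None:
        intervals = [iv for iv in intervals if iv[0] == chrom]
    ctx = RepeatContext()
    best_up: tuple[int, str] | None = None
    best_down: tuple[int, str] | None = None
    for _chrom, start0, end0, name in sorted(intervals, key=lambda x: x[1]):
        first, last = start0 + 1, end0  # 1-based inclusive
        if first <= position <= last:
            ctx.containing_repeat = _split_name(name)
        elif last < position:
            d = position - last
            if best_up is None or d < best_up[0]:
                best_up = (d, name)
        else:
            d = first - position
            if best_down is None or d < best_down[0]:
                best_down = (d, name)
    if best_up:
        ctx.nearest_upstream = (_split_name(best_up[1])[0], best_up[0])
    if best_down:
        ctx.nearest_downstream = (_split_name(best_down[1])[0], best_down[0])
    return ctx


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sv_calls_tsv(calls: Sequence[SVCall], path: str | Path) -> Path:
    import pandas as pd

    rows = [
        {
            "kind": c.kind,
            "ref_start": c.ref_start,
            "ref_end": c.ref_end,
            "length": c.length,
            "support": c.support,
            "ci": c.confidence_interval,
            "consensus_insert": c.consensus_insert or "",
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_sv_calls_vcf(
    calls: Sequence[SVCall], path: str | Path, ref_name: str = "chr6"
) -> Path:
    """Minimal VCF with SVTYPE/SVLEN/END/CIPOS in INFO."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Breakpoint CI">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            if c.kind == "DEL":
                pos, alt, svlen, end = c.ref_start - 1, "<DEL>", -c.length, c.ref_end
            else:
                pos, alt, svlen, end = c.ref_start, "<INS>", c.length, c.ref_end
            info = (
                f"SVTYPE={c.kind};SVLEN={svlen};END={end};"
                f"CIPOS=-{c.confidence_interval},{c.confidence_interval}"
            )
            fh.write(f"{ref_name}\t{pos}\tsv{i}\tN\t{alt}\t.\tPASS\t{info}\n")
    return path
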