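"""Soft-clip evidence at an insertion locus.

Short-read aligners map the reference-matching part of a read that crosses an
insertion junction and soft-clip the inserted bases; clustered clips at one
position, whose clipped bases reproduce the insert's ends, are therefore
direct evidence for an insertion the variant caller missed.  This module
clusters clipped reads near a locus, builds a per-column majority consensus
of the clipped bases, compares it against the expected insert end, and
quantifies the clipped-read fraction and the local coverage drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .synthetic import AlignedRead

__all__ = [
    "ClipCluster",
    "ClipSummary",
    "collect_clips",
    "clip_summary",
    "percent_clipped",
    "mean_depth",
    "depth_track",
    "write_bedgraph",
]


@dataclass
class ClipCluster:
    ref_position: int
    side: str  # "left": clip precedes the aligned part; "right": clip follows it
    clipped_sequences: list[str] = field(default_factory=list)
    n_total_overlapping: int = 0

    @property
    def n_clipped(self) -> int:
        return len(self.clipped_sequences)


@dataclass
class ClipSummary:
    percent_clipped: int
    consensus_sequence: str
    matches_expected: bool
    coverage_drop: float


def _clips(read: AlignedRead) -> list[tuple[str, int, str]]:
    """(side, boundary ref position, clipped bases) for each S op of a read.

    Reads without any aligned (M) op have no anchored boundary and contribute
    no clips.
    """
    if not any(k == "M" for k, _ in read.ops):
        return []
    out = []
    qpos = 0
    pos = read.mapped_start
    for i, (kind, length) in enumerate(read.ops):
        if kind == "S":
            if i == 0:
                # left clip: boundary is the first aligned base
                out.append(("left", read.mapped_start, read.sequence[:length]))
            else:
                out.append(("right", pos - 1, read.sequence[qpos:qpos + length]))
            qpos += length
        elif kind == "M":
            pos += length
            qpos += length
        elif kind == "D":
            pos += length
        elif kind == "I":
            qpos += length
        else:
            raise ValueError(f"unknown op kind {kind!r}")
    return out


def collect_clips(
    reads: Iterable[AlignedRead],
    locus_position: int,
    window: int = 10,
    min_clip_len: int = 8,
) -> list[ClipCluster]:
    """Cluster soft-clipped reads whose clip boundary is near a locus.

    Reads with an S op whose boundary lies within ``window`` bp of
    ``locus_position`` are grouped by (boundary position, side); clips
    shorter than ``min_clip_len`` are ignored (they carry no information
    against a ~300 bp element).  Every cluster's ``n_total_overlapping``
    counts all reads whose aligned span covers the locus position or its
    successor.
    """
    if window < 0 or min_clip_len < 1:
        raise ValueError("window must be >= 0 and min_clip_len >= 1")
    reads = list(reads)
    n_total = 0
    for read in reads:
        lo, hi = read.ref_span
        if lo <= locus_position <= hi or lo <= locus_position + 1 <= hi:
            n_total += 1
    clusters: dict[tuple[int, str], ClipCluster] = {}
    for read in reads:
        for side, boundary, clipped in _clips(read):
            if len(clipped) < min_clip_len:
                continue
            if abs(boundary - locus_position) > window:
                continue
            key = (boundary, side)
            if key not in clusters:
                clusters[key] = ClipCluster(ref_position=boundary, side=side)
            clusters[key].clipped_sequences.append(clipped)
    out = sorted(clusters.values(), key=lambda c: (c.ref_position, c.side))
    for c in out:
        c.n_total_overlapping = n_total
    return out


def percent_clipped(n_clipped: int, n_total: int) -> int:
    """Clipped-read percentage, rounded to the nearest integer for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return int(round(100.0 * n_clipped / n_total))


def _majority_consensus(sequences: Sequence[str], side: str) -> str:
    """Per-column majority over clips anchored at the clip boundary.

    Right-side clips are anchored at their first base, left-side clips at
    their last base (both abut the junction).  Ties break alphabetically.
    """
    if side == "left":
        sequences = [s[::-1] for s in sequences]
    width = max(len(s) for s in sequences)
    cols = []
    for i in range(width):
        counts: dict[str, int] = {}
        for s in sequences:
            if i < len(s):
                counts[s[i]] = counts.get(s[i], 0) + 1
        cols.append(max(sorted(counts), key=lambda b: counts[b]))
    cons = "".join(cols)
    return cons[::-1] if side == "left" else cons


def clip_summary(
    cluster: ClipCluster,
    expected: Optional[str],
    coverage_in_window: float,
    coverage_flanking: float,
) -> ClipSummary:
    """Summarize one clip cluster.

    ``expected`` is the insert end the clipped bases should reproduce (the
    insert prefix for a right-side cluster, the suffix for a left-side one);
    ``matches_expected`` requires >= 90% identity over the shorter of the
    two.  ``coverage_drop`` is 1 - in_window/flanking, floored at 0.
    """
    if cluster.n_clipped == 0:
        raise ValueError("empty clip cluster")
    if coverage_in_window < 0 or coverage_flanking < 0:
        raise ValueError("coverage values must be >= 0")
    consensus = _majority_consensus(cluster.clipped_sequences, cluster.side)
    matches = False
    if expected:
        n = min(len(consensus), len(expected))
        if n > 0:
            if cluster.side == "right":
                a, b = consensus[:n], expected[:n]
            else:
                a, b = consensus[-n:], expected[-n:]
            ident = sum(x == y for x, y in zip(a, b)) / n
            matches = ident >= 0.9
    drop = 0.0
    if coverage_flanking > 0:
        drop = max(0.0, 1.0 - coverage_in_window / coverage_flanking)
    return ClipSummary(
        percent_clipped=percent_clipped(cluster.n_clipped, cluster.n_total_overlapping),
        consensus_sequence=consensus,
        matches_expected=matches,
        coverage_drop=drop,
    )


# ---------------------------------------------------------------------------
# depth helpers
# ---------------------------------------------------------------------------

def depth_track(reads: Iterable[AlignedRead], ref_start: int, ref_end: int) -> np.ndarray:
    """Per-base aligned (M-op) depth over a 1-based inclusive interval."""
    depth = np.zeros(ref_end - ref_start + 1, dtype=np.int64)
    for read in reads:
        pos = read.mapped_start
        for kind, length in read.ops:
            if kind == "M":
                lo = max(pos, ref_start)
                hi = min(pos + length - 1, ref_end)
                if lo <= hi:
                    depth[lo - ref_start: hi - ref_start + 1] += 1
                pos += length
            elif kind == "D":
                pos += length
    return depth


def mean_depth(
    reads: Sequence[AlignedRead],
    junction: int,
    in_half_width: int = 25,
    flank_offset: int = 200,
    flank_width: int = 100,
) -> tuple[float, float]:
    """Mean depth in a window around the junction and in two distant flanks.

    In-window: +/- ``in_half_width`` bp of the junction; flanking: two
    ``flank_width``-bp windows ``flank_offset`` bp away on each side.
    """
    d_in = depth_track(reads, junction - in_half_width, junction + in_half_width)
    left = depth_track(
        reads, junction - flank_offset - flank_width + 1, junction - flank_offset
    )
    right = depth_track(
        reads, junction + flank_offset, junction + flank_offset + flank_width - 1
    )
    return float(d_in.mean()), float(np.concatenate([left, right]).mean())


def write_bedgraph(
    reads: Iterable[AlignedRead],
    ref_name: str,
    ref_start: int,
    ref_end: int,
    path,
) -> None:
    """Optional per-base depth track as bedGraph (0-based half-open)."""
    depth = depth_track(reads, ref_start, ref_end)
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                fh.write(
                    f"{ref_name}\t{ref_start - 1 + run_start}\t{ref_start - 1 + i}\t{depth[run_start]}\n"
                )
                run_start = i
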