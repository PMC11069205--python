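"""SAM-dialect round-tripping for :class:`~aluscan.synthetic.AlignedRead`.

Reads are written as plain-text SAM (QNAME/FLAG/RNAME/POS/CIGAR/SEQ are the
load-bearing columns) and re-imported through pysam, so files interoperate
with samtools and genome browsers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pysam

from .synthetic import AlignedRead, Op

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE_TO_OP = {v: k for k, v in _OP_TO_CODE.items()}


def ops_to_cigar(ops: Sequence[Op]) -> str:
    return "".join(f"{n}{k}" for k, n in ops)


def cigartuples_to_ops(cigartuples) -> list[Op]:
    ops = []
    for code, length in cigartuples:
        kind = _CODE_TO_OP.get(code)
        if kind is None:
            raise ValueError(f"unsupported CIGAR op code {code}")
        ops.append((kind, length))
    return ops


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | Path,
    ref_name: str,
    ref_length: int,
) -> Path:
    """Write reads as SAM text (MAPQ 60, qualities 'I', unpaired)."""
    path = Path(path)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": ref_name, "LN": int(ref_length)}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.query_sequence = r.sequence
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.mapped_start - 1  # SAM POS is 1-based on disk
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_TO_CODE[k], n) for k, n in r.ops]
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            out.write(seg)
    return path


def read_sam(path: str | Path, sample_id: str = "sample") -> list[AlignedRead]:
    """Re-import a SAM-dialect file as AlignedRead records."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    sequence=seg.query_sequence or "",
                    mapped_start=seg.reference_start + 1,
                    ops=cigartuples_to_ops(seg.cigartuples),
                    sample_id=sample_id,
                )
            )
    return reads
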