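"""Mobile-element insertion decomposition.

An insertion call is partitioned into its retrotransposition anatomy --
target-site duplication (TSD), poly-A/T tail and element body -- in that
order, the body is classified against a consensus library by free-end-gap
alignment, and the result is reported as an HGVS-like description plus an
optional coding consequence.

Conventions
-----------
* TSD matching is exact; the longest shared string wins, with ties broken
  toward the 3'-end placement.
* Homopolymer bases that could belong either to the TSD or to the adjacent
  poly-tail are assigned to the tail (tail-maximal convention).  Without this
  rule the partition of e.g. ``...A|GAAGGATACAATGTT`` between a 15 bp TSD +
  56 bp tail and a 16 bp TSD + 55 bp tail is arbitrary.
* The poly-tail is the maximal window anchored at the chosen insert end whose
  fraction of the majority base stays at or above ``purity`` and whose both
  endpoint bases equal that base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from Bio import Align
from Bio.Seq import Seq

from .synthetic import DeletionSpec, InsertionSpec, revcomp

__all__ = [
    "InsertionCall",
    "MEIReport",
    "ConsensusLibrary",
    "CodingConsequence",
    "DecompositionParams",
    "detect_tsd",
    "detect_poly_tail",
    "classify_body",
    "decompose_insertion",
    "hgvs_describe",
    "coding_consequence",
]


@dataclass(frozen=True)
class InsertionCall:
    """An insertion with its reference context.

    ``ref_position`` is the 1-based reference position of the last base
    before the inserted sequence; flanks are reference (not mutant) sequence
    of at least ~50 bp on each side.
    """

    ref_position: int
    insert_sequence: str
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if not self.insert_sequence:
            raise ValueError("insert_sequence must be non-empty")


@dataclass
class ConsensusLibrary:
    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        labels = [name for name, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("consensus labels must be unique")
        if any(not seq for _, seq in self.entries):
            raise ValueError("consensus sequences must be non-empty")


@dataclass
class MEIReport:
    """Decomposition of one insertion, on a chosen reporting strand."""

    tsd_sequence: Optional[str]
    tsd_len: int
    tail_base: Optional[str]
    tail_len: int
    body_sequence: str
    body_len: int
    family: Optional[str]
    body_identity: float
    body_orientation: Optional[str]
    hgvs: str
    reporting_strand: Literal["plus", "minus"] = "plus"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CodingConsequence:
    aberrant_aa_count: int
    premature_stop: bool
    frame_offset: int
    peptide: str = ""


@dataclass(frozen=True)
class DecompositionParams:
    """Defaults: TSDs of TPRT insertions are typically 5-20 bp (the EYS one
    is 15); tail purity 0.9 tolerates sequencing error while still finding a
    pure 56-mer; body identity 0.8 separates Alu subfamilies from noise."""

    min_tsd: int = 5
    max_tsd: int = 50
    tail_min_len: int = 10
    tail_purity: float = 0.9
    body_min_identity: float = 0.8


@dataclass(frozen=True)
class TsdHit:
    sequence: str
    placement: Literal["five_prime", "three_prime"]

    def __len__(self) -> int:
        return len(self.sequence)


def detect_tsd(
    call: InsertionCall, min_tsd: int = 5, max_tsd: int = 50
) -> Optional[TsdHit]:
    """Find the target-site duplication of an insertion call.

    Returns the longest exact string that is both a suffix of the insert and
    a suffix of the left reference flank (3'-end placement of the TSD copy),
    or symmetrically a prefix of the insert and of the right flank (5'-end
    placement).  The longer placement wins; ties go to the 3' placement.
    Homopolymer bases shared with the abutting would-be tail are then
    reassigned to the tail, never shrinking the TSD below ``min_tsd``.
    """
    if min_tsd < 3:
        raise ValueError("min_tsd must be >= 3")
    if min(len(call.left_flank), len(call.right_flank)) < max_tsd:
        raise ValueError("flanks shorter than max_tsd")
    ins, left, right = call.insert_sequence, call.left_flank, call.right_flank

    cap = min(max_tsd, len(ins))
    len3 = 0
    while len3 < cap and ins[-(len3 + 1)] == left[-(len3 + 1)]:
        len3 += 1
    len5 = 0
    while len5 < cap and ins[len5] == right[len5]:
        len5 += 1

    if max(len3, len5) < min_tsd:
        return None
    if len3 >= len5:
        L = len3
        # tail-maximal trim: transfer leading bases equal to the adjacent
        # insert base (the prospective tail) from the TSD to the tail
        if L < len(ins):
            t = ins[-(L + 1)]
            while L > min_tsd and ins[-L] == t:
                L -= 1
        return TsdHit(ins[-L:], "three_prime")
    L = len5
    if L < len(ins):
        t = ins[L]
        while L > min_tsd and ins[L - 1] == t:
            L -= 1
    return TsdHit(ins[:L], "five_prime")


def detect_poly_tail(
    seq: str,
    search_end: Literal["head", "tail"] = "tail",
    min_len: int = 10,
    purity: float = 0.9,
) -> Optional[tuple[str, int]]:
    """Detect a homopolymer A/T tail anchored at one end of ``seq``.

    The tail is the longest window anchored at ``search_end`` whose majority
    base (A or T) makes up at least ``purity`` of the window and whose first
    and last bases both equal that base.  Returns ``(base, length)`` or
    ``None`` if no window of at least ``min_len`` qualifies.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.5 < purity <= 1:
        raise ValueError("purity must be in (0.5, 1]")
    if min_len < 5:
        raise ValueError("min_len must be >= 5")
    s = seq[::-1] if search_end == "tail" else seq
    best: tuple[int, str] | None = None
    for base in "AT":
        if s[0] != base:
            continue
        count = 0
        longest = 0
        for i, ch in enumerate(s):
            if ch == base:
                count += 1
                if count / (i + 1) >= purity:
                    longest = i + 1
        if longest >= min_len and (best is None or longest > best[0]):
            best = (longest, base)
    if best is None:
        return None
    return best[1], best[0]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def _identity(alignment, target_len: int, query_len: int) -> float:
    """Matches over alignment columns.

    Terminal overhang columns (free end gaps) are excluded, but the column
    count is floored at the shorter sequence length so that a short,
    perfectly matching core of an otherwise unrelated pair cannot score 1.0;
    a truncated element aligned exactly within a longer consensus still does.
    """
    a = str(alignment[0])
    b = str(alignment[1])
    start = 0
    while start < len(a) and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = len(a)
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    cols = max(end - start, min(target_len, query_len))
    if cols <= 0:
        return 0.0
    matches = sum(a[i] == b[i] and a[i] != "-" for i in range(start, end))
    return matches / cols


def classify_body(
    body: str,
    library: ConsensusLibrary | Sequence[tuple[str, str]],
    min_identity: float = 0.8,
) -> Optional[tuple[str, float, str]]:
    """Classify an element body against a consensus library.

    Aligns the body (global, free end gaps; match +1 / mismatch -1 / gap -2)
    against each consensus and its reverse complement; identity is matches
    over alignment columns.  Returns ``(family, identity, orientation)`` for
    the best hit at or above ``min_identity``, else ``None``.  Ties favour
    the plus strand, then library order.
    """
    if not body:
        raise ValueError("empty body")
    entries = library.entries if isinstance(library, ConsensusLibrary) else list(library)
    if not entries:
        raise ValueError("empty consensus library")
    aligner = _aligner()
    best: tuple[float, int, int, str] | None = None  # (identity, -strandrank, -order, family)
    for order, (family, consensus) in enumerate(entries):
        for strand_rank, (strand, query) in enumerate(
            [("plus", body), ("minus", revcomp(body))]
        ):
            aln = aligner.align(consensus, query)[0]
            ident = _identity(aln, len(consensus), len(query))
            key = (ident, -strand_rank, -order, family)
            if best is None or key[:3] > best[:3]:
                best = key
                best_strand = strand
    assert best is not None
    if best[0] < min_identity:
        return None
    return best[3], best[0], best_strand


def decompose_insertion(
    call: InsertionCall,
    library: ConsensusLibrary | Sequence[tuple[str, str]],
    params: DecompositionParams = DecompositionParams(),
    reporting_strand: Literal["plus", "minus"] = "plus",
) -> MEIReport:
    """Decompose an insertion call into TSD, poly-tail and element body.

    Order of operations: TSD first, then the tail searched at the insert end
    adjacent to the TSD (falling back to the opposite end, which is where the
    tail of a minus-orientation element sits), then the remainder is the body,
    which is classified against the library.  With ``reporting_strand=
    "minus"`` the report is mirrored onto the transcript strand (TSD and body
    reverse-complemented, tail base complemented).
    """
    tsd = detect_tsd(call, params.min_tsd, params.max_tsd)
    ins = call.insert_sequence
    if tsd is None:
        remainder = ins
        tail_ends = ["tail", "head"]
    elif tsd.placement == "three_prime":
        remainder = ins[: len(ins) - len(tsd)]
        tail_ends = ["tail", "head"]
    else:
        remainder = ins[len(tsd):]
        tail_ends = ["head", "tail"]

    tail = None
    if remainder:
        for end in tail_ends:
            tail = detect_poly_tail(
                remainder, end, params.tail_min_len, params.tail_purity  # type: ignore[arg-type]
            )
            if tail is not None:
                tail_end = end
                break
    if tail is None:
        body = remainder
        tail_base, tail_len = None, 0
    else:
        tail_base, tail_len = tail
        body = remainder[:-tail_len] if tail_end == "tail" else remainder[tail_len:]

    family, identity, orientation = None, 0.0, None
    if body:
        hit = classify_body(body, library, params.body_min_identity)
        if hit is not None:
            family, identity, orientation = hit

    hgvs = hgvs_describe(
        InsertionSpec(insert_after=call.ref_position, tsd="", body=ins, tail_len=0)
    )

    tsd_seq = tsd.sequence if tsd else None
    if reporting_strand == "minus":
        tsd_seq = revcomp(tsd_seq) if tsd_seq else None
        tail_base = {"A": "T", "T": "A"}.get(tail_base) if tail_base else None
        body = revcomp(body)
        if orientation is not None:
            orientation = "minus" if orientation == "plus" else "plus"
    return MEIReport(
        tsd_sequence=tsd_seq,
        tsd_len=len(tsd_seq) if tsd_seq else 0,
        tail_base=tail_base,
        tail_len=tail_len,
        body_sequence=body,
        body_len=len(body),
        family=family,
        body_identity=identity,
        body_orientation=orientation,
        hgvs=hgvs,
        reporting_strand=reporting_strand,
    )


def hgvs_describe(variant) -> str:
    """HGVS-like description of an insertion or deletion.

    Insertions render as ``g.<pos>_<pos+1>ins<len>``; deletions as
    ``g.<start>_<end>del`` (``g.<pos>del`` for a single base).  Accepts
    :class:`InsertionSpec`, :class:`DeletionSpec`, or any object with the
    corresponding coordinate attributes (e.g. an SV call).
    """
    if isinstance(variant, DeletionSpec) or hasattr(variant, "del_start"):
        start, end = variant.del_start, variant.del_end
        if start > end:
            raise ValueError("deletion start > end")
        return f"g.{start}del" if start == end else f"g.{start}_{end}del"
    if isinstance(variant, InsertionSpec):
        pos, length = variant.insert_after, len(variant)
    else:
        pos, length = variant.insert_after, variant.length
    return f"g.{pos}_{pos + 1}ins{length}"


_STOPS = {"TAA", "TAG", "TGA"}


def coding_consequence(
    insert_in_transcript_orientation: str,
    phase_within_codon: int,
    upstream: str = "",
    downstream: str = "",
) -> CodingConsequence:
    """Translate an exonic insertion and count novel residues.

    ``phase_within_codon`` (0-2) is the number of bases of the interrupted
    codon that lie upstream of the insertion; those bases are taken from
    ``upstream`` and read-through continues into ``downstream``.  Novel
    residues are codons containing at least one inserted base -- plus, for
    frameshifting inserts, every downstream codon -- counted strictly before
    the first stop.  ``premature_stop`` is true when that stop is itself
    insert-derived.
    """
    insert = insert_in_transcript_orientation.upper()
    if phase_within_codon not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    for name, s in [("insert", insert), ("upstream", upstream), ("downstream", downstream)]:
        if set(s) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in {name}")
    p = phase_within_codon
    if p and len(upstream) < p:
        raise ValueError("upstream context shorter than phase")
    seq = (upstream[-p:] if p else "") + insert + downstream
    ins_lo, ins_hi = p, p + len(insert)  # insert occupies seq[ins_lo:ins_hi]
    frameshift = len(insert) % 3 != 0

    count = 0
    peptide = []
    premature = False
    for j in range(0, len(seq) - 2, 3):
        codon = seq[j:j + 3]
        novel = (j < ins_hi and j + 3 > ins_lo) or (frameshift and j >= ins_hi)
        if codon in _STOPS:
            premature = novel
            break
        peptide.append(str(Seq(codon).translate()))
        if novel:
            count += 1
    return CodingConsequence(
        aberrant_aa_count=count,
        premature_stop=premature,
        frame_offset=len(insert) % 3,
        peptide="".join(peptide),
    )
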