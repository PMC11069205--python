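"""Allele-diagnostic junction k-mer (probe) design and validation.

A characterized insertion has two informative mutant junctions on the plus
strand -- reference→element-body at the 5' end and poly-tail→TSD-copy at the
3' end (the junction between the insert end and the downstream reference is
uninformative because the TSD copy reproduces reference sequence) -- plus the
uninterrupted wild-type site.  For each, a k-mer spanning the junction and
its reverse complement are emitted, so a probe set screens both read strands
with plain substring matching.

``EYS_JUNCTION_SPLITS`` reproduces the exact per-side base counts of the six
diagnostic sequences used in the original EYS-AluYa5 screen (including the
two 22-mers at the poly-A junction, preserved as published).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .synthetic import AllelePair, InsertionSpec, revcomp

__all__ = [
    "Probe",
    "ProbeSet",
    "design_junction_probes",
    "check_specificity",
    "emit_patterns",
    "EYS_WT_PROBES",
    "EYS_MUT_PROBES",
    "EYS_JUNCTION_SPLITS",
    "write_probes_tsv",
    "read_probes_tsv",
]

# The six diagnostic k-mers of the EYS exon-43 AluYa5 screen.
EYS_WT_PROBES = (
    "ATTAGAAGGATACAATGTTTATG",
    "CATAAACATTGTATCCTTCTAAT",
)
EYS_MUT_PROBES = (
    "GAAGGATACAATGTTGGCCGGGC",
    "GCCCGGCCAACATTGTATCCTTC",
    "ACATTGTATCCTTCTTTTTTTT",
    "AAAAAAAAGAAGGATACAATGT",
)

# (bases 5' of junction, bases 3' of junction) used by the original screen.
EYS_JUNCTION_SPLITS: dict[str, tuple[int, int]] = {
    "five_prime": (15, 8),
    "three_prime": (8, 14),
    "wt_site": (19, 4),
}

Junction = Literal["five_prime", "three_prime", "wt_site"]


@dataclass(frozen=True)
class Probe:
    sequence: str
    allele_class: Literal["WT", "MUT"]
    junction: Junction
    strand: Literal["plus", "minus"]
    validated: Optional[bool] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeSet:
    probes: list[Probe]
    k: int

    def __post_init__(self) -> None:
        seqs = [p.sequence for p in self.probes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate probe sequences in set")
        for p in self.probes:
            if set(p.sequence) - set("ACGT"):
                raise ValueError(f"probe {p.sequence!r} contains non-ACGT characters")

    def by_class(self, allele_class: str, validated_only: bool = False) -> list[Probe]:
        return [
            p
            for p in self.probes
            if p.allele_class == allele_class
            and (not validated_only or p.validated)
        ]

    @property
    def all_validated(self) -> bool:
        return all(p.validated for p in self.probes)


def _homopolymer_run(seq: str, from_end: Literal["head", "tail"]) -> int:
    """Length of the homopolymer run at one end of a sequence."""
    s = seq if from_end == "head" else seq[::-1]
    if not s:
        return 0
    i = 1
    while i < len(s) and s[i] == s[0]:
        i += 1
    return i


def _junction_kmer(
    left: str,
    right: str,
    k: int,
    homopolymer_cap: int,
    split: tuple[int, int] | None,
) -> str:
    """k-mer spanning a junction: ``split`` fixes the per-side base counts,
    otherwise the probe is centered (ceil(k/2) bases from the 5' side) with
    a homopolymer side capped at ``homopolymer_cap`` bases."""
    if split is not None:
        n_left, n_right = split
    else:
        n_left = (k + 1) // 2
        n_right = k - n_left
        run_l = _homopolymer_run(left, "tail")
        run_r = _homopolymer_run(right, "head")
        if run_l >= n_left and homopolymer_cap < n_left:
            n_left = homopolymer_cap
            n_right = min(k - n_left, len(right))
        elif run_r >= n_right and homopolymer_cap < n_right:
            n_right = homopolymer_cap
            n_left = min(k - n_right, len(left))
    if n_left > len(left) or n_right > len(right):
        raise ValueError("insufficient flank for probe design")
    return left[len(left) - n_left:] + right[:n_right]


def design_junction_probes(
    pair: AllelePair,
    insertion: InsertionSpec | None = None,
    k: int = 23,
    homopolymer_cap: int = 8,
    splits: dict[str, tuple[int, int]] | None = None,
) -> ProbeSet:
    """Design WT and MUT junction probes for a characterized insertion.

    Emits, for each of the two informative mutant junctions, the plus-strand
    k-mer spanning it plus its reverse complement (4 MUT probes), and the
    k-mer spanning the uninterrupted wild-type site plus its reverse
    complement (2 WT probes).  ``splits`` overrides the centered layout with
    explicit (5'-side, 3'-side) base counts per junction, which is how the
    published EYS probe set (``EYS_JUNCTION_SPLITS``) is reproduced.
    """
    if k < 12:
        raise ValueError("k must be >= 12")
    if insertion is None:
        if not isinstance(pair.variant, InsertionSpec):
            raise ValueError("pair does not carry an insertion")
        insertion = pair.variant
    a = insertion.insert_after - pair.locus.ref_offset + 1
    left_ref = pair.wt[:a]
    right_ref = pair.wt[a:]
    ins = insertion.insert_sequence
    tsd_len = len(insertion.tsd)
    novel = ins[: len(ins) - tsd_len] if tsd_len else ins
    tsd_and_right = ins[len(ins) - tsd_len:] + right_ref

    splits = splits or {}
    layout: list[tuple[Junction, str, str]] = [
        ("five_prime", left_ref, novel if novel else ins),
        ("three_prime", novel, tsd_and_right),
        ("wt_site", left_ref, right_ref),
    ]
    probes: list[Probe] = []
    for junction, left, right in layout:
        kmer = _junction_kmer(left, right, k, homopolymer_cap, splits.get(junction))
        allele_class = "WT" if junction == "wt_site" else "MUT"
        probes.append(Probe(kmer, allele_class, junction, "plus"))
        probes.append(Probe(revcomp(kmer), allele_class, junction, "minus"))
    return ProbeSet(probes=probes, k=k)


def _occurs(probe: str, seq: str) -> bool:
    return probe in seq or revcomp(probe) in seq


def check_specificity(
    probeset: ProbeSet,
    wt_allele: str,
    mut_allele: str,
    background: Iterable[str] = (),
) -> ProbeSet:
    """Flag each probe as validated by exact substring matching on both strands.

    A MUT probe validates iff it occurs in the mutant allele and in neither
    the wild-type allele nor any background sequence; a WT probe validates
    iff it occurs in the wild-type allele and in no background sequence.
    """
    background = list(background)
    out = []
    for p in probeset.probes:
        in_bg = any(_occurs(p.sequence, b) for b in background)
        if p.allele_class == "MUT":
            ok = _occurs(p.sequence, mut_allele) and not _occurs(p.sequence, wt_allele) and not in_bg
        else:
            ok = _occurs(p.sequence, wt_allele) and not in_bg
        out.append(replace(p, validated=ok))
    return ProbeSet(probes=out, k=probeset.k)


def emit_patterns(
    probeset: ProbeSet, dialect: Literal["fastq_grep", "sam_grep", "plain"] = "plain"
) -> dict[str, str]:
    """Render validated probes as search patterns, grouped by allele class.

    ``fastq_grep`` emits a zgrep alternation over FASTQ.gz, ``sam_grep`` a
    samtools-view pipe with one ``-e`` per probe, ``plain`` one sequence per
    line.  Unvalidated probes are never emitted; an empty validated class is
    an error.
    """
    out: dict[str, str] = {}
    for allele_class in ("WT", "MUT"):
        seqs = [p.sequence for p in probeset.by_class(allele_class, validated_only=True)]
        if not seqs:
            raise ValueError(f"no validated {allele_class} probes to emit")
        if dialect == "fastq_grep":
            out[allele_class] = 'zgrep -c "' + "\\|".join(seqs) + '" *fastq.gz'
        elif dialect == "sam_grep":
            flags = " ".join(f"-e {s}" for s in seqs)
            out[allele_class] = f"samtools view sample.bam | grep -c {flags}"
        elif dialect == "plain":
            out[allele_class] = "\n".join(seqs)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return out


def write_probes_tsv(probeset: ProbeSet, path: str | Path) -> Path:
    rows = [
        {
            "sequence": p.sequence,
            "class": p.allele_class,
            "junction": p.junction,
            "strand": p.strand,
            "validated": "" if p.validated is None else int(p.validated),
        }
        for p in probeset.probes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_probes_tsv(path: str | Path) -> ProbeSet:
    df = pd.read_csv(path, sep="\t", dtype={"validated": "object"})
    probes = [
        Probe(
            sequence=row["sequence"],
            allele_class=row["class"],
            junction=row["junction"],
            strand=row["strand"],
            validated=None if pd.isna(row["validated"]) or row["validated"] == ""
            else bool(int(row["validated"])),
        )
        for _, row in df.iterrows()
    ]
    k = max((p.length for p in probes), default=0)
    return ProbeSet(probes=probes, k=k)
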