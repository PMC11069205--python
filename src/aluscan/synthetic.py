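"""Synthetic locus, allele and read construction.

Everything downstream of this module (insertion decomposition, long-read SV
calling, probe screening, soft-clip analysis, STR linkage) is exercised on
alleles and reads built here, so no external sequencing data is required.

The central fixture, :func:`eys_fixture`, reconstructs the study conditions of
a pathogenic AluYa5 insertion in coding exon 43 of *EYS*
(chr6(GRCh37):g.64430524_64430525, anatomy: 282 bp element body, 56 bp
poly-A/T tail, 15 bp target-site duplication ``AACATTGTATCCTTC`` on the
transcript strand) together with the recurrent ~56.4 kb deletion of exons
32-33 (g.64764235_64820592del).  The two variants are ~334 kb apart, so the
fixture carries them on two compact loci -- a ~2 kb insertion locus and a
~58.4 kb deletion locus -- each with 1 kb of seeded-random flank beyond the
known junction context.

Coordinates are 1-based inclusive (HGVS convention) in every public field;
0-based half-open arithmetic is internal only.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_RC = str.maketrans("ACGTacgt", "TGCAtgca")

# Plus-strand junction context of the EYS exon-43 insertion site.  The
# 15-mer is the reverse complement of the transcript-strand TSD
# AACATTGTATCCTTC; ATTA/TATG are the four printed reference bases on
# either side of the duplicated tract.
EYS_TSD_PLUS = "GAAGGATACAATGTT"
EYS_CONTEXT_LEFT = "ATTA"
EYS_CONTEXT_RIGHT = "TATG"
EYS_INSERTION_AFTER = 64_430_524
EYS_DEL_START = 64_764_235
EYS_DEL_END = 64_820_592

CONSENSUS_RESOURCE = "synthetic_sine_consensus.fasta"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_RC)[::-1]


def _check_alphabet(seq: str, what: str) -> None:
    if not seq or set(seq) - set(ALPHABET):
        raise ValueError(f"{what} must be a non-empty ACGT string")


def random_sequence(n: int, rng: random.Random, weights=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choices(ALPHABET, weights=weights, k=n))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusConfig:
    """A local reference window with its genomic anchor.

    ``ref_offset`` is the 1-based reference coordinate of the first base of
    ``wt_sequence``; local 0-based position ``p`` therefore maps to reference
    position ``ref_offset + p``.
    """

    ref_name: str
    ref_offset: int
    wt_sequence: str

    def __post_init__(self) -> None:
        _check_alphabet(self.wt_sequence, "wt_sequence")
        if self.ref_offset < 1:
            raise ValueError("ref_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.wt_sequence)

    @property
    def ref_end(self) -> int:
        return self.ref_offset + len(self.wt_sequence) - 1

    def to_local(self, ref_pos: int) -> int:
        if not self.ref_offset <= ref_pos <= self.ref_end:
            raise ValueError(f"position {ref_pos} outside locus")
        return ref_pos - self.ref_offset

    def to_ref(self, local_pos: int) -> int:
        if not 0 <= local_pos < len(self.wt_sequence):
            raise ValueError(f"local position {local_pos} outside locus")
        return self.ref_offset + local_pos


@dataclass(frozen=True)
class InsertionSpec:
    """A mobile-element style insertion: body + homopolymer tail + TSD copy.

    ``insert_after`` is the 1-based reference position of the last reference
    base before the inserted material; by TPRT geometry the reference bases
    immediately 5' of that point are duplicated, so ``tsd`` must equal the
    reference suffix ending at ``insert_after`` and a copy of it terminates
    the inserted sequence.
    """

    insert_after: int
    tsd: str
    body: str
    tail_base: Literal["A", "T"] = "A"
    tail_len: int = 0
    body_orientation: Literal["plus", "minus"] = "plus"

    def __post_init__(self) -> None:
        if self.tail_len < 0:
            raise ValueError("tail_len must be >= 0")
        if self.tail_base not in "AT":
            raise ValueError("tail_base must be A or T")
        if self.tsd:
            _check_alphabet(self.tsd, "tsd")
        if self.body:
            _check_alphabet(self.body, "body")

    @property
    def insert_sequence(self) -> str:
        """The full inserted tract on the construction (plus) strand.

        Plus-orientation elements integrate as body + poly-A + TSD copy;
        minus-orientation elements appear as poly-T + revcomp(body) + TSD
        copy on the plus strand.
        """
        tail = self.tail_base * self.tail_len
        if self.body_orientation == "plus":
            return self.body + tail + self.tsd
        return tail + revcomp(self.body) + self.tsd

    def __len__(self) -> int:
        return len(self.insert_sequence)


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion of the 1-based inclusive reference interval [del_start, del_end]."""

    del_start: int
    del_end: int

    def __post_init__(self) -> None:
        if self.del_start > self.del_end:
            raise ValueError("del_start must be <= del_end")

    def __len__(self) -> int:
        return self.del_end - self.del_start + 1


@dataclass
class AllelePair:
    """Wild-type and mutant haplotype for one locus plus the coordinate map.

    ``mut_to_ref`` holds, for every mutant local 0-based position, the 1-based
    reference position of that base, or -1 for bases with no reference
    counterpart (inserted material).
    """

    locus: LocusConfig
    variant: InsertionSpec | DeletionSpec
    wt: str
    mut: str
    mut_to_ref: np.ndarray

    def __post_init__(self) -> None:
        self._ref_to_mut: dict[int, int] | None = None

    def mut_pos_to_ref(self, local_pos: int) -> int | None:
        r = int(self.mut_to_ref[local_pos])
        return None if r == -1 else r

    def ref_pos_to_mut(self, ref_pos: int) -> int | None:
        if self._ref_to_mut is None:
            self._ref_to_mut = {
                int(r): i for i, r in enumerate(self.mut_to_ref) if r != -1
            }
        return self._ref_to_mut.get(ref_pos)


Op = tuple[str, int]  # CIGAR-style (kind in {M,I,D,S}, length)


@dataclass
class AlignedRead:
    """A read with an explicit operation list against the reference.

    Stands in for a SAM record: ``mapped_start`` is the 1-based reference
    position of the first aligned (M) base, and ``ops`` is an ordered list of
    (kind, length) with kind in M/I/D/S.
    """

    read_id: str
    sequence: str
    mapped_start: int
    ops: list[Op]
    source_haplotype: Literal["wt", "mut"] = "wt"
    sample_id: str = "sample"
    inserted_sequences: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("ops list must be non-empty")
        qlen = sum(n for k, n in self.ops if k in "MIS")
        if qlen != len(self.sequence):
            raise ValueError(
                f"query-consuming op lengths ({qlen}) != sequence length ({len(self.sequence)})"
            )

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference interval covered by M/D ops (end < start if none)."""
        rlen = sum(n for k, n in self.ops if k in "MD")
        return self.mapped_start, self.mapped_start + rlen - 1


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated short-read screening cohort."""

    n_samples: int
    carrier_genotypes: tuple[str, ...]
    depth: float = 5.0
    read_len: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples != len(self.carrier_genotypes):
            raise ValueError("n_samples must equal the genotype list length")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for g in self.carrier_genotypes:
            if g not in ("ref/ref", "ref/mut", "mut/mut"):
                raise ValueError(f"invalid genotype {g!r}")


@dataclass(frozen=True)
class EysFixture:
    """The reconstructed EYS study conditions: two loci, two variants."""

    insertion_locus: LocusConfig
    insertion: InsertionSpec
    deletion_locus: LocusConfig
    deletion: DeletionSpec


# ---------------------------------------------------------------------------
# consensus library access
# ---------------------------------------------------------------------------

def consensus_fasta_path() -> Path:
    """Path to the bundled synthetic mobile-element consensus FASTA."""
    path = resources.files("aluscan").joinpath("data", CONSENSUS_RESOURCE)
    p = Path(str(path))
    if not p.exists():
        raise FileNotFoundError(
            f"bundled consensus fixture {CONSENSUS_RESOURCE} is missing"
        )
    return p


def load_consensus_library() -> list[tuple[str, str]]:
    """(name, sequence) entries of the bundled synthetic consensus library."""
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(consensus_fasta_path()), "fasta")
    ]


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 64_430_524


def _probe_free(seq: str, probes: Iterable[str]) -> bool:
    return not any(p in seq or revcomp(p) in seq for p in probes)


@lru_cache(maxsize=4)
def eys_fixture(flank: int = 1000) -> EysFixture:
    """Build the EYS insertion and deletion study loci.

    The insertion locus embeds the printed junction context
    ``...ATTA|GAAGGATACAATGTT|TATG...`` so that the reference TSD ends at
    g.64430524; the inserted tract is the bundled 282 bp AluYa5-like body,
    a 56 bp poly-A tail and a copy of the TSD (353 bp total).  The deletion
    locus spans g.64764235-64820592 (56,358 bp) plus ``flank`` random bases
    on each side.  Flanks are seeded-random and regenerated until they are
    free of all diagnostic junction k-mers.  Deterministic.
    """
    from . import probes as _probes  # late import; probes imports this module

    library = load_consensus_library()
    body = dict(library).get("AluYa5_synthetic")
    if body is None:
        raise FileNotFoundError("AluYa5_synthetic entry missing from consensus fixture")

    rng = random.Random(_FIXTURE_SEED)
    known = list(_probes.EYS_WT_PROBES + _probes.EYS_MUT_PROBES)

    core = EYS_CONTEXT_LEFT + EYS_TSD_PLUS + EYS_CONTEXT_RIGHT
    while True:
        left = random_sequence(flank, rng)
        right = random_sequence(flank, rng)
        wt = left + core + right
        if _probe_free(left + EYS_CONTEXT_LEFT, known) and _probe_free(
            EYS_CONTEXT_RIGHT + right, known
        ) and wt.count(EYS_TSD_PLUS) == 1:
            break

    tsd_end_local = flank + len(EYS_CONTEXT_LEFT) + len(EYS_TSD_PLUS)  # 1-based
    ins_locus = LocusConfig(
        ref_name="chr6",
        ref_offset=EYS_INSERTION_AFTER - tsd_end_local + 1,
        wt_sequence=wt,
    )
    insertion = InsertionSpec(
        insert_after=EYS_INSERTION_AFTER,
        tsd=EYS_TSD_PLUS,
        body=body,
        tail_base="A",
        tail_len=56,
        body_orientation="plus",
    )

    del_len = EYS_DEL_END - EYS_DEL_START + 1
    while True:
        del_seq = random_sequence(flank, rng) + random_sequence(del_len, rng) + random_sequence(flank, rng)
        if _probe_free(del_seq, known):
            break
    del_locus = LocusConfig(
        ref_name="chr6", ref_offset=EYS_DEL_START - flank, wt_sequence=del_seq
    )
    deletion = DeletionSpec(del_start=EYS_DEL_START, del_end=EYS_DEL_END)
    return EysFixture(ins_locus, insertion, del_locus, deletion)


def eys_repeat_intervals() -> list[tuple[str, int, int, str]]:
    """Synthetic RepeatMasker-style intervals matching the deletion breakpoint context.

    BED convention (0-based half-open): an L2/LINE element containing the 5'
    breakpoint, and MIR/SINE elements ending 200 bp upstream and starting
    600 bp downstream of the 3' breakpoint, plus unrelated decoys.
    """
    bp5, bp3 = EYS_DEL_START, EYS_DEL_END
    return [
        ("chr6", bp5 - 151, bp5 + 250, "L2:LINE"),
        ("chr6", bp3 - 200 - 180, bp3 - 200, "MIR:SINE"),
        ("chr6", bp3 + 600 - 1, bp3 + 600 + 149, "MIR:SINE"),
        ("chr6", bp5 - 5000, bp5 - 4500, "AluSx:SINE"),
        ("chr6", bp3 + 8000, bp3 + 8600, "L1MB7:LINE"),
    ]


def write_repeat_bed(path: str | Path, intervals=None) -> Path:
    intervals = eys_repeat_intervals() if intervals is None else intervals
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, name in sorted(intervals, key=lambda x: (x[0], x[1])):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return path


# ---------------------------------------------------------------------------
# allele construction
# ---------------------------------------------------------------------------

def build_alleles(locus: LocusConfig, variant: InsertionSpec | DeletionSpec) -> AllelePair:
    """Apply a variant to a locus, producing both haplotypes and the coordinate map.

    Raises ``ValueError`` when an insertion's declared TSD does not match the
    reference bases immediately 5' of the insertion point (an inconsistent
    variant description).
    """
    wt = locus.wt_sequence
    off = locus.ref_offset
    if isinstance(variant, InsertionSpec):
        a = variant.insert_after - off + 1  # number of wt bases before the insert
        if not 0 <= a <= len(wt):
            raise ValueError("insertion point outside locus")
        if variant.tsd and wt[a - len(variant.tsd): a] != variant.tsd:
            raise ValueError(
                "TSD does not match the reference bases 5' of the insertion point"
            )
        ins = variant.insert_sequence
        mut = wt[:a] + ins + wt[a:]
        m2r = np.concatenate(
            [
                np.arange(off, off + a, dtype=np.int64),
                np.full(len(ins), -1, dtype=np.int64),
                np.arange(off + a, off + len(wt), dtype=np.int64),
            ]
        )
    elif isinstance(variant, DeletionSpec):
        d0 = variant.del_start - off
        d1 = variant.del_end - off + 1
        if not 0 <= d0 < d1 <= len(wt):
            raise ValueError("deletion outside locus")
        mut = wt[:d0] + wt[d1:]
        m2r = np.concatenate(
            [
                np.arange(off, off + d0, dtype=np.int64),
                np.arange(off + d1, off + len(wt), dtype=np.int64),
            ]
        )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported variant type {type(variant)!r}")
    return AllelePair(locus=locus, variant=variant, wt=wt, mut=mut, mut_to_ref=m2r)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _mut_read_ops_insertion(
    pair: AllelePair, s: int, e: int
) -> tuple[int, list[Op], str | None]:
    """Ops for a mutant-haplotype read [s, e) over an insertion allele."""
    variant: InsertionSpec = pair.variant  # type: ignore[assignment]
    off = pair.locus.ref_offset
    a = variant.insert_after - off + 1
    ilen = len(variant)
    left_m = max(0, min(e, a) - s)
    ins_cov = max(0, min(e, a + ilen) - max(s, a))
    right_m = max(0, e - max(s, a + ilen))
    if ins_cov == 0:
        start = s if e <= a else s - ilen
        return off + start, [("M", e - s)], None
    if left_m and right_m:
        # read fully spans the insert
        return off + s, [("M", left_m), ("I", ilen), ("M", right_m)], pair.mut[a:a + ilen]
    if left_m:
        return off + s, [("M", left_m), ("S", ins_cov)], None
    if right_m:
        return off + a, [("S", ins_cov), ("M", right_m)], None
    # read entirely within the insert: fully clipped, anchored at the junction
    return off + a, [("S", ins_cov)], None


def _mut_read_ops_deletion(pair: AllelePair, s: int, e: int) -> tuple[int, list[Op]]:
    variant: DeletionSpec = pair.variant  # type: ignore[assignment]
    off = pair.locus.ref_offset
    d0 = variant.del_start - off
    dlen = len(variant)
    if e <= d0:
        return off + s, [("M", e - s)]
    if s >= d0:
        return off + s + dlen, [("M", e - s)]
    return off + s, [("M", d0 - s), ("D", dlen), ("M", e - d0)]


def _inject_errors(seq: str, error_rate: float, rng: random.Random) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < error_rate:
            out[i] = rng.choice([c for c in ALPHABET if c != b])
    return "".join(out)


def simulate_reads(
    pair: AllelePair,
    genotype: str,
    depth: float,
    read_len: int,
    error_rate: float = 0.0,
    mode: Literal["short", "long"] = "short",
    seed: int = 0,
    sample_id: str = "sample",
) -> list[AlignedRead]:
    """Simulate reads from the two haplotypes of a genotype.

    Reads are drawn uniformly along the chosen haplotype; operation lists are
    computed against the wild-type reference by construction (insert-spanning
    reads carry an I op, junction-partial reads an S op, deletion-spanning
    reads a D op).  ``mode="long"`` draws read lengths uniformly from
    [read_len/2, 3*read_len/2]; ``mode="short"`` uses a fixed length.
    Substitution errors only.  Deterministic for a fixed seed.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if genotype not in ("ref/ref", "ref/mut", "mut/mut"):
        raise ValueError(f"invalid genotype {genotype!r}")
    haps = {"ref/ref": ("wt",), "ref/mut": ("wt", "mut"), "mut/mut": ("mut",)}[genotype]
    if min(len(pair.wt), len(pair.mut)) == 0:
        raise ValueError("zero-length haplotype")
    if mode == "short" and read_len > min(len(pair.wt), len(pair.mut)):
        raise ValueError("read_len exceeds haplotype length")

    rng = random.Random(seed)
    n_reads = max(1, round(depth * len(pair.wt) / read_len))
    reads: list[AlignedRead] = []
    off = pair.locus.ref_offset
    for i in range(n_reads):
        hap = rng.choice(haps)
        hap_seq = pair.wt if hap == "wt" else pair.mut
        if mode == "long":
            length = rng.randint(max(1, read_len // 2), read_len + read_len // 2)
            length = min(length, len(hap_seq))
        else:
            length = read_len
        s = rng.randint(0, len(hap_seq) - length)
        e = s + length
        inserted = None
        if hap == "wt":
            mapped, ops = off + s, [("M", length)]
        elif isinstance(pair.variant, InsertionSpec):
            mapped, ops, inserted = _mut_read_ops_insertion(pair, s, e)
        else:
            mapped, ops = _mut_read_ops_deletion(pair, s, e)
        seq = _inject_errors(hap_seq[s:e], error_rate, rng)
        read = AlignedRead(
            read_id=f"{sample_id}_r{i:06d}",
            sequence=seq,
            mapped_start=mapped,
            ops=ops,
            source_haplotype=hap,  # type: ignore[arg-type]
            sample_id=sample_id,
        )
        if inserted is not None:
            # record the error-bearing inserted bases as sequenced
            qpos = ops[0][1]
            read.inserted_sequences[qpos] = seq[qpos:qpos + len(inserted)]
        reads.append(read)
    return reads


def write_fastq(reads: Sequence[AlignedRead], path: str | Path) -> Path:
    """Write reads as 4-line FASTQ (gzip if the suffix is .gz); qualities are 'I'."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return path


def simulate_cohort(
    spec: CohortSpec, pair: AllelePair, out_dir: str | Path
) -> pd.DataFrame:
    """Write one FASTQ.gz per sample plus a truth table of planted genotypes.

    Returns the truth table (sample_id, genotype, seed); also written to
    ``out_dir/truth.tsv``.  Per-sample seeds are derived from ``spec.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, genotype in enumerate(spec.carrier_genotypes):
        sample = f"S{i:04d}"
        sample_seed = (spec.seed * 1_000_003 + i) % 2**31
        reads = simulate_reads(
            pair,
            genotype,
            depth=spec.depth,
            read_len=spec.read_len,
            error_rate=spec.error_rate,
            mode="short",
            seed=sample_seed,
            sample_id=sample,
        )
        write_fastq(reads, out_dir / f"{sample}.fastq.gz")
        rows.append({"sample_id": sample, "genotype": genotype, "seed": sample_seed})
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# STR families
# ---------------------------------------------------------------------------

# Synthetic chr6 positions (bp) for the eight STR markers flanking EYS used
# for founder-haplotype analysis; spacing spans ~12.6 Mb around the gene.
DEFAULT_STR_MARKERS: list[tuple[str, int]] = [
    ("D6S1573", 57_100_000),
    ("D6S402", 59_800_000),
    ("D6S1658", 62_300_000),
    ("D6S1026", 63_900_000),
    ("D6S1670", 65_200_000),
    ("D6S430", 66_000_000),
    ("D6S1557", 68_100_000),
    ("D6S1681", 69_700_000),
]

_ALLELE_POOL = list(range(150, 400, 2))


def simulate_str_families(
    n_families: int,
    markers: Sequence[tuple[str, int]] | None = None,
    shared_interval: tuple[int, int] | None = None,
    seed: int = 0,
    n_children: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate STR genotypes for unrelated nuclear families sharing a founder haplotype.

    Every carrier (one carrier parent per family plus the children who inherit
    the haplotype) shares one allele at every marker whose position falls in
    ``shared_interval`` (bp, inclusive); alleles elsewhere are drawn
    independently and re-drawn if, by chance, a single allele is shared by all
    carriers at an outside marker, so the planted interval is exact.

    Returns ``(genotypes, pedigree)``: genotypes has columns family,
    individual, carrier and one ``a1/a2`` column per marker; pedigree has
    family, individual, father, mother, affected.
    """
    markers = list(DEFAULT_STR_MARKERS if markers is None else markers)
    if not markers:
        raise ValueError("marker list must be non-empty")
    if any(markers[i][1] >= markers[i + 1][1] for i in range(len(markers) - 1)):
        raise ValueError("markers must be strictly increasing by position")
    rng = random.Random(seed)
    shared_interval = shared_interval or (0, -1)  # default: nothing forced
    in_interval = [shared_interval[0] <= pos <= shared_interval[1] for _, pos in markers]
    shared_allele = {name: rng.choice(_ALLELE_POOL) for name, _ in markers}

    ped_rows, geno_rows = [], []
    fam_ids = [chr(ord("A") + i) for i in range(n_families)]
    carriers_per_marker: dict[str, list[tuple[int, int]]] = {m: [] for m, _ in markers}

    def draw() -> int:
        return rng.choice(_ALLELE_POOL)

    for fam in fam_ids:
        father, mother = f"{fam}_1", f"{fam}_2"
        carrier_parent = rng.choice([father, mother])
        children = [f"{fam}_{i + 3}" for i in range(n_children)]
        child_carrier = {c: rng.random() < 0.5 for c in children}
        if not any(child_carrier.values()):
            child_carrier[children[0]] = True
        members = [(father, None, None), (mother, None, None)] + [
            (c, father, mother) for c in children
        ]
        carrier_flags = {father: father == carrier_parent, mother: mother == carrier_parent}
        carrier_flags.update(child_carrier)
        for ind, pa, ma in members:
            ped_rows.append(
                {
                    "family": fam,
                    "individual": ind,
                    "father": pa or "0",
                    "mother": ma or "0",
                    "affected": 0,
                }
            )
            row: dict[str, object] = {
                "family": fam,
                "individual": ind,
                "carrier": int(carrier_flags[ind]),
            }
            for (name, _pos), shared_here in zip(markers, in_interval):
                if carrier_flags[ind] and shared_here:
                    pair = [shared_allele[name], draw()]
                else:
                    pair = [draw(), draw()]
                rng.shuffle(pair)
                row[name] = f"{pair[0]}/{pair[1]}"
                if carrier_flags[ind]:
                    carriers_per_marker[name].append((pair[0], pair[1]))
            geno_rows.append(row)

    genotypes = pd.DataFrame(geno_rows)
    # enforce exactness: outside the planted interval no allele may be common
    # to every carrier (re-draw one carrier genotype until the overlap breaks)
    carrier_idx = genotypes.index[genotypes["carrier"] == 1]
    for (name, _pos), shared_here in zip(markers, in_interval):
        if shared_here:
            continue
        while True:
            sets = [
                set(map(int, genotypes.loc[i, name].split("/"))) for i in carrier_idx
            ]
            common = set.intersection(*sets) if sets else set()
            if not common:
                break
            i = rng.choice(list(carrier_idx))
            pair = [draw(), draw()]
            genotypes.loc[i, name] = f"{pair[0]}/{pair[1]}"
    pedigree = pd.DataFrame(ped_rows)
    return genotypes, pedigree


# ---------------------------------------------------------------------------
# random insertion specs (round-trip property material)
# ---------------------------------------------------------------------------

def random_insertion_spec(
    rng: random.Random,
    flank: int = 120,
    min_tsd: int = 5,
    max_tsd: int = 20,
    min_tail: int = 10,
    max_tail: int = 70,
    body_len_range: tuple[int, int] = (80, 320),
) -> tuple[LocusConfig, InsertionSpec]:
    """Draw a random, identifiable insertion spec with its host locus.

    Identifiability constraints (without which the TSD/tail/body partition is
    genuinely ambiguous): the reference base 5' of the TSD differs from both
    the TSD's and the tail's first base, the reference base 3' of the
    insertion point differs from the insert's first base, the TSD's first base
    differs from the tail base, and the body ends with 8 bases free of the
    tail base.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    orientation = rng.choice(["plus", "minus"])
    tail_base = "A" if orientation == "plus" else "T"
    tail_len = rng.randint(min_tail, max_tail)
    tsd_len = rng.randint(min_tsd, max_tsd)
    blen = rng.randint(*body_len_range)
    # the base abutting the eventual tail on the insert (body end for plus,
    # revcomp'd body end for minus) must avoid the tail base: exclude A from
    # the body's last 8 bases (comp(T) = A makes this the same base both ways)
    body = random_sequence(blen - 8, rng) + "".join(
        rng.choices("CGT", k=8)
    )
    # base of the insert immediately 5' of the TSD copy
    adj = tail_base if orientation == "plus" else comp[body[0]]
    while True:
        tsd = random_sequence(tsd_len, rng)
        if tsd[0] != adj:
            break
    left = random_sequence(flank, rng)
    while left[-1] == adj:
        left = left[:-1] + rng.choice(ALPHABET)
    spec_tmp = InsertionSpec(
        insert_after=1, tsd="", body=body, tail_base=tail_base,  # type: ignore[arg-type]
        tail_len=tail_len, body_orientation=orientation,  # type: ignore[arg-type]
    )
    first_ins = spec_tmp.insert_sequence[0]
    right = random_sequence(flank, rng)
    while right[0] == first_ins:
        right = rng.choice(ALPHABET) + right[1:]
    wt = left + tsd + right
    offset = rng.randint(1, 10_000)
    locus = LocusConfig("chrS", offset, wt)
    spec = InsertionSpec(
        insert_after=offset + flank + tsd_len - 1,
        tsd=tsd,
        body=body,
        tail_base=tail_base,  # type: ignore[arg-type]
        tail_len=tail_len,
        body_orientation=orientation,  # type: ignore[arg-type]
    )
    return locus, spec
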