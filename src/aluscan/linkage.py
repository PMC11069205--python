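"""Pedigree phase inference, recessive-segregation checking and STR haplotype sharing.

Phase of two variants in a compound-heterozygous individual is inferred by
exhaustive enumeration of haplotype assignments consistent with the pedigree
and the observed genotypes (de novo events and intragenic recombination are
not modelled).  Founder-haplotype sharing across families uses an
identity-by-state criterion: a marker is shared when a single allele value is
present in every carrier's genotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "Pedigree",
    "VariantGenotypes",
    "PhaseResult",
    "SharedHaplotype",
    "infer_phase",
    "check_ar_segregation",
    "shared_haplotype",
    "shared_haplotype_subsets",
    "read_pedigree_tsv",
    "read_str_table",
]

Status = Literal["absent", "het", "hom"]


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]
    mother: Optional[str]
    affected: bool = False


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [i.iid for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        known = set(ids)
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in known:
                    raise ValueError(f"parent {parent!r} of {ind.iid!r} not in pedigree")
        # cycle check: no individual is its own ancestor
        by_id = {i.iid: i for i in self.individuals}
        for ind in self.individuals:
            seen = set()
            stack = [p for p in (ind.father, ind.mother) if p]
            while stack:
                cur = stack.pop()
                if cur == ind.iid:
                    raise ValueError(f"{ind.iid!r} is its own ancestor")
                if cur in seen:
                    continue
                seen.add(cur)
                node = by_id[cur]
                stack.extend(p for p in (node.father, node.mother) if p)

    def __iter__(self):
        return iter(self.individuals)

    def get(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.iid == iid:
                return ind
        raise KeyError(iid)

    def topological(self) -> list[Individual]:
        """Parents before children."""
        placed: list[Individual] = []
        placed_ids: set[str] = set()
        pending = list(self.individuals)
        while pending:
            progressed = False
            for ind in list(pending):
                parents = [p for p in (ind.father, ind.mother) if p]
                if all(p in placed_ids for p in parents):
                    placed.append(ind)
                    placed_ids.add(ind.iid)
                    pending.remove(ind)
                    progressed = True
            if not progressed:  # pragma: no cover - cycles rejected in __post_init__
                raise ValueError("pedigree is not acyclic")
        return placed


# per-individual (variant1 status, variant2 status); missing id = ungenotyped
VariantGenotypes = dict[str, tuple[Status, Status]]


@dataclass
class PhaseResult:
    phase: Literal["cis", "trans", "unknown"]
    conflict: bool = False
    target: Optional[str] = None


# haplotypes are frozensets over {1, 2}: which variants the haplotype carries
_HAPLOTYPES = [frozenset(), frozenset({1}), frozenset({2}), frozenset({1, 2})]


def _pair_options(genotype: Optional[tuple[Status, Status]]):
    """All ordered haplotype pairs consistent with a genotype (or any pair)."""
    pairs = []
    for h1, h2 in itertools.product(_HAPLOTYPES, repeat=2):
        if genotype is not None:
            ok = True
            for v, status in zip((1, 2), genotype):
                n = (v in h1) + (v in h2)
                want = {"absent": 0, "het": 1, "hom": 2}[status]
                if n != want:
                    ok = False
                    break
            if not ok:
                continue
        pairs.append((h1, h2))
    return pairs


def infer_phase(
    pedigree: Pedigree,
    genotypes: VariantGenotypes,
    target: Optional[str] = None,
) -> PhaseResult:
    """Infer whether two variants are in cis or trans in a double heterozygote.

    ``target`` defaults to the first individual heterozygous for both
    variants.  All haplotype assignments consistent with the pedigree and
    genotypes are enumerated (ungenotyped individuals are unconstrained;
    missing parents are free founders): ``trans`` if every consistent
    assignment places the two variants on different haplotypes of the target,
    ``cis`` if every one places them together, ``unknown`` otherwise.  No
    consistent assignment at all is a conflict (``unknown`` with the flag
    set).
    """
    ped_ids = {i.iid for i in pedigree}
    for iid in genotypes:
        if iid not in ped_ids:
            raise ValueError(f"genotyped individual {iid!r} absent from pedigree")
    if target is None:
        for ind in pedigree:
            g = genotypes.get(ind.iid)
            if g == ("het", "het"):
                target = ind.iid
                break
        if target is None:
            raise ValueError("no double-heterozygous individual to phase")

    order = pedigree.topological()
    outcomes: set[str] = set()

    def recurse(idx: int, assigned: dict[str, tuple[frozenset, frozenset]]) -> None:
        if idx == len(order):
            h1, h2 = assigned[target]
            if 1 in h1 and 2 in h1 or (1 in h2 and 2 in h2):
                # target is het/het so the other haplotype carries the rest
                outcomes.add("cis")
            else:
                outcomes.add("trans")
            return
        ind = order[idx]
        g = genotypes.get(ind.iid)
        if ind.father is None and ind.mother is None:
            options = _pair_options(g)
        else:
            paternal = list(assigned[ind.father]) if ind.father else _HAPLOTYPES
            maternal = list(assigned[ind.mother]) if ind.mother else _HAPLOTYPES
            allowed = set(_pair_options(g))
            options = [
                (hp, hm)
                for hp in paternal
                for hm in maternal
                if (hp, hm) in allowed
            ]
        for pair in options:
            assigned[ind.iid] = pair
            recurse(idx + 1, assigned)
        assigned.pop(ind.iid, None)

    # guard: target must be het for both for cis/trans to be meaningful
    if genotypes.get(target) != ("het", "het"):
        raise ValueError("target individual must be heterozygous for both variants")

    try:
        recurse(0, {})
    except KeyError:  # pragma: no cover - defensive
        pass
    if not outcomes:
        return PhaseResult("unknown", conflict=True, target=target)
    if outcomes == {"trans"}:
        return PhaseResult("trans", target=target)
    if outcomes == {"cis"}:
        return PhaseResult("cis", target=target)
    return PhaseResult("unknown", target=target)


def check_ar_segregation(
    pedigree: Pedigree, genotypes: VariantGenotypes
) -> tuple[bool, list[str]]:
    """Check autosomal-recessive segregation of a biallelic variant pair.

    Consistent iff every affected individual carries both variants (or is
    homozygous for one) and no unaffected individual does.  Ungenotyped
    individuals are skipped.  Returns (consistent, violations).
    """
    violations = []
    for ind in pedigree:
        g = genotypes.get(ind.iid)
        if g is None:
            continue
        s1, s2 = g
        biallelic = (s1 != "absent" and s2 != "absent") or "hom" in (s1, s2)
        if ind.affected and not biallelic:
            violations.append(
                f"affected {ind.iid} lacks a biallelic genotype ({s1}/{s2})"
            )
        if not ind.affected and biallelic:
            violations.append(
                f"unaffected {ind.iid} carries a biallelic genotype ({s1}/{s2})"
            )
    return not violations, violations


# ---------------------------------------------------------------------------
# STR haplotype sharing
# ---------------------------------------------------------------------------

@dataclass
class SharedHaplotype:
    shared_alleles: dict[str, Optional[int]]  # marker -> shared allele (or None)
    interval_markers: tuple[str, ...]
    interval_start: int
    interval_end: int
    interval_len: int
    families: tuple[str, ...]


def _marker_shared_allele(
    genotypes: pd.DataFrame, marker: str, carrier_idx
) -> Optional[int]:
    sets = []
    for i in carrier_idx:
        a1, a2 = str(genotypes.loc[i, marker]).split("/")
        sets.append({int(a1), int(a2)})
    common = set.intersection(*sets) if sets else set()
    return min(common) if common else None


def _interval_around_anchor(
    shared: dict[str, Optional[int]],
    markers: Sequence[tuple[str, int]],
    anchor: int,
) -> tuple[str, ...]:
    names = [m for m, _ in markers]
    positions = dict(markers)
    # anchor marker: nearest to the anchor position
    anchor_marker = min(names, key=lambda m: abs(positions[m] - anchor))
    ai = names.index(anchor_marker)
    if shared.get(anchor_marker) is None:
        return ()
    lo = ai
    while lo > 0 and shared.get(names[lo - 1]) is not None:
        lo -= 1
    hi = ai
    while hi < len(names) - 1 and shared.get(names[hi + 1]) is not None:
        hi += 1
    return tuple(names[lo:hi + 1])


def shared_haplotype(
    genotypes: pd.DataFrame,
    markers: Sequence[tuple[str, int]],
    anchor: int,
) -> SharedHaplotype:
    """Identity-by-state shared haplotype across all carriers.

    ``genotypes`` must have columns family, individual, carrier and one
    ``a1/a2`` column per marker.  A marker is shared when one allele value is
    present in every carrier's genotype; the reported interval is the maximal
    run of consecutive shared markers containing the marker nearest
    ``anchor`` (bp).  ``interval_len`` is the bp span between the first and
    last marker of the run.
    """
    carrier_idx = genotypes.index[genotypes["carrier"].astype(int) == 1]
    if len(carrier_idx) == 0:
        raise ValueError("no carriers in table")
    families = tuple(sorted(genotypes.loc[carrier_idx, "family"].unique()))
    shared = {
        name: _marker_shared_allele(genotypes, name, carrier_idx)
        for name, _ in markers
    }
    run = _interval_around_anchor(shared, markers, anchor)
    positions = dict(markers)
    if run:
        start, end = positions[run[0]], positions[run[-1]]
    else:
        start = end = 0
    return SharedHaplotype(
        shared_alleles=shared,
        interval_markers=run,
        interval_start=start,
        interval_end=end,
        interval_len=end - start,
        families=families,
    )


def shared_haplotype_subsets(
    genotypes: pd.DataFrame,
    markers: Sequence[tuple[str, int]],
    anchor: int,
    min_families: int = 2,
) -> list[SharedHaplotype]:
    """Shared haplotype for every family subset of size >= ``min_families``.

    Ordered by family count (descending) then interval length (descending),
    so the all-family interval comes first and the largest extended intervals
    over subsets follow.
    """
    fams = sorted(genotypes["family"].unique())
    out = []
    for r in range(len(fams), min_families - 1, -1):
        for subset in itertools.combinations(fams, r):
            sub = genotypes[genotypes["family"].isin(subset)]
            if (sub["carrier"].astype(int) == 1).sum() == 0:
                continue
            out.append(shared_haplotype(sub, markers, anchor))
    out.sort(key=lambda h: (-len(h.families), -h.interval_len, h.families))
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_pedigree_tsv(path: str | Path) -> Pedigree:
    """PED-like TSV with columns family, individual, father, mother, affected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    individuals = [
        Individual(
            iid=row["individual"],
            father=None if row["father"] in ("0", "", None) else row["father"],
            mother=None if row["mother"] in ("0", "", None) else row["mother"],
            affected=str(row["affected"]) in ("1", "True", "true"),
        )
        for _, row in df.iterrows()
    ]
    return Pedigree(individuals)


def read_str_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"family": str, "individual": str})
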