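"""Independent brute-force oracles shared by the test modules."""

import itertools

_HAPS = [frozenset(), frozenset({1}), frozenset({2}), frozenset({1, 2})]
_WANT = {"absent": 0, "het": 1, "hom": 2}


def _options(genotype):
    """All ordered haplotype pairs consistent with a two-variant genotype."""
    if genotype is None:
        return [(a, b) for a in _HAPS for b in _HAPS]
    out = []
    for a, b in itertools.product(_HAPS, repeat=2):
        if all((v in a) + (v in b) == _WANT[s] for v, s in zip((1, 2), genotype)):
            out.append((a, b))
    return out


def phase_oracle(pedigree, genotypes, target):
    """Flat enumeration over per-individual haplotype pairs with a
    transmission post-filter; returns (phase, conflict)."""
    ids = [i.iid for i in pedigree.individuals]
    parents = {i.iid: (i.father, i.mother) for i in pedigree.individuals}
    outcomes = set()
    for combo in itertools.product(*[_options(genotypes.get(i)) for i in ids]):
        asg = dict(zip(ids, combo))
        ok = True
        for iid, (pa, ma) in parents.items():
            h1, h2 = asg[iid]
            if pa is not None and h1 not in asg[pa]:
                ok = False
                break
            if ma is not None and h2 not in asg[ma]:
                ok = False
                break
        if not ok:
            continue
        h1, h2 = asg[target]
        outcomes.add("cis" if frozenset({1, 2}) in (h1, h2) else "trans")
    if not outcomes:
        return "unknown", True
    if len(outcomes) == 2:
        return "unknown", False
    return outcomes.pop(), False
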