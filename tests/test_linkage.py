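"""Phase inference, recessive segregation and STR haplotype sharing."""

import itertools
import random

import pandas as pd
import pytest

from aluscan import synthetic
from aluscan.linkage import (
    Individual,
    Pedigree,
    check_ar_segregation,
    infer_phase,
    shared_haplotype,
    shared_haplotype_subsets,
)

MARKERS = synthetic.DEFAULT_STR_MARKERS


def trio(child_g, father_g, mother_g, affected_child=True):
    ped = Pedigree(
        [
            Individual("F", None, None),
            Individual("M", None, None),
            Individual("C", "F", "M", affected=affected_child),
        ]
    )
    genotypes = {"F": father_g, "M": mother_g, "C": child_g}
    return ped, genotypes


# independent oracle: flat product over genotype-consistent ordered pairs
# with a transmission post-filter (structurally unlike the recursive engine)
from oracles import phase_oracle  # noqa: E402


class TestInferPhase:
    def test_compound_het_trio_is_trans(self):
        ped, g = trio(("het", "het"), ("het", "absent"), ("absent", "het"))
        assert infer_phase(ped, g).phase == "trans"

    def test_cotransmitted_variants_are_cis(self):
        ped, g = trio(("het", "het"), ("het", "het"), ("absent", "absent"))
        assert infer_phase(ped, g, target="C").phase == "cis"

    def test_no_parents_is_unknown(self):
        ped = Pedigree([Individual("X", None, None)])
        g = {"X": ("het", "het")}
        res = infer_phase(ped, g)
        assert res.phase == "unknown" and not res.conflict

    def test_impossible_genotypes_flag_conflict(self):
        # child hom for v1 but one parent lacks it entirely
        ped, g = trio(("het", "het"), ("absent", "absent"), ("absent", "absent"))
        res = infer_phase(ped, g, target="C")
        assert res.phase == "unknown" and res.conflict

    def test_genotyped_nonmember_rejected(self):
        ped, g = trio(("het", "het"), ("het", "absent"), ("absent", "het"))
        g["ghost"] = ("het", "het")
        with pytest.raises(ValueError, match="absent from pedigree"):
            infer_phase(ped, g)

    def test_matches_exhaustive_enumeration_on_random_pedigrees(self):
        rng = random.Random(71)
        statuses = ["absent", "het", "hom"]
        checked = 0
        while checked < 60:
            n_children = rng.randint(1, 4)  # pedigree of up to 6
            inds = [Individual("F", None, None), Individual("M", None, None)]
            inds += [Individual(f"C{i}", "F", "M") for i in range(n_children)]
            ped = Pedigree(inds)
            genotypes = {
                i.iid: (rng.choice(statuses), rng.choice(statuses)) for i in ped
            }
            targets = [i for i, gg in genotypes.items() if gg == ("het", "het")]
            if not targets:
                continue
            target = targets[0]
            expected_phase, expected_conflict = phase_oracle(ped, genotypes, target)
            res = infer_phase(ped, genotypes, target=target)
            assert (res.phase, res.conflict) == (expected_phase, expected_conflict)
            checked += 1


class TestArSegregation:
    def test_compound_het_family_consistent(self):
        ped = Pedigree(
            [
                Individual("F", None, None),
                Individual("M", None, None),
                Individual("C1", "F", "M", affected=True),
                Individual("C2", "F", "M", affected=True),
                Individual("C3", "F", "M", affected=True),
            ]
        )
        g = {
            "F": ("het", "absent"),
            "M": ("absent", "het"),
            "C1": ("het", "het"),
            "C2": ("het", "het"),
            "C3": ("het", "het"),
        }
        consistent, violations = check_ar_segregation(ped, g)
        assert consistent and not violations

    def test_unaffected_biallelic_individual_violates(self):
        ped, g = trio(("het", "het"), ("het", "absent"), ("absent", "het"),
                      affected_child=False)
        consistent, violations = check_ar_segregation(ped, g)
        assert not consistent
        assert any("unaffected C" in v for v in violations)

    def test_random_genotypes_match_rule_oracle(self):
        rng = random.Random(72)
        statuses = ["absent", "het", "hom"]
        for _ in range(50):
            ped = Pedigree(
                [
                    Individual("F", None, None),
                    Individual("M", None, None),
                    Individual("C", "F", "M", affected=rng.random() < 0.5),
                ]
            )
            g = {i.iid: (rng.choice(statuses), rng.choice(statuses)) for i in ped}
            consistent, violations = check_ar_segregation(ped, g)
            expected = True
            for ind in ped:
                s1, s2 = g[ind.iid]
                biallelic = (s1 != "absent" and s2 != "absent") or "hom" in (s1, s2)
                if ind.affected != biallelic:
                    expected = False
            assert consistent == expected
            assert consistent == (not violations)


ANCHOR = 64_792_414  # deletion midpoint


def _interval_oracle(geno, markers, anchor):
    carriers = geno[geno["carrier"] == 1]
    shared = []
    for name, _pos in markers:
        sets = [set(map(int, g.split("/"))) for g in carriers[name]]
        shared.append(bool(set.intersection(*sets)))
    names = [m for m, _ in markers]
    positions = dict(markers)
    ai = min(range(len(names)), key=lambda i: abs(positions[names[i]] - anchor))
    best = ()
    for lo in range(len(names)):
        for hi in range(lo, len(names)):
            if all(shared[lo:hi + 1]) and lo <= ai <= hi:
                if hi - lo + 1 > len(best):
                    best = tuple(names[lo:hi + 1])
    return best


class TestSharedHaplotype:
    def test_planted_interval_recovered(self):
        interval = (MARKERS[2][1], MARKERS[4][1])
        geno, _ = synthetic.simulate_str_families(4, MARKERS, interval, seed=81)
        result = shared_haplotype(geno, MARKERS, ANCHOR)
        assert result.interval_markers == tuple(m for m, p in MARKERS if interval[0] <= p <= interval[1])
        assert result.interval_len == MARKERS[4][1] - MARKERS[2][1]
        assert result.interval_markers == _interval_oracle(geno, MARKERS, ANCHOR)

    def test_no_common_allele_yields_empty_interval(self):
        geno, _ = synthetic.simulate_str_families(4, MARKERS, None, seed=82)
        result = shared_haplotype(geno, MARKERS, ANCHOR)
        assert result.interval_markers == ()
        assert result.interval_len == 0

    def test_identical_homozygous_carriers_span_all_markers(self):
        rows = []
        for fam, ind in [("A", "A_1"), ("B", "B_1"), ("C", "C_1")]:
            row = {"family": fam, "individual": ind, "carrier": 1}
            row.update({m: "200/200" for m, _ in MARKERS})
            rows.append(row)
        geno = pd.DataFrame(rows)
        result = shared_haplotype(geno, MARKERS, ANCHOR)
        assert result.interval_markers == tuple(m for m, _ in MARKERS)

    def test_allele_order_within_pair_is_irrelevant(self):
        interval = (MARKERS[1][1], MARKERS[5][1])
        geno, _ = synthetic.simulate_str_families(3, MARKERS, interval, seed=83)
        flipped = geno.copy()
        for m, _ in MARKERS:
            flipped[m] = flipped[m].map(lambda g: "/".join(reversed(g.split("/"))))
        a = shared_haplotype(geno, MARKERS, ANCHOR)
        b = shared_haplotype(flipped, MARKERS, ANCHOR)
        assert a.interval_markers == b.interval_markers

    def test_adding_noncarrier_never_changes_interval(self):
        interval = (MARKERS[2][1], MARKERS[5][1])
        geno, _ = synthetic.simulate_str_families(4, MARKERS, interval, seed=84)
        before = shared_haplotype(geno, MARKERS, ANCHOR)
        rng = random.Random(85)
        extra = {"family": "Z", "individual": "Z_9", "carrier": 0}
        extra.update({m: f"{rng.randrange(150, 400, 2)}/{rng.randrange(150, 400, 2)}" for m, _ in MARKERS})
        geno2 = pd.concat([geno, pd.DataFrame([extra])], ignore_index=True)
        after = shared_haplotype(geno2, MARKERS, ANCHOR)
        assert before.interval_markers == after.interval_markers

    def test_random_tables_match_run_scan_oracle(self):
        rng = random.Random(86)
        for _ in range(30):
            lo = rng.randint(0, len(MARKERS) - 1)
            hi = rng.randint(lo, len(MARKERS) - 1)
            interval = (MARKERS[lo][1], MARKERS[hi][1])
            geno, _ = synthetic.simulate_str_families(
                rng.randint(2, 4), MARKERS, interval, seed=rng.randint(0, 10**6)
            )
            result = shared_haplotype(geno, MARKERS, ANCHOR)
            assert result.interval_markers == _interval_oracle(geno, MARKERS, ANCHOR)

    def test_subset_intervals_extend_the_full_interval(self):
        interval = (MARKERS[3][1], MARKERS[4][1])
        geno, _ = synthetic.simulate_str_families(4, MARKERS, interval, seed=87)
        results = shared_haplotype_subsets(geno, MARKERS, ANCHOR)
        assert len(results[0].families) == 4
        full_len = results[0].interval_len
        assert all(h.interval_len >= 0 for h in results)
        assert all(
            h.interval_len >= full_len for h in results if len(h.families) == 4
        )

    def test_no_carriers_rejected(self):
        geno, _ = synthetic.simulate_str_families(2, MARKERS, None, seed=88)
        geno["carrier"] = 0
        with pytest.raises(ValueError, match="no carriers"):
            shared_haplotype(geno, MARKERS, ANCHOR)
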