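import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexsig import (ContingencyTable, DrugSignature, GeneClassSets,
                    SignatureCollection, ValidationError, associate_drugs,
                    build_contingency, fisher_exact, rank_and_report,
                    sample_odds_ratio)


def fisher_oracle(a, b, c, d, alternative="two_sided"):
    """Exact-rational hypergeometric enumeration over fixed margins.

    Two-sided: sum probabilities of tables no more probable than observed,
    with the conventional 1+1e-7 relative tolerance applied in integer
    arithmetic.  Greater: upper tail on cell a.
    """
    n, r, cc = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + cc - n), min(r, cc)
    num = {k: math.comb(r, k) * math.comb(n - r, cc - k)
           for k in range(lo, hi + 1)}
    denom = math.comb(n, cc)
    if alternative == "greater":
        tot = sum(v for k, v in num.items() if k >= a)
    else:
        tot = sum(v for v in num.values()
                  if v * 10**7 <= num[a] * (10**7 + 1))
    return Fraction(tot, denom)


class TestBuildContingency:
    def test_overlap_counts(self):
        universe = [f"g{i}" for i in range(100)]
        x = universe[:10]
        y = universe[5:25]
        t = build_contingency(x, y, universe)
        assert (t.a, t.b, t.c, t.d) == (5, 5, 15, 75)
        assert t.universe_size == 100

    def test_full_overlap_degenerate(self):
        u = [f"g{i}" for i in range(7)]
        t = build_contingency(u, u, u)
        assert (t.a, t.b, t.c, t.d) == (7, 0, 0, 0)

    def test_disjoint_sets(self):
        u = [f"g{i}" for i in range(10)]
        t = build_contingency(u[:3], u[3:7], u)
        assert (t.a, t.b, t.c, t.d) == (0, 3, 4, 3)

    def test_sets_are_intersected_with_universe(self):
        t = build_contingency(["g1", "zz"], ["g1"], ["g1", "g2"])
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValidationError):
            build_contingency(["g1"], ["g1"], [])


class TestFisherExact:
    @pytest.mark.parametrize("table, expected", [
        ((3, 1, 1, 3), Fraction(34, 70)),
        ((5, 0, 0, 5), Fraction(2, 252)),
        ((0, 0, 0, 7), Fraction(1)),
    ])
    def test_enumeration_examples(self, table, expected):
        p, _ = fisher_exact(ContingencyTable(*table))
        assert p == pytest.approx(float(expected), abs=1e-12)

    def test_matches_oracle_on_exhaustive_small_tables(self):
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        for alt in ("two_sided", "greater"):
                            p, _ = fisher_exact(ContingencyTable(a, b, c, d),
                                                alt)
                            assert p == pytest.approx(
                                float(fisher_oracle(a, b, c, d, alt)),
                                abs=1e-10)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_two_sided_p_invariant_under_transpose_and_swaps(self, cells):
        a, b, c, d = cells
        base, _ = fisher_exact(ContingencyTable(a, b, c, d))
        transposed, _ = fisher_exact(ContingencyTable(a, c, b, d))
        swapped, _ = fisher_exact(ContingencyTable(d, c, b, a))
        assert base == pytest.approx(transposed, abs=1e-12)
        assert base == pytest.approx(swapped, abs=1e-12)

    def test_greater_p_never_increases_with_overlap(self):
        # move one gene from b,c into a,d holding margin complements fixed
        ps = [fisher_exact(ContingencyTable(a, 10 - a, 10 - a, 80 + a),
                           "greater")[0] for a in range(11)]
        assert np.all(np.diff(ps) <= 1e-12)

    def test_sample_odds_ratio_plain_and_continuity(self):
        assert sample_odds_ratio(ContingencyTable(6, 3, 2, 4)) == (4.0, False)
        odds, corrected = sample_odds_ratio(ContingencyTable(5, 0, 0, 5))
        assert corrected and odds == pytest.approx(5.5**2 / 0.25)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 0, 0, 1)


def _classes(mg, fg, universe):
    return GeneClassSets(frozenset(mg), frozenset(fg), frozenset(universe))


def _collection(sigs):
    return SignatureCollection(list(sigs))


class TestAssociateDrugs:
    def test_perfect_signature_composes_the_oracles(self):
        universe = [f"g{i}" for i in range(200)]
        mg, fg = universe[:10], universe[10:20]
        classes = _classes(mg, fg, universe)
        sig = DrugSignature("hit", frozenset(mg), frozenset(fg),
                            frozenset(universe))
        (res,) = associate_drugs(classes, _collection([sig]))
        assert (res.table_overall.a, res.table_overall.b,
                res.table_overall.c, res.table_overall.d) == (20, 0, 0, 180)
        expected = float(fisher_oracle(20, 0, 0, 180))
        assert res.p_overall == pytest.approx(expected, abs=1e-12)
        assert res.rank == 1
        assert res.tables_directional["mg_up"].a == 10
        assert res.tables_directional["fg_down"].a == 10

    def test_drug_outside_universe_is_skipped(self):
        universe = [f"g{i}" for i in range(50)]
        classes = _classes(universe[:5], [], universe)
        inside = DrugSignature("in", frozenset(universe[:3]), frozenset(),
                               frozenset(universe))
        outside = DrugSignature("out", frozenset(["x1"]), frozenset(["x2"]),
                                frozenset(["x1", "x2"]))
        results = associate_drugs(classes, _collection([inside, outside]))
        assert [r.drug_id for r in results] == ["in"]

    def test_zero_testable_drugs_is_an_error(self):
        classes = _classes(["g1"], [], ["g1", "g2"])
        sig = DrugSignature("out", frozenset(["x1"]), frozenset(),
                            frozenset(["x1"]))
        with pytest.raises(ValidationError, match="zero drugs"):
            associate_drugs(classes, _collection([sig]))

    def test_q_values_and_ranks_are_consistent(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(300)]
        classes = _classes(universe[:15], universe[15:30], universe)
        sigs = []
        for k in range(25):
            picks = rng.choice(universe, 30, replace=False)
            sigs.append(DrugSignature(f"d{k:02d}", frozenset(picks[:15]),
                                      frozenset(picks[15:]),
                                      frozenset(universe)))
        results = associate_drugs(classes, _collection(sigs))
        assert sorted(r.rank for r in results) == list(range(1, 26))
        for r in results:
            assert r.q_value >= r.p_overall - 1e-15
        by_rank = sorted(results, key=lambda r: r.rank)
        assert all(r1.p_overall <= r2.p_overall + 1e-15
                   for r1, r2 in zip(by_rank, by_rank[1:]))

    def test_expression_side_universe_policy(self):
        universe = [f"g{i}" for i in range(50)]
        classes = _classes(universe[:5], [], universe)
        sig = DrugSignature("d", frozenset(universe[:3]), frozenset(),
                            frozenset(universe[:10]))  # small measured set
        (res_int,) = associate_drugs(classes, _collection([sig]),
                                     "intersection")
        (res_expr,) = associate_drugs(classes, _collection([sig]),
                                      "expression_side")
        assert res_int.table_overall.universe_size == 10
        assert res_expr.table_overall.universe_size == 50


class TestRankAndReport:
    def _result(self, drug, p, odds=2.0, rank=None):
        t = ContingencyTable(2, 3, 4, 41)
        from sexsig import DrugAssociationResult
        return DrugAssociationResult(
            drug_id=drug, table_overall=t,
            tables_directional={k: t for k in
                                ("mg_up", "mg_down", "fg_up", "fg_down")},
            odds_ratio=odds, or_continuity_corrected=False, p_overall=p,
            p_directional={k: p for k in
                           ("mg_up", "mg_down", "fg_up", "fg_down")},
            q_value=p, rank=rank)

    def test_sorted_by_p_then_odds_then_id(self):
        universe = [f"g{i}" for i in range(100)]
        classes = _classes(universe[:8], [], universe)
        rng = np.random.default_rng(9)
        sigs = [DrugSignature(f"d{k}",
                              frozenset(rng.choice(universe, 10,
                                                   replace=False)),
                              frozenset(), frozenset(universe))
                for k in range(6)]
        results = associate_drugs(classes, _collection(sigs))
        rows = rank_and_report(results, top_n=6)
        ps = [row["p_overall"] for row in rows]
        assert ps == sorted(ps)
        assert [row["rank"] for row in rows] == [1, 2, 3, 4, 5, 6]

    def test_ties_broken_by_descending_odds_ratio(self):
        r1 = self._result("b_drug", 0.01, odds=1.5, rank=2)
        r2 = self._result("a_drug", 0.01, odds=3.0, rank=1)
        rows = rank_and_report([r1, r2], top_n=2)
        assert [r["drug_id"] for r in rows] == ["a_drug", "b_drug"]

    def test_truncates_to_top_n(self):
        results = [self._result(f"d{k}", 0.01 * (k + 1), rank=k + 1)
                   for k in range(30)]
        assert len(rank_and_report(results, top_n=20)) == 20

    def test_top_n_beyond_results_returns_all_with_warning(self):
        results = [self._result("d1", 0.01, rank=1)]
        assert len(rank_and_report(results, top_n=5)) == 1

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            rank_and_report([], top_n=1)
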