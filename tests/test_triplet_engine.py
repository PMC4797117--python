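"""Tests for triplet enumeration, the decision table, correction, tallies."""

import numpy as np
import pandas as pd
import pytest

from mlhgrn.errors import ConfigurationError, InputError
from mlhgrn.triplet_engine import (
    TripletResult,
    classify_triplet,
    correct_pvalues,
    evaluate_layer,
    evaluate_triplet,
    tally_interference,
)


def _frame(rows, prefix):
    ids = [f"{prefix}{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids)


class TestClassifyTriplet:
    @pytest.mark.parametrize(
        "p1, p2, p3, expected",
        [
            (0.001, 0.5, None, (1, True)),    # correlated, partial wiped out
            (0.01, 0.01, 0.2, (2, False)),    # both stand, difference unremarkable
            (0.01, 0.01, 0.01, (2, True)),    # both stand, difference real
            (0.5, 0.01, None, (3, True)),     # correlation emerges only given z
            (0.5, 0.5, None, (4, False)),     # nothing to see
        ],
    )
    def test_decision_table(self, p1, p2, p3, expected):
        assert classify_triplet(p1, p2, p3) == expected

    @pytest.mark.parametrize(
        "p1, p2, expected_circ",
        [
            (0.05, 0.04, 3),     # p1 at the boundary is NOT significant
            (0.04, 0.05, 1),
            (0.05, 0.05, 4),
            (0.0, 1.0, 1),
            (1.0, 0.0, 3),
        ],
    )
    def test_strict_boundaries(self, p1, p2, expected_circ):
        circ, _ = classify_triplet(p1, p2, 0.5 if expected_circ == 2 else None)
        assert circ == expected_circ

    def test_missing_p3_is_contract_error(self):
        with pytest.raises(ValueError, match="p3"):
            classify_triplet(0.01, 0.01, None)

    def test_bad_pvalue_rejected(self):
        with pytest.raises(ValueError):
            classify_triplet(1.5, 0.1, None)


class TestEvaluateTriplet:
    def test_common_driver_is_detected(self, rng):
        hits = 0
        for _ in range(200):
            z = rng.standard_normal(200)
            x = z + 0.5 * rng.standard_normal(200)
            y = z + 0.5 * rng.standard_normal(200)
            if evaluate_triplet(x, y, z).interferes:
                hits += 1
        assert hits >= 180     # >= 90 % power at this signal strength

    def test_independent_regulator_rarely_interferes(self, rng):
        hits = 0
        for _ in range(200):
            shared = rng.standard_normal(500)
            x = shared + rng.standard_normal(500)
            y = shared + rng.standard_normal(500)
            z = rng.standard_normal(500)
            if evaluate_triplet(x, y, z).interferes:
                hits += 1
        assert hits / 200 <= 0.10

    def test_identical_pair_is_well_defined(self, rng):
        x = rng.standard_normal(60)
        res = evaluate_triplet(x, x.copy(), rng.standard_normal(60))
        assert res.circumstance in (1, 2, 3, 4)
        assert res.r_xy == pytest.approx(1.0)


class TestEvaluateLayer:
    def test_triplet_count(self, rng):
        bottom = _frame(rng.standard_normal((3, 30)), "b")
        cand = _frame(rng.standard_normal((2, 30)), "c")
        res = evaluate_layer(bottom, cand, keep_discarded=True)
        assert len(res) == 6       # C(3,2) * 2

    def test_empty_candidates(self, rng):
        bottom = _frame(rng.standard_normal((3, 30)), "b")
        cand = _frame(np.empty((0, 30)), "c")
        assert evaluate_layer(bottom, cand) == []

    def test_overlapping_ids_rejected(self, rng):
        bottom = _frame(rng.standard_normal((3, 30)), "g")
        cand = _frame(rng.standard_normal((3, 30)), "g")
        with pytest.raises(InputError, match="g0"):
            evaluate_layer(bottom, cand)

    def test_matches_scalar_path(self, rng):
        bottom = _frame(rng.standard_normal((4, 50)), "b")
        cand = _frame(rng.standard_normal((3, 50)), "c")
        res = evaluate_layer(bottom, cand, keep_discarded=True)
        for t in res:
            single = evaluate_triplet(
                bottom.loc[t.x_id], bottom.loc[t.y_id], cand.loc[t.z_id],
                x_id=t.x_id, y_id=t.y_id, z_id=t.z_id,
            )
            assert single.r_xy == pytest.approx(t.r_xy, abs=1e-12)
            assert single.r_xy_given_z == pytest.approx(t.r_xy_given_z, abs=1e-12)
            assert single.p1 == pytest.approx(t.p1, abs=1e-12)
            assert single.p2 == pytest.approx(t.p2, abs=1e-12)
            assert single.circumstance == t.circumstance
            assert single.interferes == t.interferes

    def test_row_order_does_not_matter(self, rng):
        bottom = _frame(rng.standard_normal((5, 40)), "b")
        cand = _frame(rng.standard_normal((4, 40)), "c")
        res1 = evaluate_layer(bottom, cand)
        res2 = evaluate_layer(bottom.iloc[::-1], cand.sample(frac=1, random_state=0))
        key = lambda t: (t.x_id, t.y_id, t.z_id)
        assert sorted(map(key, res1)) == sorted(map(key, res2))
        assert [t.interferes for t in sorted(res1, key=key)] == [
            t.interferes for t in sorted(res2, key=key)
        ]


def _mk(z_id, circ, p, interferes=True, x="a", y="b"):
    p1 = p if circ == 1 else (0.01 if circ == 2 else 0.5)
    p2 = p if circ == 3 else (0.01 if circ == 2 else 0.5)
    p3 = p if circ == 2 else None
    return TripletResult(x, y, z_id, 0.5, 0.2, p1, p2, p3, circ, interferes)


class TestCorrectPvalues:
    def test_bh_step_up_all_pass(self):
        results = [_mk(f"z{i}", 1, p, x="a", y=f"b{i}")
                   for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        out = correct_pvalues(results, "fdr_bh", alpha=0.05)
        # BH step-up: p_(i) <= i/m * alpha holds at the last rank, all kept
        assert all(t.interferes for t in out)
        assert out[-1].p_adjusted == pytest.approx(0.04)

    def test_equal_raw_gives_equal_adjusted(self):
        results = [_mk(f"z{i}", 2, 0.02) for i in range(5)]
        out = correct_pvalues(results, "fdr_bh")
        assert len({t.p_adjusted for t in out}) == 1

    def test_single_triplet_unchanged(self):
        out = correct_pvalues([_mk("z", 3, 0.03)], "fdr_bh")
        assert out[0].p_adjusted == pytest.approx(0.03)

    def test_bonferroni_and_none(self):
        results = [_mk(f"z{i}", 1, 0.02) for i in range(4)]
        bonf = correct_pvalues(results, "bonferroni")
        assert bonf[0].p_adjusted == pytest.approx(0.08)
        assert not bonf[0].interferes
        raw = correct_pvalues(results, "none")
        assert raw[0].p_adjusted == pytest.approx(0.02)
        assert raw[0].interferes

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError, match="unknown correction"):
            correct_pvalues([_mk("z", 1, 0.01)], "fdr_tsbh_typo")

    def test_p3_only_mode_leaves_circ1_standing(self):
        results = [_mk("z1", 1, 0.04), _mk("z2", 2, 0.04)]
        out = correct_pvalues(results, "bonferroni", mode="p3_only")
        assert out[0].p_adjusted is None and out[0].interferes
        assert out[1].p_adjusted == pytest.approx(0.04)

    def test_global_null_fdr_controlled(self, rng):
        # all genes independent: after BH at q, interfering fraction is tiny
        bottom = _frame(rng.standard_normal((8, 100)), "b")
        cand = _frame(rng.standard_normal((30, 100)), "c")
        res = correct_pvalues(evaluate_layer(bottom, cand), "fdr_bh", 0.05)
        frac = sum(t.interferes for t in res) / (28 * 30)
        assert frac <= 0.05 + 0.02


class TestTally:
    def test_empty(self):
        assert tally_interference([]) == []

    def test_counts_pairs(self):
        results = [
            _mk("z", 1, 0.01, x="a", y="b"),
            _mk("z", 1, 0.01, x="a", y="c"),
            _mk("w", 2, 0.5, interferes=False),
        ]
        tal = tally_interference(results)
        assert len(tal) == 1
        assert tal[0].z_id == "z" and tal[0].count == 2
        assert tal[0].pairs == [("a", "b"), ("a", "c")]

    def test_matches_brute_force_recount(self, rng):
        results = []
        for i in range(300):
            z = f"z{rng.integers(5)}"
            results.append(
                _mk(z, 1, 0.01, interferes=bool(rng.integers(2)),
                    x=f"a{rng.integers(6)}", y=f"b{rng.integers(6)}")
            )
        tal = tally_interference(results)
        brute = {}
        for t in results:
            if t.interferes:
                brute[t.z_id] = brute.get(t.z_id, 0) + 1
        assert {t.z_id: t.count for t in tal} == brute
        assert sum(t.count for t in tal) == sum(t.interferes for t in results)
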