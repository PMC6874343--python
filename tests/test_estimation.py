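"""Item calibration, person MLE, EM refinement, and the paired summary."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import sdtlatent as sl
from sdtlatent.estimation import total_log_likelihood


def wilson_closed_form(x, n, conf=0.95):
    z = norm.ppf(0.5 + conf / 2)
    p = x / n
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z / (1 + z**2 / n) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return center - half, center + half


class TestWilsonCI:
    def test_symmetric_at_half(self):
        lo, hi = sl.wilson_ci(5, 10, 0.95)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)
        assert lo < 0.5 < hi

    @pytest.mark.parametrize("x,n", [(47, 49), (1, 12), (30, 60)])
    def test_matches_closed_form(self, x, n):
        lo, hi = sl.wilson_ci(x, n, 0.95)
        elo, ehi = wilson_closed_form(x, n)
        assert lo == pytest.approx(elo, abs=1e-10)
        assert hi == pytest.approx(ehi, abs=1e-10)
        assert lo < x / n < hi

    def test_degenerate_counts_stay_inside_unit_interval(self):
        lo, hi = sl.wilson_ci(0, 10, 0.95)
        assert 0.0 < lo < hi < 0.5
        lo, hi = sl.wilson_ci(10, 10, 0.95)
        assert 0.5 < lo < hi < 1.0

    @pytest.mark.parametrize("x,n,conf", [(-1, 10, 0.95), (11, 10, 0.95),
                                          (5, 0, 0.95), (5, 10, 1.0)])
    def test_rejects_invalid_arguments(self, x, n, conf):
        with pytest.raises(ValueError):
            sl.wilson_ci(x, n, conf)


def _item_table(n_correct, n_total, m=2, item_id="it"):
    rows = [(f"p{k}", item_id, m, 1 if k < n_correct else 0) for k in range(n_total)]
    return pd.DataFrame(rows, columns=["person_id", "item_id", "m", "score"])


class TestCalibrateItems:
    @pytest.mark.parametrize("x,n,expected", [
        (44, 46, -2.4207), (48, 51, -2.2129), (43, 46, -2.1388)])
    def test_two_afc_inversion(self, x, n, expected):
        # b = -sqrt(2) Phi^-1(x/n) for 2-AFC items against the average person
        (est,) = sl.calibrate_items(_item_table(x, n))
        assert est.b == pytest.approx(expected, abs=5e-4)
        assert est.ci_low < est.b < est.ci_high
        assert not est.degenerate_flag

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_chance_score_gives_zero_b(self, m):
        (est,) = sl.calibrate_items(_item_table(10, 10 * m, m=m))
        assert est.b == pytest.approx(0.0, abs=1e-8)

    def test_ci_mapping_order_flip(self):
        # higher probability correct = easier item = lower b, so the Wilson
        # endpoints swap roles after negation
        (est,) = sl.calibrate_items(_item_table(40, 50))
        lo_p, hi_p = sl.wilson_ci(40, 50, 0.95)
        assert est.ci_low == pytest.approx(-sl.dprime_from_pc(hi_p, 2), abs=1e-9)
        assert est.ci_high == pytest.approx(-sl.dprime_from_pc(lo_p, 2), abs=1e-9)

    def test_perfect_score_flagged_and_finite(self):
        (est,) = sl.calibrate_items(_item_table(20, 20))
        assert est.degenerate_flag
        assert np.isfinite(est.b)
        # adjusted proportion (x + 0.5) / (n + 1)
        assert est.b == pytest.approx(-sl.dprime_from_pc(20.5 / 21, 2), abs=1e-9)

    def test_easier_item_has_lower_b(self, small_complete_table):
        items = sl.calibrate_items(small_complete_table)
        by_m = {}
        for it in items:
            by_m.setdefault((it.m, it.n_total), []).append(it)
        for group in by_m.values():
            group.sort(key=lambda it: it.n_correct)
            bs = [it.b for it in group]
            assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(bs, bs[1:]))


class TestFitPerson:
    def test_symmetric_responses_give_zero(self):
        est = sl.fit_person([(0.0, 2)], [(0.0, 2)])
        assert est.theta == pytest.approx(0.0, abs=1e-5)
        assert est.se > 0
        assert not est.degenerate_flag

    def test_recovers_true_ability_against_grid_search(self, rng):
        bs = rng.normal(0.0, 1.0, 50)
        theta_true = 1.0
        scores = rng.random(50) < sl.pc_from_dprime(theta_true - bs, 2)
        cor = [(b, 2) for b, s in zip(bs, scores) if s]
        inc = [(b, 2) for b, s in zip(bs, scores) if not s]
        est = sl.fit_person(cor, inc)
        assert abs(est.theta - theta_true) < 3 * est.se
        # independent dense grid search oracle
        grid = np.arange(-6.0, 6.0, 1e-3)
        ll = np.zeros_like(grid)
        for b, m in cor:
            ll += np.log(sl.pc_from_dprime(grid - b, m))
        for b, m in inc:
            ll += np.log1p(-sl.pc_from_dprime(grid - b, m))
        assert abs(grid[np.argmax(ll)] - est.theta) < 2e-3

    def test_all_correct_is_degenerate_at_bound(self):
        est = sl.fit_person([(0.0, 2), (-1.0, 3)], [])
        assert est.degenerate_flag and est.theta == 10.0

    def test_all_incorrect_is_degenerate_at_lower_bound(self):
        est = sl.fit_person([], [(0.0, 2)])
        assert est.degenerate_flag and est.theta == -10.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sl.fit_person([], [])


class TestFitAllPersons:
    def test_ids_preserved_and_order_invariant(self, small_complete_table):
        items = sl.calibrate_items(small_complete_table)
        a = sl.fit_all_persons(small_complete_table, items)
        shuffled = small_complete_table.sample(frac=1.0, random_state=1)
        b = sl.fit_all_persons(shuffled, items)
        assert [p.person_id for p in a] == [p.person_id for p in b]
        assert [p.theta for p in a] == pytest.approx([p.theta for p in b], abs=1e-12)
        assert len(a) == small_complete_table["person_id"].nunique()

    def test_single_correct_response_degenerate(self):
        tab = pd.DataFrame({"person_id": ["p"], "item_id": ["a"], "m": [2], "score": [1]})
        items = [sl.ItemEstimate("a", 0.0, -0.5, 0.5, 1, 1, 2, False)]
        (est,) = sl.fit_all_persons(tab, items)
        assert est.degenerate_flag

    def test_unknown_item_raises(self, tiny_table):
        with pytest.raises(KeyError, match="b"):
            sl.fit_all_persons(tiny_table, [sl.ItemEstimate("a", 0.0, -1, 1, 1, 2, 2, False)])


class TestFitEM:
    def test_stopping_rule_and_anchoring(self, small_complete_table):
        fr = sl.fit_em(small_complete_table, tol=1e-4, max_iter=50)
        assert fr.converged
        assert fr.trace[-1][1] < 1e-4
        anchored = [p.theta for p in fr.persons if not p.degenerate_flag]
        assert np.mean(anchored) == pytest.approx(0.0, abs=1e-9)

    def test_log_likelihood_non_decreasing(self, small_complete_table):
        fr = sl.fit_em(small_complete_table, tol=1e-4, max_iter=50)
        lls = [t[2] for t in fr.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_translation_invariance_of_likelihood(self, small_complete_table):
        fr = sl.fit_em(small_complete_table, tol=1e-3, max_iter=10)
        shifted_items = [dataclasses.replace(i, b=i.b + 0.7) for i in fr.items]
        shifted_persons = [dataclasses.replace(p, theta=p.theta + 0.7) for p in fr.persons]
        ll0 = total_log_likelihood(small_complete_table, fr.items, fr.persons)
        ll1 = total_log_likelihood(small_complete_table, shifted_items, shifted_persons)
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_max_iter_reached_reports_not_converged(self, small_complete_table):
        fr = sl.fit_em(small_complete_table, tol=1e-12, max_iter=2)
        assert not fr.converged
        assert fr.n_iterations == 2

    def test_invalid_controls_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            sl.fit_em(tiny_table, tol=0.0)
        with pytest.raises(ValueError):
            sl.fit_em(tiny_table, max_iter=0)


class TestSummarizePairedEffect:
    def _persons(self, thetas, prefix="s"):
        return [sl.PersonEstimate(f"{prefix}{i}", t, 0.1, 10, False)
                for i, t in enumerate(thetas)]

    def test_identical_sets_give_zero(self):
        a = self._persons([0.3, -0.2, 1.1])
        eff = sl.summarize_paired_effect(a, a)
        assert eff.mean_diff == 0.0
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_exact_shift_recovered(self):
        a = self._persons([0.3, -0.2, 1.1, 0.0])
        b = self._persons([0.8, 0.3, 1.6, 0.5])
        eff = sl.summarize_paired_effect(a, b)
        assert eff.mean_diff == pytest.approx(0.5, abs=1e-12)
        assert eff.n == 4

    def test_mismatched_ids_rejected(self):
        a = self._persons([0.0, 1.0])
        b = self._persons([0.0, 1.0], prefix="x")
        with pytest.raises(KeyError):
            sl.summarize_paired_effect(a, b)


class TestValidation:
    def test_duplicate_pair_rejected(self, tiny_table):
        bad = pd.concat([tiny_table, tiny_table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            sl.validate_responses(bad)

    def test_inconsistent_m_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[2, "m"] = 3
        with pytest.raises(ValueError, match="inconsistent m"):
            sl.validate_responses(bad)

    def test_bad_score_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[0, "score"] = 2
        with pytest.raises(ValueError, match="score"):
            sl.validate_responses(bad)
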