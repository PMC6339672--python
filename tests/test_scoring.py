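import numpy as np
import pytest

import irtlink as il
from irtlink.core import ItemBank, ItemParams, QuadGrid, _probs_matrix
from irtlink.data import MISSING, ResponseData
from irtlink.scoring import (
    MetricError,
    congruence_report,
    conditional_reliability,
    cronbach_alpha,
    eap_score,
    eap_scores,
    glb_reliability,
    locate_metric_origin,
    marginal_reliability,
    rescale_summed,
    score_correlations,
    standardize_score,
)


def _simulate_bank(bank, n, seed, theta=None, dataset="V"):
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = rng.normal(0, 1, n)
    ids = bank.item_ids
    X = np.empty((n, len(ids)), dtype=np.int16)
    for k, iid in enumerate(ids):
        it = bank[iid]
        cum = np.cumsum(_probs_matrix(it.a, np.asarray(it.b), theta), axis=1)
        X[:, k] = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
    data = ResponseData(
        X, np.array([f"p{i}" for i in range(n)]), list(ids),
        np.full(n, dataset, dtype=object),
    )
    return data, theta


def _instrument(ins, n_items, loc_range, seed, n_cat=4):
    rng = np.random.default_rng(seed)
    items = []
    for j in range(n_items):
        a = float(np.exp(rng.normal(0.1, 0.25)))
        loc = float(rng.uniform(*loc_range))
        steps = loc + (np.arange(n_cat - 1) - (n_cat - 2) / 2) * 0.7
        items.append(ItemParams(f"{ins}_i{j}", a, tuple(steps), {ins}))
    return items


class TestEapScore:
    def test_all_missing_returns_prior(self, small_bank):
        res = eap_score(small_bank, {})
        assert res.all_missing
        assert res.theta == pytest.approx(0.0, abs=1e-9)
        assert res.se == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_item_middle_category(self):
        bank = ItemBank([ItemParams("s", 1.0, (-1.0, 1.0), {"I"})])
        res = eap_score(bank, {"s": 1})
        assert res.theta == pytest.approx(0.0, abs=1e-9)

    def test_invalid_category_rejected(self, small_bank):
        with pytest.raises(ValueError):
            eap_score(small_bank, {"A_i2": 5})

    def test_against_fine_trapezoid_oracle(self, small_bank):
        """Brute-force 10,001-point trapezoid posterior-mean integration."""
        pattern = {"A_i0": 2, "A_i1": 1, "A_i2": 0, "B_i0": 3}
        grid_t = np.linspace(-8, 8, 10_001)
        log_post = -0.5 * grid_t**2
        for iid, x in pattern.items():
            it = small_bank[iid]
            # direct closed-form evaluation, independent implementation
            m = it.max_score
            num = np.zeros((len(grid_t), m + 1))
            for k in range(m + 1):
                num[:, k] = np.exp(
                    sum(it.a * (grid_t - it.b[v]) for v in range(k))
                    if k
                    else np.zeros(len(grid_t))
                )
            p = num / num.sum(axis=1, keepdims=True)
            log_post += np.log(p[:, x])
        w = np.exp(log_post - log_post.max())
        oracle = np.trapezoid(w * grid_t, grid_t) / np.trapezoid(w, grid_t)
        res = eap_score(
            small_bank, pattern, grid=QuadGrid.equally_spaced(-8, 8, 1001)
        )
        assert res.theta == pytest.approx(oracle, abs=1e-4)

    def test_shrinkage_toward_prior(self, small_bank):
        # posterior mean lies between 0 and the extreme pattern's direction
        high = {i: small_bank[i].max_score for i in small_bank.item_ids}
        res = eap_score(small_bank, high)
        assert 0 < res.theta < 8
        fewer = {"A_i0": 2}
        assert 0 < eap_score(small_bank, fewer).theta < res.theta

    def test_batch_matches_single(self, small_bank):
        data, _ = _simulate_bank(small_bank, 50, 4)
        batch = eap_scores(small_bank, data)
        for i in (0, 13, 49):
            pattern = {
                iid: int(data.X[i, data.col(iid)]) for iid in data.item_ids
            }
            single = eap_score(small_bank, pattern)
            assert batch["theta"][i] == pytest.approx(single.theta, abs=1e-10)
            assert batch["se"][i] == pytest.approx(single.se, abs=1e-10)


class TestMetricOrigin:
    def test_definitional_epsilon(self, small_bank):
        theta0 = locate_metric_origin(small_bank, epsilon=0.01)
        for ins in small_bank.instrument_ids:
            items = small_bank.instrument_items(ins)
            mean_score = np.mean(
                [il.expected_item_score(it, theta0) for it in items]
            )
            assert mean_score <= 0.01 + 1e-12

    def test_translation_property(self, small_bank):
        theta0 = locate_metric_origin(small_bank, epsilon=0.01)
        shifted = ItemBank(
            [
                ItemParams(it.item_id, it.a, tuple(np.array(it.b) + 1.0),
                           it.instrument_ids)
                for it in small_bank
            ]
        )
        theta0_shifted = locate_metric_origin(shifted, epsilon=0.01)
        grid_step = 16 / 60
        assert theta0_shifted - theta0 == pytest.approx(1.0, abs=grid_step + 1e-9)

    def test_epsilon_zero_warns_and_floors(self, small_bank):
        with pytest.warns(RuntimeWarning):
            theta0 = locate_metric_origin(small_bank, epsilon=0.0)
        assert theta0 == -8.0

    def test_origin_stable_under_grid_refinement(self, small_bank):
        t1 = locate_metric_origin(
            small_bank, grid=QuadGrid.equally_spaced(-8, 8, 61)
        )
        t2 = locate_metric_origin(
            small_bank, grid=QuadGrid.equally_spaced(-8, 8, 121)
        )
        assert abs(t1 - t2) <= 16 / 60 + 1e-12


class TestStandardize:
    def test_ten_points_per_logit(self, small_bank):
        theta0 = locate_metric_origin(small_bank)
        assert standardize_score(theta0, small_bank) == 0.0
        assert standardize_score(theta0 + 1.0, small_bank) == pytest.approx(10.0)
        assert standardize_score(theta0 + 7.0, small_bank) == pytest.approx(70.0)

    def test_unset_origin_raises(self):
        bank = ItemBank([ItemParams("x", 1.0, (0.0,), {"I"})])
        with pytest.raises(MetricError):
            standardize_score(0.0, bank)


class TestReliability:
    def test_marginal_identity_under_unit_prior(self):
        bank = ItemBank(_instrument("R", 10, (-1.5, 1.5), 7))
        data, _ = _simulate_bank(bank, 2000, 8)
        scores = eap_scores(bank, data)
        rel = marginal_reliability(scores)
        assert rel == pytest.approx(1 - np.mean(scores["se"] ** 2), abs=0.03)

    def test_conditional_reliability_low_info(self):
        bank = ItemBank([ItemParams("weak", 0.05, (0.0,), {"W"})])
        cr = conditional_reliability(bank, "W")
        assert np.all(cr.cr < 0.05)
        assert cr.theta_range is None

    def test_adding_items_never_decreases_cr(self):
        items = _instrument("R", 10, (-1.5, 1.5), 7)
        small = ItemBank(items[:5])
        # rename instrument membership so both banks expose instrument "R"
        big = ItemBank(items)
        cr_small = conditional_reliability(small, "R").cr
        cr_big = conditional_reliability(big, "R").cr
        assert np.all(cr_big >= cr_small - 1e-12)

    def test_cr_range_on_standardized_metric(self):
        bank = ItemBank(_instrument("R", 10, (-1.5, 1.5), 7))
        locate_metric_origin(bank)
        cr = conditional_reliability(bank, "R")
        assert cr.standardized_range is not None
        lo, hi = cr.standardized_range
        assert lo < hi


class TestGlb:
    def test_single_item_undefined(self):
        bank = ItemBank(_instrument("G", 5, (-1, 1), 3))
        data, _ = _simulate_bank(bank, 500, 5)
        with pytest.raises(ValueError):
            glb_reliability(data, ["G_i0"])

    def test_glb_close_to_alpha_for_parallel_items(self):
        # parallel items: identical loadings and uniquenesses
        rng = np.random.default_rng(12)
        n, p = 2000, 6
        theta = rng.normal(0, 1, n)
        X = np.clip(
            np.round(theta[:, None] + rng.normal(0, 1.0, (n, p)) + 2), 0, 4
        ).astype(np.int16)
        data = ResponseData(
            X, np.array([f"p{i}" for i in range(n)]),
            [f"g{j}" for j in range(p)], np.full(n, "D0", dtype=object),
        )
        ids = list(data.item_ids)
        glb = glb_reliability(data, ids)
        alpha = cronbach_alpha(data, ids)
        assert glb == pytest.approx(alpha, abs=0.03)
        assert glb >= alpha - 1e-6

    def test_glb_dominates_alpha(self):
        bank = ItemBank(_instrument("G", 8, (-1.5, 1.5), 9))
        data, _ = _simulate_bank(bank, 1000, 10)
        ids = list(data.item_ids)
        assert glb_reliability(data, ids) >= cronbach_alpha(data, ids) - 1e-6

    def test_too_few_cases_refused(self):
        bank = ItemBank(_instrument("G", 4, (-1, 1), 3))
        data, _ = _simulate_bank(bank, 30, 5)
        with pytest.raises(ValueError, match="complete cases"):
            glb_reliability(data, list(data.item_ids), min_n=50)


class TestScoreCorrelations:
    def test_observed_vs_irt_high(self):
        bank = ItemBank(_instrument("S", 10, (-1.5, 1.5), 20))
        data, _ = _simulate_bank(bank, 1000, 21)
        out = score_correlations(data, bank)
        assert out["observed_irt"]["S"] >= 0.95

    def test_single_item_scale_lower(self):
        items = _instrument("M", 10, (-1.5, 1.5), 22)
        items.append(ItemParams("N_i0", 1.0, (-0.5, 0.5), {"N"}))
        bank = ItemBank(items)
        data, _ = _simulate_bank(bank, 1000, 23)
        out = score_correlations(data, bank)
        assert out["observed_irt"]["N"] < out["observed_irt"]["M"]

    def test_disjoint_scales_same_trait(self):
        items = _instrument("A", 10, (-1.5, 1.5), 24) + _instrument(
            "B", 10, (-1.5, 1.5), 25
        )
        bank = ItemBank(items)
        data, _ = _simulate_bank(bank, 1000, 26)
        out = score_correlations(data, bank)
        r = out["inter_scale"].loc["A", "B"]
        assert r >= 0.70
        assert out["notes"].loc["A", "B"] == ""

    def test_overlap_exclusion_and_nesting(self):
        items_a = _instrument("A", 8, (-1, 1), 27)
        # scale B shares two items with A plus has its own
        items_b = _instrument("B", 6, (-1, 1), 28)
        shared = [
            ItemParams(it.item_id, it.a, it.b, {"A", "B"})
            for it in items_a[:2]
        ]
        bank = ItemBank(shared + items_a[2:] + items_b)
        data, _ = _simulate_bank(bank, 600, 29)
        scales = {
            "A": [i.item_id for i in shared + items_a[2:]],
            "B": [i.item_id for i in shared] + [i.item_id for i in items_b],
            "Bsub": [i.item_id for i in items_b[:3]],
            "Bfull": [i.item_id for i in items_b],
        }
        out = score_correlations(data, bank, scales)
        assert "excluded 2 shared" in out["notes"].loc["A", "B"]
        assert out["notes"].loc["Bsub", "Bfull"] == "nested"
        assert np.isnan(out["inter_scale"].loc["Bsub", "Bfull"])


class TestRescaleSummed:
    @pytest.fixture(scope="class")
    @staticmethod
    def bank():
        # 8 items scored 0-3
        return ItemBank(
            [
                ItemParams(f"U_i{j}", 1.0, (-0.7, 0.0, 0.7), {"U"})
                for j in range(8)
            ]
        )

    def test_extremes(self, bank):
        assert rescale_summed({f"U_i{j}": 0 for j in range(8)}, bank, "U") == 0.0
        assert rescale_summed({f"U_i{j}": 3 for j in range(8)}, bank, "U") == 100.0

    def test_midpoint_arithmetic(self, bank):
        # summed 12 of 24 -> 50
        pattern = {f"U_i{j}": 3 if j < 4 else 0 for j in range(8)}
        assert rescale_summed(pattern, bank, "U") == pytest.approx(50.0)

    def test_missing_response_rejected(self, bank):
        pattern = {f"U_i{j}": 1 for j in range(7)}
        with pytest.raises(ValueError, match="missing"):
            rescale_summed(pattern, bank, "U")


class TestCongruence:
    @pytest.fixture(scope="class")
    @staticmethod
    def overlapping_bank():
        items = []
        for k, ins in enumerate(("I1", "I2", "I3", "I4")):
            items += _instrument(ins, 10, (-1, 1), 50 + k)
        bank = ItemBank(items)
        locate_metric_origin(bank)
        return bank

    def test_requires_two_instruments(self, overlapping_bank):
        data, _ = _simulate_bank(overlapping_bank, 50, 60)
        with pytest.raises(ValueError):
            congruence_report(data, overlapping_bank, ["I1"])

    def test_identical_scores_give_d_zero_p_one(self, overlapping_bank):
        data, _ = _simulate_bank(overlapping_bank, 100, 61)
        rep = congruence_report(data, overlapping_bank, ["I1", "I1"])
        row = rep.irt_pairs.iloc[0]
        assert row["cohen_d"] == 0.0
        assert row["p_raw"] == 1.0

    def test_congruent_instruments_trivial_effects(self, overlapping_bank):
        data, _ = _simulate_bank(overlapping_bank, 250, 62)
        rep = congruence_report(data, overlapping_bank, ["I1", "I2", "I3", "I4"])
        assert rep.irt_pairs["cohen_d"].abs().max() < 0.20
        assert rep.n_comparisons == 6
        assert (rep.irt_pairs["p_bonferroni"] >= rep.irt_pairs["p_raw"] - 1e-12).all()

    def test_disjoint_difficulty_dissociation(self):
        items = (
            _instrument("EZ1", 10, (-2.2, -1.2), 70)
            + _instrument("HARD", 10, (1.2, 2.2), 71)
        )
        bank = ItemBank(items)
        locate_metric_origin(bank)
        data, _ = _simulate_bank(bank, 250, 72)
        rep = congruence_report(data, bank, ["EZ1", "HARD"])
        assert rep.summed_pairs["cohen_d"].abs().max() > 0.50
        assert rep.irt_pairs["cohen_d"].abs().max() < 0.20
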