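"""Burden tests: collapsing, weighted-sum, C-alpha, and the suite grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from extremevar.burden_tests import (
    BurdenConfig,
    burden_suite,
    c_alpha_components,
    c_alpha_test,
    cmc_test,
    collapse_carriers,
    ws_test,
)
from extremevar.errors import AssociationError

from conftest import make_gm, toy_annotations
from oracles import chi_square_2x2


def binomial_gm(q, n, rng, case_q=None, n_cases=0):
    """Cohort with per-variant allele frequencies q (cases may differ)."""
    m = len(q)
    dose = rng.binomial(2, q, size=(n, m)).astype(np.int8)
    if case_q is not None:
        dose[:n_cases] = rng.binomial(2, case_q, size=(n_cases, m)).astype(np.int8)
    return make_gm(dose)


class TestCollapse:
    def test_indicator_examples(self):
        gm = make_gm([[0, 0, 2], [0, 0, 0], [1, 1, 0]])
        assert list(collapse_carriers(gm)) == [1, 0, 1]

    def test_missing_calls_are_non_carrier(self):
        gm = make_gm([[1, 0], [0, 0]], missing=[[True, False], [False, False]])
        assert list(collapse_carriers(gm)) == [0, 0]

    def test_carrier_frequency_closed_form(self):
        # under linkage equilibrium: P(carrier) = 1 - prod_j (1 - q_j)^2
        rng = np.random.default_rng(8)
        q = np.array([0.02, 0.05, 0.01, 0.08])
        gm = binomial_gm(q, 20_000, rng)
        expected = 1 - np.prod((1 - q) ** 2)
        assert collapse_carriers(gm).mean() == pytest.approx(expected, abs=0.01)


class TestCMC:
    def test_identical_rates_give_p_one(self):
        dose = np.zeros((100, 1), dtype=np.int8)
        dose[:10, 0] = 1      # 10/50 carriers in each half
        dose[50:60, 0] = 1
        gm = make_gm(dose)
        hyper = np.arange(100) < 50
        res = cmc_test(gm, hyper, BurdenConfig(rarity_filter="all"))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "0"

    def test_chi_square_matches_textbook_oracle(self):
        dose = np.zeros((100, 1), dtype=np.int8)
        dose[:20, 0] = 1      # 20/50 carriers in hyper
        dose[50:55, 0] = 1    # 5/50 in hypo
        gm = make_gm(dose)
        hyper = np.arange(100) < 50
        res = cmc_test(gm, hyper, BurdenConfig(rarity_filter="all"))
        chi2 = chi_square_2x2([[20, 5], [30, 45]])
        assert res.statistic == pytest.approx(chi2, rel=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)
        assert res.direction == "+"

    def test_single_variant_set_equals_carrier_table(self):
        rng = np.random.default_rng(17)
        gm = binomial_gm(np.array([0.15]), 120, rng)
        hyper = np.arange(120) < 60
        carrier = collapse_carriers(gm)
        a = carrier[hyper].sum(); b = carrier[~hyper].sum()
        table = [[a, b], [60 - a, 60 - b]]
        res = cmc_test(gm, hyper, BurdenConfig(rarity_filter="all"))
        assert res.statistic == pytest.approx(chi_square_2x2(table), rel=1e-9)

    def test_no_rare_variants_refused(self):
        gm = make_gm(np.ones((10, 2), dtype=np.int8))  # both variants common
        with pytest.raises(AssociationError):
            cmc_test(gm, np.arange(10) < 5, BurdenConfig(rarity_filter="rare_only"))


class TestWeightedSum:
    def test_pseudocount_frequency(self):
        # variant absent among 27 controls -> q = (0+1)/(2*27+2) = 1/56
        dose = np.zeros((52, 1), dtype=np.int8)
        dose[0, 0] = 1  # one case carrier
        case = np.arange(52) < 25
        n_ctrl = 27
        q = (0 + 1) / (2 * n_ctrl + 2)
        assert q == pytest.approx(1 / 56)
        gm = make_gm(dose)
        res = ws_test(gm, case, BurdenConfig(rarity_filter="all", n_permutations=50, rng_seed=0))
        assert res.method == "ws" and 0 < res.p_value <= 1

    def test_min_attainable_p(self):
        rng = np.random.default_rng(3)
        # strong signal: all 10 case subjects carry, no control does
        dose = np.zeros((30, 4), dtype=np.int8)
        dose[:10] = rng.integers(1, 3, size=(10, 4))
        case = np.arange(30) < 10
        gm = make_gm(dose)
        cfg = BurdenConfig(rarity_filter="all", n_permutations=2000, rng_seed=1)
        res = ws_test(gm, case, cfg)
        assert res.p_value >= 1 / 2001
        assert res.p_value == pytest.approx(1 / 2001, rel=0.5)

    def test_p_bounds_and_degenerate_scores(self):
        gm = make_gm(np.zeros((20, 3), dtype=np.int8))
        cfg = BurdenConfig(rarity_filter="all", n_permutations=99, rng_seed=5)
        res = ws_test(gm, np.arange(20) < 10, cfg)
        assert res.p_value == 1.0  # all gamma identical

    def test_subject_order_permutation_invariance(self):
        rng = np.random.default_rng(23)
        gm = binomial_gm(rng.uniform(0.02, 0.2, 6), 60, rng)
        case = rng.random(60) < 0.5
        if case.sum() in (0, 60):
            case[:5] = ~case[:5]
        cfg = BurdenConfig(rarity_filter="all", n_permutations=300, rng_seed=9)
        res1 = ws_test(gm, case, cfg)
        perm = rng.permutation(60)
        gm2 = gm.subset_subjects(perm)
        res2 = ws_test(gm2, case[perm], cfg)
        assert res1.p_value == pytest.approx(res2.p_value, abs=0.03)
        # analytic statistics identical under relabelling of subjects
        res3 = cmc_test(gm2, case[perm], BurdenConfig(rarity_filter="all"))
        res4 = cmc_test(gm, case, BurdenConfig(rarity_filter="all"))
        assert res3.p_value == pytest.approx(res4.p_value)

    def test_power_exceeds_type_one_rate(self):
        """8-variant in-case enrichment at OR 2 is detected more often than
        the null rejects, on the same generator."""
        def or_freq(q, r):
            return r * q / (1 - q + r * q)

        q = np.full(8, 0.12)
        hits = {True: 0, False: 0}
        n_rep = 120
        for effect in (True, False):
            rng = np.random.default_rng(100 if effect else 200)
            for i in range(n_rep):
                qc = or_freq(q, 2.0) if effect else q
                gm = binomial_gm(q, 52, rng, case_q=qc, n_cases=25)
                cfg = BurdenConfig(rarity_filter="all", n_permutations=250, rng_seed=i)
                hits[effect] += ws_test(gm, np.arange(52) < 25, cfg).p_value <= 0.05
        assert hits[True] > hits[False]
        assert hits[True] / n_rep > 0.3


class TestCAlpha:
    def test_no_overdispersion_gives_large_p(self):
        # every variant splits exactly at the case fraction -> T <= 0
        dose = np.zeros((100, 5), dtype=np.int8)
        case = np.arange(100) < 50
        for j in range(5):
            dose[j, j] = 1       # one copy in cases
            dose[50 + j, j] = 1  # one copy in controls
        gm = make_gm(dose)
        res = c_alpha_test(gm, case, BurdenConfig(rarity_filter="all", n_permutations=100,
                                                  rng_seed=0))
        T, c, p0 = c_alpha_components(dose.astype(float), case)
        assert p0 == 0.5
        assert T <= 0
        assert res.p_value >= 0.5

    def test_components_match_direct_formula(self):
        rng = np.random.default_rng(31)
        dose = rng.binomial(2, 0.1, size=(40, 6)).astype(float)
        case = np.arange(40) < 15
        T, c, p0 = c_alpha_components(dose, case)
        # direct recomputation
        n_i = dose.sum(axis=0)
        y_i = dose[case].sum(axis=0)
        keep = n_i >= 1
        T2 = sum((y - n * p0) ** 2 - n * p0 * (1 - p0) for n, y in zip(n_i[keep], y_i[keep]))
        assert T == pytest.approx(T2, rel=1e-12)
        assert c > 0

    def test_mixed_direction_power_beats_ws(self):
        """Half the variants enriched in cases, half in controls (OR 3):
        the dispersion test rejects more often than the weighted sum."""
        def or_freq(q, r):
            return r * q / (1 - q + r * q)

        q = np.full(10, 0.06)
        rng = np.random.default_rng(55)
        n, n_cases = 120, 60
        ca_hits = ws_hits = 0
        for i in range(150):
            q_case = q.copy()
            q_ctrl = q.copy()
            q_case[:5] = or_freq(q[:5], 3.0)
            q_ctrl[5:] = or_freq(q[5:], 3.0)
            dose = np.vstack([
                rng.binomial(2, q_case, size=(n_cases, 10)),
                rng.binomial(2, q_ctrl, size=(n - n_cases, 10)),
            ]).astype(np.int8)
            gm = make_gm(dose)
            case = np.arange(n) < n_cases
            cfg = BurdenConfig(rarity_filter="all", n_permutations=200, rng_seed=i)
            ca_hits += c_alpha_test(gm, case, cfg).p_value < 0.05
            ws_hits += ws_test(gm, case, cfg).p_value <= 0.05
        assert ca_hits > ws_hits


class TestBurdenSuite:
    def test_grid_shape_and_counts(self):
        rng = np.random.default_rng(41)
        func = ["missense"] * 7 + ["synonymous"] * 8
        ann = toy_annotations(func)
        q = np.concatenate([rng.uniform(0.01, 0.04, 4), rng.uniform(0.1, 0.3, 3),
                            rng.uniform(0.01, 0.04, 1), rng.uniform(0.1, 0.3, 7)])
        gm = binomial_gm(q, 52, rng)
        gm = make_gm(gm.dosage, variant_ids=ann["variant_id"].to_numpy())
        grid = burden_suite(gm, ann, np.arange(52) < 25, n_permutations=50, rng_seed=0)
        assert len(grid) == 9  # 3 classes x (cmc rare, ws rare, ws all)
        combined_all = grid[(grid["classes"] == "missense_synonymous")
                            & (grid["rarity"] == "all")]
        assert (combined_all["n_variants"] <= 15).all()
        rare_rows = grid[grid["rarity"] == "rare"]
        all_rows = grid[grid["rarity"] == "all"]
        assert rare_rows["n_variants"].max() <= all_rows["n_variants"].max()

    def test_empty_cell_reported_as_no_test(self):
        ann = toy_annotations(["missense"] * 3)  # no synonymous variants
        rng = np.random.default_rng(2)
        gm = binomial_gm(np.full(3, 0.2), 40, rng)
        gm = make_gm(gm.dosage, variant_ids=ann["variant_id"].to_numpy())
        grid = burden_suite(gm, ann, np.arange(40) < 20, n_permutations=50, rng_seed=0)
        syn = grid[grid["classes"] == "synonymous"]
        assert (syn["note"] == "no test").all()
        assert syn["p_value"].isna().all()

    def test_single_rare_synonymous_has_n_one(self):
        ann = toy_annotations(["synonymous"] * 3)
        dose = np.zeros((40, 3), dtype=np.int8)
        dose[0, 0] = 1                      # one rare synonymous variant
        dose[:, 1] = np.tile([0, 1], 20)    # two common ones
        dose[:, 2] = np.tile([1, 0], 20)
        gm = make_gm(dose, variant_ids=ann["variant_id"].to_numpy())
        grid = burden_suite(gm, ann, np.arange(40) < 20, n_permutations=50, rng_seed=0)
        row = grid[(grid["classes"] == "synonymous") & (grid["method"] == "cmc")]
        assert row["n_variants"].iloc[0] == 1
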