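"""Nonparametric battery and correlation matrices.

The Mann-Whitney implementation is cross-checked against an independent
brute-force enumeration oracle (all label assignments of the pooled
sample) at small n.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from octapipe.stats_analysis import (
    average_eyes_per_subject,
    chi_square,
    correlation_matrix,
    kruskal_wallis,
    mann_whitney,
    spearman,
    strength_label,
    welch_t,
)
from octapipe.synthetic_data import CohortConfig, generate_cohort, implied_spearman_rho


def mann_whitney_enumeration_p(a, b):
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) group
    assignments of the pooled values (independent oracle)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    observed = u_stat(a, b)
    n_total = 0
    n_extreme = 0
    mean_u = n_a * len(b) / 2.0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        n_total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_p_near_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(
                mann_whitney_enumeration_p(a, b), abs=1e-9
            )

    def test_shift_alternative_power(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            mann_whitney(rng.normal(0, 1, 50), rng.normal(2, 1, 50)).p_value < 0.05
            for _ in range(1000)
        )
        assert rejections / 1000 > 0.99


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_computation(self):
        # ranks 1..6, R = (3, 7, 11): H = 12/42 * (9+49+121)/2 - 21 = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_two_group_case_orders_like_mann_whitney(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(30):
            a, b = rng.normal(size=12), rng.normal(rng.uniform(0, 1), 1, 12)
            pairs.append((mann_whitney(a, b).p_value,
                          kruskal_wallis([a, b]).p_value))
        mw_order = np.argsort([p[0] for p in pairs])
        kw_order = np.argsort([p[1] for p in pairs])
        assert (mw_order == kw_order).all()


class TestChiSquare:
    def test_cohort_sex_table(self):
        # sex x group counts 8/7 vs 42/41
        res = chi_square([[8, 7], [42, 41]])
        assert res.statistic == pytest.approx(0.04, abs=0.005)
        assert res.p_value == pytest.approx(0.846, abs=0.001)
        assert res.df == 1

    def test_proportional_table_is_zero(self):
        assert chi_square([[10, 20], [30, 60]]).statistic == pytest.approx(0.0)

    def test_perfect_association(self):
        assert chi_square([[10, 0], [0, 10]]).statistic == pytest.approx(20.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestWelch:
    def test_age_comparison_from_summaries(self):
        # 57.5 +/- 13.0 (n=15) vs 60.5 +/- 12.9 (n=83)
        res = welch_t(57.5, 13.0, 15, 60.5, 12.9, 83)
        assert res.statistic == pytest.approx(-0.83, abs=0.01)
        assert res.df == pytest.approx(19.33, abs=0.02)
        assert res.p_value == pytest.approx(0.416, abs=0.005)

    def test_equal_means(self):
        res = welch_t(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_scaling_both_sds_scales_t_inversely(self):
        base = welch_t(1.0, 1.0, 20, 0.0, 1.5, 25)
        scaled = welch_t(1.0, 2.0, 20, 0.0, 3.0, 25)
        assert scaled.statistic == pytest.approx(base.statistic / 2.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1.0, 1.0, 1, 0.0, 1.0, 10)


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # d = (1-2, 2-1, 3-4, 4-3, 0): sum d^2 = 4, rho = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestStrength:
    @pytest.mark.parametrize(
        "rho,label",
        [
            (0.44, "moderate"), (0.37, "moderate"), (0.27, "weak"),
            (-0.85, "high"), (0.3, "moderate"), (0.7, "high"), (0.0, "weak"),
        ],
    )
    def test_bins(self, rho, label):
        assert strength_label(rho) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_label(1.2)


class TestCorrelationMatrix:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        oct_t = pd.DataFrame(rng.normal(size=(30, 5)),
                             columns=[f"rnfl_{r}" for r in "wSNIT"])
        octa_t = pd.DataFrame(rng.normal(size=(30, 30)),
                              columns=[f"m{k}" for k in range(30)])
        matrix = correlation_matrix(oct_t, octa_t)
        assert len(matrix) == 5 * 30
        assert set(matrix["oct_var"]) == set(oct_t.columns)

    def test_recovers_configured_latent_coupling(self):
        # n=200 per draw; averaged over seeds to tame sampling noise
        # (se of rho at n=200 is ~0.07)
        rhos = []
        for seed in range(5):
            cfg = CohortConfig(n_per_grade={"DR0": 200}, seed=seed)
            cohort = generate_cohort(cfg)
            matrix = correlation_matrix(
                cohort[["rnfl_I"]], cohort[["octa_disc_flux_I"]]
            )
            rhos.append(matrix["rho"].iloc[0])
        assert np.mean(rhos) == pytest.approx(
            implied_spearman_rho(CohortConfig().latent_coupling), abs=0.1
        )

    def test_permutation_destroys_significance(self):
        cfg = CohortConfig(n_per_grade={"DR0": 200}, seed=9)
        cohort = generate_cohort(cfg)
        oct_cols = [c for c in cohort.columns if c.startswith("rnfl_")]
        octa_cols = [c for c in cohort.columns if c.startswith("octa_disc_")]
        rng = np.random.default_rng(4)
        perm = cohort[oct_cols].sample(frac=1, random_state=4).reset_index(drop=True)
        matrix = correlation_matrix(perm, cohort[octa_cols].reset_index(drop=True))
        assert matrix["significant"].mean() <= 0.05

    def test_bonferroni_only_removes_significance(self):
        rng = np.random.default_rng(2)
        oct_t = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        octa_t = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("uvwxyz"))
        matrix = correlation_matrix(oct_t, octa_t)
        assert (matrix["p_adj"] >= matrix["p"]).all()
        n_adj = matrix["significant"].sum()
        n_raw = (matrix["p"] < 0.05).sum()
        assert n_adj <= n_raw

    def test_sparse_cells_flagged_missing(self):
        oct_t = pd.DataFrame({"a": [1.0, np.nan, np.nan, np.nan, 2.0]})
        octa_t = pd.DataFrame({"b": [1.0, 2.0, np.nan, np.nan, 3.0]})
        matrix = correlation_matrix(oct_t, octa_t)
        assert matrix["strength"].iloc[0] == "missing"
        assert not matrix["significant"].iloc[0]

    def test_fellow_eye_averaging_for_sensitivity(self):
        cohort = pd.DataFrame({
            "subject_id": ["s1", "s1", "s2"],
            "eye": ["OD", "OS", "OD"],
            "rnfl_I": [100.0, 110.0, 90.0],
            "grade": ["DR1", "DR1", "DR2"],
        })
        per_subject = average_eyes_per_subject(cohort)
        assert len(per_subject) == 2
        s1 = per_subject.set_index("subject_id").loc["s1"]
        assert s1["rnfl_I"] == 105.0 and s1["grade"] == "DR1"

    def test_global_family_requires_size(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            correlation_matrix(df, df, family="global")
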