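"""Filament statistics, bundling, solubility and integration scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myotail import morphometry as mor
from myotail import synthetic as syn


def records(groups):
    rows = []
    for group, values in groups.items():
        rows += [
            {"group": group, "field_id": f"{group}-{i}", "length_nm": v,
             "width_nm": v / 20, "bundled": False}
            for i, v in enumerate(values)
        ]
    return pd.DataFrame(rows)


class TestFilamentStats:
    def test_mean_and_sem(self):
        out = mor.filament_stats(records({"WT": [1.0, 2.0, 3.0]}))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert row["n"] == 3

    def test_identical_groups_not_significant(self):
        vals = list(np.random.default_rng(0).normal(100, 5, 20))
        out = mor.filament_stats(records({"WT": vals, "MUT": vals}))
        row = out[out["group"] == "MUT"].iloc[0]
        assert row["p_vs_ref"] > 0.05
        assert row["stars"] == ""

    def test_wt_preset_recovery(self):
        """Synthetic WT population (n=34) lands within 2×SEM of 431 nm."""
        fil = syn.gen_filaments(seed=0)
        out = mor.filament_stats(fil)
        row = out[out["group"] == "WT"].iloc[0]
        assert row["n"] == 34
        assert abs(row["mean"] - 431.0) < 2 * 34.0

    def test_welch_matches_permutation_oracle(self):
        """Welch p-value agrees with a 10⁴-permutation test within MC error."""
        rng = np.random.default_rng(1)
        a = rng.normal(100, 10, 12)
        b = rng.normal(110, 18, 9)
        out = mor.filament_stats(records({"WT": list(a), "MUT": list(b)}))
        p_welch = out[out["group"] == "MUT"].iloc[0]["p_vs_ref"]
        res = sps.permutation_test(
            (b, a),
            lambda x, y, axis=-1: sps.ttest_ind(x, y, equal_var=False, axis=axis).statistic,
            permutation_type="independent", n_resamples=10_000,
            alternative="two-sided", rng=2,
        )
        assert p_welch == pytest.approx(res.pvalue, abs=3 * np.sqrt(0.05 * 0.95 / 10_000) + 0.02)


class TestBundleFraction:
    def test_extremes(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3 + ["b"] * 3, "field_id": list(range(6)),
             "bundled": [True] * 3 + [False] * 3}
        )
        out = mor.bundle_fraction(df).set_index("group")
        assert out.loc["a", "bundled_pct"] == 100.0
        assert out.loc["b", "bundled_pct"] == 0.0

    def test_bernoulli_recovery_within_ci(self):
        """200 Bernoulli(0.7) fields: estimate brackets the preset rate."""
        fil = syn.gen_filaments(seed=3)
        out = mor.bundle_fraction(fil).set_index("group")
        row = out.loc["K1617del"]
        assert row["ci_low_pct"] <= 70.0 <= row["ci_high_pct"]
        assert row["n_fields"] == 200


class TestSolubility:
    def test_extremes_and_clipping(self):
        df = pd.DataFrame(
            {"NaCl_mM": [100.0, 200.0, 300.0], "supernatant": [1.0, 0.0, 1.2],
             "total": [1.0, 1.0, 1.0]}
        )
        with pytest.warns(UserWarning, match="clipped"):
            out, _ = mor.solubility_curve(df, fit_midpoint=False)
        assert list(out["fraction_soluble"]) == [1.0, 0.0, 1.0]

    def test_logistic_midpoint_recovery(self):
        """Synthetic logistic curve: midpoint recovered within 10 mM."""
        s = np.arange(50.0, 351.0, 10.0)
        frac = 1.0 / (1.0 + np.exp(-(s - 180.0) / 30.0))
        df = pd.DataFrame({"NaCl_mM": s, "supernatant": frac, "total": 1.0})
        _, fit = mor.solubility_curve(df)
        assert fit["midpoint_mM"] == pytest.approx(180.0, abs=10.0)

    def test_mutant_midpoint_ordering(self):
        """A1603P stays soluble at lower salt: smaller fitted midpoint than WT."""
        sol = syn.gen_solubility(seed=4)
        mids = {}
        for group, sub in sol.groupby("group"):
            _, fit = mor.solubility_curve(sub)
            mids[group] = fit["midpoint_mM"]
        assert mids["A1603P"] < mids["WT"]

    def test_nonpositive_total_rejected(self):
        df = pd.DataFrame({"NaCl_mM": [100.0], "supernatant": [0.5], "total": [0.0]})
        with pytest.raises(ValueError):
            mor.solubility_curve(df)


class TestIntegration:
    def test_all_one_category(self):
        df = pd.DataFrame(
            {"group": "WT", "experiment": "e1", "cell_id": range(30),
             "category": ["integrated"] * 30}
        )
        per_exp, _ = mor.integration_summary(df)
        pcts = per_exp.set_index("category")["pct"]
        assert pcts["integrated"] == 100.0 and pcts["partial"] == 0.0

    def test_percentages(self):
        cats = ["integrated"] * 15 + ["partial"] * 10 + ["aggregated"] * 5
        df = pd.DataFrame(
            {"group": "WT", "experiment": "e1", "cell_id": range(30), "category": cats}
        )
        per_exp, _ = mor.integration_summary(df)
        pcts = per_exp.set_index("category")["pct"]
        assert pcts["integrated"] == pytest.approx(50.0)
        assert pcts["partial"] == pytest.approx(100 / 3)
        assert pcts["aggregated"] == pytest.approx(50 / 3)

    def test_percentages_sum_to_100_per_experiment(self):
        scores = syn.gen_integration(seed=5)
        per_exp, _ = mor.integration_summary(scores)
        sums = per_exp.groupby(["group", "experiment"])["pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_multinomial_recovery(self):
        """Three-experiment means land near the preset probabilities."""
        scores = syn.gen_integration(n_cells=60, seed=6)
        _, summary = mor.integration_summary(scores)
        truth = scores.attrs["truth"]
        for _, row in summary.iterrows():
            probs = dict(zip(mor.INTEGRATION_CATEGORIES, truth[row["group"]]["probs"]))
            expected = 100.0 * probs[row["category"]]
            sd = max(row["sd_pct"], 3.0)
            assert abs(row["mean_pct"] - expected) < 4 * sd

    def test_unknown_category_rejected(self):
        df = pd.DataFrame(
            {"group": "WT", "experiment": "e1", "cell_id": [0], "category": ["weird"]}
        )
        with pytest.raises(ValueError, match="unknown categories"):
            mor.integration_summary(df)

    def test_low_cell_count_warns(self):
        df = pd.DataFrame(
            {"group": "WT", "experiment": "e1", "cell_id": range(5),
             "category": ["integrated"] * 5}
        )
        with pytest.warns(UserWarning, match="recommended"):
            mor.integration_summary(df)
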