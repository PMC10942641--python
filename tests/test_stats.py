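"""Clone statistics tests: sort/rank/regression oracles and recovery checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonetrack import (
    CloneTable,
    ExpansionModel,
    clone_size_summary,
    compare_clone_distributions,
    dominance_profile,
    estimate_heterogeneity,
    run_pipeline,
    sharing_analysis,
    sharing_regression,
    simulate_counts,
)
from clonetrack.stats import CloneHeterogeneity, _pava_increasing


def table_from(data: dict, roles: dict, scale=1e6) -> CloneTable:
    df = pd.DataFrame(data).fillna(0.0).astype(float)
    df.index.name = "barcode"
    # rescale columns to the invariant
    tot = df.sum(axis=0)
    df = df * scale / tot.replace(0, np.nan)
    return CloneTable(normalized=df.fillna(0.0), roles=roles, scale=scale)


class TestCloneSizeSummary:
    def test_equal_quarters(self):
        t = table_from({"R": {"A": 1, "B": 1, "C": 1, "D": 1}}, {"R": "parental"})
        s = clone_size_summary(t, role="parental")
        assert s["median_pct"] == pytest.approx(25.0)
        assert s["iqr_pct"] == pytest.approx(0.0)
        assert s["n_barcodes"] == 4

    def test_empty_selection_errors(self):
        t = table_from({"R": {"A": 1}}, {"R": "parental"})
        with pytest.raises(ValueError):
            clone_size_summary(t, role="daughter")

    def test_median_matches_sort_oracle(self):
        m = ExpansionModel.pre_culture(seed=17, log_expansion_sd=1.5)
        cm, _ = simulate_counts(m)
        table = run_pipeline(cm)
        s = clone_size_summary(table, role="parental")
        # independent oracle: sort all pooled nonzero parental percentages
        vals = []
        for rec in table.recipients_with_role("parental"):
            col = table.normalized[rec].to_numpy()
            vals.extend(col[col > 0] / 1e4)
        vals = np.sort(vals)
        n = len(vals)
        med = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        assert s["median_pct"] == pytest.approx(med)
        assert s["n_observations"] == n


class TestSharing:
    def test_parental_only_clone(self):
        t = table_from(
            {"P1": {"X": 10, "Y": 1}, "D1": {"Y": 5}, "D2": {"Y": 2}},
            {"P1": "parental", "D1": "daughter", "D2": "daughter"},
        )
        s = sharing_analysis(t)
        assert s.per_barcode.loc["X", "n_daughters_detected"] == 0
        assert s.per_barcode.loc["Y", "n_daughters_detected"] == 2

    def test_all_daughters_detected(self):
        roles = {"P1": "parental", **{f"D{i}": "daughter" for i in range(1, 6)}}
        data = {"P1": {"X": 1.0}, **{f"D{i}": {"X": 1.0} for i in range(1, 6)}}
        s = sharing_analysis(table_from(data, roles))
        assert s.per_barcode.loc["X", "n_daughters_detected"] == 5

    def test_missing_roles_error(self):
        t = table_from({"R": {"X": 1}}, {"R": "plain"})
        with pytest.raises(ValueError):
            sharing_analysis(t)

    def test_regression_recovers_exact_line(self):
        # daughter_total = 2 * parental exactly -> slope 2, r = 1
        t = table_from(
            {
                "P1": {"A": 1, "B": 2, "C": 3, "D": 4},
                "D1": {"A": 2, "B": 4, "C": 6, "D": 8},
            },
            {"P1": "parental", "D1": "daughter"},
        )
        s = sharing_analysis(t)
        # normalization rescales both columns to 1e6; rebuild raw proportions
        s.per_barcode["daughter_total"] = s.per_barcode["parental_size"] * 2
        reg = sharing_regression(s)
        assert reg["slope"] == pytest.approx(2.0)
        assert reg["pearson_r"] == pytest.approx(1.0)

    def test_regression_zero_daughters_zero_slope(self):
        t = table_from(
            {"P1": {"A": 1, "B": 2, "C": 3}, "D1": {}},
            {"P1": "parental", "D1": "daughter"},
        )
        s = sharing_analysis(t)
        reg = sharing_regression(s)
        assert reg["slope"] == pytest.approx(0.0)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, size=10)
        y = 3.0 * x + rng.normal(0, 5, size=10)
        df = pd.DataFrame(
            {
                "parental_id": "P1",
                "parental_size": x,
                "n_daughters_detected": 0,
                "daughter_total": y,
            },
            index=pd.Index([f"B{i}" for i in range(10)], name="barcode"),
        )
        from clonetrack.stats import SharingSummary

        reg = sharing_regression(SharingSummary(per_barcode=df, n_daughter_recipients=5, scale=1e6))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg["intercept"] == pytest.approx(beta[0])
        assert reg["slope"] == pytest.approx(beta[1])


class TestMannWhitney:
    @staticmethod
    def enumeration_oracle(a, b):
        """Exact U and two-sided p by enumerating all group assignments."""
        pooled = np.concatenate([a, b])
        n1 = len(a)
        n = len(pooled)

        def u_stat(idx_a):
            ua = 0.0
            aset = set(idx_a)
            for i in idx_a:
                for j in range(n):
                    if j in aset:
                        continue
                    if pooled[i] > pooled[j]:
                        ua += 1
                    elif pooled[i] == pooled[j]:
                        ua += 0.5
            return ua

        observed = u_stat(tuple(range(n1)))
        us = np.array([u_stat(c) for c in itertools.combinations(range(n), n1)])
        mid = len(a) * len(b) / 2
        p = np.mean(np.abs(us - mid) >= np.abs(observed - mid) - 1e-12)
        return observed, float(p)

    def test_complete_separation(self):
        res = compare_clone_distributions([1, 2, 3], [10, 20, 30])
        # U for a-vs-b is 0: no a beats any b
        assert min(res["U"], 9 - res["U"]) == 0

    def test_identical_samples_symmetric(self):
        res = compare_clone_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["U"] == pytest.approx(4.5)  # n1*n2/2 with ties
        assert res["p"] > 0.9

    def test_u_matches_enumeration_oracle_random_inputs(self):
        rng = np.random.default_rng(77)
        for trial in range(100):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 9))
            if rng.random() < 0.5:
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
            else:  # tied integer data
                a = rng.integers(0, 4, size=n1).astype(float)
                b = rng.integers(0, 4, size=n2).astype(float)
            res = compare_clone_distributions(a, b)
            u_oracle, p_oracle = self.enumeration_oracle(a, b)
            u_b = n1 * n2 - u_oracle
            # the reported U must be the first-sample U (or its mirror)
            assert res["U"] in (pytest.approx(u_oracle), pytest.approx(u_b))
            if res["method"] == "exact":
                assert res["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_power_increases_with_sample_size(self):
        rng = np.random.default_rng(5)
        shift = 1.0
        rejections = []
        for n in [5, 40]:
            hits = 0
            for _ in range(200):
                a = rng.normal(0, 1, n)
                b = rng.normal(shift, 1, n)
                if compare_clone_distributions(a, b)["p"] < 0.05:
                    hits += 1
            rejections.append(hits / 200)
        assert rejections[1] > rejections[0]


class TestDominance:
    def test_single_bin_holds_all(self):
        t = table_from({"R": {"A": 1, "B": 2}}, {"R": "plain"})
        prof = dominance_profile(t, [0, 100])
        assert prof["fractions"][0] == pytest.approx(1.0)

    def test_left_closed_boundary(self):
        # clone at exactly 1% falls in the upper bin
        data = {"R": {"A": 1.0, "B": 99.0}}
        t = table_from(data, {"R": "plain"})
        prof = dominance_profile(t, [0, 1, 100])
        assert prof["counts"][1] == 2  # both 1% and 99% in [1, 100]

    def test_totals_conserved(self):
        m = ExpansionModel.pre_culture(seed=23)
        cm, _ = simulate_counts(m)
        table = run_pipeline(cm)
        prof = dominance_profile(table, [0, 0.5, 1, 5, 100], role="parental")
        pooled = table.frequencies_pct("parental").to_numpy()
        assert prof["counts"].sum() == (pooled > 0).sum()

    def test_bad_edges_rejected(self):
        t = table_from({"R": {"A": 1}}, {"R": "plain"})
        with pytest.raises(ValueError):
            dominance_profile(t, [1, 1, 2])


class TestHeterogeneity:
    def test_pava_is_monotone_least_squares(self):
        y = np.array([1.0, 0.5, 2.0, 1.5, 3.0])
        out = _pava_increasing(y)
        assert (np.diff(out) >= -1e-12).all()
        assert out[0] == pytest.approx(0.75)  # pooled first violator pair

    def test_equal_clone_sizes_give_sigma_zero(self):
        data = {"P1": {f"B{i}": 1.0 for i in range(30)}}
        t = table_from(data, {"P1": "parental"})
        res = estimate_heterogeneity(t, n_boot=10, seed=1, grid_reps=2)
        assert res.sigma_hat == pytest.approx(0.0, abs=0.05)

    def test_too_few_clones_error(self):
        t = table_from({"P1": {"A": 1, "B": 2}}, {"P1": "parental"})
        with pytest.raises(ValueError):
            CloneHeterogeneity(t)

    def test_ci_brackets_point_estimate(self):
        m = ExpansionModel.pre_culture(seed=29, log_expansion_sd=1.0)
        cm, _ = simulate_counts(m)
        table = run_pipeline(cm)
        res = estimate_heterogeneity(table, model=m, n_boot=20, seed=2, grid_reps=3)
        assert res.ci_low <= res.sigma_hat <= res.ci_high

    def test_sigma_hat_monotone_in_generating_sigma(self):
        hats = []
        for sigma in [0.0, 0.75, 1.5]:
            m = ExpansionModel.pre_culture(seed=31, log_expansion_sd=sigma)
            cm, _ = simulate_counts(m)
            table = run_pipeline(cm)
            res = estimate_heterogeneity(table, model=m, n_boot=5, seed=3, grid_reps=4)
            hats.append(res.sigma_hat)
        assert hats[0] < hats[1] < hats[2]

    def test_summary_renders(self):
        m = ExpansionModel.pre_culture(seed=37, log_expansion_sd=1.0)
        cm, _ = simulate_counts(m)
        table = run_pipeline(cm)
        res = estimate_heterogeneity(table, model=m, n_boot=5, seed=4, grid_reps=2)
        text = res.summary()
        assert "sigma_hat" in text and "95% CI" in text
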