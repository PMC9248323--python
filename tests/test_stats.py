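"""Group statistics: outlier and covariate screening, PCA adequacy and
rotation invariants, ANCOVA against textbook oracles, simple slopes, and
the correlation families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hdwm.stats import (
    adequacy,
    ancova,
    dbs,
    pca_varimax,
    remove_outliers,
    screen_covariates,
    simple_slopes,
    spearman_family,
    varimax,
)


def _exact_corr_pair(n, r, rng):
    """Two vectors whose sample Pearson correlation is exactly r."""
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    y = y - y.mean()
    y -= x * (x @ y) / (x @ x)  # orthogonalize
    y /= y.std()
    return x, r * x + np.sqrt(1 - r**2) * y


class TestDbs:
    def test_printed_example(self):
        assert dbs(40.0, 40.5) == pytest.approx(200.0)

    def test_roots(self):
        assert dbs(63.0, 35.5) == 0.0
        assert dbs(0.0, 44.0) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(age=st.floats(18, 90), cag=st.floats(36, 55))
    def test_exact_product(self, age, cag):
        assert dbs(age, cag) == pytest.approx(age * (cag - 35.5), rel=1e-12)


class TestRemoveOutliers:
    def _frame(self, ctl, pat):
        return pd.DataFrame({
            "group": ["control"] * len(ctl) + ["patient"] * len(pat),
            "value": list(ctl) + list(pat),
        })

    def test_3p5_sd_removed_2p9_retained(self, rng):
        base = rng.normal(size=30)
        base = (base - base.mean()) / base.std(ddof=1)
        for z, removed in [(3.5, True), (2.9, False)]:
            vals = np.append(base, base.mean() + z * base.std(ddof=1))
            # appending shifts the group stats; verify against the actual z
            df = self._frame(vals, rng.normal(size=10))
            out, log = remove_outliers(df, "value")
            zs = np.abs(sps.zscore(vals, ddof=1))
            expect_removed = int(np.sum(zs > 3.0))
            assert len(log[log["group"] == "control"]) == expect_removed

    def test_within_group_z_not_global(self, rng):
        """A point extreme overall but typical within its own (shifted)
        group is retained."""
        ctl = rng.normal(0, 1, 40)
        pat = rng.normal(10, 1, 40)  # far from controls, typical for patients
        df = self._frame(ctl, pat)
        out, log = remove_outliers(df, "value")
        assert len(log) == int(np.sum(np.abs(sps.zscore(ctl, ddof=1)) > 3)) + \
            int(np.sum(np.abs(sps.zscore(pat, ddof=1)) > 3))
        assert (out["group"] == "patient").sum() >= 39

    def test_small_group_raises(self):
        df = self._frame([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            remove_outliers(df, "value")


class TestAdequacy:
    def test_identity_correlation_gives_zero_chi2(self, rng):
        # exactly orthogonal centered columns -> sample R = I -> ln det = 0
        M = rng.normal(size=(40, 4))
        M = M - M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = Q - Q.mean(axis=0)
        res = adequacy(X)
        assert res["bartlett_chi2"] == pytest.approx(0.0, abs=1e-8)
        assert res["bartlett_p"] == pytest.approx(1.0)

    def test_two_variable_closed_form(self, rng):
        x, y = _exact_corr_pair(50, 0.6, rng)
        res = adequacy(np.column_stack([x, y]))
        n, r = 50, 0.6
        expected = -(n - 1 - (2 * 2 + 5) / 6.0) * np.log(1 - r**2)
        assert res["bartlett_chi2"] == pytest.approx(expected, rel=1e-9)
        assert res["bartlett_df"] == 1

    def test_collinear_pair_raises(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="singular"):
            adequacy(np.column_stack([x, 2 * x, rng.normal(size=30)]))

    def test_more_variables_than_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="observations"):
            adequacy(rng.normal(size=(4, 6)))

    def test_kmo_range(self, rng):
        X = rng.normal(size=(60, 5))
        X[:, 1] += 0.8 * X[:, 0]
        res = adequacy(X)
        assert 0.0 < res["kmo"] < 1.0


class TestPcaVarimax:
    def test_rotation_preserves_communalities(self, rng):
        L = rng.normal(size=(8, 3))
        R_, rot = varimax(L)
        np.testing.assert_allclose(np.sum(R_**2, axis=1), np.sum(L**2, axis=1),
                                   rtol=1e-8)
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-10)

    def test_single_component_rotation_is_identity(self, rng):
        L = rng.normal(size=(6, 1))
        R_, rot = varimax(L)
        np.testing.assert_array_equal(R_, L)
        np.testing.assert_array_equal(rot, np.eye(1))

    def test_scores_zero_mean_and_unrotated_uncorrelated(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5)))
        res = pca_varimax(X, retain=3, rotate=False)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        C = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-8)

    def test_zero_variance_column_named(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.raises(ValueError, match="b"):
            pca_varimax(X)

    def test_two_factor_structure_recovered_by_kaiser(self, rng):
        """A four-metric co-loading block plus a second factor carried by the
        fifth metric (with a small cross-loading, so its population
        eigenvalue exceeds 1): Kaiser retains 2 components in >= 90% of
        seeds at the study row count (49 subjects x 7 segments).

        A perfectly isolated fifth metric would have population eigenvalue
        exactly 1 and could not satisfy a strict lambda > 1 rule more than
        about half the time at any sample size."""
        n = 49 * 7
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(400 + seed)
            f1 = r.normal(size=n)
            f2 = r.normal(size=n)
            X = pd.DataFrame({
                "m1": 0.9 * f1 + 0.4 * r.normal(size=n),
                "m2": 0.9 * f1 + 0.4 * r.normal(size=n),
                "m3": -0.9 * f1 + 0.4 * r.normal(size=n),
                "m4": 0.9 * f1 - 0.35 * f2 + 0.4 * r.normal(size=n),
                "m5": 0.9 * f2 + 0.3 * r.normal(size=n),
            })
            res = pca_varimax(X, retain="kaiser")
            hits += res.n_components == 2
        assert hits >= 0.9 * n_seeds

    def test_component_labeled_by_dominant_metric(self, rng):
        n = 300
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame({
            "FA": 0.9 * f1 + 0.3 * rng.normal(size=n),
            "FR": 0.9 * f1 + 0.3 * rng.normal(size=n),
            "MTR": 0.95 * f2 + 0.2 * rng.normal(size=n),
        })
        res = pca_varimax(X, retain=2)
        assert set(res.component_labels) == {"FA", "MTR"} or \
            set(res.component_labels) == {"FR", "MTR"}


class TestScreenCovariates:
    def test_threshold_contract(self, rng):
        out = pd.Series(rng.normal(size=200))
        x = (out - out.mean()) / out.std()
        cands = {}
        for name, r in [("just_above", 0.31), ("just_below", 0.29),
                        ("negative", -0.35)]:
            _, y = _exact_corr_pair(200, abs(r), rng)
            # rebuild with the outcome as the x side for an exact sample r
            y = out.to_numpy().copy()
            y = (y - y.mean()) / y.std()
            z = rng.normal(size=200)
            z = z - z.mean()
            z -= y * (y @ z) / (y @ y)
            z /= z.std()
            cands[name] = np.sign(r) * (abs(r) * y + np.sqrt(1 - r**2) * z)
        sel = screen_covariates(out, pd.DataFrame(cands))
        assert sel == ["just_above", "negative"]

    def test_null_candidates_rarely_selected(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(500 + seed)
            out = pd.Series(r.normal(size=300))
            cands = pd.DataFrame(r.normal(size=(300, 3)),
                                 columns=["age", "icv", "iq"])
            hits += len(screen_covariates(out, cands)) == 0
        assert hits >= 0.9 * n_seeds


def _segment_frame(rng, n_per_group=12, shift=None, noise=1.0):
    rows = []
    for g, n in [("patient", n_per_group), ("control", n_per_group)]:
        for i in range(n):
            base = rng.normal(0, 0.5)
            for s in range(1, 8):
                y = base + rng.normal(0, noise)
                if g == "patient" and shift is not None:
                    y += shift[s - 1]
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "segment": s, "score": y,
                             "age": 40 + rng.normal(0, 10)})
    return pd.DataFrame(rows)


class TestAncova:
    def test_group_f_equals_squared_t_in_balanced_oneway(self, rng):
        df = _segment_frame(rng)
        df = df[df["segment"] == 1]
        res = ancova(df, dv="score", factors=("group",), factor_interactions=())
        F = float(res.anova_table.loc["C(group, Sum)", "F"])
        t, _ = sps.ttest_ind(df[df.group == "patient"]["score"],
                             df[df.group == "control"]["score"])
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_planted_interaction_detected(self):
        shift = np.array([0.5, 0.3, 0.1, 0.0, -0.1, -0.3, -0.5]) * 2
        detected = 0
        for seed in range(5):
            r = np.random.default_rng(600 + seed)
            df = _segment_frame(r, n_per_group=12, shift=shift, noise=0.3)
            res = ancova(df, dv="score")
            p = float(res.anova_table.loc["C(group, Sum):C(segment, Sum)", "p"])
            detected += p < 0.05
        assert detected >= 4

    def test_balanced_type3_equals_type1(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _segment_frame(rng)
        res = ancova(df, dv="score")
        m = smf.ols(res.formula, data=df).fit()
        t1 = sm.stats.anova_lm(m, typ=1)
        for term in ["C(group, Sum)", "C(segment, Sum)",
                     "C(group, Sum):C(segment, Sum)"]:
            assert float(res.anova_table.loc[term, "F"]) == pytest.approx(
                float(t1.loc[term, "F"]), rel=1e-8)

    def test_f_invariant_to_covariate_rescaling(self, rng):
        df = _segment_frame(rng)
        a = ancova(df, dv="score", covariates=("age",))
        df2 = df.assign(age=df["age"] * 1000.0 + 7.0)
        b = ancova(df2, dv="score", covariates=("age",))
        for term in ["C(group, Sum)", "C(group, Sum):C(segment, Sum)"]:
            assert float(a.anova_table.loc[term, "F"]) == pytest.approx(
                float(b.anova_table.loc[term, "F"]), rel=1e-8)


class TestSimpleSlopes:
    def test_balanced_betas_equal_raw_mean_differences(self, rng):
        df = _segment_frame(rng)
        res = ancova(df, dv="score")
        sl = simple_slopes(res)
        raw = df.groupby(["segment", "group"])["score"].mean().unstack()
        diff = raw["patient"] - raw["control"]
        np.testing.assert_allclose(sl["beta"].to_numpy(),
                                   diff.to_numpy(), rtol=1e-9)

    def test_mean_slope_matches_overall_group_effect(self, rng):
        df = _segment_frame(rng)
        res = ancova(df, dv="score")
        sl = simple_slopes(res)
        overall = (df[df.group == "patient"]["score"].mean()
                   - df[df.group == "control"]["score"].mean())
        assert sl["beta"].mean() == pytest.approx(overall, rel=1e-9)

    def test_planted_endpoint_effects_recovered(self):
        """+delta in segment 1 and -delta in segment 7 only: exactly those
        two segments are significant at uncorrected .05 in >= 80% of
        seeds."""
        shift = np.array([0.5, 0, 0, 0, 0, 0, -0.5])
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(700 + seed)
            df = _segment_frame(r, n_per_group=25, shift=shift, noise=0.25)
            sl = simple_slopes(ancova(df, dv="score"))
            sig = (sl["p"] < 0.05).to_numpy()
            ok += sig[0] and sig[6] and sl.loc[0, "beta"] > 0 and sl.loc[6, "beta"] < 0
        assert ok >= 0.8 * n_seeds

    def test_missing_interaction_raises(self, rng):
        df = _segment_frame(rng)
        res = ancova(df, dv="score", factor_interactions=())
        with pytest.raises(ValueError, match="interaction"):
            simple_slopes(res)


class TestSpearmanFamily:
    def test_monotone_gives_r_one(self, rng):
        x = pd.DataFrame({"segment_1": rng.uniform(size=20)})
        y = pd.Series(np.exp(3 * x["segment_1"]))  # strictly monotone
        out = spearman_family(x, y)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(
            min(1.0, 1 * out.loc[0, "p"]))

    def test_bonferroni_scales_with_family_size(self, rng):
        x = pd.DataFrame({f"segment_{i}": rng.normal(size=30) for i in range(1, 8)})
        y = pd.Series(rng.normal(size=30))
        out = spearman_family(x, y)
        np.testing.assert_allclose(out["p_bonferroni"],
                                   np.minimum(1.0, 7 * out["p"]))
        assert (out["p_bonferroni"] >= out["p"] - 1e-12).all()

    def test_empty_covariates_equal_plain_spearman(self, rng):
        x = pd.DataFrame({"s": rng.normal(size=25)})
        y = pd.Series(rng.normal(size=25))
        a = spearman_family(x, y)
        b = spearman_family(x, y, covariates=pd.DataFrame(index=y.index))
        r, p = sps.spearmanr(x["s"], y)
        assert a.loc[0, "r"] == pytest.approx(r) == b.loc[0, "r"]
        assert a.loc[0, "p"] == pytest.approx(p) == b.loc[0, "p"]

    def test_confound_removed_by_partialling(self):
        """x and y linked only through a shared covariate z: the partial
        correlation is near zero (median |r| < 0.15 over seeds, n=200)."""
        rs = []
        for seed in range(20):
            r = np.random.default_rng(800 + seed)
            z = r.normal(size=200)
            x = pd.DataFrame({"s": z + 0.5 * r.normal(size=200)})
            y = pd.Series(z + 0.5 * r.normal(size=200))
            out = spearman_family(x, y, covariates=pd.DataFrame({"z": z}))
            rs.append(abs(out.loc[0, "r"]))
            assert abs(sps.spearmanr(x["s"], y).statistic) > 0.5
        assert np.median(rs) < 0.15

    def test_constant_input_raises(self):
        x = pd.DataFrame({"s": np.ones(10)})
        y = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            spearman_family(x, y)

    def test_too_few_pairs_raises(self):
        x = pd.DataFrame({"s": [1.0, 2.0, 3.0, np.nan] * 2})
        y = pd.Series([1.0, np.nan, 2.0, 3.0] * 2)
        with pytest.raises(ValueError, match="5 complete"):
            spearman_family(x, y)
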