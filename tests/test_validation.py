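"""Hold-out metrics, stratum t-test, admin aggregation, stratified runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from voromap.synthetic import SyntheticConfig, simulate_dataset
from voromap.validation import (
    aggregate_to_admin,
    holdout_metrics,
    stratified_run,
    stratum_ttest,
)


def duplicate_metrics(o, p):
    """Hand-rolled formulas, independent of the package implementation."""
    o, p = np.asarray(o, float), np.asarray(p, float)
    n = len(o)
    rmse = (np.sum((o - p) ** 2) / n) ** 0.5
    mae = np.sum(np.abs(o - p)) / n
    oc, pc = o - o.mean(), p - p.mean()
    r = np.sum(oc * pc) / np.sqrt(np.sum(oc**2) * np.sum(pc**2))
    rank = lambda v: np.argsort(np.argsort(v)).astype(float)
    ro, rp = rank(o), rank(p)
    roc, rpc = ro - ro.mean(), rp - rp.mean()
    rho = np.sum(roc * rpc) / np.sqrt(np.sum(roc**2) * np.sum(rpc**2))
    return r, rho, r * r, rmse, mae


class TestHoldoutMetrics:
    def test_perfect_prediction(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        rep = holdout_metrics(o, o.copy())
        assert rep.r2 == 1.0 and rep.rmse == 0.0 and rep.mae == 0.0

    def test_unit_errors(self):
        rep = holdout_metrics(np.zeros(4), np.array([1.0, -1.0, 1.0, -1.0]))
        assert rep.rmse == 1.0 and rep.mae == 1.0

    def test_matches_duplicate_formulas_to_1e10(self):
        rng = np.random.default_rng(0)
        o = rng.normal(size=1000)
        p = o + rng.normal(scale=0.5, size=1000)
        rep = holdout_metrics(o, p)
        r, rho, r2, rmse, mae = duplicate_metrics(o, p)
        assert abs(rep.pearson_r - r) < 1e-10
        assert abs(rep.spearman_rho - rho) < 1e-10
        assert abs(rep.r2 - r2) < 1e-10
        assert abs(rep.rmse - rmse) < 1e-10
        assert abs(rep.mae - mae) < 1e-10

    @pytest.mark.parametrize("n,expected", [(99, "spearman"), (100, "pearson"),
                                            (101, "pearson")])
    def test_spearman_switch_boundary(self, n, expected):
        rng = np.random.default_rng(n)
        o = rng.normal(size=n)
        rep = holdout_metrics(o, o + rng.normal(size=n))
        assert rep.metric_used == expected

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = holdout_metrics(np.ones(5), np.arange(5.0))
        assert rep.zero_variance and np.isnan(rep.pearson_r)

    def test_translation_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(1)
        o = rng.normal(size=50)
        p = o + rng.normal(size=50)
        a, b = holdout_metrics(o, p), holdout_metrics(o + 10, p + 10)
        assert a.rmse == b.rmse and a.mae == b.mae
        assert abs(a.pearson_r - b.pearson_r) < 1e-12

    def test_r2_definitions_differ_for_biased_predictions(self):
        rng = np.random.default_rng(2)
        o = rng.normal(size=200)
        p = o + 1.0  # biased but perfectly correlated
        sq = holdout_metrics(o, p).r2
        ev = holdout_metrics(o, p, r2_definition="explained_variance").r2
        assert sq > 0.99 and ev < sq

    def test_invariants_rmse_ge_mae(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            o, p = rng.normal(size=30), rng.normal(size=30)
            rep = holdout_metrics(o, p)
            assert rep.rmse >= rep.mae >= 0.0


class TestTtest:
    def test_identical_groups_give_zero_t(self):
        g = np.array([1.0, 2.0, 3.0])
        t, df, p, (lo, hi) = stratum_ttest(g, g.copy())
        assert t == 0.0 and abs(lo + hi) < 1e-12

    def test_shifted_groups_and_df_arithmetic(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=300)
        a = b + 10.0
        t, df, p, _ = stratum_ttest(a, b)
        assert df == 598 and p < 1e-10

    def test_matches_scipy_pooled_to_1e10(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.3, 1.2, size=40)
        b = rng.normal(0.0, 0.9, size=55)
        t, df, p, _ = stratum_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert abs(t - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10
        assert df == len(a) + len(b) - 2

    def test_ci_covers_true_difference(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1.0, 1.0, size=200)
        b = rng.normal(0.0, 1.0, size=200)
        _, _, _, (lo, hi) = stratum_ttest(a, b)
        assert lo < 1.0 < hi

    def test_zero_pooled_variance_flagged(self):
        with pytest.warns(UserWarning, match="pooled variance"):
            t, _, _, _ = stratum_ttest(np.ones(3), np.ones(4))
        assert np.isnan(t)


class TestAdminAggregation:
    def test_single_admin_unit_is_area_weighted_mean(self):
        polys = [box(0, 0, 1, 1), box(1, 0, 3, 1)]  # areas 1 and 2
        admin = [box(0, 0, 3, 1)]
        out = aggregate_to_admin(np.array([3.0, 6.0]), polys, admin)
        assert abs(out["aggregate"].iloc[0] - (3.0 * 1 + 6.0 * 2) / 3) < 1e-12

    def test_identity_mapping_when_units_match(self):
        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1)]
        out = aggregate_to_admin(np.array([1.5, -2.5]), polys, polys)
        assert np.allclose(out["aggregate"], [1.5, -2.5])

    def test_negative_reference_correlation_convention(self):
        polys = [box(i, 0, i + 1, 1) for i in range(6)]
        pred = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        ref = pd.DataFrame({"below_line": -pred + 1e-9})
        out = aggregate_to_admin(pred, polys, polys, reference=ref)
        assert out.attrs["reference_r"]["below_line"] < -0.999999

    def test_zero_intersection_unit_missing(self):
        polys = [box(0, 0, 1, 1)]
        admin = [box(5, 5, 6, 6)]
        out = aggregate_to_admin(np.array([1.0]), polys, admin)
        assert np.isnan(out["aggregate"].iloc[0])

    def test_global_weighted_mean_conserved(self):
        rng = np.random.default_rng(7)
        polys = [box(i, 0, i + 1, 1) for i in range(8)]
        admin = [box(0, 0, 3, 1), box(3, 0, 8, 1)]
        pred = rng.normal(size=8)
        out = aggregate_to_admin(pred, polys, admin)
        total = np.sum(out["aggregate"] * out["weight"]) / out["weight"].sum()
        assert abs(total - pred.mean()) < 1e-12


@pytest.fixture(scope="module")
def dataset():
    return simulate_dataset(
        SyntheticConfig(n_towers_urban=30, n_towers_rural=50, seed=13)
    )


class TestStratifiedRun:

    def test_single_stratum_equals_national(self, dataset):
        ds = dataset
        labels = np.array(["urban"] * ds.support.n_polygons)
        reports = stratified_run(
            ds.outcomes, ds.covariates, ds.support, labels,
            seed=1, n_iter=400, n_burn=150, n_chains=1,
        )
        assert set(reports) == {"national", "urban"}
        nat, urb = reports["national"], reports["urban"]
        assert nat.rmse == urb.rmse and nat.r2 == urb.r2

    def test_reports_cover_both_strata_and_national(self, dataset):
        ds = dataset
        reports = stratified_run(
            ds.outcomes, ds.covariates, ds.support, ds.strata,
            seed=1, n_iter=400, n_burn=150, n_chains=1, min_observed=15,
        )
        assert set(reports) <= {"national", "urban", "rural"}
        assert "national" in reports
        assert all(np.isfinite(r.rmse) for r in reports.values())
        assert all(r.dic_spatial is not None for r in reports.values())

    def test_small_stratum_skipped_with_warning(self, dataset):
        ds = dataset
        labels = np.array(["big"] * (ds.support.n_polygons - 3) + ["tiny"] * 3)
        with pytest.warns(UserWarning, match="tiny"):
            reports = stratified_run(
                ds.outcomes, ds.covariates, ds.support, labels,
                seed=1, n_iter=300, n_burn=100, n_chains=1,
            )
        assert "tiny" not in reports

    def test_stratum_specific_effects_recovered_better_stratified(self):
        """Stratified fits beat the pooled fit when slopes differ by stratum."""
        from voromap.model import IcarModel

        rng = np.random.default_rng(8)
        errs_strat, errs_pooled = [], []
        for rep in range(6):
            cfg = SyntheticConfig(n_towers_urban=40, n_towers_rural=40,
                                  observed_fraction=1.0, seed=100 + rep)
            ds = simulate_dataset(cfg)
            X = ds.covariates.design_matrix()
            urban = ds.strata == "urban"
            beta_u = np.array([0.5, 1.5, -0.2, 0.1])
            beta_r = np.array([0.5, -0.5, 0.8, 0.7])
            y = np.where(
                urban,
                beta_u[0] + X @ beta_u[1:],
                beta_r[0] + X @ beta_r[1:],
            ) + rng.normal(scale=0.2, size=len(X))
            pooled = IcarModel(y, X, support=ds.support).fit(
                n_iter=350, n_burn=150, n_chains=1, seed=rep)
            err_p = 0.0
            for mask, truth in ((urban, beta_u), (~urban, beta_r)):
                y_s = np.where(mask, y, np.nan)
                fit = IcarModel(y_s, X, support=ds.support).fit(
                    n_iter=350, n_burn=150, n_chains=1, seed=rep)
                errs_strat.append(np.mean((fit.beta_mean - truth) ** 2))
                err_p += np.mean((pooled.beta_mean - truth) ** 2)
            errs_pooled.append(err_p / 2)
        assert np.mean(errs_strat) < np.mean(errs_pooled)
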