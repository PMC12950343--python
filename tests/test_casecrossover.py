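"""Time-stratified conditional quasi-Poisson fitting and its diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatlag.casecrossover import (
    ConditionalQuasiPoisson,
    assign_strata,
    gvif_check,
    select_spec,
    shared_crossbasis_spec,
)
from heatlag.crossbasis import build_crossbasis
from heatlag.synthetic import (
    BaselineParams,
    default_study_config,
    make_study,
    null_surface,
)


def dummy_variable_oracle(X, y, codes):
    """Unconditional Poisson GLM with one dummy per informative stratum."""
    totals = np.bincount(codes, weights=y)
    sizes = np.bincount(codes)
    keep = ((totals > 0) & (sizes >= 2))[codes]
    Xk, yk, ck = X[keep], y[keep], codes[keep]
    ck = np.unique(ck, return_inverse=True)[1]
    D = np.eye(ck.max() + 1)[ck]
    res = sm.GLM(yk, np.hstack([Xk, D]), family=sm.families.Poisson()).fit()
    p = X.shape[1]
    pearson = float(((yk - res.mu) ** 2 / res.mu).sum())
    phi = pearson / (len(yk) - (p + ck.max() + 1))
    vcov = phi * np.asarray(res.cov_params())[:p, :p] / res.scale
    return np.asarray(res.params[:p]), vcov, phi


class TestAssignStrata:
    def test_same_weekday_of_month_shares_stratum(self):
        dates = pd.date_range("2020-03-01", "2020-03-31")
        sa = assign_strata(dates)
        mondays = [i for i, d in enumerate(dates) if d.dayofweek == 0]
        assert len(mondays) == 5
        assert len({sa.codes[i] for i in mondays}) == 1

    def test_28_day_february_partitions_into_seven_strata_of_four(self):
        dates = pd.date_range("2021-02-01", "2021-02-28")  # starts Monday
        sa = assign_strata(dates)
        sizes = np.bincount(sa.codes)
        assert len(sizes) == 7 and (sizes == 4).all()

    def test_month_boundary_separates_strata(self):
        dates = pd.DatetimeIndex(["2014-04-07", "2014-04-14", "2014-05-05"])
        sa = assign_strata(dates)
        assert sa.codes[0] == sa.codes[1]
        assert sa.codes[0] != sa.codes[2]


class TestConditionalFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dummy_variable_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, n_strata, p = 200, 20, 3
        codes = rng.integers(0, n_strata, n)
        X = rng.normal(size=(n, p))
        eta = 0.3 + X @ np.array([0.4, -0.3, 0.0]) + 0.4 * rng.normal(size=n_strata)[codes]
        y = rng.poisson(np.exp(eta))
        est = ConditionalQuasiPoisson().fit(X, y, strata=codes)
        coef_o, vcov_o, phi_o = dummy_variable_oracle(X, y, codes)
        np.testing.assert_allclose(est.coef_, coef_o, atol=1e-6)
        np.testing.assert_allclose(est.dispersion_, phi_o, rtol=1e-8)
        np.testing.assert_allclose(est.vcov_, vcov_o, atol=1e-5)

    def test_dispersion_recovers_variance_inflation(self):
        rng = np.random.default_rng(1)
        n, n_strata = 3000, 300
        codes = np.repeat(np.arange(n_strata), n // n_strata)
        X = rng.normal(size=(n, 2))
        lam = np.exp(1.0 + X @ np.array([0.2, -0.1]))
        phi = 1.5
        r = lam / (phi - 1.0)
        y = rng.negative_binomial(r, r / (r + lam))
        est = ConditionalQuasiPoisson().fit(X, y, strata=codes)
        assert 1.3 <= est.dispersion_ <= 1.7

    def test_all_zero_counts_is_an_error(self):
        X = np.random.default_rng(0).normal(size=(40, 2))
        codes = np.repeat(np.arange(8), 5)
        with pytest.raises(ValueError, match="informative"):
            ConditionalQuasiPoisson().fit(X, np.zeros(40), strata=codes)

    def test_stratum_constant_column_is_absorbed(self, small_strata):
        """A column constant within strata carries no conditional information;
        it is dropped and the remaining coefficients are unchanged."""
        X, y, codes, _ = small_strata
        est0 = ConditionalQuasiPoisson().fit(X, y, strata=codes)
        Xa = np.column_stack([X, np.random.default_rng(0).normal(size=20)[codes]])
        est1 = ConditionalQuasiPoisson().fit(Xa, y, strata=codes)
        assert est1.dropped_ == [3]
        np.testing.assert_allclose(est1.coef_[:3], est0.coef_, atol=1e-8)

    def test_vcov_scales_linearly_in_dispersion(self, small_strata):
        X, y, codes, _ = small_strata
        est = ConditionalQuasiPoisson().fit(X, y, strata=codes)
        ratio = est.vcov_ / est.dispersion_
        est2 = ConditionalQuasiPoisson().fit(X, 2 * y, strata=codes)
        # doubling counts roughly doubles information; the vcov/phi ratio is
        # the inverse information, independent of the dispersion estimate
        np.testing.assert_allclose(
            est2.vcov_ / est2.dispersion_ * 2, ratio, rtol=0.2
        )

    def test_parameter_recovery_improves_with_sample_size(self):
        """With the generating surface inside the fitted basis span, the
        coefficient error shrinks as the series lengthens."""
        rng = np.random.default_rng(5)
        cfg = default_study_config(n_units=1)
        cfg["units"][0].update(count_mean=5.0, start="2015-01-01", end="2022-12-31")
        cfg["surface"] = null_surface().to_dict()
        unit = make_study(cfg, 9)[0]
        temps = unit.weather["temp_c"].to_numpy()
        spec = shared_crossbasis_spec([unit], 1, 3, 21)
        cb = build_crossbasis(temps, spec)
        eta_true = rng.normal(0, 0.02, spec.n_columns)
        linpred = cb.values @ eta_true
        lam = np.exp(np.log(5.0) + linpred - linpred.mean())
        y = rng.poisson(lam)
        errs = []
        for n in (730, 2920):
            sl = slice(0, n)
            est = ConditionalQuasiPoisson().fit(
                cb.values[sl][cb.complete[sl]], y[sl][cb.complete[sl]],
                strata=assign_strata(unit.dates[sl]).codes[cb.complete[sl]],
            )
            errs.append(np.linalg.norm(est.coef_ - eta_true))
        assert errs[1] < errs[0]


class TestQAIC:
    def test_unit_reference_dispersion_reduces_to_aic(self, small_strata):
        X, y, codes, _ = small_strata
        est = ConditionalQuasiPoisson().fit(X, y, strata=codes)
        assert est.qaic(1.0) == pytest.approx(-2 * est.loglik_ + 2 * est.n_params_)

    def test_useless_covariate_usually_increases_qaic(self):
        rng = np.random.default_rng(2)
        wins = 0
        n_sim = 20
        for _ in range(n_sim):
            n, n_strata = 400, 40
            codes = np.repeat(np.arange(n_strata), n // n_strata)
            X = rng.normal(size=(n, 2))
            y = rng.poisson(np.exp(0.5 + 0.3 * rng.normal(size=n_strata)[codes]))
            if y.sum() == 0:
                continue
            base = ConditionalQuasiPoisson().fit(X[:, :1], y, strata=codes)
            full = ConditionalQuasiPoisson().fit(X, y, strata=codes)
            phi = full.dispersion_
            wins += full.qaic(phi) > base.qaic(phi)
        assert wins > n_sim / 2


class TestSelectSpec:
    def test_single_cell_grid_returns_that_cell(self):
        cfg = default_study_config(n_units=1)
        cfg["units"][0].update(count_mean=3.0, start="2019-01-01", end="2021-12-31")
        units = make_study(cfg, 4)
        (lk, vdf), audit = select_spec(units, lag_knots_grid=(2,), var_df_grid=(4,))
        assert (lk, vdf) == (2, 4)
        assert len(audit) == 1

    def test_full_grid_audit_has_nine_rows(self):
        cfg = default_study_config(n_units=2)
        for u in cfg["units"]:
            u.update(count_mean=2.0, start="2019-01-01", end="2021-12-31")
        units = make_study(cfg, 4)
        _, audit = select_spec(units)
        assert len(audit) == 9
        assert audit["valid"].all()


class TestGVIF:
    def test_orthogonal_single_column_terms_have_unit_gvif(self):
        rng = np.random.default_rng(0)
        n = 4000
        q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        y = rng.poisson(np.exp(0.5 + 0.1 * q[:, 0] * np.sqrt(n)))
        out = gvif_check(y, {"a": q[:, :1] * np.sqrt(n), "b": q[:, 1:2] * np.sqrt(n),
                             "c": q[:, 2:3] * np.sqrt(n)})
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_duplicated_column_flags_unbounded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 1))
        y = rng.poisson(np.exp(0.2 + 0.1 * x[:, 0]))
        out = gvif_check(y, {"a": x, "b": x.copy()})
        assert not np.isfinite(out["a"]) or out["a"] > 1e3

    def test_matches_determinant_ratio_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        Z = rng.normal(size=(n, 5))
        Z[:, 2] += 0.6 * Z[:, 0]
        Z[:, 4] += 0.4 * Z[:, 1]
        y = rng.poisson(np.exp(0.3 + 0.05 * Z[:, 0]))
        blocks = {"t1": Z[:, :2], "t2": Z[:, 2:3], "t3": Z[:, 3:]}
        out = gvif_check(y, blocks)
        # independent oracle: determinant ratios on the coefficient
        # correlation matrix from the same unstratified quasi-Poisson fit
        X = sm.add_constant(Z, prepend=True)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        v = np.asarray(res.cov_params())[1:, 1:]
        R = v / np.outer(np.sqrt(np.diag(v)), np.sqrt(np.diag(v)))
        idx = {"t1": [0, 1], "t2": [2], "t3": [3, 4]}
        for name, cols in idx.items():
            rest = [i for i in range(5) if i not in cols]
            gvif = (
                np.linalg.det(R[np.ix_(cols, cols)])
                * np.linalg.det(R[np.ix_(rest, rest)])
                / np.linalg.det(R)
            )
            assert out[name] == pytest.approx(gvif ** (1 / (2 * len(cols))), rel=1e-8)
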