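"""Time-stratified case-crossover fitting by conditional quasi-Poisson.

The design compares each day only to the other days sharing its (year,
month, day-of-week) stratum, which absorbs seasonality and the weekly cycle.
The Poisson likelihood conditioned on the stratum totals is a product of
multinomials; maximizing it is equivalent to a Poisson regression with one
intercept per informative stratum, with those intercepts profiled out.  The
estimator here runs Newton iterations on the profiled (multinomial)
likelihood directly — identical estimates to the dummy-variable fit, but the
normal equations stay at the dimension of the substantive covariates
regardless of how many strata the series spans.

Overdispersion is handled quasi-likelihood style: the covariance of the
coefficients is the inverse conditional information scaled by the Pearson
dispersion, and model comparison uses QAIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from sklearn.base import BaseEstimator

from .crossbasis import CrossBasis, CrossBasisSpec
from .splines import equal_interval_knots, ns_basis


@dataclass
class StratumAssignment:
    """Per-day stratum labels under the (year, month, weekday) partition."""

    codes: np.ndarray  # dense integer code per day
    keys: list[tuple[int, int, int]]  # code -> (year, month, weekday)

    @property
    def n_strata(self) -> int:
        return len(self.keys)


def assign_strata(dates) -> StratumAssignment:
    """Assign each calendar day to its (year, month, day-of-week) stratum."""
    idx = pd.DatetimeIndex(dates)
    keys = list(zip(idx.year.tolist(), idx.month.tolist(), idx.dayofweek.tolist()))
    uniq = sorted(set(keys))
    lookup = {k: i for i, k in enumerate(uniq)}
    codes = np.fromiter((lookup[k] for k in keys), dtype=np.int64, count=len(keys))
    return StratumAssignment(codes=codes, keys=uniq)


def _informative_mask(y: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Days in strata with positive total count and at least two days.

    Strata failing either condition carry no information about the
    within-stratum rate contrasts and are dropped from the conditional
    likelihood (standard practice; logged by the estimator).
    """
    n_codes = codes.max() + 1 if codes.size else 0
    totals = np.bincount(codes, weights=y, minlength=n_codes)
    sizes = np.bincount(codes, minlength=n_codes)
    ok = (totals > 0) & (sizes >= 2)
    return ok[codes], int(ok.sum())


class ConditionalQuasiPoisson(BaseEstimator):
    """Conditional quasi-Poisson regression on time-stratified strata.

    Parameters
    ----------
    max_iter : int
        Newton iteration cap.
    tol : float
        Convergence threshold on the max absolute coefficient update.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Coefficients of the retained design columns.
    vcov_ : ndarray of shape (p, p)
        Dispersion-scaled covariance: ``dispersion_ * J^{-1}`` with J the
        conditional information at the optimum.
    dispersion_ : float
        Pearson chi-square over residual degrees of freedom
        ``n_informative_days - rank(X) - n_informative_strata``.
    loglik_ : float
        Conditional log-likelihood at the optimum (multinomial kernel;
        the data-only combinatorial constant is omitted).
    dropped_ : list of int
        Indices of design columns removed as collinear after stratum
        absorption.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, strata: StratumAssignment | np.ndarray = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if strata is None:
            raise ValueError("strata are required for a conditional fit")
        codes = strata.codes if isinstance(strata, StratumAssignment) else np.asarray(strata)
        if X.shape[0] != y.shape[0] or y.shape[0] != codes.shape[0]:
            raise ValueError("X, y and strata must have equal length")
        if (y < 0).any():
            raise ValueError("counts must be nonnegative")

        keep_days, n_informative_strata = _informative_mask(y, codes)
        if n_informative_strata == 0:
            raise ValueError("no informative strata (all stratum totals zero or single-day)")
        X, y, codes = X[keep_days], y[keep_days], codes[keep_days]
        # re-densify codes and sort days by stratum for reduceat segments
        codes = np.unique(codes, return_inverse=True)[1]
        order = np.argsort(codes, kind="stable")
        X, y, codes = X[order], y[order], codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) > 0])
        stratum_of = codes
        Y_s = np.add.reduceat(y, starts)

        # collinearity after stratum absorption: pivoted QR of the
        # within-stratum-centered design
        means = np.add.reduceat(X, starts, axis=0) / np.add.reduceat(
            np.ones_like(y), starts
        )[:, None]
        Xc = X - means[stratum_of]
        _, r, piv = _qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0)).sum())
        kept_cols = np.sort(piv[:rank])
        self.dropped_ = sorted(set(range(X.shape[1])) - set(kept_cols.tolist()))
        Xk = X[:, kept_cols]
        p = Xk.shape[1]

        def loglik(beta):
            eta = Xk @ beta
            m = np.maximum.reduceat(eta, starts)
            e = np.exp(eta - m[stratum_of])
            denom = np.add.reduceat(e, starts)
            return float(y @ eta - Y_s @ (np.log(denom) + m))

        beta = np.zeros(p)
        converged = False
        ll = loglik(beta)
        for it in range(self.max_iter):
            eta = Xk @ beta
            # per-stratum softmax with max-shift for stability
            m = np.maximum.reduceat(eta, starts)
            e = np.exp(eta - m[stratum_of])
            denom = np.add.reduceat(e, starts)
            prob = e / denom[stratum_of]
            mu = Y_s[stratum_of] * prob
            score = Xk.T @ (y - mu)
            Xmu = Xk * mu[:, None]
            M = np.add.reduceat(Xmu, starts, axis=0)  # (S, p)
            J = Xk.T @ Xmu - (M / np.sqrt(Y_s)[:, None]).T @ (M / np.sqrt(Y_s)[:, None])
            try:
                step = np.linalg.solve(J, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, score, rcond=None)[0]
            # step-halving keeps the conditional likelihood monotone even on
            # near-separated designs (e.g. heavily zero-inflated covariates)
            scale = 1.0
            for _ in range(30):
                ll_new = loglik(beta + scale * step)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            improved = ll_new - ll
            ll = ll_new
            # under quasi-separation a coefficient may drift unboundedly while
            # the likelihood plateaus; declare convergence on the likelihood
            if np.max(np.abs(scale * step)) < self.tol or improved < 1e-9 * (abs(ll) + 1.0):
                converged = True
                break
        self.n_iter_ = it + 1
        self.converged_ = converged

        eta = Xk @ beta
        m = np.maximum.reduceat(eta, starts)
        e = np.exp(eta - m[stratum_of])
        denom = np.add.reduceat(e, starts)
        mu = Y_s[stratum_of] * e / denom[stratum_of]
        self.loglik_ = float(y @ eta - Y_s @ (np.log(denom) + m))
        # fitted means can underflow to 0 on separated days; their Pearson
        # contribution is 0 when y = 0 (the limit) and infinite otherwise
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where((mu == 0) & (y == 0), 0.0, (y - mu) ** 2 / mu)
        pearson = float(np.sum(contrib))
        resid_df = len(y) - rank - n_informative_strata
        self.dispersion_ = pearson / resid_df if resid_df > 0 else np.nan
        Xmu = Xk * mu[:, None]
        M = np.add.reduceat(Xmu, starts, axis=0)
        J = Xk.T @ Xmu - (M / np.sqrt(Y_s)[:, None]).T @ (M / np.sqrt(Y_s)[:, None])
        Jinv = np.linalg.pinv(J)
        phi = self.dispersion_ if np.isfinite(self.dispersion_) else 1.0

        # re-inflate to the original column dimension, zeros for dropped cols
        self.coef_ = np.zeros(X.shape[1])
        self.coef_[kept_cols] = beta
        self.vcov_ = np.zeros((X.shape[1], X.shape[1]))
        self.vcov_[np.ix_(kept_cols, kept_cols)] = phi * Jinv
        self.kept_cols_ = kept_cols
        self.fitted_mu_ = mu
        self.rank_ = rank
        self.n_informative_days_ = int(len(y))
        self.n_strata_ = int(n_informative_strata)
        return self

    @property
    def n_params_(self) -> int:
        return int(self.rank_)

    def qaic(self, phi_ref: float | None = None) -> float:
        """QAIC = -2 loglik / phi_ref + 2 k (stratum intercepts excluded)."""
        phi = self.dispersion_ if phi_ref is None else phi_ref
        if not phi > 0:
            raise ValueError("phi_ref must be positive")
        return -2.0 * self.loglik_ / phi + 2.0 * self.n_params_


@dataclass
class StratifiedFit:
    """Flat record of one unit's fit, for serialization and pooling."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    loglik: float
    qaic: float
    n_informative_days: int
    n_strata: int
    n_params: int
    spec: CrossBasisSpec | None = None
    dropped: list = field(default_factory=list)

    @classmethod
    def from_estimator(
        cls, est: ConditionalQuasiPoisson, spec: CrossBasisSpec | None = None,
        phi_ref: float | None = None,
    ) -> "StratifiedFit":
        return cls(
            coef=est.coef_,
            vcov=est.vcov_,
            dispersion=est.dispersion_,
            loglik=est.loglik_,
            qaic=est.qaic(phi_ref),
            n_informative_days=est.n_informative_days_,
            n_strata=est.n_strata_,
            n_params=est.n_params_,
            spec=spec,
            dropped=list(est.dropped_),
        )

    def to_dict(self) -> dict:
        d = {
            "coef": self.coef.tolist(),
            "vcov": self.vcov.tolist(),
            "dispersion": self.dispersion,
            "loglik": self.loglik,
            "qaic": self.qaic,
            "n_informative_days": self.n_informative_days,
            "n_strata": self.n_strata,
            "n_params": self.n_params,
            "dropped": list(self.dropped),
        }
        if self.spec is not None:
            d["spec"] = self.spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StratifiedFit":
        return cls(
            coef=np.asarray(d["coef"], float),
            vcov=np.asarray(d["vcov"], float),
            dispersion=d["dispersion"],
            loglik=d["loglik"],
            qaic=d["qaic"],
            n_informative_days=d["n_informative_days"],
            n_strata=d["n_strata"],
            n_params=d["n_params"],
            spec=CrossBasisSpec.from_dict(d["spec"]) if "spec" in d else None,
            dropped=list(d.get("dropped", [])),
        )


def fit_conditional_quasipoisson(y, X, strata) -> StratifiedFit:
    """Functional wrapper around :class:`ConditionalQuasiPoisson`."""
    est = ConditionalQuasiPoisson().fit(X, y, strata=strata)
    return StratifiedFit.from_estimator(est)


def confounder_design(weather: pd.DataFrame, df: int = 5) -> np.ndarray:
    """Same-day confounder splines: 5-df equal-interval natural cubic splines
    on relative humidity, rainfall, and sunshine duration (no lags)."""
    blocks = []
    for col in ("humidity_pct", "rain_mm", "sunshine_h"):
        v = weather[col].to_numpy(dtype=float)
        blocks.append(ns_basis(v, equal_interval_knots(v, df)))
    return np.hstack(blocks)


def unit_design(series, spec: CrossBasisSpec, confounder_df: int = 5):
    """Design matrix for one unit: cross-basis columns first, then confounder
    splines; rows before ``max_lag`` flagged incomplete.

    Returns ``(X, y, strata, complete_mask)``.
    """
    from .crossbasis import build_crossbasis

    cb = build_crossbasis(series.weather["temp_c"].to_numpy(float), spec)
    conf = confounder_design(series.weather, confounder_df)
    X = np.hstack([cb.values, conf])
    strata = assign_strata(series.dates)
    usable = cb.complete & np.isfinite(X).all(axis=1)
    return X, np.asarray(series.counts, dtype=float), strata, usable


def _fit_unit_cell(series, spec: CrossBasisSpec):
    X, y, strata, complete = unit_design(series, spec)
    est = ConditionalQuasiPoisson().fit(
        X[complete], y[complete], strata=StratumAssignment(strata.codes[complete], strata.keys)
    )
    return est


def pooled_exposure_temps(series_list) -> np.ndarray:
    """All units' temperatures concatenated (the overall distribution)."""
    return np.concatenate(
        [np.asarray(s.weather["temp_c"], dtype=float) for s in series_list]
    )


def shared_crossbasis_spec(series_list, lag_knots: int, var_df: int,
                           max_lag: int = 21) -> CrossBasisSpec:
    """One cross-basis spec shared by every unit.

    The exposure knots are placed at equal intervals over the *pooled*
    observed temperature range.  A shared basis is what makes the per-unit
    reduced coefficients commensurable: pooling coefficients estimated on
    unit-specific bases would average curves expressed in different
    coordinate systems and bias the pooled exposure-response.
    """
    cb = CrossBasis(var_df=var_df, lag_knots=lag_knots, max_lag=max_lag)
    cb.fit(pooled_exposure_temps(series_list))
    return cb.spec_


def select_spec(
    series_list,
    lag_knots_grid=(1, 2, 3),
    var_df_grid=(3, 4, 5),
    max_lag: int = 21,
):
    """Pick the cross-basis dimensions minimizing the summed QAIC.

    Every (lag-knots, exposure-df) cell of the grid is fitted on every unit
    with the shared exposure basis; each unit's QAIC uses a single reference
    dispersion taken from its fit of the richest cell, and the cell with the
    smallest sum across units wins.  Returns the winning
    ``(lag_knots, var_df)`` pair and the full grid audit table.
    """
    grid = list(product(lag_knots_grid, var_df_grid))
    rich = (max(lag_knots_grid), max(var_df_grid))
    # reference dispersion per unit from the richest model
    rich_spec = shared_crossbasis_spec(series_list, *rich, max_lag)
    phi_ref = [_fit_unit_cell(s, rich_spec).dispersion_ for s in series_list]
    rows = []
    for cell in grid:
        spec = shared_crossbasis_spec(series_list, *cell, max_lag)
        total, ok = 0.0, True
        for s, phi in zip(series_list, phi_ref):
            try:
                est = _fit_unit_cell(s, spec)
                total += est.qaic(phi)
            except (ValueError, np.linalg.LinAlgError):
                ok = False
                break
        rows.append(
            {"lag_knots": cell[0], "var_df": cell[1],
             "qaic_sum": total if ok else np.nan, "valid": ok}
        )
    audit = pd.DataFrame(rows)
    valid = audit[audit["valid"]]
    if valid.empty:
        raise ValueError("all grid cells failed")
    best = valid.loc[valid["qaic_sum"].idxmin()]
    return (int(best["lag_knots"]), int(best["var_df"])), audit


def gvif_check(y, term_blocks: dict[str, np.ndarray], add_intercept: bool = True) -> dict[str, float]:
    """Adjusted GVIF per grouped term from an *unstratified* quasi-Poisson fit.

    Multicollinearity cannot be assessed on the conditional model, so a plain
    quasi-Poisson regression with an intercept is used.  For each term block
    the generalized variance inflation factor is the determinant ratio
    ``det(R_gg) det(R_rest) / det(R)`` on the coefficient correlation matrix;
    the reported value is ``GVIF^(1/(2 df_g))``, comparable across terms of
    different dimension.  Perfectly collinear designs yield ``inf``.
    """
    import statsmodels.api as sm

    names, blocks = list(term_blocks.keys()), list(term_blocks.values())
    X = np.hstack(blocks)
    sizes = [b.shape[1] for b in blocks]
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
    model = sm.GLM(np.asarray(y, float), X, family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2")
        v = np.asarray(res.cov_params())
    except Exception:
        return {n: float("inf") for n in names}
    if add_intercept:
        v = v[1:, 1:]
    sd = np.sqrt(np.diag(v))
    if not np.all(sd > 0):
        return {n: float("inf") for n in names}
    R = v / np.outer(sd, sd)
    det_R = np.linalg.det(R)
    out = {}
    offset = 0
    for name, k in zip(names, sizes):
        idx = np.arange(offset, offset + k)
        rest = np.setdiff1d(np.arange(R.shape[0]), idx)
        if det_R <= 0:
            out[name] = float("inf")
        else:
            gvif = (
                np.linalg.det(R[np.ix_(idx, idx)])
                * np.linalg.det(R[np.ix_(rest, rest)])
                / det_R
            )
            out[name] = float(gvif ** (1.0 / (2.0 * k)))
        offset += k
    return out
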