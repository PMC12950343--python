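"""Multivariate random-effects meta-analysis of reduced-curve coefficients.

Second stage of the two-stage design: each unit contributes its overall
cumulative coefficients ``theta_i`` (length p) with within-unit covariance
``S_i``; the units are pooled under

    theta_i ~ N(theta, S_i + psi)

with ``psi`` the between-unit covariance, estimated by REML (default), ML,
or fixed at zero.  ``psi`` is parameterized through its Cholesky factor so
it stays positive semidefinite during optimization.  The fit also yields
Cochran's Q (against the fixed-effect pooled estimate), I-squared, and the
per-unit best linear unbiased predictions (BLUPs), which shrink each unit's
curve toward the pool in proportion to its within-unit uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator


def _gls_pool(thetas, vcovs, psi):
    """GLS pooled estimate and covariance for a given psi."""
    W_sum = np.zeros_like(psi)
    Wt_sum = np.zeros(psi.shape[0])
    Ws = []
    for t, S in zip(thetas, vcovs):
        W = np.linalg.inv(S + psi)
        Ws.append(W)
        W_sum += W
        Wt_sum += W @ t
    pooled_vcov = np.linalg.inv(W_sum)
    pooled = pooled_vcov @ Wt_sum
    return pooled, pooled_vcov, Ws, W_sum


def _neg_loglik(chol_params, thetas, vcovs, p, reml):
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = chol_params
    psi = L @ L.T
    try:
        pooled, _, Ws, W_sum = _gls_pool(thetas, vcovs, psi)
    except np.linalg.LinAlgError:
        return 1e12
    ll = 0.0
    for t, S, W in zip(thetas, vcovs, Ws):
        r = t - pooled
        sign, logdet = np.linalg.slogdet(S + psi)
        if sign <= 0:
            return 1e12
        ll += -0.5 * (logdet + r @ W @ r)
    if reml:
        sign, logdet = np.linalg.slogdet(W_sum)
        if sign <= 0:
            return 1e12
        ll += -0.5 * logdet
    return -ll


def _moment_psi(thetas, vcovs):
    """Method-of-moments start/fallback: between-unit covariance of the
    estimates minus the mean within-unit covariance, clipped to PSD."""
    T = np.asarray(thetas)
    emp = np.cov(T.T, ddof=1) if T.shape[0] > 1 else np.zeros((T.shape[1],) * 2)
    emp = np.atleast_2d(emp)
    raw = emp - np.mean(vcovs, axis=0)
    w, v = np.linalg.eigh((raw + raw.T) / 2)
    return (v * np.clip(w, 0, None)) @ v.T


class MVMeta(BaseEstimator):
    """Intercept-only multivariate meta-analysis estimator.

    Parameters
    ----------
    method : {"reml", "ml", "fixed"}
        Between-unit covariance estimation.  On optimizer failure the fit
        falls back reml -> ml -> method-of-moments, recorded in
        ``method_used_``.

    Attributes
    ----------
    coef_ : pooled coefficients (p,)
    vcov_ : covariance of the pooled coefficients (p, p)
    psi_ : between-unit covariance (p, p), PSD
    q_, q_df_, q_pvalue_, i2_ : heterogeneity statistics (Cochran
        construction against the fixed-effect pooled estimate)
    blups_ : list of (theta, vcov) per unit
    """

    def __init__(self, method: str = "reml", max_iter: int = 500):
        self.method = method
        self.max_iter = max_iter

    def fit(self, thetas, vcovs, y=None):
        thetas = [np.asarray(t, float) for t in thetas]
        vcovs = [np.asarray(S, float) for S in vcovs]
        p = thetas[0].shape[0]
        if any(t.shape != (p,) for t in thetas) or any(S.shape != (p, p) for S in vcovs):
            raise ValueError("all theta vectors and vcov matrices must share one dimension")
        n = len(thetas)
        if self.method != "fixed" and n < 2:
            raise ValueError("random-effects pooling needs at least 2 units")

        # fixed-effect fit always computed: it anchors Q and serves method="fixed"
        zero = np.zeros((p, p))
        fixed_pooled, fixed_vcov, _, _ = _gls_pool(thetas, vcovs, zero)
        q = 0.0
        for t, S in zip(thetas, vcovs):
            r = t - fixed_pooled
            q += float(r @ np.linalg.solve(S, r))
        self.q_ = q
        self.q_df_ = (n - 1) * p
        self.q_pvalue_ = float(stats.chi2.sf(q, self.q_df_)) if self.q_df_ > 0 else np.nan
        self.i2_ = float(max(0.0, (q - self.q_df_) / q) * 100.0) if q > 0 else 0.0

        if self.method == "fixed":
            psi = zero
            self.method_used_ = "fixed"
            self.converged_ = True
        else:
            psi, used, ok = self._estimate_psi(thetas, vcovs, p)
            self.method_used_ = used
            self.converged_ = ok

        pooled, pooled_vcov, _, _ = _gls_pool(thetas, vcovs, psi)
        self.coef_ = pooled
        self.vcov_ = pooled_vcov
        self.psi_ = psi
        self.n_units_ = n
        self.thetas_ = thetas
        self.vcovs_ = vcovs
        self.blups_ = self._blups(thetas, vcovs, psi, pooled, pooled_vcov)
        return self

    def _estimate_psi(self, thetas, vcovs, p):
        def chol_params(psi):
            w, v = np.linalg.eigh(psi)
            L = np.linalg.cholesky((v * np.maximum(w, 1e-10)) @ v.T + 1e-10 * np.eye(p))
            return L[np.tril_indices(p)]

        # two starts: the method-of-moments estimate, and a near-zero matrix.
        # In directions where the within-unit covariances dominate, the
        # likelihood is flat in psi and the optimizer keeps whatever the
        # start supplied; preferring the smaller-trace solution on a
        # likelihood tie avoids spuriously large heterogeneity there.
        starts = [
            chol_params(_moment_psi(thetas, vcovs)),
            chol_params(1e-4 * np.mean([np.diag(np.diag(S)) for S in vcovs], axis=0)),
        ]
        methods = ["reml", "ml"] if self.method == "reml" else ["ml"]
        for m in methods:
            best = None
            for x0 in starts:
                for opt_method, options in (
                    ("L-BFGS-B", {"maxiter": self.max_iter}),
                    ("Nelder-Mead", {"maxiter": self.max_iter * p,
                                     "xatol": 1e-8, "fatol": 1e-10}),
                ):
                    res = optimize.minimize(
                        _neg_loglik, x0, args=(thetas, vcovs, p, m == "reml"),
                        method=opt_method, options=options,
                    )
                    if np.isfinite(res.fun) and res.fun < 1e11:
                        break
                else:
                    continue
                L = np.zeros((p, p))
                L[np.tril_indices(p)] = res.x
                cand = (res.fun, float(np.trace(L @ L.T)), L @ L.T, bool(res.success))
                if (
                    best is None
                    or cand[0] < best[0] - 1e-6
                    or (abs(cand[0] - best[0]) <= 1e-6 and cand[1] < best[1])
                ):
                    best = cand
            if best is not None:
                return best[2], m, best[3]
        return _moment_psi(thetas, vcovs), "moments", False

    @staticmethod
    def _blups(thetas, vcovs, psi, pooled, pooled_vcov):
        out = []
        eye = np.eye(psi.shape[0])
        for t, S in zip(thetas, vcovs):
            H = psi @ np.linalg.inv(psi + S)
            b = pooled + H @ (t - pooled)
            resid = eye - H
            v = psi - H @ psi + resid @ pooled_vcov @ resid.T
            out.append((b, (v + v.T) / 2))
        return out


@dataclass
class MetaResult:
    """Serializable summary of a multivariate meta-analysis."""

    pooled_theta: np.ndarray
    pooled_vcov: np.ndarray
    psi: np.ndarray
    q: float
    q_df: int
    q_pvalue: float
    i2: float
    blups: list = field(default_factory=list)
    method_used: str = "reml"
    converged: bool = True

    @classmethod
    def from_estimator(cls, est: MVMeta) -> "MetaResult":
        return cls(
            pooled_theta=est.coef_,
            pooled_vcov=est.vcov_,
            psi=est.psi_,
            q=est.q_,
            q_df=est.q_df_,
            q_pvalue=est.q_pvalue_,
            i2=est.i2_,
            blups=est.blups_,
            method_used=est.method_used_,
            converged=est.converged_,
        )

    def to_dict(self) -> dict:
        return {
            "pooled_theta": self.pooled_theta.tolist(),
            "pooled_vcov": self.pooled_vcov.tolist(),
            "psi": self.psi.tolist(),
            "q": self.q,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
            "i2": self.i2,
            "blups": [{"theta": b.tolist(), "vcov": v.tolist()} for b, v in self.blups],
            "method_used": self.method_used,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetaResult":
        return cls(
            pooled_theta=np.asarray(d["pooled_theta"], float),
            pooled_vcov=np.asarray(d["pooled_vcov"], float),
            psi=np.asarray(d["psi"], float),
            q=d["q"],
            q_df=d["q_df"],
            q_pvalue=d["q_pvalue"],
            i2=d["i2"],
            blups=[
                (np.asarray(b["theta"], float), np.asarray(b["vcov"], float))
                for b in d["blups"]
            ],
            method_used=d.get("method_used", "reml"),
            converged=d.get("converged", True),
        )


def mvmeta_fit(thetas, vcovs, method: str = "reml") -> MetaResult:
    """Functional wrapper around :class:`MVMeta`."""
    return MetaResult.from_estimator(MVMeta(method=method).fit(thetas, vcovs))


def blup(meta: MetaResult, thetas=None, vcovs=None) -> list:
    """Per-unit BLUP coefficient vectors (and covariances) from a fit."""
    if thetas is None:
        return meta.blups
    return MVMeta._blups(
        [np.asarray(t, float) for t in thetas],
        [np.asarray(S, float) for S in vcovs],
        meta.psi, meta.pooled_theta, meta.pooled_vcov,
    )


def heterogeneity(meta: MetaResult) -> tuple[float, int, float, float]:
    """(Q, df, p, I-squared) of a fitted meta-analysis."""
    return meta.q, meta.q_df, meta.q_pvalue, meta.i2
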