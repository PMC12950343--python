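"""Reduction of cross-basis coefficients to overall cumulative curves.

Summing the fitted exposure-lag surface over lags 0..L collapses the
cross-basis coefficients ``eta`` (length v_x * v_l) to ``theta`` (length
v_x), the coefficients of the *overall cumulative* exposure-response on the
exposure basis alone.  Risk ratios are then contrasts of that curve against
a reference temperature — by convention the minimum-risk temperature (MMT)
inside a percentile band of the observed temperature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .crossbasis import CrossBasisSpec, cumulative_lag_weights
from .splines import NCSSpec, ns_basis


@dataclass
class ReducedCurve:
    """Overall cumulative exposure-response coefficients.

    ``ref`` is the centering temperature; ``None`` means uncentered (log-RR
    predictions are raw basis contractions, meaningful only as differences).
    """

    theta: np.ndarray
    vcov: np.ndarray
    var_spec: NCSSpec
    ref: float | None = None
    unit_id: str = "pooled"

    @property
    def centered(self) -> bool:
        return self.ref is not None

    def predict_loglink(self, temps) -> np.ndarray:
        """Cumulative log-RR at ``temps`` (vs ``ref`` when centered)."""
        b = np.atleast_2d(ns_basis(temps, self.var_spec))
        if self.centered:
            b = b - ns_basis(self.ref, self.var_spec)[None, :]
        return b @ self.theta

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "vcov": self.vcov.tolist(),
            "var_spec": self.var_spec.to_dict(),
            "ref": self.ref,
            "unit_id": self.unit_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedCurve":
        return cls(
            theta=np.asarray(d["theta"], float),
            vcov=np.asarray(d["vcov"], float),
            var_spec=NCSSpec.from_dict(d["var_spec"]),
            ref=d.get("ref"),
            unit_id=d.get("unit_id", "pooled"),
        )


def reduce_overall(coef, vcov, spec: CrossBasisSpec, unit_id: str = "unit") -> ReducedCurve:
    """Collapse cross-basis coefficients over lags.

    With the exposure-fastest column order, ``theta_j = sum_k eta_{jk} M_k``
    where ``M_k`` sums the lag basis column over integer lags; the covariance
    maps through the same linear transform.  ``coef``/``vcov`` may include
    trailing confounder-spline entries — only the leading cross-basis block
    is used.
    """
    coef = np.asarray(coef, float)
    vcov = np.asarray(vcov, float)
    nc = spec.n_columns
    if coef.shape[0] < nc:
        raise ValueError(
            f"coefficient vector of length {coef.shape[0]} shorter than "
            f"cross-basis width {nc}"
        )
    eta = coef[:nc]
    V = vcov[:nc, :nc]
    M = cumulative_lag_weights(spec)
    A = np.kron(M.reshape(1, -1), np.eye(spec.n_var))  # (v_x, v_x*v_l)
    theta = A @ eta
    return ReducedCurve(theta=theta, vcov=A @ V @ A.T, var_spec=spec.var_spec,
                        unit_id=unit_id)


def find_mmt(curve: ReducedCurve, temps_observed, band=(1.0, 99.0),
             resolution: float = 0.1) -> float:
    """Minimum-risk temperature: grid argmin of the cumulative curve.

    The search runs at the stated resolution over the band's percentiles of
    the observed temperatures; ties break toward the lower temperature (a
    flat/null curve therefore returns the band's lower bound).
    """
    temps_observed = np.asarray(temps_observed, float)
    temps_observed = temps_observed[np.isfinite(temps_observed)]
    if temps_observed.size == 0:
        raise ValueError("empty temperature series")
    lo, hi = band
    if not (0 < lo < hi < 100):
        raise ValueError("band percentiles must satisfy 0 < low < high < 100")
    p_lo, p_hi = np.percentile(temps_observed, [lo, hi])
    grid = np.arange(p_lo, p_hi + resolution / 2, resolution)
    pred = np.atleast_2d(ns_basis(grid, curve.var_spec)) @ curve.theta
    # round to suppress float jitter so exact ties resolve to the lower temp
    return float(grid[np.argmin(np.round(pred, 12))])


def center_curve(curve: ReducedCurve, ref: float) -> ReducedCurve:
    """Re-express the curve relative to a reference temperature.

    Centering is a property of prediction, not of the coefficients: the
    returned curve carries the same ``theta``/``vcov`` with ``ref`` recorded,
    so re-centering is idempotent and exactly invertible.
    """
    return replace(curve, ref=float(ref))


def rr_curve(curve: ReducedCurve, temps, alpha: float = 0.05) -> pd.DataFrame:
    """RR and pointwise CI along a temperature grid, relative to the ref.

    Normal-approximation intervals on the log scale; a point is flagged
    significant when the CI lower bound exceeds 1.
    """
    if not curve.centered:
        raise ValueError("curve must be centered at a reference temperature")
    temps = np.atleast_1d(np.asarray(temps, float))
    contrast = np.atleast_2d(ns_basis(temps, curve.var_spec)) - ns_basis(
        curve.ref, curve.var_spec
    )[None, :]
    logrr = contrast @ curve.theta
    var = np.einsum("ij,jk,ik->i", contrast, curve.vcov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    out = pd.DataFrame(
        {
            "temperature": temps,
            "rr": np.exp(logrr),
            "ci_low": np.exp(logrr - z * se),
            "ci_high": np.exp(logrr + z * se),
        }
    )
    out["significant"] = out["ci_low"] > 1.0
    return out
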