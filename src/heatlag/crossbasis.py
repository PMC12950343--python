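"""Exposure-lag tensor-product cross-basis for distributed-lag models.

The cross-basis couples a natural-spline basis over the exposure (daily mean
temperature) with a natural-spline basis over the lag dimension (integer lags
``0..L``).  Entry ``(t, jk)`` of the matrix is

    sum_{l=0..L}  b_j(x_{t-l}) * c_k(l)

so a coefficient vector on the cross-basis encodes a full bivariate
exposure-lag-response surface.  Columns are ordered exposure-fastest
("j-major"): column index = ``k * v_x + j``.  This ordering is recorded with
the matrix and relied upon by the curve-reduction step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .splines import NCSSpec, equal_interval_knots, log_spaced_lag_knots, ns_basis


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure spec, lag spec, and maximum lag of a cross-basis."""

    var_spec: NCSSpec
    lag_spec: NCSSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def n_var(self) -> int:
        return self.var_spec.df

    @property
    def n_lag(self) -> int:
        return self.lag_spec.df

    @property
    def n_columns(self) -> int:
        return self.n_var * self.n_lag

    def column_labels(self) -> list[str]:
        """Header names encoding (j, k) per column, exposure index fastest."""
        return [
            f"b{j + 1}.c{k + 1}"
            for k in range((self.n_lag))
            for j in range(self.n_var)
        ]

    def to_dict(self) -> dict:
        return {
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": int(self.max_lag),
            "column_order": "exposure-fastest",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            var_spec=NCSSpec.from_dict(d["var_spec"]),
            lag_spec=NCSSpec.from_dict(d["lag_spec"]),
            max_lag=int(d["max_lag"]),
        )


@dataclass
class CrossBasisMatrix:
    """A built cross-basis with its spec and the first complete row index.

    Rows ``0..max_lag-1`` lack a full lag window; they are computed with the
    available lags only and must be excluded from fitting (``valid_from``
    marks the first complete row).
    """

    values: np.ndarray
    spec: CrossBasisSpec

    @property
    def valid_from(self) -> int:
        return self.spec.max_lag

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of rows with a full lag window."""
        mask = np.ones(len(self.values), dtype=bool)
        mask[: self.valid_from] = False
        return mask


def lag_basis_values(spec: CrossBasisSpec) -> np.ndarray:
    """Lag basis evaluated at the integer lags 0..L, shape (L+1, v_l)."""
    lags = np.arange(spec.max_lag + 1, dtype=float)
    return ns_basis(lags, spec.lag_spec)


def build_crossbasis(x, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Build the cross-basis matrix of a temperature series."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= spec.max_lag:
        raise ValueError(
            f"series of length {n} is shorter than max_lag + 1 = {spec.max_lag + 1}"
        )
    bx = ns_basis(x, spec.var_spec)  # (n, v_x)
    cl = lag_basis_values(spec)  # (L+1, v_l)
    v_x, v_l = spec.n_var, spec.n_lag
    out = np.zeros((n, v_l, v_x))
    for lag in range(spec.max_lag + 1):
        # day t gets b(x_{t-lag}) weighted by the lag basis at `lag`
        out[lag:] += cl[lag][None, :, None] * bx[: n - lag, None, :]
    return CrossBasisMatrix(out.reshape(n, v_l * v_x), spec)


def cumulative_lag_weights(spec: CrossBasisSpec) -> np.ndarray:
    """M_k = sum over integer lags 0..L of the lag basis column c_k."""
    return lag_basis_values(spec).sum(axis=0)


class CrossBasis(BaseEstimator, TransformerMixin):
    """Cross-basis construction as a scikit-learn transformer.

    ``fit`` derives the knot placement from the data: exposure knots at equal
    intervals between the observed min and max (``var_df`` columns, no
    intercept), lag knots equally spaced on the log-lag scale
    (``lag_knots`` interior knots, intercept included).  Explicit
    :class:`~heatlag.splines.NCSSpec` objects may be passed instead to pin
    the knots, e.g. when transferring a basis across units.

    Parameters
    ----------
    var_df : int
        Dimension of the exposure basis (the field's usual grid is 3-5).
    lag_knots : int
        Number of interior knots on the log-lag scale (usual grid 1-3).
    max_lag : int
        Maximum lag in days; 21 captures delayed cold effects.
    var_spec, lag_spec : NCSSpec, optional
        Pre-specified bases overriding the data-driven placement.
    """

    def __init__(self, var_df=4, lag_knots=2, max_lag=21, var_spec=None, lag_spec=None):
        self.var_df = var_df
        self.lag_knots = lag_knots
        self.max_lag = max_lag
        self.var_spec = var_spec
        self.lag_spec = lag_spec

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        var_spec = self.var_spec or equal_interval_knots(x, self.var_df)
        lag_spec = self.lag_spec or log_spaced_lag_knots(self.lag_knots, self.max_lag)
        self.spec_ = CrossBasisSpec(var_spec, lag_spec, self.max_lag)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "spec_"):
            raise RuntimeError("CrossBasis must be fitted before transform")
        return build_crossbasis(np.asarray(X, dtype=float).ravel(), self.spec_).values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.spec_.column_labels(), dtype=object)
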