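"""Natural cubic spline bases for exposure, lag, and confounder dimensions.

A natural cubic spline is a piecewise cubic polynomial, C2-continuous at its
knots, constrained to be *linear* beyond the boundary knots.  The basis built
here follows the convention of R's ``splines::ns``: a cubic B-spline basis on
the augmented knot sequence is projected onto the null space of the
second-derivative constraints at the two boundary knots, and evaluation
outside the boundaries extrapolates linearly (first-order Taylor expansion at
the nearest boundary).  With ``K`` interior knots the basis has ``K + 1``
columns without an intercept and ``K + 2`` with one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class NCSSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    interior_knots : tuple of float
        Strictly increasing knots strictly inside the boundary knots.
    boundary_knots : (float, float)
        Interval on which the spline is cubic; linear outside.
    intercept : bool
        Whether the basis spans constants.  The exposure basis of a
        cross-basis carries no intercept (absorbed by the strata); the lag
        basis does, so that lag-0 effects are representable.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        a, b = self.boundary_knots
        if not np.isfinite([a, b]).all() or not a < b:
            raise ValueError(f"invalid boundary knots {self.boundary_knots!r}")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (np.diff(ik) <= 0).any():
            raise ValueError("interior knots must be strictly increasing")
        if ik.size and ((ik <= a) | (ik >= b)).any():
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in ik))
        object.__setattr__(self, "boundary_knots", (float(a), float(b)))

    @property
    def df(self) -> int:
        """Number of basis columns."""
        return len(self.interior_knots) + 1 + (1 if self.intercept else 0)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NCSSpec":
        return cls(
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            intercept=bool(d["intercept"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NCSSpec":
        return cls.from_dict(yaml.safe_load(text))


def _ns_projection(spec: NCSSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (augmented knot vector, projection matrix) for the spec."""
    a, b = spec.boundary_knots
    t = np.concatenate([[a] * 4, np.asarray(spec.interior_knots, float), [b] * 4])
    n_b = len(t) - 4  # cubic B-spline columns
    # second derivatives of every B-spline column at the two boundaries
    bs = BSpline(t, np.eye(n_b), 3, extrapolate=True)
    const = bs.derivative(2)(np.array([a, b]))  # (2, n_b)
    keep = slice(None) if spec.intercept else slice(1, None)
    const = const[:, keep]
    q, _ = np.linalg.qr(const.T, mode="complete")
    proj = q[:, 2:]  # null space of the two natural constraints
    return t, proj


def ns_basis(x, spec: NCSSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Values outside the boundary knots are handled by linear extrapolation
    from the nearest boundary (the natural-spline property), never an error:
    subgroup curves may be evaluated at a shared reference temperature that
    lies outside the subgroup's own observed range.
    """
    x = np.asarray(x, dtype=float)
    if spec.df < 2 and not spec.intercept:
        raise ValueError("basis must have at least 2 columns without an intercept")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    a, b = spec.boundary_knots
    t, proj = _ns_projection(spec)
    n_b = len(t) - 4
    keep = slice(None) if spec.intercept else slice(1, None)

    xc = np.clip(x, a, b)
    bs = BSpline(t, np.eye(n_b), 3, extrapolate=True)
    basis = bs(xc)[:, keep] @ proj

    outside = (x < a) | (x > b)
    if outside.any():
        d1 = bs.derivative(1)
        for bound in (a, b):
            mask = (x < bound) if bound == a else (x > bound)
            if mask.any():
                f0 = bs(np.array([bound]))[:, keep] @ proj
                g0 = d1(np.array([bound]))[:, keep] @ proj
                basis[mask] = f0 + (x[mask, None] - bound) * g0
    return basis[0] if scalar else basis


def equal_interval_knots(x, df: int, intercept: bool = False) -> NCSSpec:
    """Spline spec with equally spaced interior knots over the range of ``x``.

    Boundary knots sit at ``min(x)`` and ``max(x)``; the ``df - 1`` interior
    knots (no-intercept convention) divide that range into equal intervals.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values in x")
    a, b = float(x.min()), float(x.max())
    if a == b:
        raise ValueError("cannot place knots on a constant series")
    if df < 2:
        raise ValueError("df must be >= 2")
    n_interior = df - 1 - (1 if intercept else 0)
    interior = a + (b - a) * np.arange(1, n_interior + 1) / (n_interior + 1)
    return NCSSpec(tuple(interior), (a, b), intercept=intercept)


def log_spaced_lag_knots(n_knots: int, max_lag: int) -> NCSSpec:
    """Lag-dimension spec with knots equally spaced on the log-lag scale.

    Interior knots sit at ``exp(k * log(max_lag) / (n_knots + 1))`` for
    ``k = 1..n_knots`` — equal spacing on ``[log 1, log max_lag]`` with the
    endpoints excluded — with boundary knots at 0 and ``max_lag``.  The lag
    basis includes an intercept so that cumulative (summed-over-lags) effects
    and pure lag-0 effects are both representable.
    """
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2 for interior lag knots")
    ks = np.arange(1, n_knots + 1)
    interior = np.exp(ks * np.log(max_lag) / (n_knots + 1))
    return NCSSpec(tuple(interior), (0.0, float(max_lag)), intercept=True)
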