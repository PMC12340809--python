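"""B-spline bases for time-varying coefficient curves.

Every smooth effect in the model -- the subtype mean trajectory mu_k(t), the
static-covariate effects beta_pk(t) and the longitudinal-covariate effects
rho_mk(t) -- is represented as a linear combination of a common B-spline basis
b(t) = (b_1(t), ..., b_nb(t)).  Smoothness is controlled by a roughness
penalty R(theta) = theta' Q theta with Q_rs = int b_r''(t) b_s''(t) dt, whose
null space is exactly the affine curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """A clamped B-spline basis on [t_min, t_max].

    Attributes
    ----------
    degree : polynomial degree (3 = cubic).
    interior_knots : sorted knots strictly inside the boundary.
    boundary : (t_min, t_max).
    nb : number of basis functions, = len(interior_knots) + degree + 1.
    """

    degree: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    nb: int = field(init=False)

    def __post_init__(self) -> None:
        ik = np.asarray(self.interior_knots, dtype=float)
        object.__setattr__(self, "interior_knots", ik)
        object.__setattr__(self, "nb", ik.size + self.degree + 1)

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector with degree+1 repeats at each boundary."""
        lo, hi = self.boundary
        return np.concatenate(
            [np.full(self.degree + 1, lo), self.interior_knots, np.full(self.degree + 1, hi)]
        )

    def to_dict(self) -> dict:
        return {
            "degree": int(self.degree),
            "interior_knots": self.interior_knots.tolist(),
            "boundary": [float(self.boundary[0]), float(self.boundary[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(
            degree=int(d["degree"]),
            interior_knots=np.asarray(d["interior_knots"], dtype=float),
            boundary=(float(d["boundary"][0]), float(d["boundary"][1])),
        )


def build_basis(
    t_min: float,
    t_max: float,
    nb: int = 8,
    degree: int = 3,
    knot_rule: str = "equal",
    times: np.ndarray | None = None,
) -> SplineBasis:
    """Construct a B-spline basis with ``nb`` functions on [t_min, t_max].

    ``knot_rule`` places the nb - degree - 1 interior knots either equally
    spaced ("equal", default) or at quantiles of the pooled observed times
    ("quantile", requires ``times``).
    """
    if not t_max > t_min:
        raise ValueError(f"degenerate time range [{t_min}, {t_max}]")
    n_interior = nb - degree - 1
    if n_interior < 0:
        raise ValueError(f"nb={nb} too small for degree={degree}; need nb >= degree + 1")
    if knot_rule == "equal":
        interior = np.linspace(t_min, t_max, n_interior + 2)[1:-1]
    elif knot_rule == "quantile":
        if times is None:
            raise ValueError("knot_rule='quantile' requires observed times")
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.asarray(times, dtype=float), probs)
        interior = np.clip(interior, t_min + 1e-12, t_max - 1e-12)
    else:
        raise ValueError(f"unknown knot_rule {knot_rule!r}")
    return SplineBasis(degree=degree, interior_knots=interior, boundary=(t_min, t_max))


def _clamp(basis: SplineBasis, t: np.ndarray) -> np.ndarray:
    lo, hi = basis.boundary
    t = np.asarray(t, dtype=float)
    if np.any(t < lo) or np.any(t > hi):
        warnings.warn(
            "evaluation times outside the basis range were clamped to the boundary",
            RuntimeWarning,
            stacklevel=3,
        )
        t = np.clip(t, lo, hi)
    return t


def eval_basis(basis: SplineBasis, t_values: np.ndarray) -> np.ndarray:
    """Design matrix B with B[j, r] = b_r(t_j); rows sum to one.

    Times outside the boundary are clamped (no extrapolation).
    """
    t = _clamp(basis, t_values)
    B = BSpline.design_matrix(t, basis.knots, basis.degree, extrapolate=False)
    return np.asarray(B.todense())


def eval_basis_deriv(basis: SplineBasis, t_values: np.ndarray, order: int = 2) -> np.ndarray:
    """Matrix of order-th derivatives b_r^(order)(t_j)."""
    t = _clamp(basis, t_values)
    spl = BSpline(basis.knots, np.eye(basis.nb), basis.degree, extrapolate=True)
    return spl.derivative(order)(t)


def eval_curve(basis: SplineBasis, coef: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the curve b(t)' theta on a grid."""
    coef = np.asarray(coef, dtype=float)
    if coef.shape[-1] != basis.nb:
        raise ValueError(f"coefficient length {coef.shape[-1]} != nb {basis.nb}")
    return eval_basis(basis, t_grid) @ coef if coef.ndim == 1 else eval_basis(basis, t_grid) @ coef.T


def roughness_matrix(basis: SplineBasis) -> np.ndarray:
    """Exact integrated squared-second-derivative penalty matrix Q.

    Q_rs = int b_r''(t) b_s''(t) dt over the basis range.  The integrand is a
    piecewise polynomial of degree 2*(degree-2) on each knot interval, so
    Gauss-Legendre quadrature with max(degree-1, 1) nodes per interval is
    exact.  Degree < 2 gives the zero matrix.
    """
    nb = basis.nb
    if basis.degree < 2:
        return np.zeros((nb, nb))
    lo, hi = basis.boundary
    breaks = np.unique(np.concatenate([[lo], basis.interior_knots, [hi]]))
    n_gl = max(basis.degree - 1, 1)
    nodes, weights = leggauss(n_gl)
    Q = np.zeros((nb, nb))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        t = 0.5 * (a + b) + half * nodes
        D2 = eval_basis_deriv(basis, t, order=2)  # (n_gl, nb)
        Q += half * (D2 * weights[:, None]).T @ D2
    return 0.5 * (Q + Q.T)
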