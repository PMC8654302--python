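"""Kimura distribution of heteroplasmy under pure random drift.

The distribution of an allele frequency ``h`` after a period of neutral
drift from an initial frequency ``p`` is a mixture of point masses at the
fixation boundaries ``h = 0`` and ``h = 1`` and a continuous density on
``(0, 1)`` given by an eigenfunction series in Gegenbauer polynomials.
Drift intensity is summarised by a single parameter ``b`` in ``[0, 1]``:
``b = 1`` means no drift (the distribution is a point mass at ``p``) and
``b -> 0`` means complete fixation (masses ``1 - p`` at 0 and ``p`` at 1).
For every ``(p, b)`` the mean is ``p`` and the variance is
``p(1-p)(1-b)``, which is what makes the moment fit below possible.

The series uses ``F_i(x) = 2F1(1-i, i+2; 2; x)``, a degree ``i-1``
polynomial proportional to the Jacobi polynomial ``P_{i-1}^{(1,1)}(1-2x)``:

    density   f(x) = sum_i  i(i+1)(2i+1) p q F_i(p) F_i(x) b^{i(i+1)/2}
    loss      P0   = q + sum_i (2i+1) p q (-1)^i F_i(q) b^{i(i+1)/2}
    fixation  P1   = p + sum_i (2i+1) p q (-1)^i F_i(p) b^{i(i+1)/2}

with ``q = 1 - p``; the two masses are mirror images under ``p -> q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_legendre

from .errors import ConvergenceError, DegenerateInputError, InsufficientDataError
from .het_stats import normalized_variance

__all__ = [
    "KimuraParams",
    "kimura_pmf_density",
    "kimura_cdf_grid",
    "kimura_sample",
    "kimura_fit",
    "ks_test_kimura",
    "ks_statistic",
    "moments",
]

#: number of uniform grid points on (0,1) for CDF inversion / KS evaluation
GRID_N = 2048
#: hard cap on series terms; convergence failure past this raises
MAX_TERMS = 500
#: a term whose sup-norm bound falls below this stops the series
SERIES_TOL = 1e-10


@dataclass(frozen=True)
class KimuraParams:
    """Parameters of the Kimura heteroplasmy distribution.

    p : mean (= initial) heteroplasmy fraction, in (0, 1)
    b : drift parameter in [0, 1]; variance is p(1-p)(1-b)
    """

    p: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise DegenerateInputError(f"p must be in (0,1), got {self.p}")
        if not (0.0 <= self.b <= 1.0):
            raise DegenerateInputError(f"b must be in [0,1], got {self.b}")

    @property
    def variance(self) -> float:
        return self.p * (1.0 - self.p) * (1.0 - self.b)


# ---------------------------------------------------------------------------
# polynomial basis

def _jacobi11_all(y, n_max: int) -> np.ndarray:
    """Jacobi polynomials ``P_n^{(1,1)}(y)`` for n = 0..n_max-1.

    Three-term recurrence specialised to alpha = beta = 1; returns an
    array of shape ``(n_max, len(y))``.  Cross-checked against
    ``scipy.special.eval_jacobi`` in the test suite.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.empty((n_max, y.size))
    if n_max == 0:
        return out
    out[0] = 1.0
    if n_max > 1:
        out[1] = 2.0 * y
    for n in range(2, n_max):
        out[n] = ((n + 1) * (2 * n + 1) * y * out[n - 1]
                  - n * (n + 1) * out[n - 2]) / (n * (n + 2))
    return out


def _hyp_f(x, i_max: int) -> np.ndarray:
    """``F_i(x) = 2F1(1-i, i+2; 2; x)`` for i = 1..i_max, shape (i_max, len(x))."""
    basis = _jacobi11_all(1.0 - 2.0 * np.atleast_1d(np.asarray(x, dtype=float)), i_max)
    scale = 1.0 / np.arange(1.0, i_max + 1)
    return basis * scale[:, None]


def _grid() -> np.ndarray:
    return (np.arange(GRID_N) + 0.5) / GRID_N


_grid_cache: dict[str, np.ndarray] = {}


def _grid_f_basis(i_max: int) -> np.ndarray:
    """Cached ``F_i`` on the uniform grid; grown on demand."""
    cur = _grid_cache.get("F")
    if cur is None or cur.shape[0] < i_max:
        _grid_cache["F"] = _hyp_f(_grid(), max(i_max, 64))
    return _grid_cache["F"][:i_max]


def _gauss_nodes(n: int = 256):
    key = f"gl{n}"
    if key not in _grid_cache:
        nodes, weights = roots_legendre(n)
        _grid_cache[key] = np.vstack([0.5 * (nodes + 1.0), 0.5 * weights])
    xw = _grid_cache[key]
    return xw[0], xw[1]


def _n_terms(b: float) -> int:
    """Series length so the neglected tail is below SERIES_TOL.

    The i-th density term is bounded by ``i(i+1)(2i+1)/4 * b^{i(i+1)/2}``
    because ``|F_i| <= 1`` on [0,1] and ``pq <= 1/4``.
    """
    if b <= 0.0:
        return 1
    for i in range(1, MAX_TERMS + 1):
        bound = i * (i + 1) * (2 * i + 1) / 4.0 * b ** (i * (i + 1) / 2.0)
        if bound < SERIES_TOL and i >= 3:
            return i
    raise ConvergenceError(
        f"Kimura series did not converge within {MAX_TERMS} terms for b={b}; "
        f"last term bound {bound:.3e}"
    )


# ---------------------------------------------------------------------------
# one evaluated distribution, shared by density / CDF / sampling / KS

class _KimuraDist:
    """Fully evaluated distribution for one (p, b): masses, grid density, CDF."""

    def __init__(self, params: KimuraParams):
        self.params = params
        p, b = params.p, params.b
        self.degenerate = b >= 1.0
        if self.degenerate:
            self.P0 = self.P1 = 0.0
            self.f = None
            self.x = _grid()
            self.F = np.where(self.x < p, 0.0, 1.0)
            return
        n = _n_terms(b)
        i = np.arange(1, n + 1)
        damp = b ** (i * (i + 1) / 2.0)
        fi_p = _hyp_f(p, n)[:, 0]
        fi_q = _hyp_f(1.0 - p, n)[:, 0]
        pq = p * (1.0 - p)
        sign = (-1.0) ** i
        self.P0 = float(1.0 - p + np.sum((2 * i + 1) * pq * sign * fi_q * damp))
        self.P1 = float(p + np.sum((2 * i + 1) * pq * sign * fi_p * damp))
        coef = i * (i + 1) * (2 * i + 1) * pq * fi_p * damp
        self._coef = coef
        self._n = n
        self.x = _grid()
        self.f = coef @ _grid_f_basis(n)
        fpos = np.clip(self.f, 0.0, None)
        cum = np.cumsum(fpos) / GRID_N - fpos / (2 * GRID_N)
        interior = 1.0 - self.P0 - self.P1
        total = cum[-1] + fpos[-1] / (2 * GRID_N)
        if total > 0 and interior > 0:
            cum *= interior / total
        self.F = self.P0 + cum

    def density_at(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._coef @ _hyp_f(x, self._n)

    def cdf_at(self, t):
        """Right-continuous CDF and its left limit at each point of ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        Fm = np.concatenate([[self.P0], self.F, [1.0 - self.P1]])
        xm = np.concatenate([[0.0], self.x, [1.0]])
        right = np.interp(t, xm, Fm)
        right[t >= 1.0] = 1.0
        left = right.copy()
        left[t <= 0.0] = 0.0
        left[t >= 1.0] = 1.0 - self.P1
        if self.degenerate:
            p = self.params.p
            right[:] = np.where(t >= p, 1.0, 0.0)
            left[:] = np.where(t > p, 1.0, 0.0)
        return right, left

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate:
            return np.full(n, self.params.p)
        u = rng.uniform(size=n)
        out = np.empty(n)
        lo = u < self.P0
        hi = u > 1.0 - self.P1
        mid = ~(lo | hi)
        out[lo] = 0.0
        out[hi] = 1.0
        if mid.any():
            Fm = np.concatenate([[self.P0], self.F, [1.0 - self.P1]])
            xm = np.concatenate([[0.0], self.x, [1.0]])
            out[mid] = np.interp(u[mid], Fm, xm)
        return out


# ---------------------------------------------------------------------------
# public API

def kimura_pmf_density(params: KimuraParams, x=None):
    """Fixation masses and continuous density of the Kimura distribution.

    Returns ``(P0, P1, f)`` where ``P0``/``P1`` are the point masses at
    ``h = 0`` and ``h = 1`` and ``f`` is the density evaluated at ``x``
    (default: the module's uniform grid on (0,1)).  ``b = 1`` is the
    degenerate no-drift case — a point mass at ``p`` — signalled by
    ``f = None``.
    """
    d = _KimuraDist(params)
    if d.degenerate:
        return 0.0, 0.0, None
    if x is None:
        return d.P0, d.P1, d.f
    return d.P0, d.P1, d.density_at(x)


def kimura_cdf_grid(params: KimuraParams):
    """CDF on the uniform grid: ``F(x) = P0 + int_0^x f`` (right-continuous)."""
    d = _KimuraDist(params)
    return d.x, d.F


def moments(params: KimuraParams, n_quad: int = 256) -> tuple[float, float, float]:
    """(total mass, mean, variance) by Gauss–Legendre quadrature.

    Quadrature is exact for the truncated polynomial series once
    ``2*n_quad - 1`` exceeds the top polynomial degree, so the residuals
    of the identities mass = 1, mean = p, var = p(1-p)(1-b) measure pure
    series truncation error.
    """
    if params.b >= 1.0:
        return 1.0, params.p, 0.0
    xq, wq = _gauss_nodes(n_quad)
    P0, P1, f = kimura_pmf_density(params, xq)
    mass = P0 + P1 + float(wq @ f)
    mean = P1 + float(wq @ (xq * f))
    second = P1 + float(wq @ (xq**2 * f))
    return mass, mean, second - mean**2


def kimura_sample(params: KimuraParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. heteroplasmy values, including the fixation atoms.

    Interior draws are inverse-CDF on the uniform grid; atoms at 0 and 1
    are hit with their exact masses.
    """
    if n < 1:
        raise InsufficientDataError("n must be >= 1")
    return _KimuraDist(params).sample(n, rng)


def kimura_fit(hs, ddof: int = 0) -> KimuraParams:
    """Method-of-moments fit: ``p_hat`` = mean, ``b_hat = 1 - V'(h)``.

    ``V'`` is the normalized heteroplasmy variance Var(h)/(mu(1-mu));
    ``b_hat`` is clamped to [0, 1].
    """
    hs = np.asarray(hs, dtype=float)
    if hs.size < 2:
        raise InsufficientDataError("need >=2 heteroplasmy values to fit")
    p_hat = float(hs.mean())
    if not (0.0 < p_hat < 1.0):
        raise DegenerateInputError(f"sample mean {p_hat} not in (0,1)")
    vprime = normalized_variance(hs, ddof=ddof)
    b_hat = float(np.clip(1.0 - vprime, 0.0, 1.0))
    return KimuraParams(p=p_hat, b=b_hat)


def _ks_statistic_dist(hs_sorted: np.ndarray, d: _KimuraDist) -> float:
    n = hs_sorted.size
    pts = np.unique(np.concatenate([hs_sorted, [0.0, 1.0]]))
    right, left = d.cdf_at(pts)
    emp_right = np.searchsorted(hs_sorted, pts, side="right") / n
    emp_left = np.searchsorted(hs_sorted, pts, side="left") / n
    return float(np.max(np.maximum(np.abs(emp_right - right),
                                   np.abs(emp_left - left))))


def ks_statistic(hs, params: KimuraParams) -> float:
    """Sup-distance between the empirical CDF and the Kimura CDF.

    The theoretical CDF has jumps at 0 and 1 (the fixation masses), so
    both one-sided deviations are checked at every observation and at
    the two atoms.
    """
    hs = np.sort(np.asarray(hs, dtype=float))
    return _ks_statistic_dist(hs, _KimuraDist(params))


def ks_test_kimura(hs, params: KimuraParams | None = None, n_mc: int = 500,
                   rng: np.random.Generator | None = None, refit: bool = True):
    """Monte-Carlo Kolmogorov–Smirnov test against a Kimura distribution.

    If ``params`` is None the parameters are fitted from ``hs`` by
    moments, and (with ``refit=True``, the default) they are re-fitted
    inside every Monte-Carlo replicate so the null distribution of D
    accounts for the estimation step — a parametric bootstrap.  The
    p-value uses the (1 + #exceed)/(n_mc + 1) convention.  Asymptotic KS
    p-values are never used here: the distribution has atoms and the
    parameters are estimated, both of which invalidate them.
    """
    hs = np.asarray(hs, dtype=float)
    if hs.size < 5:
        raise InsufficientDataError("need >=5 observations for the KS test")
    rng = np.random.default_rng() if rng is None else rng
    fitted = params is None
    if fitted:
        params = kimura_fit(hs)
    null_dist = _KimuraDist(params)
    d_obs = _ks_statistic_dist(np.sort(hs), null_dist)
    n = hs.size
    exceed = 0
    for _ in range(n_mc):
        sim = null_dist.sample(n, rng)
        rep_dist = null_dist
        if refit and fitted:
            try:
                rep_dist = _KimuraDist(kimura_fit(sim))
            except DegenerateInputError:
                pass
        if _ks_statistic_dist(np.sort(sim), rep_dist) >= d_obs:
            exceed += 1
    p_value = (1 + exceed) / (n_mc + 1)
    return d_obs, p_value
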