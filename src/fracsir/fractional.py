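"""Fractional calculus operators: Riemann-Liouville integrals, Caputo
derivatives, their collocation matrices on a wavelet basis, and the
Mittag-Leffler function used by closed-form validation problems.

The weakly singular kernel (t-s)^{alpha-1} is integrated analytically
against a piecewise-linear reconstruction of the integrand (product
trapezoidal rule), which is the same quadrature family as the classical
fractional Adams corrector and is exact for piecewise-linear data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.special import gamma as _gamma
from scipy.integrate import quad as _quad


__all__ = [
    "FractionalOrder",
    "CaputoCollocationOperator",
    "rl_integral",
    "caputo_derivative",
    "build_operator",
    "mittag_leffler",
]


@dataclass(frozen=True)
class FractionalOrder:
    """Caputo order alpha in (0, 1]; alpha = 1 is the classical derivative."""

    alpha: float

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"fractional order must lie in (0, 1], got {self.alpha}")

    @property
    def is_classical(self) -> bool:
        return self.alpha == 1.0


def _product_trapezoid_weights(n: int, alpha: float) -> np.ndarray:
    """Weights a_j such that I^alpha f(t_n) ~= h^a/Gamma(a+2) * sum a_j f(t_j)
    on the uniform grid t_j = j*h, exact for piecewise-linear f."""
    a = np.empty(n + 1)
    k = np.arange(n + 1, dtype=float)
    s = k ** (alpha + 1.0)
    a[0] = (n - 1.0) ** (alpha + 1.0) - (n - 1.0 - alpha) * n**alpha if n >= 1 else 0.0
    if n >= 2:
        j = np.arange(1, n)
        a[1:n] = s[n - j + 1] + s[n - j - 1] - 2.0 * s[n - j]
    if n >= 1:
        a[n] = 1.0
    return a


def _as_callable(f):
    if callable(f):
        return f
    ts, ys = f
    ts = np.asarray(ts, dtype=float)
    ys = np.asarray(ys, dtype=float)
    return lambda t: np.interp(t, ts, ys)


def rl_integral(f, alpha: float, t_eval, n_panels: int = 256) -> np.ndarray:
    """Left-sided Riemann-Liouville integral I^alpha f at the times ``t_eval``.

    ``f`` is a callable on [0, max(t_eval)] or a (times, values) sample
    pair (interpolated linearly).  Each evaluation uses ``n_panels``
    uniform panels on [0, t] with the product trapezoidal rule.
    """
    if alpha <= 0:
        raise ValueError("rl_integral requires alpha > 0")
    fc = _as_callable(f)
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    if np.any(t_eval < 0):
        raise ValueError("t_eval must be nonnegative")
    out = np.zeros_like(t_eval)
    w = _product_trapezoid_weights(n_panels, alpha)
    scale = 1.0 / _gamma(alpha + 2.0)
    for i, t in enumerate(t_eval):
        if t == 0.0:
            continue
        h = t / n_panels
        grid = np.linspace(0.0, t, n_panels + 1)
        out[i] = h**alpha * scale * np.dot(w, fc(grid))
    return out


def caputo_derivative(f, alpha: float, t_eval, fprime=None,
                      n_panels: int = 256, fd_points: int = 4096) -> np.ndarray:
    """Caputo derivative of order alpha in (0, 1]: I^{1-alpha} applied to f'.

    The derivative is taken analytically when ``fprime`` is supplied,
    otherwise by central differences on a refined uniform grid.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("caputo_derivative requires 0 < alpha <= 1")
    fc = _as_callable(f)
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    if fprime is None:
        tmax = max(float(np.max(t_eval)), 1e-12)
        grid = np.linspace(0.0, tmax, fd_points + 1)
        dvals = np.gradient(fc(grid), grid)
        fprime = lambda t: np.interp(t, grid, dvals)
    else:
        fprime = _as_callable(fprime)
    if alpha == 1.0:
        return np.asarray(fprime(t_eval), dtype=float) * np.ones_like(t_eval)
    return rl_integral(fprime, 1.0 - alpha, t_eval, n_panels=n_panels)


# ---------------------------------------------------------------------------
# Mittag-Leffler function
# ---------------------------------------------------------------------------

_ML_SERIES_LIMIT = 5.0
_ML_RANGE = 50.0


def _ml_series(alpha: float, beta: float, z: float, tol: float = 1e-16) -> float:
    total = 0.0
    term_k = 0
    while term_k < 400:
        g = _gamma(alpha * term_k + beta)
        if np.isfinite(g):
            term = z**term_k / g
            total += term
            if term_k > 2 and abs(term) < tol * max(1.0, abs(total)):
                break
        term_k += 1
    return total


def _ml_negative_integral(alpha: float, x: float) -> float:
    """E_alpha(-x) for x > 0, 0 < alpha < 1, via the spectral representation
    E_alpha(-x) = sin(pi a)/pi * int_0^inf e^-r x r^{a-1} /
                  (r^{2a} + 2 x r^a cos(pi a) + x^2) dr."""
    s, c = np.sin(np.pi * alpha), np.cos(np.pi * alpha)

    def integrand(r):
        ra = r**alpha
        return np.exp(-r) * x * r ** (alpha - 1.0) / (ra * ra + 2.0 * x * ra * c + x * x)

    val, _ = _quad(integrand, 0.0, np.inf, limit=200, epsabs=1e-13, epsrel=1e-12)
    return s / np.pi * val


def mittag_leffler(alpha: float, z, beta: float = 1.0):
    """Mittag-Leffler function E_{alpha,beta}(z) for real z, |z| <= 50.

    E_1 is the exponential; E_2(-x^2) = cos(x); for 0 < alpha < 1 and
    strongly negative arguments the alternating series is abandoned in
    favor of the completely monotone spectral-integral representation.
    """
    if alpha <= 0:
        raise ValueError("mittag_leffler requires alpha > 0")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(np.abs(z_arr) > _ML_RANGE):
        raise ValueError(f"|z| <= {_ML_RANGE} is the supported range")
    out = np.empty_like(z_arr)
    for i, zz in enumerate(z_arr):
        if beta == 1.0:
            if alpha == 1.0:
                out[i] = np.exp(zz)
            elif alpha < 1.0 and zz < -_ML_SERIES_LIMIT:
                out[i] = _ml_negative_integral(alpha, -zz)
            else:
                out[i] = _ml_series(alpha, 1.0, zz)
        else:
            if abs(zz) <= _ML_SERIES_LIMIT:
                out[i] = _ml_series(alpha, beta, zz)
            elif beta == alpha + 1.0 and zz != 0.0:
                # E_{a,a+1}(z) = (E_a(z) - 1)/z
                out[i] = (float(mittag_leffler(alpha, zz)) - 1.0) / zz
            else:
                raise ValueError(
                    "general beta supported only for |z| <= 5 (series range)"
                )
    return out if np.ndim(z) else float(out[0])


# ---------------------------------------------------------------------------
# Collocation operators on a basis
# ---------------------------------------------------------------------------

def fractional_integral_matrix(basis, alpha: float, nodes: np.ndarray,
                               n_panels: int | None = None) -> np.ndarray:
    """Matrix with entries (I^alpha u_j)(t_l) for the basis members u_j.

    Applied to a coefficient vector this is the product-trapezoidal
    quadrature of the reconstructed function, so the accuracy for smooth
    combinations is governed by the quadrature step, not by the roughness
    of individual wavelets.
    """
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    if n_panels is None:
        n_panels = 4 * basis.n_b
    w = _product_trapezoid_weights(n_panels, alpha) / _gamma(alpha + 2.0)
    P = np.zeros((nodes.size, basis.n_b))
    for i, t in enumerate(nodes):
        if t == 0.0:
            continue
        h = t / n_panels
        grid = np.linspace(0.0, t, n_panels + 1)
        B = basis.evaluate(grid)
        P[i, :] = h**alpha * (w @ B)
    return P


@dataclass
class CaputoCollocationOperator:
    """Collocation matrices of the Caputo derivative / RL integral on a basis.

    ``D_alpha`` maps basis coefficients to Caputo-derivative values at the
    nodes, assembled as I^{1-alpha} of the basis first derivatives;
    ``P_alpha`` maps coefficients to fractional-integral values.  The
    Galerkin matrix of inner products <D^a u_j, u_i> is available as a
    cross-check but the solver enforces residuals in physical space.
    """

    basis: object
    order: FractionalOrder
    nodes: np.ndarray
    n_panels: int
    D_alpha: np.ndarray
    P_alpha: np.ndarray

    @cached_property
    def gram_D_alpha(self) -> np.ndarray:
        # midpoint rule: avoids the kernel singularity at t = 0 and handles
        # the roughness of the wavelet integrands far better than endpoint rules
        nq = 16 * self.basis.n_b
        h = self.basis.T / nq
        tq = (np.arange(nq) + 0.5) * h
        Dq = _caputo_basis_matrix(self.basis, self.order.alpha, tq, self.n_panels)
        Bq = self.basis.evaluate(tq)
        return h * (Bq.T @ Dq)


def _caputo_basis_matrix(basis, alpha: float, nodes: np.ndarray,
                         n_panels: int) -> np.ndarray:
    if alpha == 1.0:
        return basis.evaluate_derivative(nodes)
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    w = _product_trapezoid_weights(n_panels, 1.0 - alpha) / _gamma(3.0 - alpha)
    D = np.zeros((nodes.size, basis.n_b))
    for i, t in enumerate(nodes):
        if t == 0.0:
            continue
        h = t / n_panels
        grid = np.linspace(0.0, t, n_panels + 1)
        Bp = basis.evaluate_derivative(grid)
        D[i, :] = h ** (1.0 - alpha) * (w @ Bp)
    return D


def build_operator(basis, alpha: float, nodes: np.ndarray,
                   n_panels: int | None = None) -> CaputoCollocationOperator:
    """Assemble the Caputo/RL collocation matrices at the given nodes.

    Nodes must avoid t = 0 for alpha < 1 (the Caputo kernel is singular at
    the left endpoint); midpoint collocation grids satisfy this naturally.
    """
    order = FractionalOrder(float(alpha))
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    if order.alpha < 1.0 and np.any(nodes == 0.0):
        raise ValueError(
            "collocation node at t = 0 with alpha < 1: the Caputo kernel is "
            "singular there; use midpoint nodes"
        )
    if n_panels is None:
        n_panels = 4 * basis.n_b
    D = _caputo_basis_matrix(basis, order.alpha, nodes, n_panels)
    P = fractional_integral_matrix(basis, order.alpha, nodes, n_panels)
    return CaputoCollocationOperator(basis=basis, order=order, nodes=nodes,
                                     n_panels=n_panels, D_alpha=D, P_alpha=P)
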