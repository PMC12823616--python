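"""Delay handling: the sparse shift matrix T_tau and history functions.

``T_tau`` maps grid values x(t_l) to delayed values x(t_l - tau) by
Lagrange interpolation.  Nodes whose shifted time falls before t = 0 are
served by the prescribed history function (the solver default), or
wrapped periodically in index space ("cyclic") — a convention kept only
to reproduce the textbook permutation-matrix illustration, where an
integer delay-to-spacing ratio rolls the value vector forward by
tau/h positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["DelayShiftMatrix", "HistorySet", "build_shift_matrix", "delayed_values"]


@dataclass
class HistorySet:
    """Prescribed compartment trajectories on [-tau, 0].

    These generalized initial conditions make the delayed system
    well-posed: every delayed lookup with t - tau < 0 reads from them.
    """

    phi1: object
    phi2: object
    phi3: object
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        self.phi1 = _history_callable(self.phi1)
        self.phi2 = _history_callable(self.phi2)
        self.phi3 = _history_callable(self.phi3)
        probe = np.linspace(-self.tau, 0.0, 7)
        for name, phi in (("phi1", self.phi1), ("phi2", self.phi2),
                          ("phi3", self.phi3)):
            vals = np.asarray(phi(probe), dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"history {name} is not finite on [-tau, 0]")

    @classmethod
    def from_polynomials(cls, c1, c2, c3, tau: float) -> "HistorySet":
        """Histories from coefficient lists in constant-first order."""
        mk = lambda c: np.polynomial.Polynomial(np.asarray(c, dtype=float))
        return cls(mk(c1), mk(c2), mk(c3), float(tau))

    def at_zero(self) -> tuple[float, float, float]:
        return (float(self.phi1(0.0)), float(self.phi2(0.0)), float(self.phi3(0.0)))


def _history_callable(phi):
    if callable(phi):
        return phi
    ts, ys = phi
    ts = np.asarray(ts, dtype=float)
    ys = np.asarray(ys, dtype=float)

    def interp(t):
        t = np.asarray(t, dtype=float)
        if np.any(t < ts[0] - 1e-12) or np.any(t > ts[-1] + 1e-12):
            raise ValueError("history requested outside its tabulated domain")
        return np.interp(t, ts, ys)

    return interp


@dataclass
class DelayShiftMatrix:
    """Sparse interpolation matrix mapping x(t_l) to x(t_l - tau)."""

    nodes: np.ndarray
    tau: float
    weights: sparse.csr_matrix
    prehistory_rows: np.ndarray
    policy: str

    @property
    def n_c(self) -> int:
        return self.nodes.size

    def toarray(self) -> np.ndarray:
        return self.weights.toarray()

    def to_coordinate_text(self) -> str:
        coo = self.weights.tocoo()
        lines = [f"{r} {c} {v:.17g}" for r, c, v in zip(coo.row, coo.col, coo.data)]
        return "\n".join(lines) + ("\n" if lines else "")


def _lagrange_row(nodes: np.ndarray, s: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Column indices and Lagrange weights of the ``order+1``-point stencil
    nearest to ``s``.  One-sided stencils are used near the edges, which
    keeps the rule exact for polynomials up to the stencil degree."""
    n = nodes.size
    npts = min(order + 1, n)
    j = int(np.searchsorted(nodes, s))
    lo = max(0, min(j - (npts + 1) // 2, n - npts))
    idx = np.arange(lo, lo + npts)
    x = nodes[idx]
    w = np.ones(npts)
    for a in range(npts):
        for b in range(npts):
            if a != b:
                w[a] *= (s - x[b]) / (x[a] - x[b])
    return idx, w


def build_shift_matrix(nodes, tau: float, interp_order: int = 3,
                       policy: str = "history") -> DelayShiftMatrix:
    """Build T_tau on the given nodes.

    policy="history": rows with t_l - tau < 0 are left empty (the history
    contribution is added by :func:`delayed_values`); shifted times in
    [0, min(nodes)) use the one-sided edge stencil.
    policy="cyclic": the shifted lookup wraps in index space, rolling the
    vector forward by tau/h positions; for integer tau/h this is exactly
    the illustrative permutation matrix.
    """
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    if nodes.size == 0:
        raise ValueError("empty node set")
    if np.any(np.diff(nodes) <= 0):
        raise ValueError("nodes must be strictly increasing")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if interp_order not in (1, 3):
        raise ValueError("interp_order must be 1 (linear) or 3 (cubic)")
    if policy not in ("history", "cyclic"):
        raise ValueError("policy must be 'history' or 'cyclic'")
    n = nodes.size
    rows, cols, vals = [], [], []
    pre = []
    if policy == "cyclic":
        h = float(np.mean(np.diff(nodes))) if n > 1 else 1.0
        if n > 1 and np.max(np.abs(np.diff(nodes) - h)) > 1e-10 * max(1.0, abs(h)):
            raise ValueError("cyclic policy requires a uniform grid")
        if tau >= n * h:
            raise ValueError("cyclic policy requires tau < node span")
        shift = tau / h
        npts = 2 if interp_order == 1 else 4
        for ell in range(n):
            p = ell + shift  # forward roll, matching the illustrative convention
            if abs(p - round(p)) < 1e-12:
                rows.append(ell)
                cols.append(int(round(p)) % n)
                vals.append(1.0)
                continue
            base = int(np.floor(p)) - (npts // 2 - 1)
            stencil = np.arange(base, base + npts)
            w = np.ones(npts)
            for a in range(npts):
                for b in range(npts):
                    if a != b:
                        w[a] *= (p - stencil[b]) / (stencil[a] - stencil[b])
            for m, wm in zip(stencil, w):
                rows.append(ell)
                cols.append(int(m) % n)
                vals.append(wm)
    else:
        for ell, t in enumerate(nodes):
            s = t - tau
            if s < 0.0:
                pre.append(ell)
                continue
            idx, w = _lagrange_row(nodes, s, interp_order)
            rows.extend([ell] * idx.size)
            cols.extend(idx.tolist())
            vals.extend(w.tolist())
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return DelayShiftMatrix(nodes=nodes, tau=float(tau), weights=W,
                            prehistory_rows=np.asarray(pre, dtype=int),
                            policy=policy)


def delayed_values(shift: DelayShiftMatrix, grid_values, history=None) -> np.ndarray:
    """Evaluate x(t_l - tau): interpolated from ``grid_values`` where the
    shifted time is nonnegative, read from ``history`` where it is not."""
    grid_values = np.asarray(grid_values, dtype=float)
    if grid_values.shape[0] != shift.n_c:
        raise ValueError("grid_values length does not match the node count")
    out = shift.weights @ grid_values
    if shift.prehistory_rows.size:
        if history is None:
            raise ValueError(
                "shifted nodes fall before t = 0 but no history was provided"
            )
        s = shift.nodes[shift.prehistory_rows] - shift.tau
        out[shift.prehistory_rows] = np.asarray(history(s), dtype=float)
    return out
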