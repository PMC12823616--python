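"""Independent reference solvers used to validate the collocation scheme.

Two oracles, deliberately built on different numerics than the wavelet
solver: the Diethelm-Ford-Freed fractional Adams-Bashforth-Moulton
predictor-corrector extended to a single discrete delay, and classical
RK4 by the method of steps for the integer-order limit alpha = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .delay import HistorySet
from .model import SIRParameters, rhs

__all__ = ["OracleConfig", "Trajectory", "abm_fractional_dde", "rk4_dde"]


@dataclass(frozen=True)
class OracleConfig:
    """Step size and delayed-lookup settings for the oracle solvers."""

    h: float = 1e-3
    interpolation: str = "linear"  # or "cubic_hermite" (alpha = 1 only)
    corrector_iterations: int = 1

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("step size must be positive")
        if self.interpolation not in ("linear", "cubic_hermite"):
            raise ValueError("interpolation must be 'linear' or 'cubic_hermite'")
        if self.corrector_iterations < 1:
            raise ValueError("corrector_iterations must be >= 1")


@dataclass
class Trajectory:
    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    solver: str

    @property
    def N(self) -> float:
        return float(self.S[0] + self.I[0] + self.R[0])

    def sample(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return tuple(np.interp(t, self.times, y) for y in (self.S, self.I, self.R))


def _delayed_I(times, I_hist, n, tau, h, histories):
    """I(t_n - tau) from the history (t < 0) or linear interpolation of
    already-computed steps."""
    s = times[n] - tau
    if s < 0.0:
        return float(histories.phi2(s))
    p = s / h
    j = min(int(np.floor(p)), n - 1)
    w = p - j
    if w < 1e-14:  # avoid touching the not-yet-computed step when s hits a node
        return float(I_hist[j])
    return (1.0 - w) * I_hist[j] + w * I_hist[j + 1]


def abm_fractional_dde(params: SIRParameters, histories: HistorySet,
                       config: OracleConfig = OracleConfig(),
                       forcing=None) -> Trajectory:
    """Fractional Adams predictor-corrector (PECE) with a discrete delay.

    Convolution quadrature uses the classical rectangle (predictor) and
    product-trapezoid (corrector) weights; the delayed infected level is
    read from the history for t - tau < 0 and from dense linear
    interpolation of past steps otherwise.  ``forcing`` optionally adds a
    (f_S, f_I, f_R) source triple, matching the manufactured fixtures.
    """
    h, alpha = config.h, params.alpha
    if h > params.tau:
        raise ValueError("oracle step must not exceed the delay tau")

    def full_rhs(t, y_now, Id):
        out = np.asarray(rhs(tuple(y_now), Id, params))
        if forcing is not None:
            out = out + np.array([float(np.asarray(g(t)).reshape(())) for g in forcing])
        return out

    n_steps = int(round(params.T / h))
    times = np.arange(n_steps + 1) * h
    y = np.empty((n_steps + 1, 3))
    f = np.empty((n_steps + 1, 3))
    y[0] = histories.at_zero()
    Id0 = float(histories.phi2(-params.tau))
    f[0] = full_rhs(0.0, y[0], Id0)

    k = np.arange(n_steps + 2, dtype=float)
    ka = k**alpha
    ka1 = k ** (alpha + 1.0)
    c_pred = h**alpha / _gamma(alpha + 1.0)
    c_corr = h**alpha / _gamma(alpha + 2.0)

    for n in range(n_steps):
        m = n + 1
        # predictor weights b_j = (m-j)^a - (m-1-j)^a, j = 0..n
        b = ka[1:m + 1][::-1] - ka[0:m][::-1]
        yp = y[0] + c_pred * (b @ f[:m])
        Id = _delayed_I(times, y[:, 1], m, params.tau, h, histories)
        fp = full_rhs(times[m], yp, Id)
        # corrector weights: a_0 = (m-1)^{a+1} - (m-1-a) m^a; interior
        # a_j = (m-j+1)^{a+1} + (m-j-1)^{a+1} - 2 (m-j)^{a+1}; a_m = 1
        a0 = ka1[m - 1] - (m - 1.0 - alpha) * ka[m]
        w = np.empty(m)
        w[0] = a0
        if m >= 2:
            j = np.arange(1, m)
            w[1:] = ka1[m - j + 1] + ka1[m - j - 1] - 2.0 * ka1[m - j]
        yc = yp
        for _ in range(config.corrector_iterations):
            fc = full_rhs(times[m], yc, Id)
            yc = y[0] + c_corr * (w @ f[:m] + fc)
        y[m] = yc
        f[m] = full_rhs(times[m], y[m], Id)
    return Trajectory(times=times, S=y[:, 0], I=y[:, 1], R=y[:, 2], solver="abm")


class _Segment:
    """Dense cubic-Hermite output of one method-of-steps segment."""

    def __init__(self, times, values, derivs):
        self.times = times
        self.values = values
        self.derivs = derivs
        self.h = times[1] - times[0]

    def __call__(self, t):
        j = min(max(int(np.floor((t - self.times[0]) / self.h)), 0),
                self.times.size - 2)
        s = (t - self.times[j]) / self.h
        y0, y1 = self.values[j], self.values[j + 1]
        d0, d1 = self.derivs[j] * self.h, self.derivs[j + 1] * self.h
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return h00 * y0 + h10 * d0 + h01 * y1 + h11 * d1


def rk4_dde(params: SIRParameters, histories: HistorySet,
            config: OracleConfig = OracleConfig()) -> Trajectory:
    """Classical RK4 by the method of steps; valid only for alpha = 1.

    Each segment [k tau, (k+1) tau] is integrated with fixed-step RK4,
    reading delayed values from a cubic-Hermite dense interpolant of the
    previous segment (or from the history on the first segment).
    """
    if params.alpha != 1.0:
        raise ValueError("rk4_dde applies only to the classical case alpha = 1")
    tau = params.tau
    steps_per_seg = max(1, int(round(tau / config.h)))
    h = tau / steps_per_seg
    n_segs = int(np.ceil(params.T / tau))

    def history_lookup(t):
        return float(histories.phi2(t))

    prev_lookup = history_lookup
    all_t = [np.array([0.0])]
    y0 = np.asarray(histories.at_zero(), dtype=float)
    all_y = [y0[None, :]]

    def f(t, y, lookup):
        Id = lookup(t - tau)
        return np.asarray(rhs(tuple(y), Id, params))

    t_start, y = 0.0, y0.copy()
    for seg in range(n_segs):
        t_end = min(t_start + tau, params.T)
        n = int(round((t_end - t_start) / h))
        ts = t_start + np.arange(n + 1) * h
        ys = np.empty((n + 1, 3))
        ds = np.empty((n + 1, 3))
        ys[0] = y
        ds[0] = f(ts[0], y, prev_lookup)
        for i in range(n):
            t = ts[i]
            k1 = f(t, ys[i], prev_lookup)
            k2 = f(t + h / 2, ys[i] + h / 2 * k1, prev_lookup)
            k3 = f(t + h / 2, ys[i] + h / 2 * k2, prev_lookup)
            k4 = f(t + h, ys[i] + h * k3, prev_lookup)
            ys[i + 1] = ys[i] + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ds[i + 1] = f(ts[i + 1], ys[i + 1], prev_lookup)
        seg_I = _Segment(ts, ys[:, 1].copy(), ds[:, 1].copy())
        older = prev_lookup

        def make_lookup(segment, fallback, lo):
            def lookup(t):
                if t < lo:
                    return fallback(t)
                return float(segment(min(t, segment.times[-1])))
            return lookup

        prev_lookup = make_lookup(seg_I, older, t_start)
        all_t.append(ts[1:])
        all_y.append(ys[1:])
        t_start, y = t_end, ys[-1]
        if t_start >= params.T:
            break
    times = np.concatenate(all_t)
    Y = np.concatenate(all_y, axis=0)
    return Trajectory(times=times, S=Y[:, 0], I=Y[:, 1], R=Y[:, 2], solver="rk4")
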