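"""Manufactured and closed-form test problems.

Every verification stage of the solver chain rests on problems whose
exact solution is known analytically:

* manufactured polynomial triples — a chosen polynomial solution is
  substituted into the delayed SIR equations and the imbalance is added
  back as a forcing term, so the triple solves the forced system exactly
  (Caputo derivatives of polynomials have closed Gamma-ratio forms);
* Mittag-Leffler relaxation — with transmission and reinfection switched
  off the infected compartment decays as I0 * E_alpha(-gamma t^alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

from .delay import HistorySet
from .model import SIRParameters, rhs
from .fractional import mittag_leffler

__all__ = ["ManufacturedProblem", "make_manufactured", "make_ml_decay"]


def _poly_caputo(coeffs: np.ndarray, alpha: float):
    """Closed-form Caputo derivative of sum_p c_p t^p (constant-first):
    D^alpha t^p = Gamma(p+1)/Gamma(p+1-alpha) t^{p-alpha} for p >= 1,
    and the derivative of a constant vanishes."""
    coeffs = np.asarray(coeffs, dtype=float)

    def d(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for p, c in enumerate(coeffs):
            if p == 0 or c == 0.0:
                continue
            out = out + c * _gamma(p + 1.0) / _gamma(p + 1.0 - alpha) * t ** (p - alpha)
        return out

    return d


@dataclass
class ManufacturedProblem:
    """A forced delayed SIR instance with a known polynomial solution."""

    params: SIRParameters
    histories: HistorySet
    forcing: tuple
    exact: tuple
    exact_caputo: tuple
    coefficients: tuple = field(default=())


#: default polynomial triples per degree (constant-first), chosen to keep
#: compartments positive on typical horizons
_DEFAULT_TRIPLES = {
    0: ([500.0], [80.0], [120.0]),
    1: ([500.0, -3.0], [80.0, 1.5], [120.0, 1.5]),
    2: ([500.0, -3.0, 0.1], [80.0, 1.5, -0.05], [120.0, 1.5, -0.05]),
    3: ([500.0, -3.0, 0.1, -0.004], [80.0, 1.5, -0.05, 0.002],
        [120.0, 1.5, -0.05, 0.002]),
}


def make_manufactured(degree: int, params: SIRParameters, tau: float | None = None,
                      triples=None) -> ManufacturedProblem:
    """Build a forced problem solved exactly by polynomials of ``degree``.

    The forcing of each equation is F_X = D^alpha X* - rhs_X evaluated on
    the chosen triple, with the delayed infected level taken from the
    exact polynomial (which also supplies the histories on [-tau, 0]).
    """
    if not (0 <= degree <= 3):
        raise ValueError("degree must be between 0 and 3")
    if tau is not None:
        params = params.with_(tau=float(tau))
    cS, cI, cR = triples if triples is not None else _DEFAULT_TRIPLES[degree]
    polys = [np.polynomial.Polynomial(np.asarray(c, dtype=float))
             for c in (cS, cI, cR)]
    S_ex, I_ex, R_ex = polys
    dS_ex = _poly_caputo(cS, params.alpha)
    dI_ex = _poly_caputo(cI, params.alpha)
    dR_ex = _poly_caputo(cR, params.alpha)

    def forcing_factory(d_exact, which):
        def F(t):
            t = np.asarray(t, dtype=float)
            Id = I_ex(t - params.tau)
            model = rhs((S_ex(t), I_ex(t), R_ex(t)), Id, params)[which]
            return d_exact(t) - model
        return F

    forcing = (forcing_factory(dS_ex, 0), forcing_factory(dI_ex, 1),
               forcing_factory(dR_ex, 2))
    histories = HistorySet(S_ex, I_ex, R_ex, tau=params.tau)
    return ManufacturedProblem(params=params, histories=histories,
                               forcing=forcing, exact=(S_ex, I_ex, R_ex),
                               exact_caputo=(dS_ex, dI_ex, dR_ex),
                               coefficients=(tuple(cS), tuple(cI), tuple(cR)))


@dataclass
class MLDecayProblem:
    """Relaxation problem with Mittag-Leffler closed form (beta = delta = 0)."""

    params: SIRParameters
    histories: HistorySet
    forcing: None
    exact: tuple
    I0: float


def make_ml_decay(alpha: float, gamma: float = 0.1, I0: float = 70.0,
                  T: float = 10.0, tau: float = 2.0,
                  S0: float = 620.0, R0: float = 10.0) -> MLDecayProblem:
    """Fractional relaxation instance: D^alpha I = -gamma I.

    With beta = delta = 0 the system decouples: S stays constant,
    I(t) = I0 E_alpha(-gamma t^alpha), and the recovered class follows the
    fractional-integral identity R(t) = R0 + gamma I0 t^alpha
    E_{alpha,alpha+1}(-gamma t^alpha).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    params = SIRParameters(beta=0.0, gamma=gamma, delta=0.0, alpha=alpha,
                           tau=tau, N=S0 + I0 + R0, T=T)
    histories = HistorySet(lambda t: S0 * np.ones_like(np.asarray(t, float)),
                           lambda t: I0 * np.ones_like(np.asarray(t, float)),
                           lambda t: R0 * np.ones_like(np.asarray(t, float)),
                           tau=tau)

    def I_exact(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return I0 * np.asarray([mittag_leffler(alpha, -gamma * tt**alpha)
                                for tt in t])

    def S_exact(t):
        return S0 * np.ones_like(np.asarray(t, dtype=float))

    def R_exact(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        vals = [mittag_leffler(alpha, -gamma * tt**alpha, beta=alpha + 1.0)
                if tt > 0 else 0.0 for tt in t]
        return R0 + gamma * I0 * t**alpha * np.asarray(vals)

    return MLDecayProblem(params=params, histories=histories, forcing=None,
                          exact=(S_exact, I_exact, R_exact), I0=I0)
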