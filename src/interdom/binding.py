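"""Binding isotherm (Hill) fitting and steady-state anisotropy.

The Hill equation relates observed signal to titrant concentration:

    S_obs = S_U + (S_B − S_U) · [L]^n / (K_D^n + [L]^n)

with unbound/bound plateaus S_U, S_B, dissociation constant K_D and Hill
coefficient n.  The denominator uses K_D^n so the expression is dimensionally
consistent for n ≠ 1 and reduces exactly to the n = 1 hyperbola; the
historical variant with a bare K_D in the denominator is available via
``printed_form=True``.

Steady-state and time-resolved anisotropy are related by the Perrin equation
r = r0 / (1 + τ/T_r) for fluorescence lifetime τ and rotational correlation
time T_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = ["HillFit", "hill_equation", "fit_hill", "steady_state_anisotropy"]


def hill_equation(x, s_u, s_b, kd, n, printed_form: bool = False):
    x = np.asarray(x, dtype=float)
    denom = (kd + x**n) if printed_form else (kd**n + x**n)
    return s_u + (s_b - s_u) * x**n / denom


@dataclass
class HillFit:
    s_u: float
    s_b: float
    kd: float
    n: float
    stderr: dict
    success: bool
    printed_form: bool
    result: object  # lmfit ModelResult for diagnostics

    def predict(self, x):
        return hill_equation(x, self.s_u, self.s_b, self.kd, self.n, self.printed_form)


def fit_hill(
    isotherm: pd.DataFrame,
    initial: dict | None = None,
    printed_form: bool = False,
    weights: np.ndarray | None = None,
) -> HillFit:
    """Nonlinear least-squares Hill fit of a (concentration, signal) table.

    Requires ≥ 4 points spanning at least one decade of concentration.
    Defaults: K_D at the geometric mean of the concentration range, n = 1,
    plateaus at the signals of the extreme concentrations.  K_D is bounded
    positive and n to (0.1, 5).
    """
    conc = np.asarray(isotherm["concentration"], dtype=float)
    sig = np.asarray(isotherm["signal"], dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 titration points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) != len(conc):
        raise ValueError("concentrations must be distinct")
    if conc.max() / conc.min() < 10.0:
        raise ValueError("titration must span at least one decade of concentration")

    order = np.argsort(conc)
    conc, sig = conc[order], sig[order]
    init = {
        "s_u": sig[0],
        "s_b": sig[-1],
        "kd": float(np.exp(np.mean(np.log(conc)))),
        "n": 1.0,
        **(initial or {}),
    }
    model = Model(lambda x, s_u, s_b, kd, n: hill_equation(x, s_u, s_b, kd, n, printed_form))
    params = model.make_params(**init)
    params["kd"].set(min=1e-15)
    params["n"].set(min=0.1, max=5.0)
    res = model.fit(sig, params, x=conc, weights=weights)
    if not res.success:
        raise RuntimeError(f"Hill fit did not converge: {res.message}; best iterate {res.best_values}")
    stderr = {k: (p.stderr if p.stderr is not None else np.nan) for k, p in res.params.items()}
    return HillFit(
        s_u=res.params["s_u"].value,
        s_b=res.params["s_b"].value,
        kd=res.params["kd"].value,
        n=res.params["n"].value,
        stderr=stderr,
        success=res.success,
        printed_form=printed_form,
        result=res,
    )


def steady_state_anisotropy(r0: float, tau: float, t_r: float) -> float:
    """Perrin relation r = r0 / (1 + τ/T_r).

    ``r0`` is the initial (fundamental) anisotropy, ``tau`` the fluorescence
    lifetime and ``t_r`` the rotational correlation time (same time units).
    """
    if not (0.0 < r0 <= 0.4):
        raise ValueError("r0 must lie in (0, 0.4]")
    if tau <= 0 or t_r <= 0:
        raise ValueError("lifetime and rotational correlation time must be positive")
    return r0 / (1.0 + tau / t_r)
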