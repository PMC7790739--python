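"""Wnt/beta-catenin signalling network with Hippo-dependent sequestration.

The model tracks ten molecular species in a single epithelial cell:

==========  ==========================================================
symbol      species (all concentrations in nM)
==========  ==========================================================
``X``       free Axin
``D``       active destruction complex (APC/Axin/GSK-3/CK1)
``A``       free adhesive partner molecules (E-cadherin pool)
``T``       free transcription partner molecules (TCF/LEF pool)
``C_A``     beta-catenin in adhesive junctions
``C_C``     free cytoplasmic beta-catenin
``C_T``     transcriptional (nuclear) beta-catenin
``C_U``     beta-catenin marked for ubiquitination/degradation
``C_H``     cytoplasmic YAP-P/beta-catenin complex (Hippo output)
``Y``       Wnt target protein
==========  ==========================================================

Kinetics are mass action except for two saturable steps: the
destruction-complex-mediated marking of cytoplasmic beta-catenin
(Michaelis-Menten in ``C_C`` with constant ``K_D``) and the Hippo-driven
sequestration of ``C_C`` into the YAP-P complex (Michaelis-Menten in
``C_C`` with constant ``K_H``).  Wnt acts by scaling three degradation /
dissociation rates of the Axin / destruction-complex subsystem (the
"tilde" rates), linearly between their Wnt-off and Wnt-on values.

The total amount of transcription partner molecules is conserved
(``T + C_T`` constant), so the system has nine independent ODEs for ten
species; ``T`` is reconstructed algebraically.

Hippo sequestration moves beta-catenin between ``C_C`` and ``C_H`` at a
matched instantaneous rate (binding flux ``p_hat_H * C_C / (K_H + C_C)``
out of ``C_C``, first-order unbinding ``k_off * C_H`` back), and the
complex additionally decays at rate ``d_CH`` — the net drain that lowers
the steady-state nuclear pool when cells are contact inhibited.  Setting
``p_hat_H = 0`` recovers the Wnt-only baseline model.

Units: hours for time, nM for concentrations throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SPECIES",
    "SignallingState",
    "SignallingParams",
    "HippoInput",
    "wnt_modulated_rates",
    "signalling_rhs",
    "integrate_signalling",
    "steady_state",
]

#: species order of the nine integrated variables (T is conserved out)
SPECIES = ("X", "D", "A", "C_A", "C_C", "C_T", "C_U", "C_H", "Y")

#: full ten-species order used by :class:`SignallingState`
ALL_SPECIES = ("X", "D", "A", "T", "C_A", "C_C", "C_T", "C_U", "C_H", "Y")


@dataclass
class SignallingState:
    """Concentrations of the ten network species (nM)."""

    X: float
    D: float
    A: float
    T: float
    C_A: float
    C_C: float
    C_T: float
    C_U: float
    C_H: float
    Y: float

    def to_vector(self) -> np.ndarray:
        """Nine-component state vector (T eliminated by conservation)."""
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, T_total: float) -> "SignallingState":
        d = dict(zip(SPECIES, np.asarray(y, dtype=float)))
        d["T"] = T_total - d["C_T"]
        return cls(**d)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SignallingParams:
    """Rate constants of the Wnt/Hippo network.

    The Axin/destruction-complex/beta-catenin backbone keeps the
    structure (and Wnt-responsive "tilde" rates) of the parent
    beta-catenin localisation model; the Hippo constants ``pH`` and
    ``K_H`` follow the single-cell sensitivity analysis (defaults
    pH = 26,000 1/h, K_H = 20 nM).
    """

    # Axin / destruction complex
    s_X: float = 10.0        # Axin synthesis, nM/h
    dX_off: float = 1.0      # Axin degradation, Wnt off, 1/h
    dX_on: float = 5.0       # Axin degradation, Wnt on, 1/h
    p_DX: float = 50.0       # destruction-complex assembly from Axin, 1/h
    dDX_off: float = 1.0     # complex dissociation back to Axin, Wnt off, 1/h
    dDX_on: float = 20.0     # complex dissociation back to Axin, Wnt on, 1/h
    dD_off: float = 0.5      # complex degradation, Wnt off, 1/h
    dD_on: float = 5.0       # complex degradation, Wnt on, 1/h

    # beta-catenin
    s_C: float = 25.0        # synthesis, nM/h
    d_C: float = 0.2         # basal degradation, 1/h
    p_U: float = 10.0        # max complex-mediated marking per nM D, 1/h
    K_D: float = 50.0        # Michaelis constant of marking, nM
    d_U: float = 10.0        # degradation of marked beta-catenin, 1/h

    # adhesive pool
    s_A: float = 20.0        # synthesis of adhesive molecules, nM/h
    d_A: float = 2.0         # degradation of free adhesive molecules, 1/h
    p_A: float = 0.02        # C_C + A binding, 1/(nM h)
    d_CA: float = 1.0        # adhesive-junction release, 1/h

    # transcriptional pool (conserved total)
    T_total: float = 50.0    # total TCF/LEF, nM
    p_T: float = 0.01        # C_C + T binding, 1/(nM h)
    d_CT: float = 1.0        # transcriptional-complex dissociation, 1/h

    # Wnt target protein
    s_Y: float = 10.0        # max target synthesis, nM/h
    K_Y: float = 15.0        # activation constant in C_T, nM
    d_Y: float = 1.0         # target degradation, 1/h

    # Hippo: YAP-P / beta-catenin complex
    pH: float = 26_000.0     # maximal binding rate, 1/h
    K_H: float = 20.0        # saturation (dissociation) constant, nM
    k_off: float = 130.0     # unbinding back to C_C, 1/h
    d_CH: float = 0.027      # decay of the complex, 1/h

    # mutation switch: 0 disables destruction-complex marking (APC mutant)
    destruction_activity: float = 1.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if name == "destruction_activity":
                if not 0.0 <= val <= 1.0:
                    raise ValueError("destruction_activity must be in [0, 1]")
            elif not val > 0:
                raise ValueError(f"rate constant {name} must be > 0, got {val}")


@dataclass
class HippoInput:
    """Effective volume-dependent YAP-P/beta-catenin binding rate (1/h)."""

    p_hat_H: float = 0.0

    def __post_init__(self) -> None:
        if self.p_hat_H < 0:
            raise ValueError("p_hat_H must be >= 0")


def wnt_modulated_rates(params: SignallingParams, W: float):
    """Effective Wnt-responsive rates ``(dX, dDX, dD)`` at Wnt level ``W``.

    Linear interpolation between the Wnt-off (``W = 0``) and Wnt-on
    (``W = 1``) values of the three "tilde" rates.
    """
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"Wnt level W must lie in [0, 1], got {W}")
    dX = params.dX_off + W * (params.dX_on - params.dX_off)
    dDX = params.dDX_off + W * (params.dDX_on - params.dDX_off)
    dD = params.dD_off + W * (params.dD_on - params.dD_off)
    return dX, dDX, dD


def _rhs_vector(y, params: SignallingParams, W: float, p_hat_H: float,
                destruction=None):
    """RHS of the nine integrated ODEs.  ``y`` ordered as :data:`SPECIES`.

    Vectorised: ``y`` may be shape (9,) or (9, n) for n cells, in which
    case ``W``, ``p_hat_H`` and ``destruction`` (per-cell override of
    ``params.destruction_activity``) may be arrays of length n.
    """
    y = np.maximum(y, 0.0)  # guard tiny negative excursions of the integrator
    X, D, A, C_A, C_C, C_T, C_U, C_H, Y = y

    dX_r = params.dX_off + W * (params.dX_on - params.dX_off)
    dDX_r = params.dDX_off + W * (params.dDX_on - params.dDX_off)
    dD_r = params.dD_off + W * (params.dD_on - params.dD_off)

    if destruction is None:
        destruction = params.destruction_activity
    assembly = params.p_DX * X
    dissoc = dDX_r * D
    marking = destruction * params.p_U * D * C_C / (params.K_D + C_C)
    adh_on = params.p_A * A * C_C
    adh_off = params.d_CA * C_A
    T_free = params.T_total - C_T
    tr_on = params.p_T * T_free * C_C
    tr_off = params.d_CT * C_T
    # Hippo sequestration; reference concentration c0 = 1 nM keeps
    # p_hat_H in 1/h as quoted.
    bind = p_hat_H * C_C / (params.K_H + C_C)
    unbind = params.k_off * C_H

    dX = params.s_X - dX_r * X - assembly + dissoc
    dD = assembly - dissoc - dD_r * D
    dA = params.s_A - params.d_A * A - adh_on + adh_off
    dC_A = adh_on - adh_off
    dC_C = (params.s_C - params.d_C * C_C - marking
            - adh_on + adh_off - tr_on + tr_off - bind + unbind)
    dC_T = tr_on - tr_off
    dC_U = marking - params.d_U * C_U
    dC_H = bind - unbind - params.d_CH * C_H
    dY = params.s_Y * C_T * C_T / (params.K_Y**2 + C_T * C_T) - params.d_Y * Y

    return np.array([dX, dD, dA, dC_A, dC_C, dC_T, dC_U, dC_H, dY])


def signalling_rhs(state: SignallingState, params: SignallingParams,
                   W: float, hippo: HippoInput) -> dict:
    """Time derivatives (nM/h) of all ten species.

    ``dT/dt`` is minus ``dC_T/dt`` (conservation of total transcription
    molecules).  Hippo binding removes beta-catenin from ``C_C`` and adds
    it to ``C_H`` at the identical instantaneous rate.
    """
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"Wnt level W must lie in [0, 1], got {W}")
    if not 0.0 <= hippo.p_hat_H <= params.pH:
        raise ValueError("p_hat_H must lie in [0, pH]")
    vec = state.to_vector()
    if np.any(vec < 0) or state.T < 0:
        raise ValueError("negative concentration in signalling state")
    dy = _rhs_vector(vec, params, W, hippo.p_hat_H)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite derivative in signalling RHS")
    out = dict(zip(SPECIES, dy))
    out["T"] = -out["C_T"]
    return {s: float(out[s]) for s in ALL_SPECIES}


def integrate_signalling(state0: SignallingState, params: SignallingParams,
                         W_of_t: Callable[[float], float] | float,
                         p_hat_H_of_t: Callable[[float], float] | float,
                         t_span: tuple[float, float],
                         rtol: float = 1e-6, atol: float = 1e-9,
                         t_eval: np.ndarray | None = None):
    """Integrate the network with adaptive RK45 (ode45-equivalent).

    ``W_of_t`` and ``p_hat_H_of_t`` may be constants or callables of time.
    Returns ``(t, states)`` with ``states`` a list of
    :class:`SignallingState` (non-negative, tiny integrator undershoots
    clipped to zero).
    """
    t0, t1 = map(float, t_span)
    if not (np.isfinite(t0) and np.isfinite(t1)):
        raise ValueError("t_span must be finite")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    W_f = W_of_t if callable(W_of_t) else (lambda t, w=float(W_of_t): w)
    pH_f = (p_hat_H_of_t if callable(p_hat_H_of_t)
            else (lambda t, p=float(p_hat_H_of_t): p))

    if t1 == t0:
        return np.array([t0]), [replace(state0)]

    def rhs(t, y):
        return _rhs_vector(y, params, W_f(t), pH_f(t))

    sol = solve_ivp(rhs, (t0, t1), state0.to_vector(), method="RK45",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"signalling integration failed at t={sol.t[-1]:.4g} h: "
            f"{sol.message}")
    states = [SignallingState.from_vector(np.maximum(col, 0.0),
                                          params.T_total)
              for col in sol.y.T]
    return sol.t, states


def _default_initial_vector(params: SignallingParams) -> np.ndarray:
    # modest positive seed concentrations; steady state does not depend
    # on them (the network is globally attracting in practice)
    return np.array([1.0, 5.0, 10.0, 5.0, 10.0, 5.0, 1.0, 0.0, 1.0])


def steady_state(params: SignallingParams, W: float,
                 p_hat_H: float = 0.0, tol: float = 1e-8,
                 t_max: float = 2000.0) -> SignallingState:
    """Locate the steady state at fixed Wnt level and Hippo rate.

    Long LSODA integration to near-equilibrium followed by a Newton
    polish; the returned state has an RHS norm below ``tol`` (nM/h).
    """
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"Wnt level W must lie in [0, 1], got {W}")

    def rhs(t, y):
        return _rhs_vector(y, params, W, p_hat_H)

    sol = solve_ivp(rhs, (0.0, t_max), _default_initial_vector(params),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    y = np.maximum(sol.y[:, -1], 0.0)
    res = root(lambda v: _rhs_vector(v, params, W, p_hat_H), y,
               method="hybr", tol=1e-12)
    if res.success and np.all(res.x >= -1e-9):
        y = np.maximum(res.x, 0.0)
    norm = float(np.linalg.norm(_rhs_vector(y, params, W, p_hat_H)))
    if norm > tol:
        raise RuntimeError(
            f"steady state not converged: |rhs| = {norm:.3g} nM/h")
    return SignallingState.from_vector(y, params.T_total)
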