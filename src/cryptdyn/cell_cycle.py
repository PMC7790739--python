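"""Restriction-point cell-cycle model coupled to transcriptional beta-catenin.

Five ODEs in the Swat G1/S-transition family describe the
retinoblastoma / E2F1 switch that gates the G1-to-S transition:

* ``R``  — hypophosphorylated (active) retinoblastoma protein pRb
* ``E``  — free E2F1 transcription factor
* ``Di`` — inactive cyclin D/Cdk4-6 complexes
* ``Da`` — active cyclin D/Cdk4-6 complexes
* ``P``  — phosphorylated (inactive) pRb

Active cyclin D phosphorylates pRb, releasing E2F1 from repression;
E2F1 auto-activates and feeds back on cyclin D, producing a bistable
switch.  The G1-to-S transition fires when ``E2F1 > 1`` (strict).  The
mitogenic input driving cyclin D synthesis is linear in the
transcriptional beta-catenin level ``C_T`` supplied by the signalling
module: ``m = coupling_gain * C_T``.  S, G2 and M have fixed
deterministic durations, so only G1 is ODE-controlled.

All cell-cycle variables are dimensionless; time is in hours (a global
``time_scale`` converts the dimensionless kinetic rates to 1/h).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Phase",
    "ARRESTED",
    "CellCycleState",
    "CycleParams",
    "cycle_rhs",
    "g1_exit_reached",
    "cycle_duration",
    "sensitivity_scan",
    "POST_MITOTIC_IC",
]

CYCLE_VARS = ("pRb", "E2F1", "CycDi", "CycDa", "pRb_p")

#: state both daughters are reset to immediately after mitosis
POST_MITOTIC_IC = np.array([2.0, 0.1, 0.0, 0.0, 0.0])

#: sentinel returned by :func:`cycle_duration` when E2F1 never crosses 1
ARRESTED = float("inf")


class Phase(enum.IntEnum):
    G1 = 0
    S = 1
    G2 = 2
    M = 3


@dataclass
class CellCycleState:
    """Continuous cycle variables plus discrete phase bookkeeping."""

    pRb: float = POST_MITOTIC_IC[0]
    E2F1: float = POST_MITOTIC_IC[1]
    CycDi: float = POST_MITOTIC_IC[2]
    CycDa: float = POST_MITOTIC_IC[3]
    pRb_p: float = POST_MITOTIC_IC[4]
    phase: Phase = Phase.G1
    phase_age: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([self.pRb, self.E2F1, self.CycDi,
                         self.CycDa, self.pRb_p], dtype=float)


@dataclass
class CycleParams:
    """Rate constants of the restriction-point module and phase timing.

    Dimensionless kinetic constants follow the published values of the
    parent G1/S model; ``time_scale`` and ``coupling_gain`` set the
    absolute clock (G1 of ~11 h at the Wnt-on transcriptional
    beta-catenin level) and the arrest threshold (no G1 exit below a
    C_T of roughly 19.6 nM within the arrest horizon, the level
    reached near Wnt level 0.65).
    """

    k1: float = 1.0
    Km1: float = 0.5
    J11: float = 0.5
    phi_R: float = 0.005
    kp: float = 0.05
    k2: float = 1.6
    a: float = 0.04
    Km2: float = 4.0
    J12: float = 5.0
    phi_E: float = 0.1
    k3: float = 0.05
    k23: float = 0.3
    J13: float = 0.002
    k34: float = 0.04
    k34b: float = 0.003
    Km4: float = 0.3
    k43: float = 0.01
    phi_Di: float = 0.023
    phi_Da: float = 0.03
    k16: float = 0.4
    k61: float = 0.3
    phi_P: float = 0.06

    time_scale: float = 19.0     # dimensionless-time units per hour
    coupling_gain: float = 0.0118  # mitogenic input per nM of C_T

    # deterministic phase durations (h)
    t_S: float = 5.0
    t_G2: float = 4.0
    t_M: float = 1.0

    # horizon after which a cell still in G1 is declared arrested (h)
    T_max: float = 100.0

    def __post_init__(self) -> None:
        if min(self.t_S, self.t_G2, self.t_M) <= 0:
            raise ValueError("phase durations must be > 0")
        if self.T_max <= self.t_S + self.t_G2 + self.t_M:
            raise ValueError("T_max must exceed a typical cycle length")

    @property
    def t_SG2M(self) -> float:
        return self.t_S + self.t_G2 + self.t_M


def cycle_rhs_vector(y: np.ndarray, C_T, params: CycleParams) -> np.ndarray:
    """Derivatives (1/h) of the five cycle variables.

    Vectorised: ``y`` may be (5,) or (5, n); ``C_T`` scalar or length n.
    """
    y = np.maximum(y, 0.0)
    R, E, Di, Da, P = y
    p = params
    m = p.coupling_gain * C_T
    dR = (p.k1 * E / (p.Km1 + E) * p.J11 / (p.J11 + R + P)
          - p.k16 * R * Da + p.k61 * P - p.phi_R * R)
    dE = (p.kp + p.k2 * (p.a**2 + E * E) / (p.Km2**2 + E * E)
          * p.J12 / (p.J12 + R) - p.phi_E * E)
    conv = p.k34 * Di * Da / (p.Km4 + Da) + p.k34b * Di
    dDi = (p.k3 * m + p.k23 * E * p.J13 / (p.J13 + R)
           - conv + p.k43 * Da - p.phi_Di * Di)
    dDa = conv - (p.k43 + p.phi_Da) * Da
    dP = p.k16 * R * Da - p.k61 * P - p.phi_P * P
    return p.time_scale * np.array([dR, dE, dDi, dDa, dP])


def cycle_rhs(state: CellCycleState, C_T: float,
              params: CycleParams) -> dict:
    """Derivatives of the cycle variables at transcriptional level ``C_T``."""
    if C_T < 0:
        raise ValueError("C_T must be >= 0")
    dy = cycle_rhs_vector(state.to_vector(), float(C_T), params)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite cell-cycle derivative")
    return dict(zip(CYCLE_VARS, (float(v) for v in dy)))


def g1_exit_reached(state: CellCycleState) -> bool:
    """Strict restriction-point test: ``E2F1 > 1`` while in G1."""
    if state.phase != Phase.G1:
        raise ValueError("g1_exit_reached is only defined in G1")
    return state.E2F1 > 1.0


def g1_duration(C_T_of_t, params: CycleParams,
                y0: np.ndarray | None = None) -> float:
    """Time (h) for E2F1 to cross 1 from the post-mitotic state.

    ``C_T_of_t`` is a constant or callable of time.  Returns
    :data:`ARRESTED` if the threshold is not crossed within ``T_max``.
    """
    ct = C_T_of_t if callable(C_T_of_t) else (lambda t, c=float(C_T_of_t): c)
    y0 = POST_MITOTIC_IC if y0 is None else np.asarray(y0, dtype=float)

    def rhs(t, y):
        return cycle_rhs_vector(y, ct(t), params)

    def crossed(t, y):
        return y[1] - 1.0
    crossed.terminal = True
    crossed.direction = 1

    sol = solve_ivp(rhs, (0.0, params.T_max), y0, events=crossed,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"cell-cycle integration failed: {sol.message}")
    if len(sol.t_events[0]) == 0:
        return ARRESTED
    return float(sol.t_events[0][0])


def cycle_duration(W: float, p_hat_H: float, params: CycleParams,
                   signalling_params=None) -> float:
    """Division-to-division time (h) of a single cell, or ``ARRESTED``.

    The signalling network is held at its steady state for the given
    Wnt level ``W`` and Hippo rate ``p_hat_H`` (single-cell setting:
    the cycle is slow relative to signalling relaxation), and the cycle
    module is integrated from the post-mitotic state until E2F1 crosses
    1; fixed S/G2/M durations are appended.
    """
    from .signalling import SignallingParams, steady_state

    if not 0.0 <= W <= 1.0:
        raise ValueError("W must lie in [0, 1]")
    if p_hat_H < 0:
        raise ValueError("p_hat_H must be >= 0")
    sp = signalling_params if signalling_params is not None else SignallingParams()
    C_T = steady_state(sp, W, p_hat_H).C_T
    g1 = g1_duration(C_T, params)
    if g1 is ARRESTED or np.isinf(g1):
        return ARRESTED
    return g1 + params.t_SG2M


def sensitivity_scan(axis1: np.ndarray, axis2: np.ndarray,
                     params: CycleParams, signalling_params=None,
                     mode: str = "pH_KH") -> np.ndarray:
    """Matrix of cycle durations (h; inf = arrest) over a parameter grid.

    ``mode="pH_KH"`` scans the Hippo binding rate (axis1) against the
    saturation constant K_H (axis2) at maximal Wnt, mirroring the
    single-cell sensitivity analysis of the Hippo module;
    ``mode="W_pH"`` scans Wnt level (axis1) against binding rate (axis2)
    at the default K_H.
    """
    from dataclasses import replace as dreplace
    from .signalling import SignallingParams

    sp = signalling_params if signalling_params is not None else SignallingParams()
    out = np.empty((len(axis1), len(axis2)))
    for i, a1 in enumerate(axis1):
        for j, a2 in enumerate(axis2):
            if mode == "pH_KH":
                spij = dreplace(sp, pH=max(float(a1), 1e-12),
                                K_H=float(a2))
                out[i, j] = cycle_duration(1.0, float(a1), params, spij)
            elif mode == "W_pH":
                spij = dreplace(sp, pH=max(float(a2), 1e-12))
                out[i, j] = cycle_duration(float(a1), float(a2), params, spij)
            else:
                raise ValueError(f"unknown scan mode {mode!r}")
    return out
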