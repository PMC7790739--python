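"""Multiscale crypt simulation engine.

Orchestrates, per time step ``dt``:

1. mechanics update (spring forces on the Voronoi neighbour graph,
   overdamped motion),
2. Voronoi cell volumes,
3. Wnt reservoir refresh (division-based model),
4. per-cell volume-dependent Hippo activation,
5. signalling and cell-cycle ODE advance,
6. divisions (E2F1-gated G1 exit, fixed S/G2/M), and
7. sloughing of cells leaving the crypt top.

Per-cell state lives in numpy arrays; the signalling system is advanced
with a fixed-step RK4 integrator vectorised over all cells, sub-stepped
below the mechanics step so the fast Hippo exchange remains stable.
Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell_cycle import (POST_MITOTIC_IC, CycleParams, Phase,
                         cycle_rhs_vector)
from .mechanics import CryptDomain, MechParams, spring_forces, tessellate
from .signalling import SignallingParams, _rhs_vector, steady_state
from .wnt_field import WntConfig, WntMode, divide_wnt, external_wnt

__all__ = [
    "V_EQ",
    "Cell",
    "EngineConfig",
    "CryptSimulation",
    "effective_hippo_rate",
    "apply_mutation",
    "run_simulation",
    "run_washout_ensemble",
    "WASHOUT", "TAKEOVER", "TIMEOUT",
]

#: equilibrium cell area: hexagonal packing at unit spacing (diameters^2)
V_EQ = math.sqrt(3.0) / 2.0

WASHOUT = "WASHOUT"
TAKEOVER = "TAKEOVER"
TIMEOUT = "TIMEOUT"


@dataclass
class Cell:
    """Materialised per-cell record (the engine stores arrays)."""

    id: int
    lineage: int
    mutant: bool
    birth_time: float
    W: float
    position: tuple[float, float]
    volume: float
    phase: Phase
    phase_age: float
    signalling: np.ndarray  # 9-vector, see signalling.SPECIES
    cycle: np.ndarray       # 5-vector, see cell_cycle.CYCLE_VARS


@dataclass
class EngineConfig:
    """Full configuration of a crypt simulation."""

    domain: CryptDomain = field(default_factory=CryptDomain)
    mech: MechParams = field(default_factory=MechParams)
    wnt: WntConfig = field(default_factory=WntConfig)
    cycle: CycleParams = field(default_factory=CycleParams)
    signalling: SignallingParams = field(default_factory=SignallingParams)
    theta_CI: float = 0.9          # CI volume threshold, fraction of V_EQ
    t_max: float = 200.0           # simulated time (h)
    snapshot_interval: float = 1.0  # h
    burn_in: float = 10.0          # excluded from statistics downstream
    seed: int = 0
    tessellation_every: int = 3    # mechanics steps between Voronoi rebuilds
    ode_substeps: int = 12         # signalling substeps per mechanics step
    desync_window: float = 14.0    # random cycle head start at t=0 (h)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_CI <= 1.0:
            raise ValueError("theta_CI must lie in (0, 1]")
        if self.t_max < 0 or self.snapshot_interval <= 0:
            raise ValueError("invalid time configuration")


def effective_hippo_rate(V, V_eq: float, theta_CI: float, pH: float,
                         mutant=False):
    """Volume-dependent YAP-P/beta-catenin binding rate.

    Step activation: the full rate ``pH`` when the cell volume is below
    ``theta_CI * V_eq``, zero otherwise; mutants are never contact
    inhibited.  Vectorised over ``V`` and ``mutant``.
    """
    V = np.asarray(V, dtype=float)
    below = V < theta_CI * V_eq
    rate = np.where(below & ~np.asarray(mutant, dtype=bool), pH, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def apply_mutation(cell: Cell) -> Cell:
    """APC double mutant: destruction complex and Hippo response disabled.

    The returned copy proliferates independently of Wnt and volume; the
    original record is untouched.
    """
    if cell.mutant:
        raise ValueError("cell is already mutant")
    return replace(cell, mutant=True)


def _hex_lattice(domain: CryptDomain) -> np.ndarray:
    """Hexagonal packing at unit spacing filling the crypt band."""
    n_rows = int(round(domain.height / (math.sqrt(3.0) / 2.0)))
    n_cols = int(round(domain.width))
    # the bottom row sits half a diameter above the base wall so basal
    # cells start with full-sized Voronoi regions
    pts = [((c + 0.5 * (r % 2)) % domain.width,
            0.5 + r * math.sqrt(3.0) / 2.0)
           for r in range(n_rows) for c in range(n_cols)]
    return np.array(pts)


class CryptSimulation:
    """One crypt, advanced step by step.  Deterministic given the seed."""

    def __init__(self, cfg: EngineConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.t = 0.0
        self.events: list[dict] = []
        self._snapshots: list[dict] = []
        self._next_snapshot = 0.0
        self._steps = 0
        self._dirty = False
        self._mutant_introduced = False

        pos = _hex_lattice(cfg.domain)
        n = len(pos)
        self.pos = pos
        self.ids = np.arange(n)
        self._next_id = n
        self.lineage = np.arange(n)
        self.mutant = np.zeros(n, dtype=bool)
        self.birth_time = np.zeros(n)
        self.partner_id = np.full(n, -1)  # sibling for spring maturation

        h = np.clip(pos[:, 1] / cfg.domain.height, 0.0, 1.0)
        if cfg.wnt.mode == WntMode.MI:
            # seed the internal levels with the dyadic ladder closest to
            # a linear profile (levels are W_max 2^-k after k noiseless
            # divisions, so the seed respects the same structure); the
            # emergent gradient replaces it within a crypt turnover
            k = np.ceil(-np.log2(np.maximum(1.0 - h, 2.0**-8)))
            self.W = cfg.wnt.W_max * 2.0 ** (-np.maximum(k, 0.0))
            self.W[h <= cfg.wnt.rho] = cfg.wnt.W_max
        else:
            self.W = external_wnt(h, cfg.wnt)
        self.birth_W = self.W.copy()

        # signalling: per-cell steady state at birth Wnt level, Hippo off
        self.sig = self._interp_steady_states(self.W)
        # cycle: post-mitotic state with a random head start to
        # desynchronise the initial population
        self.cyc = np.tile(POST_MITOTIC_IC[:, None], (1, n)).astype(float)
        self.phase = np.full(n, int(Phase.G1))
        self.phase_age = np.zeros(n)
        self._desynchronise()

        self.volumes = np.full(n, V_EQ)
        self.edges = np.empty((0, 2), dtype=int)
        self._retessellate()
        self._take_snapshot()

    # -- initialisation helpers -------------------------------------------

    def _interp_steady_states(self, W: np.ndarray) -> np.ndarray:
        grid = np.linspace(0.0, 1.0, 11)
        table = np.stack([steady_state(self.cfg.signalling, w).to_vector()
                          for w in grid], axis=1)  # (9, 11)
        out = np.empty((9, len(W)))
        for k in range(9):
            out[k] = np.interp(W, grid, table[k])
        return out

    def _desynchronise(self) -> None:
        """Advance each cell's cycle by a random fraction of the window.

        Implemented by scaling each cell's clock with an independent
        uniform factor while integrating for the full window, which is
        equivalent to a per-cell head start but stays vectorised.
        """
        if self.cfg.desync_window <= 0:
            return
        u = self.rng.uniform(0.0, 1.0, size=len(self.ids))
        dt = 0.01
        C_T = self.sig[5]
        for _ in range(int(self.cfg.desync_window / dt)):
            self.cyc = _rk4(lambda y: cycle_rhs_vector(y, C_T,
                                                       self.cfg.cycle) * u,
                            self.cyc, dt)
        self.cyc = np.maximum(self.cyc, 0.0)

    # -- per-step physics -------------------------------------------------

    def _retessellate(self) -> None:
        self.edges, self.volumes = tessellate(
            self.pos, self.cfg.domain, cutoff=self.cfg.mech.cutoff)

    def _rest_lengths(self) -> np.ndarray:
        mech = self.cfg.mech
        rest = np.full(len(self.edges), mech.rest_length)
        if len(self.edges) == 0:
            return rest
        i, j = self.edges[:, 0], self.edges[:, 1]
        sib = (self.partner_id[i] == self.ids[j]) \
            & (self.partner_id[j] == self.ids[i])
        if np.any(sib):
            age = self.t - self.birth_time[self.edges[sib, 0]]
            frac = np.clip(age / mech.maturation_time, 0.0, 1.0)
            rest[sib] = (mech.newborn_rest_length
                         + frac * (mech.rest_length
                                   - mech.newborn_rest_length))
        return rest

    def _heights(self) -> np.ndarray:
        return np.clip(self.pos[:, 1] / self.cfg.domain.height, 0.0, 1.0)

    def step(self) -> None:
        """Advance the crypt by one mechanics time step."""
        cfg = self.cfg
        dt = cfg.mech.dt

        # 1. mechanics (retessellate on cadence and whenever the cell
        # set changed, since edges index into the state arrays)
        if self._dirty or self._steps % cfg.tessellation_every == 0:
            self._retessellate()
            self._dirty = False
        forces = spring_forces(self.pos, self.edges, self._rest_lengths(),
                               cfg.mech.mu, cfg.domain)
        disp = forces / cfg.mech.eta * dt
        self.pos = self.pos + disp
        self.pos[:, 0] = cfg.domain.wrap_x(self.pos[:, 0])
        self.pos[:, 1] = np.maximum(self.pos[:, 1], 0.0)

        # 2./3. current Wnt level per model (+ reservoir refresh)
        h = self._heights()
        if cfg.wnt.mode == WntMode.ME2:
            self.W = external_wnt(h, cfg.wnt)
        elif cfg.wnt.mode == WntMode.ME1:
            self.W = self.birth_W
        else:  # M_I: refresh reservoir after the mechanics update
            in_res = h <= cfg.wnt.rho
            self.W[in_res] = cfg.wnt.W_max

        # 4. volume-dependent Hippo activation
        p_hat = effective_hippo_rate(self.volumes, V_EQ, cfg.theta_CI,
                                     cfg.signalling.pH, self.mutant)

        # 5a. signalling advance (sub-stepped RK4, vectorised over cells)
        destruction = np.where(self.mutant, 0.0,
                               cfg.signalling.destruction_activity)
        sub = dt / cfg.ode_substeps
        sig = self.sig
        for _ in range(cfg.ode_substeps):
            sig = _rk4(lambda y: _rhs_vector(y, cfg.signalling, self.W,
                                             p_hat,
                                             destruction=destruction),
                       sig, sub)
        self.sig = np.maximum(sig, 0.0)

        # 5b. cell-cycle advance; mutants run at the Wnt-independent
        # maximal-proliferation setting (Wnt-on transcriptional level)
        C_T = self.sig[5].copy()
        if np.any(self.mutant):
            C_T[self.mutant] = self._mutant_C_T()
        self.cyc = np.maximum(
            _rk4(lambda y: cycle_rhs_vector(y, C_T, cfg.cycle),
                 self.cyc, dt), 0.0)

        # 6. phase bookkeeping and divisions
        self.phase_age += dt
        g1 = self.phase == int(Phase.G1)
        exiting = g1 & (self.cyc[1] > 1.0)
        self.phase[exiting] = int(Phase.S)
        self.phase_age[exiting] = 0.0
        s_done = (self.phase == int(Phase.S)) \
            & (self.phase_age >= cfg.cycle.t_S)
        self.phase[s_done] = int(Phase.G2)
        self.phase_age[s_done] = 0.0
        g2_done = (self.phase == int(Phase.G2)) \
            & (self.phase_age >= cfg.cycle.t_G2)
        self.phase[g2_done] = int(Phase.M)
        self.phase_age[g2_done] = 0.0
        dividing = np.flatnonzero((self.phase == int(Phase.M))
                                  & (self.phase_age >= cfg.cycle.t_M))
        for idx in dividing:
            self._divide(int(idx))

        # 7. sloughing
        self._remove_sloughed()

        self.t += dt
        self._steps += 1
        if self.t + 1e-9 >= self._next_snapshot:
            self._take_snapshot()

    def _mutant_C_T(self) -> float:
        if not hasattr(self, "_mutant_ct_cache"):
            self._mutant_ct_cache = steady_state(
                self.cfg.signalling, 1.0, 0.0).C_T
        return self._mutant_ct_cache

    # -- division / removal ----------------------------------------------

    def _divide(self, i: int) -> None:
        cfg = self.cfg
        theta = self.rng.uniform(0.0, 2.0 * math.pi)
        offset = 0.05 * np.array([math.cos(theta), math.sin(theta)])
        p1 = self.pos[i] + offset
        p2 = self.pos[i] - offset
        for p in (p1, p2):
            p[0] = cfg.domain.wrap_x(p[0])
            p[1] = max(p[1], 0.0)

        if cfg.wnt.mode == WntMode.MI:
            W1, W2 = divide_wnt(float(self.W[i]), cfg.wnt.sigma, self.rng)
        else:
            h1 = min(max(p1[1] / cfg.domain.height, 0.0), 1.0)
            h2 = min(max(p2[1] / cfg.domain.height, 0.0), 1.0)
            W1 = external_wnt(h1, cfg.wnt)
            W2 = external_wnt(h2, cfg.wnt)

        new_id = self._next_id
        self._next_id += 1

        # daughter 1 reuses the mother's slot (and id); daughter 2 appended
        self.pos[i] = p1
        self.W[i] = W1
        self.birth_W[i] = W1
        self.birth_time[i] = self.t
        self.cyc[:, i] = POST_MITOTIC_IC
        self.phase[i] = int(Phase.G1)
        self.phase_age[i] = 0.0
        self.partner_id[i] = new_id

        self.pos = np.vstack([self.pos, p2])
        self.ids = np.append(self.ids, new_id)
        self.lineage = np.append(self.lineage, self.lineage[i])
        self.mutant = np.append(self.mutant, self.mutant[i])
        self.birth_time = np.append(self.birth_time, self.t)
        self.partner_id = np.append(self.partner_id, self.ids[i])
        self.W = np.append(self.W, W2)
        self.birth_W = np.append(self.birth_W, W2)
        self.sig = np.hstack([self.sig, self.sig[:, i:i + 1]])
        self.cyc = np.hstack([self.cyc, POST_MITOTIC_IC[:, None]])
        self.phase = np.append(self.phase, int(Phase.G1))
        self.phase_age = np.append(self.phase_age, 0.0)
        self.volumes = np.append(self.volumes, self.volumes[i] / 2.0)

        self._dirty = True
        self.events.append({"t": self.t, "event": "division",
                            "id": int(self.ids[i]), "daughter": int(new_id),
                            "lineage": int(self.lineage[i]),
                            "mutant": bool(self.mutant[i])})

    def _remove_sloughed(self) -> list[int]:
        gone = self.pos[:, 1] > self.cfg.domain.height
        if not np.any(gone):
            return []
        removed = [int(i) for i in self.ids[gone]]
        self._dirty = True
        for cid, lin, mut in zip(self.ids[gone], self.lineage[gone],
                                 self.mutant[gone]):
            self.events.append({"t": self.t, "event": "removal",
                                "id": int(cid), "lineage": int(lin),
                                "mutant": bool(mut)})
        keep = ~gone
        self.pos = self.pos[keep]
        self.ids = self.ids[keep]
        self.lineage = self.lineage[keep]
        self.mutant = self.mutant[keep]
        self.birth_time = self.birth_time[keep]
        self.partner_id = self.partner_id[keep]
        self.W = self.W[keep]
        self.birth_W = self.birth_W[keep]
        self.sig = self.sig[:, keep]
        self.cyc = self.cyc[:, keep]
        self.phase = self.phase[keep]
        self.phase_age = self.phase_age[keep]
        self.volumes = self.volumes[keep]
        return removed

    def introduce_mutant(self, bottom_fraction: float = 0.05) -> int:
        """Turn one cell in the crypt base into an APC double mutant."""
        h = self._heights()
        candidates = np.flatnonzero(h <= bottom_fraction)
        if len(candidates) == 0:
            # fall back to the basal-most cell
            candidates = np.array([int(np.argmin(h))])
        i = int(self.rng.choice(candidates))
        if self.mutant[i]:
            raise ValueError("cell is already mutant")
        self.mutant[i] = True
        self._mutant_introduced = True
        self.events.append({"t": self.t, "event": "mutation",
                            "id": int(self.ids[i]),
                            "lineage": int(self.lineage[i])})
        return int(self.ids[i])

    # -- running and output -----------------------------------------------

    def run(self, t_end: float | None = None,
            stop_on_fixation: bool = False) -> str | None:
        """Advance to ``t_end`` (default ``cfg.t_max``).

        With ``stop_on_fixation`` the run ends as soon as the mutant
        lineage is washed out or has taken over, returning the outcome.
        """
        t_end = self.cfg.t_max if t_end is None else t_end
        while self.t < t_end - 1e-9:
            self.step()
            if stop_on_fixation:
                n_mut = int(self.mutant.sum())
                if n_mut == 0:
                    return WASHOUT
                if n_mut == len(self.mutant):
                    return TAKEOVER
        return TIMEOUT if stop_on_fixation else None

    def _take_snapshot(self) -> None:
        self._snapshots.append({
            "t": self.t,
            "id": self.ids.copy(),
            "lineage": self.lineage.copy(),
            "mutant": self.mutant.copy(),
            "x": self.pos[:, 0].copy(),
            "y": self.pos[:, 1].copy(),
            "volume": self.volumes.copy(),
            "W": self.W.copy(),
            "phase": self.phase.copy(),
            "E2F1": self.cyc[1].copy(),
        })
        self._next_snapshot += self.cfg.snapshot_interval

    def trajectory(self) -> pd.DataFrame:
        """Long-format snapshot table (one row per cell per snapshot)."""
        frames = []
        for snap in self._snapshots:
            n = len(snap["id"])
            frames.append(pd.DataFrame({
                "t": np.full(n, snap["t"]),
                **{k: snap[k] for k in ("id", "lineage", "mutant", "x", "y",
                                        "volume", "W", "phase", "E2F1")}}))
        return pd.concat(frames, ignore_index=True)

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def cells(self) -> list[Cell]:
        """Materialise per-cell records (API convenience)."""
        return [Cell(id=int(self.ids[i]), lineage=int(self.lineage[i]),
                     mutant=bool(self.mutant[i]),
                     birth_time=float(self.birth_time[i]),
                     W=float(self.W[i]),
                     position=(float(self.pos[i, 0]), float(self.pos[i, 1])),
                     volume=float(self.volumes[i]),
                     phase=Phase(int(self.phase[i])),
                     phase_age=float(self.phase_age[i]),
                     signalling=self.sig[:, i].copy(),
                     cycle=self.cyc[:, i].copy())
                for i in range(len(self.ids))]


def _rk4(f, y, dt):
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def run_simulation(cfg: EngineConfig):
    """Run one crypt to ``cfg.t_max``; returns (trajectory, events)."""
    sim = CryptSimulation(cfg)
    sim.run()
    return sim.trajectory(), sim.events


def run_washout_ensemble(cfg: EngineConfig, n: int, base_seed: int,
                         warmup: float = 25.0,
                         bottom_fraction: float = 0.05) -> list[str]:
    """Ensemble of mutant-introduction experiments.

    Each run relaxes a wild-type crypt for ``warmup`` hours, mutates one
    basal cell, then runs until the mutant lineage is eliminated
    (washout), fills the crypt (takeover / monoclonal conversion), or
    ``cfg.t_max`` elapses (timeout).  Runs are independent and
    reproducible from ``(base_seed, run index)``.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    outcomes = []
    for k in range(n):
        seed = int((base_seed * 100_003 + k) % (2**31 - 1))
        run_cfg = replace(cfg, seed=seed)
        sim = CryptSimulation(run_cfg)
        sim.run(t_end=warmup)
        sim.introduce_mutant(bottom_fraction)
        outcome = sim.run(t_end=warmup + cfg.t_max, stop_on_fixation=True)
        outcomes.append(outcome)
    return outcomes
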