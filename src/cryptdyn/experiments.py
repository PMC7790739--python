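"""Canned crypt experiments and their summary statistics.

These functions reproduce the standard in-silico experiments at a
reduced problem size chosen to run on a single CPU (one 8x16-diameter
crypt per condition instead of large repeated ensembles): wild-type
imposed-gradient crypts under the two contact-inhibition thresholds and
the two gradient extents, the division-based-Wnt crypt, and mutant
washout ensembles.  The relative effects measured here are robust to
the crypt size; the methods note discusses the choice.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import CryptSimulation, EngineConfig, run_washout_ensemble
from .mechanics import CryptDomain
from .observables import (mean_crypt_speed, mitotic_index_profile,
                          washout_probability, wnt_profile)
from .wnt_field import WntConfig

__all__ = [
    "CRYPT_WIDTH", "CRYPT_HEIGHT",
    "run_wildtype_crypt", "run_internal_wnt_crypt",
    "wildtype_ci_comparison", "internal_wnt_summary",
    "mitotic_dip_height", "washout_trend",
]

CRYPT_WIDTH = 8.0
CRYPT_HEIGHT = 16.0
T_MAX_WT = 120.0       # simulated hours per wild-type run
BURN_IN_WT = 20.0      # h excluded from wild-type statistics
BURN_IN_MI = 40.0      # h excluded for the division-based model (the
                       # emergent gradient needs a crypt turnover)
N_BINS = 20


def _config(wnt: WntConfig, theta_CI: float, seed: int,
            t_max: float = T_MAX_WT) -> EngineConfig:
    return EngineConfig(domain=CryptDomain(width=CRYPT_WIDTH,
                                           height=CRYPT_HEIGHT),
                        wnt=wnt, theta_CI=theta_CI, t_max=t_max,
                        seed=seed)


def run_wildtype_crypt(theta_W: float, theta_CI: float,
                       seed: int, t_max: float = T_MAX_WT) -> pd.DataFrame:
    """One wild-type M_E1 crypt trajectory."""
    cfg = _config(WntConfig(mode="M_E1", theta_W=theta_W), theta_CI, seed,
                  t_max)
    sim = CryptSimulation(cfg)
    sim.run()
    return sim.trajectory()


def run_internal_wnt_crypt(rho: float, sigma: float, seed: int,
                           t_max: float = T_MAX_WT) -> pd.DataFrame:
    """One wild-type M_I (division-based Wnt) crypt trajectory."""
    cfg = _config(WntConfig(mode="M_I", rho=rho, sigma=sigma), 0.9, seed,
                  t_max)
    sim = CryptSimulation(cfg)
    sim.run()
    return sim.trajectory()


def _mi_profile(tr: pd.DataFrame, burn_in: float) -> np.ndarray:
    return mitotic_index_profile(tr, CRYPT_HEIGHT, n_bins=N_BINS,
                                 burn_in=burn_in).value


def _nanmean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.nanmean(x)) if np.any(np.isfinite(x)) else float("nan")


def _upper_niche_bins(profile: np.ndarray) -> np.ndarray:
    """Top third of the bins still proliferative in ``profile``.

    Proliferative = mitotic index at least 10% of the profile maximum.
    """
    vals = np.nan_to_num(profile)
    prolif = np.flatnonzero(vals >= 0.1 * vals.max())
    top = max(1, len(prolif) // 3)
    return prolif[-top:]


def wildtype_ci_comparison(base_seed: int, n_seeds: int = 2) -> dict:
    """Paired wild-type comparisons across CI thresholds and Wnt extents.

    Runs the M_E1 crypt at (theta_W, theta_CI) in {0.4, 1.0} x {0.6, 0.9}
    with matched seeds and returns the relative reductions (in %):

    - ``mi_base_reduction``: mitotic index in the bottom 20% of the
      crypt, CI 0.6 -> 0.9, averaged over both gradient extents;
    - ``mi_niche_top_reduction``: same change evaluated in the uppermost
      bins still proliferative under CI 0.6;
    - ``speed_reduction_ci``: mean cell speed, CI 0.6 -> 0.9;
    - ``speed_reduction_wnt``: mean cell speed, theta_W 1.0 -> 0.4 at
      CI 0.6.
    """
    seeds = [int(base_seed) * 1000 + k for k in range(n_seeds)]
    base = slice(0, N_BINS // 5)  # bottom 20% of the height bins

    mi = {}      # (theta_W, theta_CI) -> averaged profile
    speed = {}   # (theta_W, theta_CI) -> mean speed over seeds
    for theta_W in (0.4, 1.0):
        for theta_CI in (0.6, 0.9):
            profs, sps = [], []
            for seed in seeds:
                tr = run_wildtype_crypt(theta_W, theta_CI, seed)
                profs.append(_mi_profile(tr, BURN_IN_WT))
                sps.append(mean_crypt_speed(tr, CRYPT_WIDTH,
                                            burn_in=BURN_IN_WT))
            mi[(theta_W, theta_CI)] = np.nanmean(profs, axis=0)
            speed[(theta_W, theta_CI)] = float(np.mean(sps))

    base_reds, top_reds, ci_speed_reds = [], [], []
    for theta_W in (0.4, 1.0):
        lo, hi = mi[(theta_W, 0.6)], mi[(theta_W, 0.9)]
        base_reds.append(100.0 * (1.0 - _nanmean(hi[base])
                                  / _nanmean(lo[base])))
        bins = _upper_niche_bins(lo)
        top_reds.append(100.0 * (1.0 - _nanmean(hi[bins])
                                 / _nanmean(lo[bins])))
        ci_speed_reds.append(100.0 * (1.0 - speed[(theta_W, 0.9)]
                                      / speed[(theta_W, 0.6)]))

    return {
        "mi_base_reduction": float(np.mean(base_reds)),
        "mi_niche_top_reduction": float(np.mean(top_reds)),
        "speed_reduction_ci": float(np.mean(ci_speed_reds)),
        "speed_reduction_wnt": 100.0 * (1.0 - speed[(0.4, 0.6)]
                                        / speed[(1.0, 0.6)]),
        "profiles": mi,
        "speeds": speed,
        "n_seeds": n_seeds,
    }


def mitotic_dip_height(profile: np.ndarray, rho: float) -> float:
    """Height (% of crypt) of the dip-to-sharp-increase transition.

    Looks above the reservoir for the local minimum of the mitotic
    profile whose following bin shows the largest rise; the transition
    is placed midway between that bin and the next.
    """
    height, _ = _dip_feature(profile, rho)
    if np.isnan(height):
        raise RuntimeError("no dip-then-increase feature in the profile")
    return height


def _dip_feature(profile: np.ndarray, rho: float) -> tuple[float, float]:
    """(transition height in %, rise magnitude); (nan, 0) if absent."""
    vals = np.nan_to_num(np.asarray(profile, dtype=float))
    centers = (np.arange(len(vals)) + 0.5) / len(vals)
    lo = np.searchsorted(centers, rho)          # above the reservoir
    hi = np.searchsorted(centers, 0.75)
    best, best_rise = None, 0.0
    for i in range(max(lo, 1), hi - 1):
        if vals[i] <= vals[i - 1] and vals[i + 1] > vals[i]:
            rise = vals[i + 1] - vals[i]
            if rise > best_rise:
                best, best_rise = i, rise
    if best is None:
        return float("nan"), 0.0
    return 100.0 * 0.5 * (centers[best] + centers[best + 1]), best_rise


def internal_wnt_summary(base_seed: int, n_seeds: int = 1,
                         rho: float = 0.1, sigma: float = 0.0) -> dict:
    """Emergent-gradient statistics of the division-based Wnt crypt."""
    profs, wnts = [], []
    for k in range(n_seeds):
        tr = run_internal_wnt_crypt(rho, sigma, int(base_seed) * 1000 + k)
        profs.append(_mi_profile(tr, BURN_IN_MI))
        wnts.append(wnt_profile(tr, CRYPT_HEIGHT, n_bins=N_BINS,
                                burn_in=BURN_IN_MI).value)
    mi = np.nanmean(profs, axis=0)
    wnt = np.nanmean(wnts, axis=0)
    dip_height, dip_rise = _dip_feature(mi, rho)
    return {
        "mi_profile": mi,
        "wnt_profile": wnt,
        "dip_height_pct": dip_height,
        "dip_rise": dip_rise,
        "max_wnt_slope": float(np.nanmax(-np.diff(wnt))),
    }


def washout_trend(base_seed: int, n_runs: int = 4,
                  theta_W: float = 1.0,
                  thresholds=(0.6, 0.9),
                  t_max: float = 150.0) -> dict:
    """Reduced mutant-invasion ensembles across CI thresholds.

    Full washout/takeover fixation takes many hundreds of simulated
    hours per run; at this reduced scale the directional claim — a
    higher CI threshold favours the mutant — is measured through the
    mutant lineage's expansion.  Each paired run (matched seeds across
    conditions, 6x8 crypt) relaxes a wild-type crypt, introduces one
    basal APC double mutant and reports the mutant cell fraction after
    ``t_max`` hours together with any fixation events.
    """
    out = {}
    for theta_CI in thresholds:
        fractions, outcomes = [], []
        for k in range(n_runs):
            seed = int((base_seed * 100_003 + k) % (2**31 - 1))
            cfg = EngineConfig(domain=CryptDomain(width=6.0, height=8.0),
                               wnt=WntConfig(mode="M_E1",
                                             theta_W=theta_W),
                               theta_CI=theta_CI, t_max=t_max, seed=seed)
            sim = CryptSimulation(cfg)
            sim.run(t_end=15.0)
            sim.introduce_mutant()
            outcome = sim.run(t_end=15.0 + t_max, stop_on_fixation=True)
            outcomes.append(outcome)
            fractions.append(float(sim.mutant.mean())
                             if sim.n_cells else 0.0)
        out[theta_CI] = {"outcomes": outcomes,
                         "mutant_fractions": fractions,
                         "mean_mutant_fraction": float(np.mean(fractions))}
    return out
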