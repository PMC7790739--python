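"""Spatial and ensemble statistics of crypt simulations.

Profiles bin cells by height fraction (20 bins by default, matching the
resolution of the reported spatial curves) and average over all
snapshots after a burn-in period.  The washout probability of mutant
ensembles carries a normal-approximation 95% binomial confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import TIMEOUT, WASHOUT
from .cell_cycle import Phase

__all__ = [
    "Z_975",
    "Profile",
    "WashoutResult",
    "mitotic_index_profile",
    "velocity_profile",
    "wnt_profile",
    "washout_probability",
    "relative_change",
    "mean_crypt_speed",
    "cell_speeds",
]

#: 97.5 percentile of the standard normal distribution
Z_975 = 1.959964


@dataclass
class Profile:
    """Binned spatial statistic along the crypt axis.

    ``value`` is NaN for empty bins (undefined, not zero); ``lower`` /
    ``upper`` hold the dispersion band (mean +- sd, or quartiles for
    order-statistic profiles); ``vmin`` / ``vmax`` the most extreme
    values seen per bin.
    """

    edges: np.ndarray          # bin edges, height fractions of H
    value: np.ndarray          # central value per bin
    lower: np.ndarray
    upper: np.ndarray
    n: np.ndarray              # observations per bin
    vmin: np.ndarray | None = None
    vmax: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        d = {"bin_low": self.edges[:-1], "bin_high": self.edges[1:],
             "value": self.value, "lower": self.lower, "upper": self.upper,
             "n": self.n}
        if self.vmin is not None:
            d["min"], d["max"] = self.vmin, self.vmax
        return pd.DataFrame(d)


@dataclass
class WashoutResult:
    """Washout probability with normal-approximation 95% CI.

    ``p = k/n`` with half-width ``z_0.975 * sqrt(p (1-p) / n)``, clipped
    to [0, 1]; timeouts are excluded from the denominator and reported
    separately.
    """

    k: int
    n: int
    p: float
    ci_low: float
    ci_high: float
    n_timeout: int = 0
    z: float = Z_975

    def as_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "p": self.p,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_timeout": self.n_timeout, "z": self.z}


def _binned(tr: pd.DataFrame, crypt_height: float, n_bins: int,
            burn_in: float) -> tuple[pd.DataFrame, np.ndarray]:
    post = tr[tr["t"] >= burn_in].copy()
    if post.empty:
        raise ValueError("no snapshots after burn-in")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h = np.clip(post["y"].to_numpy() / crypt_height, 0.0, 1.0)
    post["hbin"] = np.minimum(np.searchsorted(edges, h, side="right") - 1,
                              n_bins - 1)
    return post, edges


def mitotic_index_profile(tr: pd.DataFrame, crypt_height: float,
                          n_bins: int = 20,
                          burn_in: float = 10.0) -> Profile:
    """Time-averaged fraction of cells in M phase per height bin."""
    post, edges = _binned(tr, crypt_height, n_bins, burn_in)
    in_m = (post["phase"] == int(Phase.M)).astype(float)
    g = in_m.groupby(post["hbin"])
    idx = np.arange(n_bins)
    n = g.count().reindex(idx, fill_value=0).to_numpy()
    mean = g.mean().reindex(idx).to_numpy()
    sd = g.std(ddof=0).reindex(idx).to_numpy()
    return Profile(edges=edges, value=mean, lower=mean - sd,
                   upper=mean + sd, n=n)


def cell_speeds(tr: pd.DataFrame, crypt_width: float,
                burn_in: float = 10.0, lag: int = 1) -> pd.DataFrame:
    """Per-cell speeds between snapshot pairs ``lag`` apart.

    Displacements are minimum-image in x; a cell contributes one speed
    per pair of snapshots in which it appears.  Returns columns
    ``t, id, y, speed``.
    """
    post = tr[tr["t"] >= burn_in]
    groups = [(t, g) for t, g in post.groupby("t")]
    if len(groups) < lag + 1:
        raise ValueError("need at least two snapshots after burn-in")
    out = []
    for (t0, g0), (t1, g1) in zip(groups[:-lag], groups[lag:]):
        m = g0[["id", "x", "y"]].merge(g1[["id", "x", "y"]], on="id",
                                       suffixes=("0", "1"))
        dx = m["x1"] - m["x0"]
        dx = dx - crypt_width * np.round(dx / crypt_width)
        speed = np.hypot(dx, m["y1"] - m["y0"]) / (t1 - t0)
        out.append(pd.DataFrame({"t": t0, "id": m["id"],
                                 "y": m["y0"], "speed": speed}))
    return pd.concat(out, ignore_index=True)


def velocity_profile(tr: pd.DataFrame, crypt_width: float,
                     crypt_height: float, n_bins: int = 20,
                     burn_in: float = 10.0, lag: int = 1) -> Profile:
    """Per-bin speed distribution: median, quartiles and extremes.

    Quartiles use linear interpolation between order statistics (numpy
    default convention).
    """
    sp = cell_speeds(tr, crypt_width, burn_in=burn_in, lag=lag)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h = np.clip(sp["y"].to_numpy() / crypt_height, 0.0, 1.0)
    bins = np.minimum(np.searchsorted(edges, h, side="right") - 1,
                      n_bins - 1)
    idx = np.arange(n_bins)
    med = np.full(n_bins, np.nan)
    q1 = np.full(n_bins, np.nan)
    q3 = np.full(n_bins, np.nan)
    vmin = np.full(n_bins, np.nan)
    vmax = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in idx:
        vals = sp["speed"].to_numpy()[bins == b]
        n[b] = len(vals)
        if len(vals):
            q1[b], med[b], q3[b] = np.percentile(vals, [25, 50, 75])
            vmin[b], vmax[b] = vals.min(), vals.max()
    return Profile(edges=edges, value=med, lower=q1, upper=q3, n=n,
                   vmin=vmin, vmax=vmax)


def wnt_profile(tr: pd.DataFrame, crypt_height: float, n_bins: int = 20,
                burn_in: float = 10.0) -> Profile:
    """Per-bin mean and standard deviation of the cellular Wnt level."""
    post, edges = _binned(tr, crypt_height, n_bins, burn_in)
    g = post["W"].groupby(post["hbin"])
    idx = np.arange(n_bins)
    n = g.count().reindex(idx, fill_value=0).to_numpy()
    mean = g.mean().reindex(idx).to_numpy()
    sd = g.std(ddof=0).reindex(idx).to_numpy()
    return Profile(edges=edges, value=mean, lower=mean - sd,
                   upper=mean + sd, n=n)


def mean_crypt_speed(tr: pd.DataFrame, crypt_width: float,
                     burn_in: float = 10.0, lag: int = 1) -> float:
    """Mean per-cell speed over all cells and post-burn-in snapshots."""
    return float(cell_speeds(tr, crypt_width, burn_in=burn_in,
                             lag=lag)["speed"].mean())


def washout_probability(outcomes: list[str]) -> WashoutResult:
    """Washout probability of an ensemble with binomial 95% CI.

    Timeout runs are excluded from the denominator and counted
    separately.
    """
    n_timeout = sum(1 for o in outcomes if o == TIMEOUT)
    valid = [o for o in outcomes if o != TIMEOUT]
    n = len(valid)
    if n == 0:
        raise ValueError("no valid (non-timeout) outcomes")
    k = sum(1 for o in valid if o == WASHOUT)
    p = k / n
    half = Z_975 * np.sqrt(p * (1.0 - p) / n)
    return WashoutResult(k=k, n=n, p=p,
                         ci_low=max(0.0, p - half),
                         ci_high=min(1.0, p + half),
                         n_timeout=n_timeout)


def relative_change(a: float, b: float) -> float:
    """Percent reduction from ``a`` to ``b``: ``100 (a - b) / a``."""
    if a == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (a - b) / a
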