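"""The three Wnt-propagation models of the crypt.

* ``M_E1`` — externally imposed linear gradient, read once at birth
  (static): a cell keeps the Wnt level of its birth position for life.
* ``M_E2`` — the same imposed gradient, read continuously (dynamic):
  a cell's Wnt level tracks its current height.
* ``M_I``  — division-based internal Wnt: each cell carries its own Wnt
  level; on division the mother's level is split between the daughters
  in proportions ``0.5 + xi`` and ``0.5 - xi`` with ``xi`` a zero-mean
  Gaussian of standard deviation ``sigma`` (rejection-truncated so the
  proportion stays in [0, 1], preserving the zero-mean symmetry).
  Cells inside a basal reservoir (bottom fraction ``rho`` of the crypt)
  are refreshed to the maximal level each step; there is no diffusion
  between cells.

The imposed gradient is ``W(h) = W_max * max(0, 1 - h / theta_W)`` in
the height fraction ``h``, maximal at the base and zero at and above
the gradient extent ``theta_W``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["WntMode", "WntConfig", "external_wnt", "cell_wnt",
           "divide_wnt", "apply_reservoir"]


class WntMode(str, enum.Enum):
    ME1 = "M_E1"   # imposed gradient, read at birth
    ME2 = "M_E2"   # imposed gradient, continuously updated
    MI = "M_I"     # internal, division-based


@dataclass
class WntConfig:
    """Wnt model selector and parameters."""

    mode: WntMode = WntMode.ME1
    theta_W: float = 1.0   # gradient extent, fraction of crypt height
    rho: float = 0.1       # reservoir height fraction (M_I)
    sigma: float = 0.0     # division-noise standard deviation (M_I)
    W_max: float = 1.0     # maximal Wnt level

    def __post_init__(self) -> None:
        self.mode = WntMode(self.mode)
        if not 0.0 < self.theta_W <= 1.0:
            raise ValueError("theta_W must lie in (0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.W_max <= 0:
            raise ValueError("W_max must be > 0")


def external_wnt(h, cfg: WntConfig):
    """Imposed Wnt level at height fraction ``h`` of the crypt.

    Linear, decreasing, maximal at the base and zero at and above the
    gradient extent ``theta_W``.  ``h`` may be an array.
    """
    if cfg.mode not in (WntMode.ME1, WntMode.ME2):
        raise ValueError("external_wnt applies to the imposed-gradient modes")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("height fraction must lie in [0, 1]")
    w = cfg.W_max * np.maximum(0.0, 1.0 - h / cfg.theta_W)
    return float(w) if w.ndim == 0 else w


def cell_wnt(birth_W, internal_W, h, cfg: WntConfig):
    """Wnt level the signalling module sees this step.

    ``birth_W`` is the level stored at birth (M_E1 semantics),
    ``internal_W`` the cell's carried level (M_I), ``h`` the current
    height fraction (M_E2).  Arguments may be arrays.
    """
    if cfg.mode == WntMode.ME1:
        return birth_W
    if cfg.mode == WntMode.ME2:
        return external_wnt(h, cfg)
    return internal_W


def divide_wnt(W_mother: float, sigma: float, rng: np.random.Generator):
    """Split a mother's Wnt level between two daughters.

    The first daughter receives the proportion ``f = 0.5 + xi`` with
    ``xi ~ N(0, sigma)``, redrawn until ``f`` lies in [0, 1] (rejection
    rather than clipping keeps the split symmetric around one half).
    The two daughter levels sum to the mother's level exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if W_mother < 0:
        raise ValueError("W_mother must be >= 0")
    if sigma == 0:
        f = 0.5
    else:
        while True:
            f = 0.5 + rng.normal(0.0, sigma)
            if 0.0 <= f <= 1.0:
                break
    W1 = f * W_mother
    return W1, W_mother - W1


def apply_reservoir(W, heights, cfg: WntConfig, crypt_height: float):
    """Refresh the basal Wnt reservoir (M_I only).

    Cells whose centre height is at or below ``rho * crypt_height`` are
    set to the maximal level; all other levels are untouched.  Returns a
    new array.
    """
    if cfg.mode != WntMode.MI:
        raise ValueError("apply_reservoir applies to the M_I mode")
    W = np.array(W, dtype=float, copy=True)
    in_res = np.asarray(heights, dtype=float) <= cfg.rho * crypt_height
    W[in_res] = cfg.W_max
    return W
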