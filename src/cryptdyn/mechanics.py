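"""Cell-centre mechanics on the unrolled periodic crypt surface.

The cylindrical crypt is unrolled to a planar band, periodic in ``x``
(circumference ``width``) and bounded in ``y`` (the crypt axis, base at
``y = 0``).  Each cell is a point connected to its Voronoi neighbours by
linear springs; motion is overdamped.  Cell "volumes" are the areas of
the Voronoi regions, computed with periodic images in ``x`` and mirror
images across the bottom (``y = 0``) and a clipping plane half a cell
diameter above the crypt top, so every cell has a finite area and the
areas exactly partition the band.

Lengths are in cell diameters, time in hours, forces in units of
(spring stiffness x cell diameter).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "CryptDomain",
    "MechParams",
    "CellGeometry",
    "tessellate",
    "neighbour_graph",
    "cell_volumes",
    "spring_forces",
    "step_positions",
    "cell_velocity",
]


@dataclass
class CryptDomain:
    """Unrolled crypt geometry: ``x`` periodic with period ``width``."""

    width: float = 16.0      # circumference, cell diameters
    height: float = 20.0     # crypt height, cell diameters
    clip_pad: float = 0.5    # Voronoi clipping margin above the top

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be > 0")

    @property
    def y_clip(self) -> float:
        return self.height + self.clip_pad

    def wrap_x(self, x):
        return np.mod(x, self.width)

    def min_image_dx(self, dx):
        """Wrap an x-displacement into (-width/2, width/2]."""
        return dx - self.width * np.round(dx / self.width)


@dataclass
class MechParams:
    """Spring/drag parameters of the overdamped cell-centre model."""

    mu: float = 15.0             # spring stiffness (force / diameter)
    eta: float = 1.0             # drag coefficient
    rest_length: float = 1.0     # mature spring rest length (diameters)
    newborn_rest_length: float = 0.1
    maturation_time: float = 1.0  # h over which rest length grows to mature
    dt: float = 1.0 / 120.0       # mechanics time step (h)
    cutoff: float = 1.5           # neighbour interaction cutoff (diameters)

    def __post_init__(self) -> None:
        if min(self.mu, self.eta, self.dt) <= 0:
            raise ValueError("mu, eta and dt must be > 0")
        if not 0 < self.newborn_rest_length < self.rest_length:
            raise ValueError("newborn rest length must be in (0, rest_length)")
        if self.dt > self.eta / (4.0 * self.mu):
            raise ValueError(
                f"dt={self.dt} exceeds stability bound eta/(4 mu) = "
                f"{self.eta / (4 * self.mu):.4g}")


@dataclass
class CellGeometry:
    """Per-cell geometric record."""

    position: tuple[float, float]
    volume: float = float("nan")
    volume_eq: float = np.sqrt(3.0) / 2.0  # hexagonal-packing area
    neighbours: list = field(default_factory=list)


def _extended_points(positions: np.ndarray, domain: CryptDomain,
                     pad: float | None = None,
                     mirror_pad: float | None = None):
    """Original points plus periodic x-images and y-mirror ghosts.

    Returns ``(points, owner)`` where ``owner[k]`` is the original cell
    index for periodic images and ``-1`` for mirror ghosts (mirrors
    implement clipping walls and are never neighbours).  Ghost strips
    scale with the typical point spacing so sparse configurations keep
    exact, translation-consistent boundary regions.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    spacing = math.sqrt(domain.width * domain.y_clip / max(n, 1))
    if pad is None:
        pad = max(3.0, 3.5 * spacing)
    if mirror_pad is None:
        mirror_pad = max(5.0, 6.0 * spacing)
    pts = [pos]
    owner = [np.arange(n)]

    def add(p, o):
        if len(p):
            pts.append(p)
            owner.append(o)

    # periodic x images (full copies keep the logic simple; pruned by pad)
    for shift in (-domain.width, domain.width):
        shifted = pos + np.array([shift, 0.0])
        keep = (shifted[:, 0] > -pad) & (shifted[:, 0] < domain.width + pad)
        add(shifted[keep], np.arange(n)[keep])

    base = np.vstack(pts)
    # mirror points near the walls across y = 0 and y = y_clip (wall
    # ghosts); the bottom wall is offset by an epsilon so cells sitting
    # exactly on y = 0 do not coincide with their own mirror image
    for y_wall in (-1e-6, domain.y_clip):
        near = np.abs(base[:, 1] - y_wall) < mirror_pad
        mirrored = base[near].copy()
        mirrored[:, 1] = 2.0 * y_wall - mirrored[:, 1]
        add(mirrored, np.full(len(mirrored), -1))

    return np.vstack(pts), np.concatenate(owner)


def tessellate(positions: np.ndarray, domain: CryptDomain,
               cutoff: float | None = None):
    """Periodic Voronoi tessellation of the band.

    Returns ``(edges, areas)``: a symmetric, deduplicated (i < j) array
    of Delaunay-adjacent cell pairs (periodicity-aware, pruned at
    ``cutoff``) and the clipped Voronoi area of every cell.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 3:
        raise ValueError("tessellation requires at least 3 cells")
    pts, owner = _extended_points(pos, domain)
    try:
        vor = Voronoi(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate cell configuration: {exc}") from exc

    n = len(pos)
    # area of a (convex) Voronoi cell = sum of triangles spanned by the
    # generator point and each ridge's two vertices — vectorised over
    # all ridges instead of looping over ragged region lists
    ridge = vor.ridge_points
    rv = np.asarray(vor.ridge_vertices)
    finite = (rv >= 0).all(axis=1)
    if np.any((ridge[~finite] < n)):
        raise ValueError(
            "unbounded Voronoi region for a cell; point set too sparse "
            "for the clipping ghosts")
    areas = np.zeros(n)
    for side in (0, 1):
        sel = finite & (ridge[:, side] < n)
        idx = ridge[sel, side]
        p = pts[idx]
        v1 = vor.vertices[rv[sel, 0]] - p
        v2 = vor.vertices[rv[sel, 1]] - p
        contrib = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
        areas += np.bincount(idx, weights=contrib, minlength=n)
    a, b = owner[ridge[:, 0]], owner[ridge[:, 1]]
    # keep ridges between real cells where at least one endpoint is an
    # original (unshifted) point, so each physical contact appears once
    primary = (ridge < n).any(axis=1)
    valid = (a >= 0) & (b >= 0) & (a != b) & primary
    e = np.sort(np.stack([a[valid], b[valid]], axis=1), axis=1)
    e = np.unique(e, axis=0)

    if cutoff is not None and len(e):
        d = pos[e[:, 1]] - pos[e[:, 0]]
        d[:, 0] = domain.min_image_dx(d[:, 0])
        e = e[np.hypot(d[:, 0], d[:, 1]) <= cutoff]
    return e, areas


def neighbour_graph(positions: np.ndarray, domain: CryptDomain,
                    cutoff: float = 1.5) -> np.ndarray:
    """Delaunay-adjacent cell pairs with periodic x-wrapping."""
    edges, _ = tessellate(positions, domain, cutoff=cutoff)
    return edges


def cell_volumes(positions: np.ndarray, domain: CryptDomain) -> np.ndarray:
    """Clipped Voronoi area ('volume') of every cell."""
    _, areas = tessellate(positions, domain, cutoff=None)
    return areas


def spring_forces(positions: np.ndarray, edges: np.ndarray,
                  rest_lengths, mu: float,
                  domain: CryptDomain | None = None) -> np.ndarray:
    """Linear spring force on each cell along pair separations.

    ``rest_lengths`` is scalar or per-edge.  Forces on the two endpoints
    of every edge are equal and opposite (overlapping pairs repel,
    stretched pairs attract).  If ``domain`` is given, separations use
    the minimum image in x.
    """
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    if len(edges) == 0:
        return forces
    edges = np.asarray(edges)
    rest = np.broadcast_to(np.asarray(rest_lengths, dtype=float),
                           (len(edges),))
    d = pos[edges[:, 1]] - pos[edges[:, 0]]
    if domain is not None:
        d[:, 0] = domain.min_image_dx(d[:, 0])
    sep = np.hypot(d[:, 0], d[:, 1])
    if np.any(sep < 1e-12):
        raise ValueError("coincident cell centres: zero separation on an edge")
    unit = d / sep[:, None]
    f = mu * (sep - rest)[:, None] * unit  # on edge[:,0], toward j if stretched
    np.add.at(forces, edges[:, 0], f)
    np.add.at(forces, edges[:, 1], -f)
    return forces


def step_positions(positions: np.ndarray, forces: np.ndarray,
                   eta: float, dt: float,
                   domain: CryptDomain) -> np.ndarray:
    """Overdamped update ``dr = (F/eta) dt``; x wrapped, base clamped."""
    disp = forces / eta * dt
    if np.any(np.hypot(disp[:, 0], disp[:, 1]) > 1.0):
        raise RuntimeError(
            "mechanical instability: displacement exceeds one cell "
            "diameter in a single step")
    new = np.asarray(positions, dtype=float) + disp
    new[:, 0] = domain.wrap_x(new[:, 0])
    new[:, 1] = np.maximum(new[:, 1], 0.0)  # cells cannot leave through the base
    return new


def cell_velocity(history: np.ndarray, times: np.ndarray,
                  domain: CryptDomain) -> float:
    """Speed (diameters/h) from a position history over a window.

    ``history`` is (k, 2) with k >= 2 samples at ``times``; the net
    displacement uses the minimum image in x.
    """
    history = np.asarray(history, dtype=float)
    times = np.asarray(times, dtype=float)
    if history.ndim != 2 or len(history) < 2:
        raise ValueError("velocity window needs at least 2 samples")
    dx = domain.min_image_dx(history[-1, 0] - history[0, 0])
    dy = history[-1, 1] - history[0, 1]
    return float(np.hypot(dx, dy) / (times[-1] - times[0]))
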