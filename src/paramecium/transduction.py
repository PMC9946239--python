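"""Sensory transduction: stimulus geometry to membrane current.

For sharply bounded objects (half-plane, disc) the drive is
``s = I0 * p`` where ``p`` is the fraction of the cell outline's area inside
the object.  The cell outline is an asymmetric ellipse (length a = 120 um,
width b = 35 um, bend factor beta = 0.15): the half-width profile
``(b/2) sqrt(1 - 4x^2/a^2)`` of both edges is offset by
``-beta (b/2) sin(2 pi x / a)``, a ventral bend that leaves the area
pi a b / 4 unchanged.  Overlap is computed by exact polygon intersection
(shapely) of the sampled outline with the stimulus shape; the ``resolution``
parameter sets the boundary sampling density (um per vertex step).

For spatially continuous stimuli (linear gradient, sampled grid field) the
drive is simply the field value at the cell center (bilinear interpolation
on grids).

Three receptor models convert the drive s(t) into a current:

* instantaneous: I = s
* delayed:       tau_I dI/dt = s - I   (first-order channel kinetics)
* adapting:      two pathways of opposite polarity,
                 tau_fast dIfast/dt = s - Ifast (hyperpolarizing),
                 tau_slow dIslow/dt = s - Islow (depolarizing),
                 I = Islow - Ifast  (stationary response to constant s is 0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point, Polygon, box

__all__ = ["CellOutline", "HalfPlane", "Disc", "LinearGradient", "GridField",
           "cell_outline", "cell_polygon", "overlap_fraction",
           "TransductionParams", "Transducer"]


@dataclass
class CellOutline:
    """Cell silhouette parameters (um)."""
    a: float = 120.0     # length
    b: float = 35.0      # width
    beta: float = 0.15   # asymmetry (bend) factor


def cell_outline(outline: CellOutline, n: int = 100) -> np.ndarray:
    """Closed outline polygon in the body frame, (2n, 2) array (um).

    Column 0 is the major-axis coordinate (anterior at +a/2), column 1 the
    lateral coordinate.  The tips close exactly: y(+-a/2) = 0.
    """
    x = np.linspace(-outline.a / 2.0, outline.a / 2.0, n)
    half = (outline.b / 2.0) * np.sqrt(
        np.maximum(0.0, 1.0 - 4.0 * x ** 2 / outline.a ** 2))
    bend = -outline.beta * (outline.b / 2.0) * np.sin(
        2.0 * math.pi * x / outline.a)
    upper = np.stack([x, bend + half], axis=1)
    lower = np.stack([x[::-1], (bend - half)[::-1]], axis=1)
    return np.vstack([upper, lower])


def cell_polygon(center, gamma_deg: float, outline: CellOutline,
                 n: int = 100) -> Polygon:
    """World-frame cell polygon for a planar pose.

    ``gamma_deg`` is the in-plane heading of the anterior axis; the body
    major axis maps onto it.
    """
    pts = cell_outline(outline, n)
    g = math.radians(gamma_deg)
    rot = np.array([[math.cos(g), -math.sin(g)],
                    [math.sin(g), math.cos(g)]])
    world = pts @ rot.T + np.asarray(center, float)[:2]
    return Polygon(world)


# --------------------------------------------------------------------------
# stimulus geometries
# --------------------------------------------------------------------------

@dataclass
class HalfPlane:
    """Region ``n . (r - r0) >= 0`` with unit in-plane normal n."""
    normal: tuple = (1.0, 0.0)
    point: tuple = (0.0, 0.0)

    def signed_distance(self, xy) -> np.ndarray:
        xy = np.asarray(xy, float)
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        return (xy[..., :2] - np.asarray(self.point, float)) @ n

    def shape(self, around, extent: float = 2000.0):
        """Shapely half-plane clipped to a large box around ``around`` (um)."""
        cx, cy = float(around[0]), float(around[1])
        big = box(cx - extent, cy - extent, cx + extent, cy + extent)
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        t = np.array([-n[1], n[0]])
        p0 = np.asarray(self.point, float)
        L = 4.0 * extent
        quad = Polygon([p0 + t * L, p0 - t * L,
                        p0 - t * L + n * L, p0 + t * L + n * L])
        return big.intersection(quad)


@dataclass
class Disc:
    """Disc of given center and radius (um)."""
    center: tuple = (0.0, 0.0)
    radius: float = 1000.0

    def signed_distance(self, xy) -> np.ndarray:
        """Positive inside, negative outside (distance to the boundary)."""
        xy = np.asarray(xy, float)
        d = np.linalg.norm(xy[..., :2] - np.asarray(self.center, float),
                           axis=-1)
        return self.radius - d

    def shape(self, around=None, resolution: float = 2.0):
        n_seg = max(64, int(math.pi * self.radius / resolution))
        return Point(*self.center).buffer(self.radius, quad_segs=n_seg // 4)


@dataclass
class LinearGradient:
    """Continuous linear drive field: value (nA) at the cell center.

    ``slope`` in pA/mm along ``direction``; zero at ``origin``.
    """
    slope: float = 100.0           # pA/mm
    direction: tuple = (1.0, 0.0)
    origin: tuple = (0.0, 0.0)

    def value(self, xy) -> np.ndarray:
        xy = np.asarray(xy, float)
        d = np.asarray(self.direction, float)
        d = d / np.linalg.norm(d)
        dist_mm = ((xy[..., :2] - np.asarray(self.origin, float)) @ d) * 1e-3
        return self.slope * dist_mm * 1e-3      # pA -> nA


@dataclass
class GridField:
    """Sampled 2-D drive field (nA per pixel value), bilinear interpolation.

    ``grid[i, j]`` is the value at ``(x0 + j dx, y0 + i dx)`` (um).
    Periodic in both axes (toric arenas).
    """
    grid: np.ndarray
    dx: float = 20.0               # um
    origin: tuple = (0.0, 0.0)

    def value(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))[:, :2]
        ny, nx = self.grid.shape
        fx = (xy[:, 0] - self.origin[0]) / self.dx
        fy = (xy[:, 1] - self.origin[1]) / self.dx
        i0 = np.floor(fy).astype(int)
        j0 = np.floor(fx).astype(int)
        ty = fy - i0
        tx = fx - j0
        i0 %= ny
        j0 %= nx
        i1 = (i0 + 1) % ny
        j1 = (j0 + 1) % nx
        g = self.grid
        out = (g[i0, j0] * (1 - ty) * (1 - tx) + g[i0, j1] * (1 - ty) * tx
               + g[i1, j0] * ty * (1 - tx) + g[i1, j1] * ty * tx)
        return out if out.size > 1 else float(out[0])


def overlap_fraction(center, gamma_deg: float, outline: CellOutline,
                     geometry, resolution: float = 2.0,
                     shape=None) -> float:
    """Fraction of the cell area inside the stimulus region, in [0, 1].

    ``resolution`` (um) sets the vertex sampling of both the cell outline
    and curved stimulus boundaries; halving it changes the result by much
    less than 0.5% for the default geometries.  A prebuilt shapely
    ``shape`` may be passed to avoid rebuilding the stimulus polygon.
    """
    n = max(16, int(2.0 * outline.a / resolution))
    cell = cell_polygon(center, gamma_deg, outline, n=n)
    if shape is None:
        if isinstance(geometry, Disc):
            shape = geometry.shape(resolution=resolution)
        else:
            shape = geometry.shape(around=np.asarray(center, float))
    inter = cell.intersection(shape)
    return float(inter.area / cell.area)


# --------------------------------------------------------------------------
# receptor kinetics
# --------------------------------------------------------------------------

@dataclass
class TransductionParams:
    kind: str = "instantaneous"    # instantaneous | delayed | adapting
    I0: float = 5.0                # nA, maximum current
    tau_I: float = 40.0            # ms, delayed variant
    tau_fast: float = 40.0         # ms, adapting fast (hyperpolarizing)
    tau_slow: float = 200.0        # ms, adapting slow (depolarizing)
    sign: float = 1.0              # +1 depolarizing drive, -1 hyperpolarizing

    def validate(self) -> None:
        if self.kind not in ("instantaneous", "delayed", "adapting"):
            raise ValueError(f"unknown transduction kind {self.kind!r}")
        if min(self.tau_I, self.tau_fast, self.tau_slow) <= 0:
            raise ValueError("transduction time constants must be > 0")


class Transducer:
    """Stateful stimulus-to-current converter (scalar or vectorized).

    ``step(s, dt)`` takes the drive ``s = I0 * p`` (nA) and returns the
    transduction current after one exact first-order update over dt (ms).
    """

    def __init__(self, params: TransductionParams, n: Optional[int] = None):
        params.validate()
        self.params = params
        shape = () if n is None else (n,)
        self.I = np.zeros(shape)
        self.I_fast = np.zeros(shape)
        self.I_slow = np.zeros(shape)

    def step(self, s, dt: float):
        p = self.params
        s = np.asarray(s, float) * p.sign
        if p.kind == "instantaneous":
            self.I = s
        elif p.kind == "delayed":
            k = -math.expm1(-dt / p.tau_I)
            self.I = self.I + (s - self.I) * k
        else:
            kf = -math.expm1(-dt / p.tau_fast)
            ks = -math.expm1(-dt / p.tau_slow)
            self.I_fast = self.I_fast + (s - self.I_fast) * kf
            self.I_slow = self.I_slow + (s - self.I_slow) * ks
            self.I = self.I_slow - self.I_fast
        return self.I
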