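"""Spherical hydrodynamic analysis of ciliary beating patterns.

The cell is idealized as a sphere of radius 60 um at low Reynolds number.
Each surface patch experiences a force from the fluid, opposite to the local
ciliary beating direction, tangent to the sphere, with uniform magnitude A
per unit area and local angle ``alpha`` measured from the south-pointing
meridian (alpha = 0: force toward the posterior pole).  In spherical
coordinates (theta from the anterior pole, phi from the oral meridian) the
local force in Cartesian body coordinates is

    F = A (cos th cos a cos ph - sin a sin ph,
           cos th cos a sin ph + sin a cos ph,
           -sin th cos a)

and the local torque is ``r x F``.  Total force and torque follow by
per-region surface quadrature (Gauss-Legendre nodes with the sin(theta)
area weight); for a sphere the mobility matrix is diagonal, so

    U = F_tot / (6 pi eta r),     Omega = tau_tot / (8 pi eta r^3).

Closed forms used as oracles: a uniform pattern gives
``F_z = -pi^2 A r^2 cos a`` and ``tau_z = pi^2 A r^3 sin a``; an anterior
quarter (theta in [0, pi/2], phi in [0, pi]) gives
``F = A r^2 (-2 sin a, cos a, -(pi^2/4) cos a)`` and
``tau = A r^3 (-2 cos a, -sin a, (pi^2/4) sin a)``.

This module is analysis-only: the swimming simulator couples calcium to
kinematics directly and does not call it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = ["SphereModel", "Region", "BeatingPattern", "local_force",
           "local_torque", "surface_wrench", "uniform_wrench",
           "quarter_wrench", "motion_from_wrench", "calibrate_amplitude",
           "pattern_kinematics", "forward_pattern", "backward_pattern",
           "turning_pattern"]


@dataclass
class SphereModel:
    """Sphere radius (um), fluid viscosity (Pa s) and local force amplitude.

    ``A`` is the force per unit area in N/m^2; tilt angles and spin ratios
    are independent of A and eta (Stokes linearity), only absolute speeds
    depend on them.
    """
    r: float = 60.0          # um
    eta: float = 1e-3        # Pa s (water)
    A: float = 1.0           # N/m^2

    @property
    def r_m(self) -> float:
        return self.r * 1e-6


@dataclass
class Region:
    """Spherical rectangle [theta0, theta1] x [phi0, phi1] with force angle."""
    theta: Tuple[float, float]   # rad, 0 = anterior pole
    phi: Tuple[float, float]     # rad, 0 = oral meridian
    alpha: float                 # deg, local force angle


@dataclass
class BeatingPattern:
    """Piecewise-constant local force angle over sphere regions."""
    regions: List[Region]
    name: str = ""

    def validate(self) -> "BeatingPattern":
        """Check the regions tile the sphere (area sums to 4 pi)."""
        area = sum((math.cos(rg.theta[0]) - math.cos(rg.theta[1]))
                   * (rg.phi[1] - rg.phi[0]) for rg in self.regions)
        if abs(area - 4.0 * math.pi) > 1e-9:
            raise ValueError(
                f"pattern regions cover area {area:.6f}, expected 4*pi")
        return self


def forward_pattern() -> BeatingPattern:
    """Uniform alpha = -170 deg: beating to the rear, 10 deg to the right."""
    return BeatingPattern(
        [Region((0.0, math.pi), (-math.pi, math.pi), -170.0)],
        name="forward").validate()


def backward_pattern() -> BeatingPattern:
    """Uniform alpha = -10 deg (global ciliary reversal)."""
    return BeatingPattern(
        [Region((0.0, math.pi), (-math.pi, math.pi), -10.0)],
        name="backward").validate()


def turning_pattern() -> BeatingPattern:
    """Swirl around the oral groove: left-anterior forward (-170 deg),
    right-anterior reversed (-10 deg), posterior half to the left (-90 deg)."""
    h = math.pi / 2.0
    return BeatingPattern([
        Region((0.0, h), (-math.pi, 0.0), -170.0),
        Region((0.0, h), (0.0, math.pi), -10.0),
        Region((h, math.pi), (-math.pi, math.pi), -90.0),
    ], name="turning").validate()


def local_force(theta, phi, alpha_deg: float, A: float = 1.0) -> np.ndarray:
    """Local force per unit area in Cartesian body coordinates (…, 3)."""
    a = math.radians(alpha_deg)
    th = np.asarray(theta, float)
    ph = np.asarray(phi, float)
    return A * np.stack([
        np.cos(th) * math.cos(a) * np.cos(ph) - math.sin(a) * np.sin(ph),
        np.cos(th) * math.cos(a) * np.sin(ph) + math.sin(a) * np.cos(ph),
        -np.sin(th) * math.cos(a) * np.ones_like(ph),
    ], axis=-1)


def local_torque(theta, phi, alpha_deg: float, r: float = 1.0,
                 A: float = 1.0) -> np.ndarray:
    """Local torque density r x F in Cartesian body coordinates (…, 3)."""
    a = math.radians(alpha_deg)
    th = np.asarray(theta, float)
    ph = np.asarray(phi, float)
    return r * A * np.stack([
        -np.cos(th) * math.sin(a) * np.cos(ph) - math.cos(a) * np.sin(ph),
        -np.cos(th) * math.sin(a) * np.sin(ph) + math.cos(a) * np.cos(ph),
        np.sin(th) * math.sin(a) * np.ones_like(ph),
    ], axis=-1)


def surface_wrench(pattern: BeatingPattern, sphere: SphereModel,
                   n_quad: int = 512):
    """Total force (N) and torque (N m) by per-region quadrature.

    ``n_quad`` Gauss-Legendre nodes per dimension and per region (alpha is
    piecewise constant on the regions, so every node lies strictly inside a
    constant patch and the smooth trigonometric integrands converge to the
    closed forms to machine precision).
    """
    if n_quad < 64:
        raise ValueError("n_quad must be >= 64 points per dimension")
    x, wx = np.polynomial.legendre.leggauss(n_quad)
    r = sphere.r_m
    F = np.zeros(3)
    tau = np.zeros(3)
    for rg in pattern.regions:
        th0, th1 = rg.theta
        ph0, ph1 = rg.phi
        thm = 0.5 * (th1 - th0) * x + 0.5 * (th1 + th0)
        phm = 0.5 * (ph1 - ph0) * x + 0.5 * (ph1 + ph0)
        wth = 0.5 * (th1 - th0) * wx
        wph = 0.5 * (ph1 - ph0) * wx
        TH, PH = np.meshgrid(thm, phm, indexing="ij")
        w = np.sin(TH) * np.outer(wth, wph)
        f = local_force(TH, PH, rg.alpha, sphere.A)
        F += r * r * np.tensordot(w, f, axes=([0, 1], [0, 1]))
        tq = local_torque(TH, PH, rg.alpha, r, sphere.A)
        tau += r * r * np.tensordot(w, tq, axes=([0, 1], [0, 1]))
    return F, tau


def uniform_wrench(alpha_deg: float, sphere: SphereModel):
    """Closed form for a uniform pattern: axial force and torque only."""
    a = math.radians(alpha_deg)
    r = sphere.r_m
    F = np.array([0.0, 0.0, -math.pi ** 2 * sphere.A * r ** 2 * math.cos(a)])
    tau = np.array([0.0, 0.0, math.pi ** 2 * sphere.A * r ** 3 * math.sin(a)])
    return F, tau


def quarter_wrench(alpha_deg: float, sphere: SphereModel, side: str = "right"):
    """Closed form for one anterior quarter (theta in [0, pi/2]).

    ``side='right'`` is phi in [0, pi]; the left quarter flips the signs of
    the sin(phi)-weighted components (F_x, tau_x sign pattern below).
    """
    a = math.radians(alpha_deg)
    r = sphere.r_m
    A = sphere.A
    q = math.pi ** 2 / 4.0
    F = np.array([-2.0 * math.sin(a), math.cos(a), -q * math.cos(a)])
    tau = np.array([-2.0 * math.cos(a), -math.sin(a), q * math.sin(a)])
    if side == "left":
        F = np.array([2.0 * math.sin(a), -math.cos(a), -q * math.cos(a)])
        tau = np.array([2.0 * math.cos(a), math.sin(a), q * math.sin(a)])
    elif side != "right":
        raise ValueError("side must be 'left' or 'right'")
    return A * r * r * F, A * r ** 3 * tau


def motion_from_wrench(F: np.ndarray, tau: np.ndarray, sphere: SphereModel):
    """Diagonal sphere mobility: U = F/(6 pi eta r), Omega = tau/(8 pi eta r^3).

    U in m/s, Omega in rad/s.
    """
    r = sphere.r_m
    U = np.asarray(F, float) / (6.0 * math.pi * sphere.eta * r)
    Om = np.asarray(tau, float) / (8.0 * math.pi * sphere.eta * r ** 3)
    return U, Om


def calibrate_amplitude(sphere: SphereModel, v_target: float = 500.0,
                        n_quad: int = 512) -> float:
    """Force amplitude A (N/m^2) giving forward speed ``v_target`` um/s.

    The same A is reused for every beating pattern.  Raises for a pattern
    with no net force (degenerate calibration).
    """
    probe = SphereModel(r=sphere.r, eta=sphere.eta, A=1.0)
    F, _ = surface_wrench(forward_pattern(), probe, n_quad)
    U, _ = motion_from_wrench(F, np.zeros(3), probe)
    speed = float(np.linalg.norm(U))
    if speed <= 0.0:
        raise ValueError("forward pattern produces no net force")
    return v_target * 1e-6 / speed


def pattern_kinematics(pattern: BeatingPattern, sphere: SphereModel,
                       n_quad: int = 512):
    """Swimming observables of a pattern at a calibrated amplitude.

    Returns a dict with ``v_axial`` and ``speed`` (um/s), ``tilt_deg``
    (undirected angle of the rotation axis to the main axis, in the xz
    plane) and ``spin_hz`` (|Omega|/2pi).
    """
    F, tau = surface_wrench(pattern, sphere, n_quad)
    U, Om = motion_from_wrench(F, tau, sphere)
    tilt = math.degrees(math.atan2(abs(Om[0]), abs(Om[2]))) \
        if np.linalg.norm(Om) > 0 else 0.0
    return {
        "v_axial": U[2] * 1e6,
        "speed": float(np.linalg.norm(U)) * 1e6,
        "tilt_deg": tilt,
        "spin_hz": float(np.linalg.norm(Om)) / (2.0 * math.pi),
        "F": F, "tau": tau, "U": U, "Omega": Om,
    }
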