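"""Electromotor coupling: intraciliary calcium to ciliary kinematics.

Phenomenological instantaneous maps from [Ca2+] (uM) to the ciliary beating
angle, the signed axial swimming velocity, the rotation-axis tilt and the
spinning speed.  The velocity changes sign at the reversal threshold
``Kmotor``; tilt and spin are bells peaking there, log-symmetric in
concentration (f(K x) = f(K/x)).

All Hill/bell forms are evaluated in log-concentration to stay well-behaved
as Ca -> 0.
"""

from __future__ import annotations

import numpy as np

from .constants import CA_REST, LN10
from .params import ElectromotorParams

__all__ = ["cilia_angle", "swim_velocity", "rotation_tilt", "spin_speed",
           "cilia_angle_pca", "swim_velocity_pca", "rotation_tilt_pca",
           "spin_speed_pca"]


def _pca(Ca):
    Ca = np.asarray(Ca, float)
    return np.log10(np.maximum(Ca, 1e-300) / CA_REST)


def _hill_log(pCa, pK, n):
    """1 / (1 + (K/Ca)^n) evaluated as a logistic in pCa."""
    z = n * LN10 * (np.asarray(pCa, float) - pK)
    return 1.0 / (1.0 + np.exp(np.clip(-z, -500.0, 500.0)))


def _bell_log(pCa, pK):
    """2 / ((K/Ca)^2 + (Ca/K)^2) = 1/cosh(2 ln10 (pCa - pK))."""
    z = 2.0 * LN10 * (np.asarray(pCa, float) - pK)
    return 1.0 / np.cosh(np.clip(z, -500.0, 500.0))


def cilia_angle_pca(pCa, p: ElectromotorParams):
    """Ciliary angle (deg, from the anteroposterior axis) at log-calcium."""
    return p.alpha0 + p.dAlpha * _hill_log(pCa, p.pKmotor, p.nmotor)


def swim_velocity_pca(pCa, p: ElectromotorParams):
    """Signed axial velocity (um/s, + forward): -vmax + 2 vmax/(1+(Ca/K)^2)."""
    return -p.vmax + 2.0 * p.vmax * (1.0 - _hill_log(pCa, p.pKmotor, 2.0))


def rotation_tilt_pca(pCa, p: ElectromotorParams):
    """Rotation-axis tilt (deg): bell from thetaMin up to thetaMax at K."""
    return p.thetaMin + (p.thetaMax - p.thetaMin) * _bell_log(pCa, p.pKmotor)


def spin_speed_pca(pCa, p: ElectromotorParams):
    """Spinning speed (rad/s): bell from omegaMin up to omegaMax at K."""
    return p.omegaMin + (p.omegaMax - p.omegaMin) * _bell_log(pCa, p.pKmotor)


def cilia_angle(Ca, p: ElectromotorParams):
    """alpha(Ca) = alpha0 + dAlpha / (1 + (Kmotor/Ca)^nmotor), deg."""
    return cilia_angle_pca(_pca(Ca), p)


def swim_velocity(Ca, p: ElectromotorParams):
    """v(Ca) = -vmax + 2 vmax / (1 + (Ca/Kmotor)^2), um/s (+ = forward)."""
    return swim_velocity_pca(_pca(Ca), p)


def rotation_tilt(Ca, p: ElectromotorParams):
    """theta(Ca) = thetaMin + 2 (thetaMax-thetaMin)/((K/Ca)^2+(Ca/K)^2), deg."""
    return rotation_tilt_pca(_pca(Ca), p)


def spin_speed(Ca, p: ElectromotorParams):
    """omega(Ca) = omegaMin + 2 (omegaMax-omegaMin)/((K/Ca)^2+(Ca/K)^2)."""
    return spin_speed_pca(_pca(Ca), p)
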