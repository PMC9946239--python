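"""Rigid-body swimming kinematics.

The swimmer is a rigid body with position ``x`` and orientation given by a
unit quaternion (body -> world), held in a
:class:`scipy.spatial.transform.Rotation` (possibly a stack, for vectorized
populations).  The body frame follows the spherical-model conventions: +z is
the anteroposterior axis pointing anterior, x is dorsoventral, y left-right.

Translational velocity is along the body axis only; the rotation vector is
tilted from the main axis by ``theta`` in the body xz plane (the oral-groove
plane):  ``omega_body = omega (-sin theta, 0, cos theta)``.

Orientation updates use the exact exponential map per step (rotation by
``|omega| dt`` about the rotation axis) rather than the first-order
quaternion derivative, which removes dt-dependent norm drift; scipy
rotations are unit-quaternion backed and renormalized by construction.

Swimming may be confined to the plane z = 0, as for organisms held between
slide and coverslip: after each step the world orientation vector is rotated
back into the plane about the axis ``u = z_hat x p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import electromotor as em
from .constants import CA_REST
from .ephys import BatchStepper, steady_state_init
from .params import CellParams

__all__ = ["Pose", "BodyMotion", "body_rotation_vector", "pose_step",
           "confine_to_plane", "initial_pose", "Trajectory", "simulate_swim"]


@dataclass
class Pose:
    """Swimmer position (um) and orientation quaternion (body -> world)."""
    x: np.ndarray
    q: Rotation

    @property
    def orientation_vector(self) -> np.ndarray:
        """Anterior-pointing unit vector in the world frame."""
        return self.q.apply(np.array([0.0, 0.0, 1.0]))

    def copy(self) -> "Pose":
        return Pose(x=np.copy(self.x), q=Rotation.from_quat(self.q.as_quat()))


@dataclass
class BodyMotion:
    """Axial speed (um/s), spin (rad/s) and rotation-axis tilt (deg)."""
    v: float | np.ndarray
    omega: float | np.ndarray
    theta: float | np.ndarray


def body_rotation_vector(omega, theta_deg):
    """Body-frame rotation vector ``omega(-sin theta, 0, cos theta)``, rad/s."""
    omega = np.asarray(omega, float)
    th = np.deg2rad(np.asarray(theta_deg, float))
    return np.stack([-omega * np.sin(th),
                     np.zeros_like(omega * th),
                     omega * np.cos(th)], axis=-1)


def pose_step(pose: Pose, motion: BodyMotion, dt: float) -> Pose:
    """Advance the rigid body by dt (ms) at constant body-frame motion.

    Position advances by the rotated axial velocity; orientation composes
    with the exact rotation ``exp([omega_body] dt)`` in the body frame.
    """
    dt_s = dt * 1e-3
    w_b = body_rotation_vector(motion.omega, motion.theta)  # rad/s
    v_b = np.zeros(w_b.shape)
    v_b[..., 2] = np.asarray(motion.v, float)
    x_new = pose.x + pose.q.apply(v_b) * dt_s
    q_new = pose.q * Rotation.from_rotvec(w_b * dt_s)
    return Pose(x=x_new, q=q_new)


def confine_to_plane(pose: Pose, tol: float = 1e-12) -> Pose:
    """Rotate the orientation vector into the plane z = 0.

    The orientation is rotated about ``u = z_hat x p`` by
    ``asin(p_z/|p|)``, which zeroes the out-of-plane component.  When p is
    normal to the plane (measure-zero), the rotation axis degenerates; the
    body y-axis is used instead, a deterministic tie-break.
    """
    p = pose.q.apply(np.array([0.0, 0.0, 1.0]))
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    rho = np.hypot(p2[:, 0], p2[:, 1])
    angle = np.arcsin(np.clip(p2[:, 2], -1.0, 1.0))
    u = np.stack([-p2[:, 1], p2[:, 0], np.zeros(len(p2))], axis=-1)
    degen = rho < tol
    if np.any(degen):
        q2 = pose.q if not single else Rotation.from_quat(
            np.atleast_2d(pose.q.as_quat()))
        body_y = q2.apply(np.array([0.0, 1.0, 0.0]))
        u[degen] = np.atleast_2d(body_y)[degen]
        norm = np.ones(len(p2))
        norm[~degen] = rho[~degen]
    else:
        norm = rho.copy()
    norm[norm == 0.0] = 1.0
    rotvec = u / norm[:, None] * angle[:, None]
    corr = Rotation.from_rotvec(rotvec[0] if single else rotvec)
    return Pose(x=pose.x, q=corr * pose.q)


def initial_pose(position=(0.0, 0.0, 0.0), heading_deg: float = 0.0,
                 oral_phase_deg: float = 0.0) -> Pose:
    """In-plane pose: body axis at ``heading_deg`` in the z=0 plane.

    ``oral_phase_deg`` sets the initial spin phase about the body axis (the
    azimuth of the oral groove), on which reorientation outcomes depend.
    """
    q = (Rotation.from_euler("z", heading_deg, degrees=True)
         * Rotation.from_euler("y", 90.0, degrees=True)
         * Rotation.from_euler("z", oral_phase_deg, degrees=True))
    return Pose(x=np.asarray(position, float), q=q)


@dataclass
class Trajectory:
    """Planar swimming record at the kinematic time step."""
    t: np.ndarray                 # s
    x: np.ndarray                 # um, shape (n, 3)
    p: np.ndarray                 # orientation unit vectors, (n, 3)
    V: np.ndarray                 # mV
    Ca: np.ndarray                # uM
    v: np.ndarray                 # um/s signed axial speed
    stimulus: np.ndarray = None   # nA stimulus current, optional

    @property
    def gamma(self) -> np.ndarray:
        """In-plane orientation angle, degrees (unwrapped is up to caller)."""
        return np.rad2deg(np.arctan2(self.p[:, 1], self.p[:, 0]))

    @property
    def backward(self) -> np.ndarray:
        """True where the simulator commanded backward swimming (v < 0)."""
        return self.v < 0.0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_s": self.t,
            "x_um": self.x[:, 0], "y_um": self.x[:, 1], "z_um": self.x[:, 2],
            "gamma_deg": self.gamma, "V_mV": self.V, "Ca_uM": self.Ca,
            "backward_flag": self.backward.astype(int),
        })


def simulate_swim(params: CellParams, T: float,
                  I_ext: Optional[Callable[[float], float]] = None,
                  dt_ephys: float = 0.1, dt_kin: float = 1.0,
                  pose: Optional[Pose] = None, plane: bool = True,
                  noise_rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Co-simulate membrane (fine step) and swimming pose (coarse step).

    ``T`` in seconds; ``I_ext(t_ms)`` returns the stimulus current in nA.
    The membrane advances ``dt_kin/dt_ephys`` Euler substeps per kinematic
    step, then the calcium read at the step start maps to (v, theta, omega)
    through the electromotor coupling and the pose advances once.
    """
    n_sub = int(round(dt_kin / dt_ephys))
    if abs(n_sub * dt_ephys - dt_kin) > 1e-9:
        raise ValueError("dt_kin must be a multiple of dt_ephys")
    state, params = steady_state_init(params)
    if pose is None:
        pose = initial_pose()
    emp = params.electromotor
    stepper = BatchStepper(params)

    n_steps = int(round(T * 1e3 / dt_kin))
    t = np.empty(n_steps + 1)
    xs = np.empty((n_steps + 1, 3))
    ps = np.empty((n_steps + 1, 3))
    Vs = np.empty(n_steps + 1)
    Cas = np.empty(n_steps + 1)
    vs = np.empty(n_steps + 1)
    stim = np.zeros(n_steps + 1)

    t_ms = 0.0
    for i in range(n_steps + 1):
        pca = float(state.pCa)
        v = float(em.swim_velocity_pca(pca, emp))
        t[i] = t_ms * 1e-3
        xs[i] = pose.x
        ps[i] = pose.orientation_vector
        Vs[i] = float(state.V)
        Cas[i] = CA_REST * 10.0 ** pca
        vs[i] = v
        if i == n_steps:
            break
        motion = BodyMotion(v=v,
                            omega=float(em.spin_speed_pca(pca, emp)),
                            theta=float(em.rotation_tilt_pca(pca, emp)))
        for _ in range(n_sub):
            I = I_ext(t_ms) if I_ext is not None else 0.0
            stim[i] = I
            stepper.run(state, I, dt_ephys, 1, rng=noise_rng)
            t_ms += dt_ephys
        pose = pose_step(pose, motion, dt_kin)
        if plane:
            pose = confine_to_plane(pose)
    return Trajectory(t=t, x=xs, p=ps, V=Vs, Ca=Cas, v=vs, stimulus=stim)
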