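"""Closed-loop environments and population simulations.

Arenas are planar rectangles, optionally periodic per axis (torus or
cylinder topology).  A population of independent model cells swims in the
arena; each cell's membrane integrates at a fine time step (0.1 ms) while
its pose and the stimulus coupling advance at a coarse kinematic step (1 ms
for sharp-boundary stimuli, 2 ms for continuous fields).  Agents interact
only through a shared diffusing field in the collective scenario.

Bundled scenarios:

* ``object``      — a single swimmer meets a depolarizing half-plane
* ``disc-repel``  — depolarizing disc (delayed transduction, max 5 nA)
* ``disc-attract``— adapting two-pathway transduction (max 1 nA)
* ``gradient``    — linear drive gradient on a cylinder, adapting pathway
* ``collective``  — cells produce a diffusing attractant (CO2-like)

Spontaneous avoiding reactions arise solely from the Ornstein-Uhlenbeck
noise current (no extra reversal process).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import electromotor as em
from .ephys import BatchStepper, MembraneState, steady_state_init
from .kinematics import BodyMotion, Pose, confine_to_plane, pose_step
from .params import CellParams, preset
from .transduction import (CellOutline, Disc, GridField, HalfPlane,
                           LinearGradient, Transducer, TransductionParams,
                           overlap_fraction)

__all__ = ["Arena", "DiffusionField", "diffusion_step", "ScenarioConfig",
           "PopulationResult", "run_population", "make_scenario",
           "scenario_object_encounter", "spontaneous_reaction_rate"]


@dataclass
class Arena:
    """Rectangular arena (um), periodic on the flagged axes."""
    Lx: float = 4000.0
    Ly: float = 4000.0
    wrap_x: bool = True
    wrap_y: bool = True

    def __post_init__(self):
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("arena dimensions must be positive")

    def wrap(self, xy: np.ndarray) -> np.ndarray:
        """Modular wrap of positions on the periodic axes."""
        xy = np.array(xy, float, copy=True)
        if self.wrap_x:
            xy[..., 0] %= self.Lx
        if self.wrap_y:
            xy[..., 1] %= self.Ly
        return xy

    def minimal_image(self, d: np.ndarray) -> np.ndarray:
        """Displacement vectors folded into the nearest periodic image."""
        d = np.array(d, float, copy=True)
        if self.wrap_x:
            d[..., 0] -= self.Lx * np.round(d[..., 0] / self.Lx)
        if self.wrap_y:
            d[..., 1] -= self.Ly * np.round(d[..., 1] / self.Ly)
        return d


@dataclass
class DiffusionField:
    """Explicitly integrated 2-D diffusing drive field on the arena grid.

    ``grid`` holds the transduction drive in pA per pixel; ``dx`` is the
    pixel width (um), ``D`` the diffusion coefficient (mm^2/s) and
    ``alpha_prod`` the production rate (pA/s) added to every pixel
    containing a cell.  Boundaries are periodic.
    """
    arena: Arena
    dx: float = 20.0               # um
    D: float = 0.01                # mm^2/s (0.002 accelerated 5x)
    alpha_prod: float = 100.0      # pA/s per occupied pixel
    grid: np.ndarray = None

    def __post_init__(self):
        ny = int(round(self.arena.Ly / self.dx))
        nx = int(round(self.arena.Lx / self.dx))
        if self.grid is None:
            self.grid = np.zeros((ny, nx))
        if self.grid.shape != (ny, nx):
            raise ValueError("grid shape does not match arena/dx")

    def stability_dt(self) -> float:
        """Largest stable explicit step (s): D dt / dx^2 <= 1/4."""
        dx_mm = self.dx * 1e-3
        return 0.25 * dx_mm * dx_mm / self.D

    def as_field(self) -> GridField:
        return GridField(grid=self.grid, dx=self.dx, origin=(0.0, 0.0))


def diffusion_step(field: DiffusionField, source_xy: np.ndarray,
                   dt: float) -> None:
    """One explicit diffusion update (dt in s) with cell production.

    Five-point Laplacian with periodic boundaries; adds ``alpha_prod * dt``
    to each pixel containing a cell center.  Rejects unstable steps.
    """
    if dt > field.stability_dt() * (1.0 + 1e-9):
        raise ValueError(
            f"diffusion step dt={dt} s exceeds stability bound "
            f"{field.stability_dt():.4g} s")
    g = field.grid
    dx_mm = field.dx * 1e-3
    lap = (np.roll(g, 1, 0) + np.roll(g, -1, 0)
           + np.roll(g, 1, 1) + np.roll(g, -1, 1) - 4.0 * g) / dx_mm ** 2
    g += field.D * dt * lap
    if source_xy is not None and len(source_xy):
        j = (np.asarray(source_xy)[:, 0] // field.dx).astype(int) \
            % g.shape[1]
        i = (np.asarray(source_xy)[:, 1] // field.dx).astype(int) \
            % g.shape[0]
        np.add.at(g, (i, j), field.alpha_prod * dt)


# --------------------------------------------------------------------------
# drives
# --------------------------------------------------------------------------

class _OverlapDrive:
    """Drive s = I0 * overlap fraction with a sharp-boundary object.

    The exact polygon overlap is only evaluated for agents within one cell
    length of the boundary; far agents are 0 (outside) or 1 (inside) by the
    center test.
    """

    def __init__(self, geometry, I0: float, outline: CellOutline,
                 margin: float = 80.0, resolution: float = 2.0):
        self.geometry = geometry
        self.I0 = I0
        self.outline = outline
        self.margin = margin
        self.resolution = resolution
        self._shape = None
        if isinstance(geometry, Disc):
            self._shape = geometry.shape(resolution=resolution)

    def __call__(self, xy: np.ndarray, gamma: np.ndarray, t_s: float):
        sd = self.geometry.signed_distance(xy)
        p = np.where(sd > 0.0, 1.0, 0.0)
        near = np.abs(sd) < self.margin
        for i in np.nonzero(near)[0]:
            shape = self._shape
            if shape is None:
                shape = self.geometry.shape(around=xy[i])
            p[i] = overlap_fraction(xy[i], gamma[i], self.outline,
                                    self.geometry, self.resolution,
                                    shape=shape)
        return self.I0 * p


class _FieldDrive:
    """Drive sampled at the cell center from a continuous field (nA)."""

    def __init__(self, value_fn: Callable[[np.ndarray], np.ndarray],
                 scale: float = 1.0):
        self.value_fn = value_fn
        self.scale = scale

    def __call__(self, xy, gamma, t_s):
        return np.asarray(self.value_fn(xy), float) * self.scale


# --------------------------------------------------------------------------
# configuration and results
# --------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything needed to reproduce a closed-loop run."""
    scenario: str = "disc-repel"
    n_agents: int = 100
    T: float = 20.0                       # s
    seed: int = 0
    arena: Arena = dc_field(default_factory=Arena)
    geometry: object = None               # HalfPlane | Disc | LinearGradient
    transduction: TransductionParams = dc_field(
        default_factory=TransductionParams)
    noise: bool = True
    dt_ephys: float = 0.1                 # ms
    dt_kin: float = 1.0                   # ms
    cell: CellParams = None               # default: table3_median preset
    outline: CellOutline = dc_field(default_factory=CellOutline)
    diffusion: Optional[DiffusionField] = None
    init_positions: Optional[np.ndarray] = None   # (N, 2) um
    init_headings: Optional[np.ndarray] = None    # deg
    init_phases: Optional[np.ndarray] = None      # deg, oral-groove azimuth

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be > 0")


@dataclass
class PopulationResult:
    """Population run record at the kinematic time step."""
    t: np.ndarray                   # s, (nT,)
    pos: np.ndarray                 # um, (nT, N, 2)
    gamma: np.ndarray               # deg, (nT, N)
    v: np.ndarray                   # um/s signed axial speed, (nT, N)
    V: np.ndarray                   # mV, (nT, N)
    Ca: np.ndarray                  # uM, (nT, N)
    stim: np.ndarray                # nA transduction current, (nT, N)
    inside: Optional[np.ndarray] = None   # bool, (nT, N)
    config: Optional[ScenarioConfig] = None
    field_final: Optional[np.ndarray] = None

    @property
    def occupancy(self) -> np.ndarray:
        """Fraction of agents inside the stimulus region per frame."""
        if self.inside is None:
            raise ValueError("no stimulus region was tracked for this run")
        return self.inside.mean(axis=1)

    @property
    def backward(self) -> np.ndarray:
        return self.v < 0.0


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------

def run_population(config: ScenarioConfig) -> PopulationResult:
    """Simulate N independent agents in the configured arena.

    Deterministic for a given ``config.seed``: one root seed feeds separate
    child streams for initial conditions and for the vectorized noise
    process (agent i always consumes lane i of each draw).
    """
    N = config.n_agents
    arena = config.arena
    rng_init, rng_noise = np.random.default_rng(config.seed).spawn(2)

    params = config.cell if config.cell is not None else preset("table3_median")
    state0, params = steady_state_init(params)

    # initial conditions
    if config.init_positions is not None:
        xy = np.array(config.init_positions, float).reshape(N, 2)
    else:
        xy = np.column_stack([rng_init.uniform(0, arena.Lx, N),
                              rng_init.uniform(0, arena.Ly, N)])
    if config.init_headings is not None:
        headings = np.asarray(config.init_headings, float)
    else:
        headings = rng_init.uniform(0.0, 360.0, N)
    if config.init_phases is not None:
        phases = np.asarray(config.init_phases, float)
    else:
        phases = rng_init.uniform(0.0, 360.0, N)

    q = (Rotation.from_euler("z", headings[:, None], degrees=True)
         * Rotation.from_euler("y", np.full((N, 1), 90.0), degrees=True)
         * Rotation.from_euler("z", phases[:, None], degrees=True))
    pose = Pose(x=np.column_stack([xy, np.zeros(N)]), q=q)

    state = MembraneState(
        V=np.full(N, state0.V), nKir=np.full(N, state0.nKir),
        nKd=np.full(N, state0.nKd), mCa=np.full(N, state0.mCa),
        pCa=np.full(N, state0.pCa), In=np.zeros(N))

    # stimulus drive
    geometry = config.geometry
    trans = Transducer(config.transduction, n=N)
    drive = None
    if config.diffusion is not None:
        grid_field = config.diffusion.as_field()
        drive = _FieldDrive(grid_field.value, scale=1e-3)   # pA -> nA
    elif isinstance(geometry, (Disc, HalfPlane)):
        drive = _OverlapDrive(geometry, config.transduction.I0,
                              config.outline)
    elif isinstance(geometry, LinearGradient):
        drive = _FieldDrive(geometry.value)
    elif isinstance(geometry, GridField):
        drive = _FieldDrive(geometry.value)

    n_sub = int(round(config.dt_kin / config.dt_ephys))
    if abs(n_sub * config.dt_ephys - config.dt_kin) > 1e-9:
        raise ValueError("dt_kin must be a multiple of dt_ephys")
    n_steps = int(round(config.T * 1e3 / config.dt_kin))
    emp = params.electromotor
    stepper = BatchStepper(params)

    t = np.arange(n_steps + 1) * config.dt_kin * 1e-3
    rec_pos = np.empty((n_steps + 1, N, 2))
    rec_gamma = np.empty((n_steps + 1, N))
    rec_v = np.empty((n_steps + 1, N))
    rec_V = np.empty((n_steps + 1, N))
    rec_Ca = np.empty((n_steps + 1, N))
    rec_stim = np.zeros((n_steps + 1, N))
    rec_inside = None
    if geometry is not None and hasattr(geometry, "signed_distance"):
        rec_inside = np.empty((n_steps + 1, N), bool)

    I_trans = np.zeros(N)
    for i in range(n_steps + 1):
        p_vec = pose.q.apply(np.array([0.0, 0.0, 1.0]))
        gamma = np.rad2deg(np.arctan2(p_vec[:, 1], p_vec[:, 0]))
        pca = np.asarray(state.pCa, float)
        v = em.swim_velocity_pca(pca, emp)

        rec_pos[i] = pose.x[:, :2]
        rec_gamma[i] = gamma
        rec_v[i] = v
        rec_V[i] = state.V
        rec_Ca[i] = state.Ca()
        rec_stim[i] = I_trans
        if rec_inside is not None:
            rec_inside[i] = geometry.signed_distance(pose.x[:, :2]) > 0.0
        if i == n_steps:
            break

        if drive is not None:
            s = drive(pose.x[:, :2], gamma, t[i])
            I_trans = np.asarray(trans.step(s, config.dt_kin), float)

        stepper.run(state, I_trans, config.dt_ephys, n_sub,
                    rng=rng_noise if config.noise else None)

        motion = BodyMotion(v=v, omega=em.spin_speed_pca(pca, emp),
                            theta=em.rotation_tilt_pca(pca, emp))
        pose = pose_step(pose, motion, config.dt_kin)
        pose = confine_to_plane(pose)
        pose.x[:, :2] = arena.wrap(pose.x[:, :2])
        pose.x[:, 2] = 0.0

        if config.diffusion is not None:
            diffusion_step(config.diffusion, pose.x[:, :2],
                           config.dt_kin * 1e-3)

    return PopulationResult(
        t=t, pos=rec_pos, gamma=rec_gamma, v=rec_v, V=rec_V, Ca=rec_Ca,
        stim=rec_stim, inside=rec_inside, config=config,
        field_final=None if config.diffusion is None
        else config.diffusion.grid.copy())


# --------------------------------------------------------------------------
# published scenarios
# --------------------------------------------------------------------------

def make_scenario(name: str, n_agents: int = 100, T: float = 20.0,
                  seed: int = 0, **overrides) -> ScenarioConfig:
    """Build one of the published closed-loop scenarios by name."""
    if name == "disc-repel":
        cfg = ScenarioConfig(
            scenario=name, n_agents=n_agents, T=T, seed=seed,
            arena=Arena(4000.0, 4000.0),
            geometry=Disc(center=(2000.0, 2000.0), radius=1000.0),
            transduction=TransductionParams(kind="delayed", I0=5.0,
                                            tau_I=40.0),
            dt_kin=1.0)
    elif name == "disc-attract":
        cfg = ScenarioConfig(
            scenario=name, n_agents=n_agents, T=T, seed=seed,
            arena=Arena(4000.0, 4000.0),
            geometry=Disc(center=(2000.0, 2000.0), radius=1000.0),
            transduction=TransductionParams(kind="adapting", I0=1.0,
                                            tau_fast=40.0, tau_slow=200.0),
            dt_kin=1.0)
    elif name == "gradient":
        arena = Arena(25000.0, 500.0, wrap_x=False, wrap_y=True)
        cfg = ScenarioConfig(
            scenario=name, n_agents=n_agents, T=T, seed=seed, arena=arena,
            geometry=LinearGradient(slope=100.0, direction=(1.0, 0.0)),
            transduction=TransductionParams(kind="adapting",
                                            tau_fast=40.0, tau_slow=200.0),
            dt_kin=2.0,
            init_positions=np.tile([arena.Lx / 2.0, arena.Ly / 2.0],
                                   (n_agents, 1)))
    elif name == "collective":
        arena = Arena(4000.0, 4000.0)
        cfg = ScenarioConfig(
            scenario=name, n_agents=n_agents, T=T, seed=seed, arena=arena,
            transduction=TransductionParams(kind="adapting",
                                            tau_fast=40.0, tau_slow=200.0),
            diffusion=DiffusionField(arena=arena),
            dt_kin=2.0)
    else:
        raise KeyError(f"unknown scenario {name!r}")
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def scenario_object_encounter(distance: float = 500.0,
                              kind: str = "instantaneous",
                              T: float = 6.0, seed: int = 0,
                              I0: float = 5.0, noise: bool = False,
                              cell: Optional[CellParams] = None,
                              oral_phase_deg: float = 0.0):
    """Single swimmer approaching a depolarizing half-plane.

    The swimmer starts ``distance`` um from the boundary, heading into it.
    Returns the :class:`PopulationResult` of the one-agent run (stimulus
    trace included).  With instantaneous transduction the cell bumps
    repeatedly with small avoiding reactions; with delayed transduction
    (40 ms) the current outlasts contact and reactions are larger.
    """
    arena = Arena(20000.0, 20000.0, wrap_x=False, wrap_y=False)
    x0 = 10000.0 - distance
    cfg = ScenarioConfig(
        scenario="object", n_agents=1, T=T, seed=seed, arena=arena,
        geometry=HalfPlane(normal=(1.0, 0.0), point=(10000.0, 10000.0)),
        transduction=TransductionParams(kind=kind, I0=I0, tau_I=40.0),
        noise=noise, dt_kin=1.0, cell=cell,
        init_positions=np.array([[x0, 10000.0]]),
        init_headings=np.array([0.0]),
        init_phases=np.array([oral_phase_deg]))
    return run_population(cfg)


def spontaneous_reaction_rate(params: Optional[CellParams] = None,
                              T: float = 50.0, n_agents: int = 10,
                              seed: int = 0, dt_kin: float = 1.0) -> float:
    """Rate (Hz) of noise-driven avoiding reactions per agent.

    Counts onsets of backward swimming (sign changes of the commanded
    velocity) in a stimulus-free arena and divides by the simulated time.
    The calibrated noise (sigma_n = 9 pA, tau_n = 20 ms) yields about
    0.2 Hz.
    """
    cfg = ScenarioConfig(
        scenario="free", n_agents=n_agents, T=T, seed=seed,
        arena=Arena(10000.0, 10000.0), geometry=None,
        noise=True, dt_kin=dt_kin,
        cell=params)
    res = run_population(cfg)
    bw = res.backward
    onsets = (~bw[:-1] & bw[1:]).sum()
    return float(onsets) / (T * n_agents)
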