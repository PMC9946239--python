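"""Staged least-squares estimation of model parameters from current clamp.

The fitting pipeline mirrors the experimental protocol:

1. ``fit_electrode`` — electrode resistance and time constant from small
   (<0.5 nA) pulses, assuming a passive cell; quadratic error on both
   electrode potentials from 100 ms before to 100 ms after the pulse.
2. ``fit_hyperpolarized`` — leak + inward rectifier (n^2 gates) on pulses
   0 to -4 nA; error on the reading potential from pulse start to 50 ms
   after the pulse.
3. ``fit_deciliated`` — leak + Boltzmann-n^2 delayed rectifier on pulses
   0 to +4 nA, C and EK fixed from stage 2; the response window is split
   into the first 30 ms and the rest, equally weighted.
4. ``fit_ciliated`` — the full model against voltage, ciliary-angle and
   resting-calcium objectives; traces aligned to a common resting
   potential, EK fixed; the resting-calcium penalty effectively enforces
   J = I_rest/(F v).

Conductances, binding constants and rates are fitted in log10 space (they
span decades).  Optimization is a (seeded) differential-evolution global
stage followed by trust-region least squares on the residual vector; either
stage can be disabled.  A quality-control filter rejects non-physiological
results (C > 500 pF, resting resistance outside 30-500 MOhm, EK > EL).

``generate_synthetic_dataset`` produces current-clamp datasets from known
parameters (forward model including the electrode filter, optional Gaussian
measurement noise) for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .ephys import (PulseProtocol, membrane_currents, simulate_membrane,
                    steady_state_init)
from . import electromotor as em
from .params import CellParams, ElectrodeParams

__all__ = ["FitSpec", "FitResult", "CurrentClampTrace", "Dataset",
           "generate_synthetic_dataset", "fit_electrode",
           "fit_hyperpolarized", "fit_deciliated", "fit_ciliated",
           "qc_filter", "get_param", "set_param", "LOG_PARAMS",
           "resting_resistance"]


# --------------------------------------------------------------------------
# parameter addressing
# --------------------------------------------------------------------------

#: dotted paths fitted in log10 space (span decades, always positive)
LOG_PARAMS = {
    "passive.gL", "kir.gKir", "kd.gKd", "ca.gCa", "kca.gKCa",
    "ca.KCa", "kca.KKCa", "electromotor.Kmotor",
    "cadyn.lambda_", "cadyn.J", "ca.tau_m", "kd.bKd", "kir.tauKir",
}


def get_param(cell: CellParams, path: str) -> float:
    section, name = path.split(".")
    return float(getattr(getattr(cell, section), name))


def set_param(cell: CellParams, path: str, value: float) -> None:
    section, name = path.split(".")
    setattr(getattr(cell, section), name, float(value))


@dataclass
class FitSpec:
    """Free parameters with bounds, plus optimizer settings.

    ``free`` maps dotted parameter paths (e.g. ``"kd.VKd"``) to (lo, hi)
    bounds in natural units; log-scaled parameters are transformed
    internally.  ``x0`` optionally supplies starting values (natural
    units); otherwise the bound midpoint (geometric midpoint for log
    parameters) is used.
    """
    free: Dict[str, Tuple[float, float]]
    x0: Optional[Dict[str, float]] = None
    seed: int = 0
    use_de: bool = False
    de_maxiter: int = 15
    de_popsize: int = 8
    ls_max_nfev: int = 200

    def paths(self) -> List[str]:
        return list(self.free)

    def encode(self, values: Dict[str, float]) -> np.ndarray:
        x = []
        for p in self.paths():
            v = values[p]
            x.append(math.log10(v) if p in LOG_PARAMS else v)
        return np.array(x)

    def decode(self, x: np.ndarray) -> Dict[str, float]:
        out = {}
        for p, xi in zip(self.paths(), x):
            out[p] = 10.0 ** xi if p in LOG_PARAMS else float(xi)
        return out

    def bounds_t(self) -> List[Tuple[float, float]]:
        bl = []
        for p in self.paths():
            lo, hi = self.free[p]
            if p in LOG_PARAMS:
                if lo <= 0:
                    raise ValueError(f"log-scaled {p} needs positive bounds")
                lo, hi = math.log10(lo), math.log10(hi)
            bl.append((lo, hi))
        return bl

    def start(self) -> np.ndarray:
        if self.x0 is not None:
            return self.encode(self.x0)
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bounds_t()])


@dataclass
class FitResult:
    """Estimated parameters with error metrics and QC verdict."""
    cell: CellParams
    electrode: ElectrodeParams
    values: Dict[str, float]
    rms_mV: float
    objectives: Dict[str, float] = field(default_factory=dict)
    history: List[float] = field(default_factory=list)
    nfev: int = 0
    qc: Dict = field(default_factory=dict)
    degenerate: bool = False


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

@dataclass
class CurrentClampTrace:
    """One recorded sweep: command current and both electrode potentials."""
    t: np.ndarray            # ms, uniform
    I_command: np.ndarray    # nA
    V_read: np.ndarray       # mV (membrane/reading electrode)
    V_inject: np.ndarray     # mV (injecting electrode)
    amplitude: float = 0.0   # nA pulse amplitude


@dataclass
class AngleSeries:
    """Ciliary flow-angle series (video frame rate)."""
    t: np.ndarray            # ms
    alpha_deg: np.ndarray


@dataclass
class Dataset:
    """A set of sweeps sharing one pulse protocol."""
    traces: List[CurrentClampTrace]
    protocol: PulseProtocol
    angles: Optional[List[AngleSeries]] = None
    truth: Optional[CellParams] = None
    truth_electrode: Optional[ElectrodeParams] = None

    @property
    def dt(self) -> float:
        return float(self.traces[0].t[1] - self.traces[0].t[0])


def generate_synthetic_dataset(cell: CellParams, protocol: PulseProtocol,
                               noise_sd: float = 0.0, seed: int = 0,
                               electrode: Optional[ElectrodeParams] = None,
                               angle_fps: float = 30.0,
                               with_angles: bool = False,
                               balance: bool = False) -> Dataset:
    """Simulate the forward model and package it as a recorded dataset.

    The command current passes through the RC electrode filter; Gaussian
    measurement noise of ``noise_sd`` mV is added independently to both
    electrode potentials.  Identical seeds give identical datasets.

    ``balance`` selects the resting convention: False starts from the
    natural fixed point of the given parameters (electrode / passive / Kd
    datasets); True pins rest at ``cell.V_rest`` with the calcium pump
    balanced (full ciliated model).  The returned ``truth`` holds the
    effective (possibly balanced) parameters actually simulated.
    """
    cell = cell.copy()
    if electrode is not None:
        cell.electrode = electrode
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.total, protocol.dt)
    I = protocol.command(t)
    state0, cell = steady_state_init(cell, balance=balance)
    rec, _ = simulate_membrane(cell, I, dt=protocol.dt, state=state0,
                               electrode=True)
    traces = []
    angles = [] if with_angles else None
    frame_ms = 1e3 / angle_fps
    for j, amp in enumerate(protocol.amplitudes):
        noise_r = rng.standard_normal(len(t)) * noise_sd
        noise_i = rng.standard_normal(len(t)) * noise_sd
        traces.append(CurrentClampTrace(
            t=t.copy(), I_command=I[:, j],
            V_read=rec["V"][:, j] + noise_r,
            V_inject=rec["V2"][:, j] + noise_i,
            amplitude=float(amp)))
        if with_angles:
            tf = np.arange(0.0, protocol.total, frame_ms)
            idx = np.minimum((tf / protocol.dt).astype(int), len(t) - 1)
            alpha = em.cilia_angle(rec["Ca"][idx, j], cell.electromotor)
            angles.append(AngleSeries(t=tf, alpha_deg=alpha))
    return Dataset(traces=traces, protocol=protocol, angles=angles,
                   truth=cell, truth_electrode=cell.electrode)


# --------------------------------------------------------------------------
# objective machinery
# --------------------------------------------------------------------------

def _optimize(spec: FitSpec, residual_fn) -> Tuple[np.ndarray, List[float], int]:
    """DE global stage (optional) + least-squares local stage.

    Returns the transformed optimum, the best-so-far objective history
    (monotone non-increasing) and the number of function evaluations.
    """
    history: List[float] = []
    nfev = 0

    def scalar(x):
        nonlocal nfev
        nfev += 1
        r = residual_fn(x)
        val = float(np.dot(r, r))
        if not history or val < history[-1]:
            history.append(val)
        return val

    bounds = spec.bounds_t()
    x0 = spec.start()
    if spec.use_de and len(bounds) > 0:
        de = differential_evolution(
            scalar, bounds=bounds, seed=spec.seed,
            maxiter=spec.de_maxiter, popsize=spec.de_popsize,
            init="sobol", tol=1e-8, polish=False, x0=x0)
        x0 = de.x
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(x0, lo, hi)

    def resid_tracked(x):
        nonlocal nfev
        nfev += 1
        r = residual_fn(x)
        val = float(np.dot(r, r))
        if not history or val < history[-1]:
            history.append(val)
        return r

    ls = least_squares(resid_tracked, x0, bounds=(lo, hi),
                       max_nfev=spec.ls_max_nfev, x_scale="jac")
    return ls.x, history, nfev


def _window_mask(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (t >= lo) & (t < hi)


def _stack_commands(ds: Dataset) -> np.ndarray:
    return np.column_stack([tr.I_command for tr in ds.traces])


# --------------------------------------------------------------------------
# stage 1: electrode
# --------------------------------------------------------------------------

def _simulate_passive_electrode(C, gL, V0, Re, tau_e, dV, I, dt):
    """Passive cell + RC electrode, vectorized over sweeps.

    Exact-exponential electrode update, Euler membrane update (the membrane
    is linear, so dt = 0.1 ms is far inside its stability region).
    """
    nT, nB = I.shape
    V = np.full(nB, V0)
    V2 = V + Re * I[0] + dV
    decay = math.exp(-dt / tau_e)
    Vs = np.empty((nT, nB))
    V2s = np.empty((nT, nB))
    for i in range(nT):
        target = V + Re * I[i] + dV
        V2 = target + (V2 - target) * decay
        Ie = (V2 - V - dV) / Re
        Vs[i] = V
        V2s[i] = V2
        V = V + dt * 1e3 * (gL * (V0 - V) * 1e-3 + Ie) / C
    return Vs, V2s


def fit_electrode(ds: Dataset, spec: Optional[FitSpec] = None) -> FitResult:
    """Estimate (Re, tau_e) from small-pulse responses, Eqs of the RC model.

    Only sweeps with |pulse| < 0.5 nA are used.  The quadratic error on
    both electrode potentials is taken from 100 ms before to 100 ms after
    the pulse.  The tip-potential offset dV is fitted but has no impact on
    the injected current and is discarded afterwards.
    """
    small = [tr for tr in ds.traces if abs(tr.amplitude) < 0.5
             and tr.amplitude != 0.0]
    if not small:
        raise ValueError("electrode fit needs pulses with |I| < 0.5 nA")
    t = small[0].t
    dt = ds.dt
    pr = ds.protocol
    mask = _window_mask(t, pr.t_pre - 100.0, pr.t_pre + pr.duration + 100.0)
    I = np.column_stack([tr.I_command for tr in small])
    Vr = np.column_stack([tr.V_read for tr in small])
    Vi = np.column_stack([tr.V_inject for tr in small])

    if spec is None:
        spec = FitSpec(free={
            "C": (50.0, 600.0), "gL": (1.0, 50.0), "V0": (-60.0, 0.0),
            "Re": (30.0, 400.0), "tau_e": (0.2, 10.0), "dV": (-20.0, 20.0),
        })

    names = spec.paths()

    def residual(x):
        p = dict(zip(names, x))
        Vs, V2s = _simulate_passive_electrode(
            p.get("C", 300.0), p.get("gL", 10.0), p.get("V0", -22.0),
            p["Re"], p["tau_e"], p.get("dV", 0.0), I, dt)
        return np.concatenate([(Vs - Vr)[mask].ravel(),
                               (V2s - Vi)[mask].ravel()])

    x, history, nfev = _optimize(spec, residual)
    p = dict(zip(names, x))
    elec = ElectrodeParams(Re=p["Re"], tau_e=p["tau_e"], dV=p.get("dV", 0.0))
    r = residual(x)
    n_half = r.size // 2
    rms = float(np.sqrt(np.mean(r[:n_half] ** 2)))
    cell = (ds.truth or CellParams()).copy()
    cell.electrode = elec
    return FitResult(cell=cell, electrode=elec, values=p, rms_mV=rms,
                     objectives={"both_potentials": float(np.dot(r, r))},
                     history=history, nfev=nfev)


# --------------------------------------------------------------------------
# stages 2-4: membrane models
# --------------------------------------------------------------------------

def _forward_voltage(cell: CellParams, ds: Dataset, balance: bool = False):
    """Simulate the reading potential for every sweep of the dataset.

    ``balance=False`` starts from the natural resting point implied by the
    candidate parameters (EL stays a free, identifiable parameter);
    ``balance=True`` pins rest at ``cell.V_rest`` with the pump balanced
    (the ciliated-fit alignment convention).
    """
    state, cell2 = steady_state_init(cell, balance=balance)
    I = _stack_commands(ds)
    rec, _ = simulate_membrane(cell2, I, dt=ds.dt, state=state,
                               electrode=True)
    return rec


def _make_cell(base: CellParams, spec: FitSpec, x: np.ndarray) -> CellParams:
    cell = base.copy()
    for path, value in spec.decode(x).items():
        set_param(cell, path, value)
    return cell


def _membrane_residual_factory(base: CellParams, ds: Dataset, spec: FitSpec,
                               windows, weights, big: float = 1e3,
                               balance: bool = False):
    """Residuals = per-window RMS-weighted voltage errors, concatenated.

    Each window is weighted by 1/sqrt(n_window) so windows contribute
    equally regardless of sample count.
    """
    t = ds.traces[0].t
    Vr = np.column_stack([tr.V_read for tr in ds.traces])
    masks = [_window_mask(t, lo, hi) for lo, hi in windows]

    def residual(x):
        try:
            cell = _make_cell(base, spec, x)
            cell.validate()
            rec = _forward_voltage(cell, ds, balance=balance)
        except (ValueError, FloatingPointError):
            n = sum(int(m.sum()) * Vr.shape[1] for m in masks)
            return np.full(n, big)
        parts = []
        for m, w in zip(masks, weights):
            err = (rec["V"] - Vr)[m].ravel()
            parts.append(err * math.sqrt(w / err.size))
        return np.concatenate(parts)

    return residual, masks, Vr


def fit_hyperpolarized(ds: Dataset, spec: Optional[FitSpec] = None) -> FitResult:
    """Leak + inward-rectifier fit on hyperpolarizing pulses.

    Error on the reading potential from pulse start to 50 ms after the
    pulse.  Returns the fitted cell plus the derived resting resistance R
    (leak + Kir contribution) and resting potential V0 in ``values``.
    """
    base = (ds.truth or CellParams()).copy()
    base.kir_enabled = True
    base.kd.gKd = 0.0
    base.ca.gCa = 0.0
    base.kca.gKCa = 0.0
    if ds.truth_electrode is not None:
        base.electrode = ds.truth_electrode

    if spec is None:
        spec = FitSpec(free={
            "passive.C": (100.0, 500.0), "passive.gL": (1.0, 50.0),
            "passive.EL": (-40.0, -5.0), "passive.EK": (-70.0, -30.0),
            "kir.gKir": (50.0, 5000.0), "kir.VKir": (-180.0, -80.0),
            "kir.kKir": (10.0, 60.0), "kir.tauKir": (5.0, 40.0),
        })

    pr = ds.protocol
    windows = [(pr.t_pre, pr.t_pre + pr.duration + 50.0)]
    residual, masks, Vr = _membrane_residual_factory(
        base, ds, spec, windows, weights=[1.0])
    x, history, nfev = _optimize(spec, residual)
    cell = _make_cell(base, spec, x)

    rec = _forward_voltage(cell, ds)
    rms = float(np.sqrt(np.mean(((rec["V"] - Vr)[masks[0]]) ** 2)))
    values = spec.decode(x)
    st, bal = steady_state_init(cell, balance=False)
    values["V0"] = bal.V_rest
    values["R"] = resting_resistance(bal)
    res = FitResult(cell=cell, electrode=base.electrode, values=values,
                    rms_mV=rms, history=history, nfev=nfev)
    res.qc = qc_filter(res)
    return res


def fit_deciliated(ds: Dataset, C: float, EK: float,
                   spec: Optional[FitSpec] = None,
                   simplified: bool = False) -> FitResult:
    """Leak + delayed-rectifier (Boltzmann n^2) fit on depolarizing pulses.

    ``C`` and ``EK`` come from the hyperpolarized fit.  The error window
    (pulse start to 50 ms after) is split into the first 30 ms and the
    rest, equally weighted.  ``simplified=True`` enforces VtauKd = VKd and
    ktauKd = 2 kKd.  A degenerate (non-excitable, flat) dataset is flagged
    rather than silently fitted.
    """
    base = (ds.truth or CellParams()).copy()
    base.kir_enabled = False
    base.ca.gCa = 0.0
    base.kca.gKCa = 0.0
    base.passive.C = C
    base.passive.EK = EK
    base.kd.simplified = simplified
    if not simplified and base.kd.VtauKd is None:
        base.kd.VtauKd = base.kd.VKd
        base.kd.ktauKd = 2.0 * base.kd.kKd
    if ds.truth_electrode is not None:
        base.electrode = ds.truth_electrode

    # degenerate-data guard: depolarizing sweeps must deviate from scaled
    # passive behaviour; a flat/linear family has no excitable response
    Vr = np.column_stack([tr.V_read for tr in ds.traces])
    spans = Vr.max(axis=0) - Vr.min(axis=0)
    degenerate = bool(np.all(spans < 1.0))

    if spec is None:
        free = {
            "passive.gL": (1.0, 50.0), "passive.EL": (-40.0, -5.0),
            "kd.gKd": (10.0, 5000.0), "kd.VKd": (-20.0, 60.0),
            "kd.kKd": (1.0, 25.0), "kd.bKd": (0.5, 30.0),
        }
        if not simplified:
            free["kd.VtauKd"] = (-20.0, 80.0)
            free["kd.ktauKd"] = (2.0, 40.0)
        spec = FitSpec(free=free)

    pr = ds.protocol
    windows = [(pr.t_pre, pr.t_pre + 30.0),
               (pr.t_pre + 30.0, pr.t_pre + pr.duration + 50.0)]
    residual, masks, Vr = _membrane_residual_factory(
        base, ds, spec, windows, weights=[1.0, 1.0])
    x, history, nfev = _optimize(spec, residual)
    cell = _make_cell(base, spec, x)

    rec = _forward_voltage(cell, ds)
    full = masks[0] | masks[1]
    rms = float(np.sqrt(np.mean((rec["V"] - Vr)[full] ** 2)))
    res = FitResult(cell=cell, electrode=base.electrode,
                    values=spec.decode(x), rms_mV=rms, history=history,
                    nfev=nfev, degenerate=degenerate)
    res.qc = qc_filter(res)
    return res


def fit_ciliated(ds: Dataset, spec: Optional[FitSpec] = None,
                 V_align: float = -24.0, EK: float = -48.0,
                 angle_weight: float = 1.0,
                 ca_weight: float = 1.0) -> FitResult:
    """Full-model fit: voltage, ciliary angle and resting-calcium objectives.

    Traces are aligned to the common resting potential ``V_align`` and EK
    is fixed.  The voltage error uses two equally weighted windows (pulse,
    and pulse end to +500 ms); the angle error is the quadratic error on
    unit vectors (cos, sin) of the flow angle over [-100 ms, +500 ms]
    around the pulse; the calcium error penalizes deviation of pre-pulse
    [Ca2+] from 0.1 uM.  Each objective is normalized by its target
    variance.  The forward model pins its resting state at ``V_align``
    with the pump balanced, so the calcium penalty is honoured by
    construction and J tracks I_rest/(F v).
    """
    base = (ds.truth or CellParams()).copy()
    base.kir_enabled = False
    base.passive.EK = EK
    base.V_rest = V_align
    base.kd.simplified = True
    base.kd.aKd = 0.1
    if ds.truth_electrode is not None:
        base.electrode = ds.truth_electrode

    if spec is None:
        spec = FitSpec(free={
            "ca.VCa": (-20.0, 20.0), "ca.kCa": (1.0, 10.0),
            "ca.tau_m": (0.2, 5.0), "ca.KCa": (0.5, 30.0),
            "ca.gCa": (20.0, 2000.0),
            "electromotor.Kmotor": (0.3, 20.0),
        })

    pr = ds.protocol
    t = ds.traces[0].t
    dt = ds.dt
    Vr = np.column_stack([tr.V_read for tr in ds.traces])
    # per-sweep alignment of a possible tip-potential offset
    pre = _window_mask(t, 0.0, pr.t_pre)
    Vr = Vr - (np.median(Vr[pre], axis=0) - V_align)

    w1 = _window_mask(t, pr.t_pre, pr.t_pre + pr.duration)
    w2 = _window_mask(t, pr.t_pre + pr.duration,
                      pr.t_pre + pr.duration + 500.0)
    wa = _window_mask(t, pr.t_pre - 100.0, pr.t_pre + pr.duration + 500.0)

    have_angles = ds.angles is not None
    if have_angles:
        frame_idx = [np.minimum((a.t / dt).astype(int), len(t) - 1)
                     for a in ds.angles]
        ang_data = [np.deg2rad(a.alpha_deg) for a in ds.angles]
        ang_masks = [wa[idx] for idx in frame_idx]
        var_ang = max(1e-6, float(np.var(np.concatenate(
            [np.cos(a) for a in ang_data])) + np.var(np.concatenate(
                [np.sin(a) for a in ang_data]))))
    var_v = max(1e-6, float(np.var(Vr[w1 | w2])))

    def residual(x):
        try:
            cell = _make_cell(base, spec, x)
            cell.validate()
            rec = _forward_voltage(cell, ds, balance=True)
        except (ValueError, FloatingPointError):
            n = int(w1.sum() + w2.sum()) * Vr.shape[1]
            if have_angles:
                n += 2 * sum(int(m.sum()) for m in ang_masks)
            return np.full(n + Vr.shape[1], 1e3)
        parts = []
        for m in (w1, w2):
            err = (rec["V"] - Vr)[m].ravel()
            parts.append(err / math.sqrt(err.size * var_v))
        if have_angles:
            for j, (idx, a, m) in enumerate(zip(frame_idx, ang_data,
                                                ang_masks)):
                alpha_sim = np.deg2rad(em.cilia_angle(
                    rec["Ca"][idx, j], cell.electromotor))
                scale = math.sqrt(angle_weight / (m.sum() * var_ang
                                                  * len(ang_masks)))
                parts.append((np.cos(alpha_sim) - np.cos(a))[m] * scale)
                parts.append((np.sin(alpha_sim) - np.sin(a))[m] * scale)
        # resting-calcium penalty: pre-pulse [Ca] vs 0.1 uM (uM units)
        ca_err = rec["Ca"][pre].mean(axis=0) - 0.1
        parts.append(ca_err * math.sqrt(ca_weight / ca_err.size) / 0.1)
        return np.concatenate(parts)

    x, history, nfev = _optimize(spec, residual)
    cell = _make_cell(base, spec, x)
    rec = _forward_voltage(cell, ds, balance=True)
    full = w1 | w2
    rms = float(np.sqrt(np.mean((rec["V"] - Vr)[full] ** 2)))
    values = spec.decode(x)
    _, balanced = steady_state_init(cell)
    values["cadyn.J"] = balanced.cadyn.J
    res = FitResult(cell=balanced, electrode=base.electrode, values=values,
                    rms_mV=rms, history=history, nfev=nfev)
    res.qc = qc_filter(res)
    return res


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

def resting_resistance(cell: CellParams, dV: float = 0.5) -> float:
    """Resting input resistance in MOhm (numerical dI/dV at rest).

    Includes every conductance active at rest (gating variables held at
    their steady states while V is perturbed, matching a slow I-V probe).
    """
    from .ephys import MembraneState, kd_rates, kir_steady, ca_m_steady

    def net_current(V):
        st = MembraneState(
            V=V,
            nKir=float(kir_steady(V, cell.kir)) if cell.kir_enabled else 0.0,
            nKd=float(kd_rates(V, cell.kd)[0]),
            mCa=float(ca_m_steady(V, cell.ca)),
            pCa=0.0)
        return float(sum(membrane_currents(st, cell).values()))

    V0 = cell.V_rest
    dI = (net_current(V0 + dV) - net_current(V0 - dV)) / (2.0 * dV)  # nA/mV
    if dI >= 0:
        return float("inf")   # locally unstable: no meaningful resistance
    return -1.0 / dI


def qc_filter(result: FitResult) -> dict:
    """Reject non-physiological fits.

    Failure reasons: C > 500 pF, resting resistance < 30 or > 500 MOhm,
    EK > EL (biophysically impossible).
    """
    cell = result.cell
    C = cell.passive.C
    R = result.values.get("R")
    if R is None:
        R = resting_resistance(cell)
    reasons = []
    if C > 500.0:
        reasons.append(f"C = {C:.0f} pF > 500 pF")
    if R < 30.0:
        reasons.append(f"R = {R:.0f} MOhm < 30 MOhm")
    if R > 500.0:
        reasons.append(f"R = {R:.0f} MOhm > 500 MOhm")
    if cell.passive.EK > cell.passive.EL:
        reasons.append(
            f"EK ({cell.passive.EK:.1f}) > EL ({cell.passive.EL:.1f}): "
            "biophysically impossible")
    return {"passed": not reasons, "reasons": reasons,
            "C_pF": C, "R_MOhm": R,
            "EK_mV": cell.passive.EK, "EL_mV": cell.passive.EL}
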