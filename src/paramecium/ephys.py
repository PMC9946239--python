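"""Single-compartment electrophysiology of the ciliated cell.

*Paramecium* is isopotential, so the membrane is a single compartment:

    C dV/dt = I_L + I_Kd + I_Ca + I_K(Ca) [+ I_Kir] + I_ext + I_n

with a leak current, a Boltzmann-n^2 delayed rectifier, a GHK
calcium-inactivated ciliary calcium current, a calcium-activated K+ current,
and (for hyperpolarized protocols only) an inward rectifier.  Sign
convention: positive current depolarizes (opposite of the electrophysiology
plotting convention where inward is negative).

Intraciliary calcium obeys

    d[Ca]/dt = I_Ca/(2 F v) - lambda ([Ca]-[Ca]_0) - J / (1 + [Ca]_0/[Ca])

and is integrated in the numerically stable variable
``pCa = log10([Ca]/[Ca]_0)``.

All state variables may be scalars or equally-shaped numpy arrays, so a
population of cells integrates vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import (CA_REST, FARADAY, LN10, NS_MV_TO_NA, RT_OVER_F,
                        V_CILIA, ca_influx_rate_per_nA)
from .params import CellParams, KdParams, KirParams
from . import electromotor as _em

__all__ = [
    "ghk_factor", "kir_steady", "kd_rates", "ca_m_steady", "ca_h",
    "kca_activation", "leak_current", "kir_current", "kd_current",
    "ca_current", "kca_current", "calcium_derivative", "MembraneState",
    "membrane_derivatives", "step_euler", "steady_state_init",
    "ou_noise_step", "electrode_inject", "PulseProtocol", "Trace",
    "run_protocol", "simulate_membrane", "BatchStepper",
]


# --------------------------------------------------------------------------
# gating and current primitives
# --------------------------------------------------------------------------

def ghk_factor(V):
    """Normalized GHK open-channel I-V factor ``x/(e^x - 1)``, x = 2V/(RT/F).

    Strictly positive, equals 1 at V = 0, ~ -x for large depolarizations of
    the wrong sign... more precisely -> 0 for V -> +inf and -> |x| for
    V -> -inf.  Overflow-safe on both tails.
    """
    x = np.asarray(2.0 * np.asarray(V, dtype=float) / RT_OVER_F)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    big_pos = x > 500.0
    big_neg = x < -500.0
    mid = ~(small | big_pos | big_neg)
    out[small] = 1.0 - x[small] / 2.0          # series: x/(e^x-1) ~ 1 - x/2
    out[big_pos] = 0.0
    out[big_neg] = -x[big_neg]
    xm = x[mid]
    out[mid] = xm / np.expm1(xm)
    return out if out.ndim else float(out)


def kir_steady(V, p: KirParams):
    """Per-gate steady-state activation of the inward rectifier."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) - p.VKir) / p.kKir))


def kd_rates(V, p: KdParams):
    """Delayed-rectifier Boltzmann steady state and bell time constant.

    Returns ``(n_inf, tau)`` with ``n_inf = 1/(1+exp((VKd-V)/kKd))`` and
    ``tau = aKd + bKd/cosh((V - VtauKd)/ktauKd)`` (maximum ``aKd+bKd``).
    """
    V = np.asarray(V, float)
    n_inf = 1.0 / (1.0 + np.exp((p.VKd - V) / p.kKd))
    tau = p.aKd + p.bKd / np.cosh((V - p.tau_center()) / p.tau_slope())
    return n_inf, tau


def ca_m_steady(V, p):
    """Steady-state activation of the ciliary calcium current."""
    return 1.0 / (1.0 + np.exp((p.VCa - np.asarray(V, float)) / p.kCa))


def ca_h(pCa, p):
    """Calcium-mediated inactivation: Hill function evaluated in pCa form.

    ``h = 1/(1 + ([Ca]/KCa)^nCa) = 1/(1 + exp(nCa ln10 (pCa - pKCa)))``.
    """
    z = p.nCa * LN10 * (np.asarray(pCa, float) - p.pKCa)
    return 1.0 / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


def kca_activation(pCa, p):
    """Hill activation of the calcium-gated K+ current, in pCa form."""
    z = p.nKCa * LN10 * (p.pKKCa - np.asarray(pCa, float))
    return 1.0 / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


def leak_current(V, p):
    """Leak current gL (EL - V), nA."""
    return p.gL * (p.EL - np.asarray(V, float)) * NS_MV_TO_NA


def kir_current(V, nKir, p: KirParams, EK: float):
    """Inward rectifier current gKir nKir^p (EK - V), nA."""
    return p.gKir * np.asarray(nKir, float) ** p.p_gates \
        * (EK - np.asarray(V, float)) * NS_MV_TO_NA


def kd_current(V, nKd, p: KdParams, EK: float):
    """Delayed rectifier current gKd n^2 (EK - V), nA."""
    return p.gKd * np.asarray(nKd, float) ** 2 \
        * (EK - np.asarray(V, float)) * NS_MV_TO_NA


def ca_current(V, mCa, pCa, p):
    """Ciliary calcium current gCa m^2 h f_GHK(V), nA (positive = inward)."""
    return p.gCa * np.asarray(mCa, float) ** 2 * ca_h(pCa, p) * ghk_factor(V)


def kca_current(V, pCa, p, EK: float):
    """Calcium-activated K+ current gKCa m([Ca]) (EK - V), nA."""
    return p.gKCa * kca_activation(pCa, p) \
        * (EK - np.asarray(V, float)) * NS_MV_TO_NA


def calcium_derivative(pCa, I_Ca, p, v_cilia: float = V_CILIA):
    """d(pCa)/dt in 1/s, equivalent to the concentration-form equation.

    ``dpCa/dt = [ I_Ca/(2 F v Ca0) 10^-pCa + lambda (10^-pCa - 1)
    - (J/Ca0)/(1 + 10^pCa) ] / ln10``.
    """
    pCa = np.asarray(pCa, float)
    influx = np.asarray(I_Ca, float) * ca_influx_rate_per_nA(v_cilia) / CA_REST
    ten_neg = np.power(10.0, -np.clip(pCa, -300.0, 300.0))
    ten_pos = np.power(10.0, np.clip(pCa, -300.0, 300.0))
    d = (influx * ten_neg
         + p.lambda_ * (ten_neg - 1.0)
         - (p.J / CA_REST) / (1.0 + ten_pos)) / LN10
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite calcium derivative")
    return d


# --------------------------------------------------------------------------
# state and integration
# --------------------------------------------------------------------------

@dataclass
class MembraneState:
    """Instantaneous dynamical state (scalars or aligned arrays).

    ``In`` is the Ornstein-Uhlenbeck noise current in pA; ``pCa`` is
    log10([Ca]/[Ca]_0).  ``trans`` is an opaque slot owned by the
    transduction module.
    """
    V: np.ndarray | float = -24.0
    nKir: np.ndarray | float = 0.0
    nKd: np.ndarray | float = 0.0
    mCa: np.ndarray | float = 0.0
    pCa: np.ndarray | float = 0.0
    In: np.ndarray | float = 0.0
    trans: object = None

    def Ca(self):
        """Calcium concentration in uM."""
        return CA_REST * np.power(10.0, self.pCa)

    def copy(self) -> "MembraneState":
        return MembraneState(
            V=np.copy(self.V), nKir=np.copy(self.nKir), nKd=np.copy(self.nKd),
            mCa=np.copy(self.mCa), pCa=np.copy(self.pCa), In=np.copy(self.In),
            trans=self.trans)


def membrane_currents(state: MembraneState, params: CellParams):
    """All ionic currents at the given state, as a dict of nA values."""
    V = state.V
    EK = params.passive.EK
    out = {
        "I_L": leak_current(V, params.passive),
        "I_Kd": kd_current(V, state.nKd, params.kd, EK),
        "I_Ca": ca_current(V, state.mCa, state.pCa, params.ca),
        "I_KCa": kca_current(V, state.pCa, params.kca, EK),
    }
    if params.kir_enabled:
        out["I_Kir"] = kir_current(V, state.nKir, params.kir, EK)
    return out


def membrane_derivatives(state: MembraneState, params: CellParams,
                         I_ext=0.0):
    """Time derivatives of (V, nKir, nKd, mCa, pCa).

    Returns a dict with dV in mV/ms, gating derivatives in 1/ms and dpCa in
    1/ms.  ``I_ext`` is in nA; the noise current state (pA) is added
    internally.
    """
    cur = membrane_currents(state, params)
    I_total = sum(cur.values()) + np.asarray(I_ext, float) \
        + np.asarray(state.In, float) * 1e-3
    dV = 1e3 * I_total / params.passive.C          # pF, nA -> mV/ms

    n_inf, tau_n = kd_rates(state.V, params.kd)
    dnKd = (n_inf - state.nKd) / tau_n
    m_inf = ca_m_steady(state.V, params.ca)
    dmCa = (m_inf - state.mCa) / params.ca.tau_m
    dpCa = calcium_derivative(state.pCa, cur["I_Ca"], params.cadyn) * 1e-3
    if params.kir_enabled:
        dnKir = (kir_steady(state.V, params.kir) - state.nKir) \
            / params.kir.tauKir
    else:
        dnKir = np.zeros_like(np.asarray(state.nKir, float))
    return {"V": dV, "nKir": dnKir, "nKd": dnKd, "mCa": dmCa, "pCa": dpCa}


def step_euler(state: MembraneState, params: CellParams, I_ext=0.0,
               dt: float = 0.1) -> MembraneState:
    """One forward-Euler step of the membrane equations (dt in ms).

    Gating variables are clipped to [0, 1] after the update (forward Euler
    can overshoot at dt = 0.1 ms).  Raises on a non-finite state.
    """
    d = membrane_derivatives(state, params, I_ext)
    V = state.V + dt * d["V"]
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("membrane potential became non-finite")
    return MembraneState(
        V=V,
        nKir=np.clip(state.nKir + dt * d["nKir"], 0.0, 1.0),
        nKd=np.clip(state.nKd + dt * d["nKd"], 0.0, 1.0),
        mCa=np.clip(state.mCa + dt * d["mCa"], 0.0, 1.0),
        pCa=state.pCa + dt * d["pCa"],
        In=state.In,
        trans=state.trans,
    )


def ou_noise_step(In, dt: float, p, rng: np.random.Generator, size=None):
    """Exact Ornstein-Uhlenbeck update of the noise current (pA).

    ``In' = In e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) N(0,1)`` so the
    stationary distribution has mean 0 and standard deviation ``sigma_n``.
    """
    decay = math.exp(-dt / p.tau_n)
    if p.sigma_n == 0.0:
        return np.asarray(In, float) * decay if size else In * decay
    amp = p.sigma_n * math.sqrt(1.0 - decay * decay)
    noise = rng.standard_normal(size) if size else rng.standard_normal()
    return In * decay + amp * noise


def electrode_inject(I_cmd, V, V2, p, dt: float):
    """RC electrode update: returns (V2', Ie).

    ``tau_e dV2/dt = V - V2 + Re I + dV``; the injected current is
    ``Ie = (V2 - V - dV)/Re``.  The update is the exact exponential solution
    over dt assuming V and I constant, so a steady command gives Ie -> I with
    time constant tau_e; the tip-potential offset dV cancels from Ie.
    """
    target = np.asarray(V, float) + p.Re * np.asarray(I_cmd, float) + p.dV
    decay = math.exp(-dt / p.tau_e)
    V2n = target + (np.asarray(V2, float) - target) * decay
    Ie = (V2n - V - p.dV) / p.Re
    return V2n, Ie


# --------------------------------------------------------------------------
# resting state
# --------------------------------------------------------------------------

def steady_state_init(params: CellParams, V0: Optional[float] = None,
                      balance: bool = True):
    """Resting state with [Ca2+] = [Ca2+]_0 at the configured potential.

    Places the resting fixed point exactly at ``V0`` (default
    ``params.V_rest``): gating variables take their steady-state values, and
    when ``balance`` is true the leak reversal ``EL`` is solved so the net
    ionic current vanishes at ``V0`` and the pump rate is set to
    ``J = I_Ca(rest)/(F v)`` so the calcium derivative vanishes at
    [Ca2+]_0 (mirroring the resting-calcium constraint of the fitting
    procedure, which ties tip-potential-aligned rest and pump rate together).

    Returns ``(state, balanced_params)``; the input is not modified.
    """
    params = params.copy()
    if V0 is None:
        V0 = params.V_rest
    else:
        params.V_rest = float(V0)
    pas = params.passive

    def _state_at(V):
        n_inf, _ = kd_rates(V, params.kd)
        return MembraneState(
            V=float(V),
            nKir=float(kir_steady(V, params.kir)) if params.kir_enabled else 0.0,
            nKd=float(n_inf),
            mCa=float(ca_m_steady(V, params.ca)),
            pCa=0.0,
            In=0.0,
        )

    st = _state_at(V0)
    cur = membrane_currents(st, params)
    I_other = sum(v for k, v in cur.items() if k != "I_L")
    if balance:
        # leak cancels every other current at V0: EL = V0 - I_other/gL
        pas.EL = float(V0 - I_other / (pas.gL * NS_MV_TO_NA))
        # pump cancels resting calcium influx: J = I_rest/(F v) in uM/s
        I_rest = float(cur["I_Ca"])
        params.cadyn.J = max(I_rest, 0.0) * 1e12 / (FARADAY * V_CILIA)
        if pas.EK >= pas.EL:
            raise ValueError(
                f"balanced EL ({pas.EL:.2f} mV) fell below EK ({pas.EK} mV); "
                "no biophysical resting state at V0")
    else:
        # find the natural resting potential by bisection on the net current
        def net(V):
            c = membrane_currents(_state_at(V), params)
            return float(sum(c.values()))
        lo, hi = pas.EK + 1e-6, -1.0
        if net(lo) * net(hi) > 0:
            raise ValueError("no resting fixed point between EK and -1 mV")
        V0 = brentq(net, lo, hi, xtol=1e-10)
        params.V_rest = float(V0)
        st = _state_at(V0)
    return _state_at(params.V_rest), params


# --------------------------------------------------------------------------
# protocols and traces
# --------------------------------------------------------------------------

class BatchStepper:
    """Fused forward-Euler integrator for populations (no inward rectifier).

    Semantically identical to repeated :func:`step_euler` calls (same
    update order, same clipping), with parameter constants hoisted and
    in-place array arithmetic; used by the closed-loop engines where the
    membrane substep loop dominates run time.
    """

    def __init__(self, params: CellParams):
        if params.kir_enabled:
            raise ValueError("BatchStepper covers the ciliated model "
                             "(inward rectifier disabled)")
        pas, kd, ca, kca, dyn = (params.passive, params.kd, params.ca,
                                 params.kca, params.cadyn)
        self.inv_C = 1e3 / pas.C
        self.gL = pas.gL * NS_MV_TO_NA
        self.EL = pas.EL
        self.EK = pas.EK
        self.gKd = kd.gKd * NS_MV_TO_NA
        self.VKd, self.kKd = kd.VKd, kd.kKd
        self.aKd, self.bKd = kd.aKd, kd.bKd
        self.Vtau, self.ktau = kd.tau_center(), kd.tau_slope()
        self.gCa = ca.gCa
        self.VCa, self.kCa, self.tau_m = ca.VCa, ca.kCa, ca.tau_m
        self.hz = ca.nCa * LN10
        self.pKCa = ca.pKCa
        self.gKCa = kca.gKCa * NS_MV_TO_NA
        self.kcz = kca.nKCa * LN10
        self.pKKCa = kca.pKKCa
        self.influx = ca_influx_rate_per_nA() / CA_REST * 1e-3 / LN10
        self.lam = dyn.lambda_ * 1e-3 / LN10
        self.pump = dyn.J / CA_REST * 1e-3 / LN10
        self.x_of_V = 2.0 / RT_OVER_F
        self.noise = params.noise

    def run(self, state: MembraneState, I_ext, dt: float, n_steps: int,
            rng: Optional[np.random.Generator] = None) -> None:
        """Advance ``state`` in place by ``n_steps`` Euler steps of dt (ms)."""
        V = np.asarray(state.V, float)
        nKd = np.asarray(state.nKd, float)
        mCa = np.asarray(state.mCa, float)
        pCa = np.asarray(state.pCa, float)
        In = np.asarray(state.In, float)
        size = V.shape if V.ndim else None
        if rng is not None:
            decay = math.exp(-dt / self.noise.tau_n)
            amp = self.noise.sigma_n * math.sqrt(1.0 - decay * decay)
        for _ in range(n_steps):
            if rng is not None:
                In = In * decay + amp * rng.standard_normal(size)
            x = np.clip(self.x_of_V * V, -700.0, 700.0)
            fghk = np.where(np.abs(x) < 1e-10, 1.0 - 0.5 * x,
                            x / np.expm1(np.where(np.abs(x) < 1e-10, 1.0, x)))
            h = 1.0 / (1.0 + np.exp(np.clip(
                self.hz * (pCa - self.pKCa), -500.0, 500.0)))
            ICa = self.gCa * mCa * mCa * h * fghk
            mk = 1.0 / (1.0 + np.exp(np.clip(
                self.kcz * (self.pKKCa - pCa), -500.0, 500.0)))
            ten_neg = np.exp(np.clip(-LN10 * pCa, -600.0, 600.0))
            ten_pos = np.exp(np.clip(LN10 * pCa, -600.0, 600.0))
            dpCa = (ICa * self.influx * ten_neg
                    + self.lam * (ten_neg - 1.0)
                    - self.pump / (1.0 + ten_pos))
            I_tot = (self.gL * (self.EL - V)
                     + self.gKd * nKd * nKd * (self.EK - V)
                     + ICa
                     + self.gKCa * mk * (self.EK - V)
                     + I_ext + In * 1e-3)
            n_inf = 1.0 / (1.0 + np.exp((self.VKd - V) / self.kKd))
            tau_n = self.aKd + self.bKd / np.cosh((V - self.Vtau) / self.ktau)
            m_inf = 1.0 / (1.0 + np.exp((self.VCa - V) / self.kCa))
            V = V + dt * self.inv_C * I_tot
            nKd = np.clip(nKd + dt * (n_inf - nKd) / tau_n, 0.0, 1.0)
            mCa = np.clip(mCa + dt * (m_inf - mCa) / self.tau_m, 0.0, 1.0)
            pCa = pCa + dt * dpCa
        if not np.all(np.isfinite(V)):
            raise FloatingPointError("membrane potential became non-finite")
        state.V, state.nKd, state.mCa, state.pCa, state.In = \
            V, nKd, mCa, pCa, In


@dataclass
class PulseProtocol:
    """Square current pulses: pre/post padding around a constant step."""
    amplitudes: Sequence[float]          # nA
    duration: float = 100.0              # ms
    t_pre: float = 100.0                 # ms
    t_post: float = 500.0                # ms
    dt: float = 0.1                      # ms

    @property
    def total(self) -> float:
        return self.t_pre + self.duration + self.t_post

    def command(self, t):
        """Command current at time(s) t (ms) for every amplitude: (nT, nA)."""
        t = np.atleast_1d(np.asarray(t, float))
        on = (t[:, None] >= self.t_pre) \
            & (t[:, None] < self.t_pre + self.duration)
        return on * np.asarray(self.amplitudes, float)[None, :]


@dataclass
class Trace:
    """Uniformly sampled simulated recording with per-current breakdown."""
    t: np.ndarray                        # ms
    V: np.ndarray                        # mV
    I_command: np.ndarray                # nA
    I_injected: np.ndarray               # nA
    currents: dict = field(default_factory=dict)   # name -> nA series
    Ca: np.ndarray = None                # uM
    alpha: np.ndarray = None             # deg, ciliary angle

    def to_frame(self):
        import pandas as pd
        data = {"t_ms": self.t, "I_command_nA": self.I_command,
                "I_injected_nA": self.I_injected, "V_mV": self.V}
        for name, series in self.currents.items():
            data[name] = series
        if self.Ca is not None:
            data["Ca_uM"] = self.Ca
        if self.alpha is not None:
            data["alpha_deg"] = self.alpha
        return pd.DataFrame(data)


def simulate_membrane(params: CellParams, I_of_t: np.ndarray, dt: float = 0.1,
                      state: Optional[MembraneState] = None,
                      noise_rng: Optional[np.random.Generator] = None,
                      electrode: bool = False,
                      record: bool = True):
    """Integrate the membrane for a command-current matrix.

    ``I_of_t`` has shape (nT,) or (nT, nBatch); all batch members share
    parameters but receive their own command column.  If ``electrode`` is
    true the command is low-pass filtered by the RC electrode model and the
    recorded ``I_injected`` is the filtered current.

    Returns ``(records, final_state)`` where records is a dict of arrays
    shaped like ``I_of_t`` (empty when ``record`` is false).
    """
    I_of_t = np.asarray(I_of_t, float)
    squeeze = I_of_t.ndim == 1
    if squeeze:
        I_of_t = I_of_t[:, None]
    nT, nB = I_of_t.shape

    if state is None:
        state, params = steady_state_init(params)
    st = MembraneState(
        V=np.full(nB, state.V, float) if np.ndim(state.V) == 0 else np.array(state.V, float),
        nKir=np.full(nB, state.nKir, float) if np.ndim(state.nKir) == 0 else np.array(state.nKir, float),
        nKd=np.full(nB, state.nKd, float) if np.ndim(state.nKd) == 0 else np.array(state.nKd, float),
        mCa=np.full(nB, state.mCa, float) if np.ndim(state.mCa) == 0 else np.array(state.mCa, float),
        pCa=np.full(nB, state.pCa, float) if np.ndim(state.pCa) == 0 else np.array(state.pCa, float),
        In=np.full(nB, state.In, float) if np.ndim(state.In) == 0 else np.array(state.In, float),
    )
    V2 = st.V + params.electrode.Re * I_of_t[0] + params.electrode.dV \
        if electrode else None

    names = ["I_L", "I_Kd", "I_Ca", "I_KCa"] \
        + (["I_Kir"] if params.kir_enabled else [])
    rec = {}
    if record:
        rec = {k: np.empty((nT, nB)) for k in
               ["V", "Ca", "I_injected", *names]}
        if electrode:
            rec["V2"] = np.empty((nT, nB))

    for i in range(nT):
        I_cmd = I_of_t[i]
        if electrode:
            V2, I_inj = electrode_inject(I_cmd, st.V, V2, params.electrode, dt)
        else:
            I_inj = I_cmd
        if noise_rng is not None:
            st.In = ou_noise_step(st.In, dt, params.noise, noise_rng,
                                  size=nB)
        if record:
            cur = membrane_currents(st, params)
            rec["V"][i] = st.V
            rec["Ca"][i] = st.Ca()
            rec["I_injected"][i] = I_inj
            if electrode:
                rec["V2"][i] = V2
            for k in names:
                rec[k][i] = cur[k]
        st = step_euler(st, params, I_ext=I_inj, dt=dt)

    if record and squeeze:
        rec = {k: v[:, 0] for k, v in rec.items()}
    return rec, st


def run_protocol(params: CellParams, protocol: PulseProtocol,
                 noise_rng: Optional[np.random.Generator] = None,
                 electrode: bool = False):
    """Simulate a pulse protocol; one :class:`Trace` per amplitude.

    Traces include the per-current decomposition, calcium and the ciliary
    angle from the electromotor coupling.  Deterministic for a given rng
    seed.
    """
    t = np.arange(0.0, protocol.total, protocol.dt)
    I = protocol.command(t)
    rec, _ = simulate_membrane(params, I, dt=protocol.dt,
                               noise_rng=noise_rng, electrode=electrode)
    traces = []
    for j, amp in enumerate(protocol.amplitudes):
        Ca = rec["Ca"][:, j]
        traces.append(Trace(
            t=t.copy(), V=rec["V"][:, j], I_command=I[:, j],
            I_injected=rec["I_injected"][:, j],
            currents={k: rec[k][:, j] for k in rec
                      if k.startswith("I_") and k != "I_injected"},
            Ca=Ca,
            alpha=_em.cilia_angle(Ca, params.electromotor),
        ))
    return traces
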