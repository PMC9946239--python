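"""Parameter containers for the membrane, calcium and motor models.

Each dataclass documents its units and checks its own biophysical
invariants.  :class:`CellParams` aggregates all sections and round-trips to
plain dictionaries (and hence YAML/TOML configs).

Bundled presets (:func:`preset`) are the median fitted parameters of the
three recording configurations: ``table1_median`` (hyperpolarized responses,
leak + inward rectifier), ``table2_median`` (deciliated cells, leak + delayed
rectifier) and ``table3_median`` (ciliated cells, full action-potential model
with electromotor coupling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, fields as _dc_fields
from typing import Optional

from .constants import CA_REST

__all__ = [
    "PassiveParams", "KirParams", "KdParams", "CaChannelParams", "KCaParams",
    "CaDynParams", "ElectrodeParams", "NoiseParams", "ElectromotorParams",
    "CellParams", "preset", "PRESET_NAMES",
]


class ParameterError(ValueError):
    """A parameter violates its biophysical invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class PassiveParams:
    """Membrane capacitance and leak; K+ reversal potential."""
    C: float = 289.10        # pF
    gL: float = 9.52         # nS
    EL: float = -23.30       # mV
    EK: float = -48.0        # mV

    def validate(self) -> None:
        _require(self.C > 0, f"passive.C must be > 0 pF, got {self.C}")
        _require(self.gL > 0, f"passive.gL must be > 0 nS, got {self.gL}")
        _require(self.EK < self.EL,
                 f"passive.EK ({self.EK}) must be below EL ({self.EL})")


@dataclass
class KirParams:
    """Inward rectifier K+ current, activated by hyperpolarization below EK."""
    gKir: float = 873.36     # nS
    VKir: float = -120.75    # mV, half-activation
    kKir: float = 30.23      # mV, activation slope
    tauKir: float = 15.10    # ms
    p_gates: int = 2

    def validate(self) -> None:
        _require(self.gKir >= 0, "kir.gKir must be >= 0")
        _require(self.kKir > 0, "kir.kKir must be > 0")
        _require(self.tauKir > 0, "kir.tauKir must be > 0")
        _require(self.p_gates in (1, 2), "kir.p_gates must be 1 or 2")


@dataclass
class KdParams:
    """Delayed rectifier K+ current (Boltzmann n^2 model).

    ``tau(V) = aKd + bKd / cosh((V - VtauKd)/ktauKd)`` peaks at ``aKd + bKd``.
    The *simplified* variant enforces ``VtauKd = VKd`` and ``ktauKd = 2 kKd``
    (opening/closing rates of the form exp(+-V/k)).
    """
    gKd: float = 114.76      # nS
    VKd: float = 4.19        # mV, half-activation
    kKd: float = 4.89        # mV, activation slope
    aKd: float = 0.1         # ms, floor of the time constant
    bKd: float = 4.50        # ms, peak amplitude of the time constant
    VtauKd: Optional[float] = None   # mV; None -> VKd (simplified)
    ktauKd: Optional[float] = None   # mV; None -> 2*kKd (simplified)
    simplified: bool = True

    def tau_center(self) -> float:
        if self.simplified or self.VtauKd is None:
            return self.VKd
        return self.VtauKd

    def tau_slope(self) -> float:
        if self.simplified or self.ktauKd is None:
            return 2.0 * self.kKd
        return self.ktauKd

    def validate(self) -> None:
        _require(self.gKd >= 0, "kd.gKd must be >= 0")
        _require(self.kKd > 0, "kd.kKd must be > 0")
        _require(self.aKd >= 0, "kd.aKd must be >= 0")
        _require(self.bKd > 0, "kd.bKd must be > 0")
        _require(self.tau_slope() > 0, "kd.ktauKd must be > 0")


@dataclass
class CaChannelParams:
    """Ciliary voltage-gated Ca2+ current (GHK, calcium-inactivated).

    The extracellular concentration is lumped into ``gCa``, which is
    homogeneous to a current (nA).  Inactivation is a Hill function of
    intraciliary [Ca2+] with ``nCa`` binding sites and half-inactivation
    ``KCa``.
    """
    gCa: float = 226.63      # nA
    VCa: float = -1.33       # mV, half-activation
    kCa: float = 4.35        # mV, activation slope
    tau_m: float = 0.94      # ms, activation time constant
    KCa: float = 3.7         # uM, half-inactivation
    nCa: float = 4.25        # binding sites

    @property
    def pKCa(self) -> float:
        """log10(KCa / Ca_rest): half-inactivation in pCa units."""
        return math.log10(self.KCa / CA_REST)

    def validate(self) -> None:
        _require(self.gCa >= 0, "ca.gCa must be >= 0")
        _require(self.kCa > 0, "ca.kCa must be > 0")
        _require(self.tau_m > 0, "ca.tau_m must be > 0")
        _require(self.KCa > 0, "ca.KCa must be > 0")
        _require(self.nCa >= 1, "ca.nCa must be >= 1")


@dataclass
class KCaParams:
    """Calcium-activated K+ current (Hill activation by [Ca2+])."""
    gKCa: float = 216.51     # nS
    KKCa: float = 63.0       # uM, half-activation
    nKCa: float = 2.94       # binding sites

    @property
    def pKKCa(self) -> float:
        return math.log10(self.KKCa / CA_REST)

    def validate(self) -> None:
        _require(self.gKCa >= 0, "kca.gKCa must be >= 0")
        _require(self.KKCa > 0, "kca.KKCa must be > 0")
        _require(self.nKCa >= 1, "kca.nKCa must be >= 1")


@dataclass
class CaDynParams:
    """Intraciliary calcium removal: linear decay plus a saturating pump.

    ``lambda_`` is the linear removal rate and ``J`` the maximum pump rate of
    the high-affinity process operating near rest.  At the resting state the
    pump exactly cancels the resting calcium influx, ``J = I_rest/(F v)``
    (enforced by :func:`paramecium.ephys.steady_state_init`).
    """
    lambda_: float = 7.79    # 1/s
    J: float = 86.602        # uM/s

    def validate(self) -> None:
        _require(self.lambda_ >= 0, "cadyn.lambda_ must be >= 0")
        _require(self.J >= 0, "cadyn.J must be >= 0")


@dataclass
class ElectrodeParams:
    """Injecting electrode as an RC circuit (used for current-clamp fits)."""
    Re: float = 121.0        # MOhm
    tau_e: float = 1.0       # ms
    dV: float = 0.0          # mV tip-potential offset

    def validate(self) -> None:
        _require(self.Re > 0, "electrode.Re must be > 0")
        _require(self.tau_e > 0, "electrode.tau_e must be > 0")


@dataclass
class NoiseParams:
    """Ornstein-Uhlenbeck membrane noise current.

    ``sigma_n`` is the *stationary standard deviation* of the noise current,
    in pA.  Calibrated so the resting model produces spontaneous action
    potentials at ~0.2 Hz.
    """
    tau_n: float = 20.0      # ms
    sigma_n: float = 9.0     # pA (stationary sd)

    def validate(self) -> None:
        _require(self.tau_n > 0, "noise.tau_n must be > 0")
        _require(self.sigma_n >= 0, "noise.sigma_n must be >= 0")


@dataclass
class ElectromotorParams:
    """Coupling from intraciliary [Ca2+] to ciliary angle and kinematics.

    The ciliary angle is a Hill function rising from ``alpha0`` to
    ``alpha0 + dAlpha`` around the reversal threshold ``Kmotor``; the axial
    velocity changes sign at ``Kmotor``; the rotation-axis tilt ``theta`` and
    spin ``omega`` are log-symmetric bells peaking at ``Kmotor``.
    """
    alpha0: float = 11.0         # deg, resting ciliary angle
    dAlpha: float = 160.0        # deg, reversal amplitude
    Kmotor: float = 2.4          # uM, reversal threshold
    nmotor: float = 7.02         # Hill sites (ciliary angle)
    vmax: float = 500.0          # um/s
    thetaMin: float = 13.0       # deg
    thetaMax: float = 90.0       # deg
    omegaMin: float = 2.0 * math.pi   # rad/s (1 cycle/s)
    omegaMax: float = 8.0 * math.pi   # rad/s (4 cycles/s)

    @property
    def pKmotor(self) -> float:
        return math.log10(self.Kmotor / CA_REST)

    def validate(self) -> None:
        _require(self.Kmotor > 0, "electromotor.Kmotor must be > 0")
        _require(self.nmotor >= 1, "electromotor.nmotor must be >= 1")
        _require(self.thetaMax >= self.thetaMin,
                 "electromotor.thetaMax must be >= thetaMin")
        _require(self.omegaMax >= self.omegaMin,
                 "electromotor.omegaMax must be >= omegaMin")
        _require(self.vmax > 0, "electromotor.vmax must be > 0")


_SECTION_TYPES = {
    "passive": PassiveParams,
    "kir": KirParams,
    "kd": KdParams,
    "ca": CaChannelParams,
    "kca": KCaParams,
    "cadyn": CaDynParams,
    "electrode": ElectrodeParams,
    "noise": NoiseParams,
    "electromotor": ElectromotorParams,
}


@dataclass
class CellParams:
    """Complete parameter record of one model cell.

    ``kir_enabled`` selects the hyperpolarized model variant; the behavioral
    (ciliated) model excludes the inward rectifier.  ``V_rest`` is the target
    resting potential at which the cell is initialized (leak reversal and
    pump rate are balanced there, see
    :func:`paramecium.ephys.steady_state_init`).
    """
    passive: PassiveParams = field(default_factory=PassiveParams)
    kir: KirParams = field(default_factory=KirParams)
    kd: KdParams = field(default_factory=KdParams)
    ca: CaChannelParams = field(default_factory=CaChannelParams)
    kca: KCaParams = field(default_factory=KCaParams)
    cadyn: CaDynParams = field(default_factory=CaDynParams)
    electrode: ElectrodeParams = field(default_factory=ElectrodeParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    electromotor: ElectromotorParams = field(default_factory=ElectromotorParams)
    kir_enabled: bool = False
    V_rest: float = -25.0    # mV

    def validate(self) -> "CellParams":
        for name in _SECTION_TYPES:
            getattr(self, name).validate()
        return self

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTION_TYPES}
        d["kir_enabled"] = self.kir_enabled
        d["V_rest"] = self.V_rest
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        kwargs = {}
        for key, value in d.items():
            if key in _SECTION_TYPES:
                typ = _SECTION_TYPES[key]
                known = {f.name for f in _dc_fields(typ)}
                unknown = set(value) - known
                if unknown:
                    raise ParameterError(
                        f"unknown keys in section [{key}]: {sorted(unknown)}")
                kwargs[key] = typ(**value)
            elif key in ("kir_enabled", "V_rest"):
                kwargs[key] = value
            else:
                raise ParameterError(f"unknown config section: {key!r}")
        return cls(**kwargs).validate()

    def copy(self) -> "CellParams":
        return CellParams.from_dict(self.to_dict())


def _table1_median() -> CellParams:
    """Hyperpolarized-response medians: leak + inward rectifier only."""
    p = CellParams(
        passive=PassiveParams(C=278.82, gL=7.11, EL=-19.03, EK=-47.92),
        kir=KirParams(gKir=873.36, VKir=-120.75, kKir=30.23, tauKir=15.10),
        kd=KdParams(gKd=0.0),
        ca=CaChannelParams(gCa=0.0),
        kca=KCaParams(gKCa=0.0),
        kir_enabled=True,
        V_rest=-22.51,
    )
    return p.validate()


def _table2_median() -> CellParams:
    """Deciliated-cell medians: leak + delayed rectifier (Boltzmann n^2)."""
    p = CellParams(
        passive=PassiveParams(C=145.61, gL=9.72, EL=-18.33, EK=-56.38),
        kd=KdParams(gKd=100.11, VKd=21.31, kKd=6.61, aKd=0.1, bKd=4.40,
                    VtauKd=23.09, ktauKd=11.74, simplified=False),
        ca=CaChannelParams(gCa=0.0),
        kca=KCaParams(gKCa=0.0),
        kir_enabled=False,
        V_rest=-18.33,
    )
    return p.validate()


def _table3_median() -> CellParams:
    """Ciliated-cell medians: the full action-potential/motor model.

    The resting potential target is -25 mV.  The median-parameter cell is
    unstable at the population-median rest (-22 mV); -25 mV lies within
    the population spread (V0 = -24.5 +/- 10.6 mV), is comfortably stable,
    and reproduces the calibrated spontaneous action-potential rate of
    ~0.2 Hz under the standard 9 pA Ornstein-Uhlenbeck noise current (see
    docs/methods.md).
    """
    p = CellParams(
        passive=PassiveParams(C=289.10, gL=9.52, EL=-23.30, EK=-48.0),
        kd=KdParams(gKd=114.76, VKd=4.19, kKd=4.89, aKd=0.1, bKd=4.50,
                    simplified=True),
        ca=CaChannelParams(gCa=226.63, VCa=-1.33, kCa=4.35, tau_m=0.94,
                           KCa=3.7, nCa=4.25),
        kca=KCaParams(gKCa=216.51, KKCa=63.0, nKCa=2.94),
        cadyn=CaDynParams(lambda_=7.79, J=86.602),
        electromotor=ElectromotorParams(nmotor=7.02, Kmotor=2.4),
        kir_enabled=False,
        V_rest=-25.0,
    )
    return p.validate()


_PRESETS = {
    "table1_median": _table1_median,
    "table2_median": _table2_median,
    "table3_median": _table3_median,
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> CellParams:
    """Return a bundled median parameter set by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None
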