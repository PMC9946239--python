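"""Physical constants and canonical units.

Canonical units used throughout the package:

====================  ==========
quantity              unit
====================  ==========
voltage               mV
current               nA
conductance           nS
capacitance           pF
time                  ms
concentration         uM
length                um
====================  ==========

Derived consistency constants:

* ``g [nS] * V [mV] = I [pA] = 1e-3 nA`` — conductance-based currents carry a
  factor ``1e-3`` to come out in nA (:data:`NS_MV_TO_NA`).
* ``dV/dt [mV/ms] = 1e3 * I [nA] / C [pF]``.
* A calcium current of 1 nA into the ciliary volume of 1700 um^3 raises
  concentration at ``1e12 / (2 F v)`` uM/s ~= 3049 uM/s
  (:func:`ca_influx_rate_per_nA`).
"""

import numpy as np

#: Faraday constant, C/mol.
FARADAY = 96485.0

#: Temperature, K (20 degrees C).
TEMPERATURE = 293.0

#: Gas constant, J/(mol K).
GAS_CONSTANT = 8.314462618

#: RT/F at 293 K, in mV.
RT_OVER_F = GAS_CONSTANT * TEMPERATURE / FARADAY * 1e3  # 25.26 mV

#: Calcium valence.
Z_CA = 2

#: Resting intraciliary calcium concentration, uM.
CA_REST = 0.1

#: Intraciliary volume, um^3.
V_CILIA = 1700.0

#: nS * mV expressed in nA.
NS_MV_TO_NA = 1e-3

LN10 = float(np.log(10.0))


def ca_influx_rate_per_nA(v_cilia_um3: float = V_CILIA) -> float:
    """Concentration rate (uM/s) produced by a 1 nA calcium current.

    ``I / (2 F v)`` with I in amperes and v in litres, rescaled to uM/s per
    nA.  For the default ciliary volume this is ~3048.8 uM/s.
    """
    # 1 nA = 1e-9 A; v um^3 = v * 1e-15 L; mol/L/s -> uM/s is 1e6
    return 1e12 / (2.0 * FARADAY * v_cilia_um3)
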