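"""Forward-Euler integration kernels (numba-compiled).

All kernels use the same unit system: voltage in mV, time in ms, current in
pA, conductance in nS, capacitance in pF (so pA/pF = mV/ms and nS*mV = pA).
Each kernel consumes a pre-built injected-current array (one sample per time
step) and returns the voltage trace plus spike sample indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["elif_euler", "passive_lif_euler", "hh_euler"]


@njit(cache=True)
def elif_euler(v0, dt, I, C, gL, EL, VT, DT, Vr, Vcut, gsh, Esh):
    """Exponential integrate-and-fire with optional linear shunt.

    C dV/dt = I + gL*DT*exp((V-VT)/DT) - gL*(V-EL) - gsh*(V-Esh)

    A spike is recorded at the first sample where V >= Vcut; the voltage is
    reset to Vr at that sample before the next Euler step.
    """
    n = I.shape[0]
    V = np.empty(n)
    spikes = np.empty(n // 8 + 16, dtype=np.int64)
    nsp = 0
    v = v0
    for i in range(n):
        if v >= Vcut:
            spikes[nsp] = i
            nsp += 1
            v = Vr
        V[i] = v
        dv = (I[i] + gL * DT * np.exp((v - VT) / DT)
              - gL * (v - EL) - gsh * (v - Esh)) / C
        v = v + dt * dv
    return V, spikes[:nsp]


@njit(cache=True)
def passive_lif_euler(v0, dt, I, C, g, E, Vth, Vr, gsh, Esh):
    """Passive (standard) leaky integrate-and-fire with artificial threshold."""
    n = I.shape[0]
    V = np.empty(n)
    spikes = np.empty(n // 8 + 16, dtype=np.int64)
    nsp = 0
    v = v0
    for i in range(n):
        if v >= Vth:
            spikes[nsp] = i
            nsp += 1
            v = Vr
        V[i] = v
        dv = (I[i] - g * (v - E) - gsh * (v - Esh)) / C
        v = v + dt * dv
    return V, spikes[:nsp]


@njit(cache=True)
def hh_euler(v0, n0, dt, I, C, gNa, gNap, gK, gleak, ENa, EK, EL,
             tau_n, m_half, m_k, n_half, n_k, p_half, p_k, ginh, Einh):
    """Reduced two-variable Hodgkin-Huxley model.

    m and p equilibrate instantaneously with voltage; h ~= 1 - n; n relaxes
    to its sigmoid steady state with time constant tau_n. Spikes are detected
    afterwards by threshold crossing on the returned voltage trace.
    """
    nsteps = I.shape[0]
    V = np.empty(nsteps)
    N = np.empty(nsteps)
    v = v0
    nn = n0
    for i in range(nsteps):
        V[i] = v
        N[i] = nn
        m = 1.0 / (1.0 + np.exp(-(v - m_half) / m_k))
        p = 1.0 / (1.0 + np.exp(-(v - p_half) / p_k))
        ninf = 1.0 / (1.0 + np.exp(-(v - n_half) / n_k))
        ion = (gNa * m * (1.0 - nn) * (v - ENa)
               + gNap * p * (v - ENa)
               + gK * nn * (v - EK)
               + gleak * (v - EL)
               + ginh * (v - Einh))
        dv = (I[i] - ion) / C
        dn = (ninf - nn) / tau_n
        v = v + dt * dv
        nn = nn + dt * dn
    return V, N
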