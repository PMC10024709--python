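"""Numba kernels for the 5 kHz membrane/dynamic-clamp integration loop.

The membrane ODE is integrated with fixed-step forward Euler for V and
Rush–Larsen exponential updates for every Hodgkin–Huxley gate, with
``n_sub`` substeps inside each 0.2 ms acquisition sample. The injected
I_K1 is recomputed once per sample from the voltage at the sample start
and held constant within it (zero-order hold), emulating a real-time
loop that computes the current within one sampling interval.

The same scalar helpers drive both the whole-run kernel and the
per-sample session path so the two produce bit-identical trajectories.
"""

import numpy as np
from numba import njit

# Fixed cell-model constants (mV). EK of the cell's own K+ currents is set
# by the bath/pipette solutions, same as the injected current's reversal.
E_NA = 60.0
E_CA = 45.0
EK_CELL = -94.7
K1N_MID = -30.0  # native I_K1 rectification midpoint
K1N_SLOPE = 14.0

# Formulation codes for the kernel.
F_NONE = 0
F_VENTR = 1
F_ATR = 2
F_TEST1 = 3
F_TEST2 = 4

FORMULATION_CODES = {"ventr": F_VENTR, "atr": F_ATR, "test1": F_TEST1, "test2": F_TEST2}

# Cell parameter vector layout (see cell.VirtualCellParams.param_vector).
P_GNA, P_GCAL, P_GKREP, P_GKUR, P_GK1N, P_GLEAK, P_ELEAK, P_TAUF, P_TAUXR = range(9)
N_STATE = 6  # V, h, d, f, xr, a


@njit(cache=True)
def k1n_rect(V):
    """Rectification factor of the cell's weak native I_K1."""
    return 1.0 / (1.0 + np.exp((V - K1N_MID) / K1N_SLOPE))


@njit(cache=True)
def gate_xinf(V, Ko, code):
    c = 57.836 if code == F_TEST1 else 144.59
    s = 1.5692 * Ko + 3.8115
    return 1.0 / (1.0 + np.exp(-(V + 2.5538 * Ko + c) / s))


@njit(cache=True)
def gate_tau(V):
    return 122.2 / (np.exp(-(V + 127.2) / 20.36) + np.exp((V + 236.8) / 69.33))


@njit(cache=True)
def ik1_code(V, x, code, g_eff, Ko, EK, frt_mV):
    """Injected I_K1 (pA/pF, outward positive) for one formulation code."""
    if code == F_NONE:
        return 0.0
    if code == F_ATR:
        e = 1.5 * (V - EK + 3.6) * frt_mV
        return g_eff * Ko**0.4457 * (V - EK) / (1.0 + np.exp(e))
    if code == F_TEST2:
        mid, slope = 135.8, 15.493
    else:
        mid, slope = 105.8, 9.493
    r = 1.0 / (1.0 + np.exp((V + mid - 2.6 * Ko) / slope))
    return g_eff * np.sqrt(Ko) * x * r * (V - EK)


@njit(cache=True)
def gate_step(V, x, dt, Ko, code):
    """Rush–Larsen update of the injected-current gate over dt ms."""
    if code == F_VENTR or code == F_TEST1 or code == F_TEST2:
        xinf = gate_xinf(V, Ko, code)
        tau = gate_tau(V)
        return xinf + (x - xinf) * np.exp(-dt / tau)
    return x


@njit(cache=True)
def cell_substeps(y, p, i_inj, i_stim, dt, n_sub):
    """Advance the cell state in place by n_sub Euler/Rush–Larsen steps.

    y = [V, h, d, f, xr, a]; i_inj and i_stim are held constant.
    """
    for _ in range(n_sub):
        V = y[0]
        minf = 1.0 / (1.0 + np.exp(-(V + 34.0) / 5.5))
        hinf = 1.0 / (1.0 + np.exp((V + 66.0) / 5.5))
        tauh = 0.8 + 12.0 / (1.0 + np.exp((V + 60.0) / 8.0))
        dinf = 1.0 / (1.0 + np.exp(-(V + 12.0) / 6.0))
        finf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.5))
        xrinf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 7.0))
        ainf = 1.0 / (1.0 + np.exp(-(V + 4.0) / 8.0))

        i_na = p[P_GNA] * minf * minf * minf * y[1] * (V - E_NA)
        i_cal = p[P_GCAL] * y[2] * y[3] * (V - E_CA)
        i_krep = p[P_GKREP] * y[4] * (V - EK_CELL)
        i_kur = p[P_GKUR] * y[5] * (V - EK_CELL)
        i_k1n = p[P_GK1N] * (V - EK_CELL) * k1n_rect(V)
        i_leak = p[P_GLEAK] * (V - p[P_ELEAK])

        y[0] = V + dt * (-(i_na + i_cal + i_krep + i_kur + i_k1n + i_leak + i_inj) + i_stim)
        y[1] = hinf + (y[1] - hinf) * np.exp(-dt / tauh)
        y[2] = dinf + (y[2] - dinf) * np.exp(-dt / 2.5)
        y[3] = finf + (y[3] - finf) * np.exp(-dt / p[P_TAUF])
        y[4] = xrinf + (y[4] - xrinf) * np.exp(-dt / p[P_TAUXR])
        y[5] = ainf + (y[5] - ainf) * np.exp(-dt / 2.0)


@njit(cache=True)
def init_state(V0):
    """Cell state with every gate at its steady value for V0."""
    y = np.empty(N_STATE)
    y[0] = V0
    y[1] = 1.0 / (1.0 + np.exp((V0 + 66.0) / 5.5))
    y[2] = 1.0 / (1.0 + np.exp(-(V0 + 12.0) / 6.0))
    y[3] = 1.0 / (1.0 + np.exp((V0 + 28.0) / 5.5))
    y[4] = 1.0 / (1.0 + np.exp(-(V0 + 10.0) / 7.0))
    y[5] = 1.0 / (1.0 + np.exp(-(V0 + 4.0) / 8.0))
    return y


@njit(cache=True)
def run_loop(
    y,
    p,
    code,
    g_eff,
    Ko,
    EK,
    frt_mV,
    x0,
    dt_sample,
    n_sub,
    n_samples,
    period_n,
    pulse_n,
    n_beats,
    pulse_amp,
    zoh,
):
    """Run the sampled loop; returns (Vm, I_inj, x_final, fail_index).

    Vm has n_samples+1 points (sample grid). I_inj[k] is the current
    injected during sample interval k (ZOH); the last entry repeats the
    value at the final voltage for plotting convenience. fail_index is
    −1 on success, else the sample index where V left [−200, 200] mV or
    became non-finite.
    """
    Vm = np.empty(n_samples + 1)
    Ii = np.empty(n_samples + 1)
    Vm[0] = y[0]
    x = x0
    dt = dt_sample / n_sub
    for k in range(n_samples):
        V = y[0]
        x = gate_step(V, x, dt_sample, Ko, code)
        i_inj = ik1_code(V, x, code, g_eff, Ko, EK, frt_mV)
        Ii[k] = i_inj
        beat = k // period_n
        i_stim = pulse_amp if (beat < n_beats and (k - beat * period_n) < pulse_n) else 0.0
        if zoh:
            cell_substeps(y, p, i_inj, i_stim, dt, n_sub)
        else:
            # continuously coupled reference: recompute the injected
            # current and gate at every substep
            for _ in range(n_sub):
                Vs = y[0]
                x = gate_step(Vs, x, dt, Ko, code)
                i_inj = ik1_code(Vs, x, code, g_eff, Ko, EK, frt_mV)
                cell_substeps(y, p, i_inj, i_stim, dt, 1)
        Vm[k + 1] = y[0]
        if not np.isfinite(y[0]) or y[0] > 200.0 or y[0] < -200.0:
            Ii[k + 1 :] = 0.0
            return Vm, Ii, x, k
    Ii[n_samples] = ik1_code(y[0], x, code, g_eff, Ko, EK, frt_mV)
    return Vm, Ii, x, -1
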