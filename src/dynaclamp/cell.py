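"""Synthetic immature-cardiomyocyte surrogate.

A minimal Hodgkin–Huxley-style membrane model standing in for a patched
hiPSC-derived cardiomyocyte: fast Na+ current (instantaneous activation,
inactivation gate h), an L-type-like Ca2+ plateau current (d, f), a
generic delayed-rectifier K+ current (xr), an optional sustained
ultrarapid K+ current I_Kur (a; atrial marker, 4-AP sensitive), a weak
native inward-rectifier I_K1 whose small conductance produces the
depolarized diastolic potential typical of immature cells, and a
depolarizing linear leak.

The model is the package's own construction — it reproduces the
qualitative electrophysiology the analysis pipeline needs (depolarized
diastole without injected I_K1, plateau-shaped ventricular-like and
triangular atrial-like APs, I_Kur sensitivity), not any published cell
model. dV/dt = −(ΣI_ion + I_injected) + I_stim with currents in pA/pF,
so dV/dt is in mV/ms.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernel as K

__all__ = [
    "VirtualCellParams",
    "StimulusProtocol",
    "VoltageTrace",
    "CurrentTrace",
    "SimulationError",
    "make_preset",
    "simulate_ap",
    "generate_cohort",
    "apply_ikur_block",
    "unassisted_rest_potential",
]

PHENOTYPES = ("atrial", "ventricular")

# Preset conductance means (nS/pF) and gate time constants (ms). The two
# presets differ where real chamber phenotypes do: plateau Ca2+ current,
# repolarizing K+ density/kinetics and the presence of I_Kur.
_PRESET_MEANS = {
    "ventricular": dict(g_Na=3.0, g_CaL=0.50, g_Krep=0.015, g_Kur=0.0, tau_f=200.0, tau_xr=60.0),
    "atrial": dict(g_Na=3.0, g_CaL=0.12, g_Krep=0.01, g_Kur=0.03, tau_f=80.0, tau_xr=40.0),
}
_CM_MEAN_PF = 45.0
_GLEAK_MEAN = 0.03
_E_LEAK = -10.0


class SimulationError(RuntimeError):
    """Raised when the membrane integration diverges."""

    def __init__(self, message: str, beat_index: Optional[int] = None):
        super().__init__(message)
        self.beat_index = beat_index


@dataclass(frozen=True)
class VirtualCellParams:
    """Parameter set of one synthetic immature cardiomyocyte.

    Conductances in nS/pF, capacitance in pF, potentials in mV, time
    constants in ms. ``g_K1_native`` is deliberately small: it sets the
    depolarized unassisted diastolic potential in (−70, −50) mV.
    """

    phenotype: str = "ventricular"
    Cm: float = _CM_MEAN_PF
    g_Na: float = 3.0
    g_CaL: float = 0.50
    g_Krep: float = 0.015
    g_Kur: float = 0.0
    g_K1_native: float = 0.05
    g_leak: float = _GLEAK_MEAN
    E_leak: float = _E_LEAK
    tau_f: float = 200.0
    tau_xr: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        for name in ("Cm", "g_Na", "g_CaL", "g_Krep", "g_Kur", "g_K1_native", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_f <= 0 or self.tau_xr <= 0:
            raise ValueError("gate time constants must be positive")

    def param_vector(self) -> np.ndarray:
        """Kernel parameter vector (see _kernel layout)."""
        return np.array(
            [
                self.g_Na,
                self.g_CaL,
                self.g_Krep,
                self.g_Kur,
                self.g_K1_native,
                self.g_leak,
                self.E_leak,
                self.tau_f,
                self.tau_xr,
            ]
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-clamp pacing protocol (1 Hz square pulses by default)."""

    frequency: float = 1.0  # Hz
    pulse_amplitude: float = 30.0  # pA/pF
    pulse_duration: float = 3.0  # ms
    n_beats: int = 10
    discard_beats: int = 5  # initial transient excluded from analysis

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not self.n_beats > self.discard_beats >= 0:
            raise ValueError("need n_beats > discard_beats >= 0")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential series (ms, mV)."""

    t: np.ndarray
    Vm: np.ndarray
    dt: float = 0.2
    stim_times: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Vm = np.asarray(self.Vm, dtype=float)
        if self.t.shape != self.Vm.shape:
            raise ValueError("t and Vm must have equal length")


@dataclass
class CurrentTrace:
    """Uniformly sampled current series aligned with a VoltageTrace."""

    t: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have equal length")


def _rest_balance_gk1n(E: float, g_leak: float, E_leak: float) -> float:
    """Native-I_K1 conductance that balances the leak at diastolic E."""
    r = 1.0 / (1.0 + math.exp((E - K.K1N_MID) / K.K1N_SLOPE))
    return -g_leak * (E - E_leak) / ((E - K.EK_CELL) * r)


def unassisted_rest_potential(cell: VirtualCellParams) -> float:
    """Diastolic potential predicted by the native-I_K1/leak balance.

    Solves ΣI(V) = 0 by bisection over [−90, −35] mV with all gates at
    steady state (Na+/Ca2+ window currents included).
    """

    def total(V: float) -> float:
        minf = 1.0 / (1.0 + math.exp(-(V + 34.0) / 5.5))
        hinf = 1.0 / (1.0 + math.exp((V + 66.0) / 5.5))
        dinf = 1.0 / (1.0 + math.exp(-(V + 12.0) / 6.0))
        finf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.5))
        xrinf = 1.0 / (1.0 + math.exp(-(V + 10.0) / 7.0))
        ainf = 1.0 / (1.0 + math.exp(-(V + 4.0) / 8.0))
        r = 1.0 / (1.0 + math.exp((V - K.K1N_MID) / K.K1N_SLOPE))
        return (
            cell.g_Na * minf**3 * hinf * (V - K.E_NA)
            + cell.g_CaL * dinf * finf * (V - K.E_CA)
            + cell.g_Krep * xrinf * (V - K.EK_CELL)
            + cell.g_Kur * ainf * (V - K.EK_CELL)
            + cell.g_K1_native * (V - K.EK_CELL) * r
            + cell.g_leak * (V - cell.E_leak)
        )

    lo, hi = -90.0, -35.0
    flo = total(lo)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = total(mid)
        if (fm < 0) == (flo < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_preset(
    phenotype: str,
    maturity: float = 0.5,
    seed: int = 0,
    jitter_cv: float = 0.15,
) -> VirtualCellParams:
    """Draw one seeded cell around the atrial or ventricular preset.

    Conductances and gate time constants get log-normal jitter with
    coefficient of variation ``jitter_cv`` (keeps them positive). The
    native I_K1 conductance is not jittered directly: a target diastolic
    potential is drawn — more negative at higher ``maturity`` — and
    ``g_K1_native`` is solved from the diastolic current balance so the
    unassisted diastole always stays in the immature (−70, −50) mV band.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if not 0.0 <= maturity <= 1.0:
        raise ValueError("maturity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2))

    def jit(mean: float) -> float:
        if mean == 0.0:
            return 0.0
        return float(mean * math.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))

    m = _PRESET_MEANS[phenotype]
    g_Na = jit(m["g_Na"])
    g_CaL = jit(m["g_CaL"])
    g_Krep = jit(m["g_Krep"])
    g_Kur = jit(m["g_Kur"])
    tau_f = jit(m["tau_f"])
    tau_xr = jit(m["tau_xr"])
    Cm = jit(_CM_MEAN_PF)
    g_leak = jit(_GLEAK_MEAN)
    e_target = -52.0 - 16.0 * maturity + 2.5 * float(rng.standard_normal())
    e_target = float(np.clip(e_target, -68.5, -51.5))
    g_k1n = _rest_balance_gk1n(e_target, g_leak, _E_LEAK)
    return VirtualCellParams(
        phenotype=phenotype,
        Cm=Cm,
        g_Na=g_Na,
        g_CaL=g_CaL,
        g_Krep=g_Krep,
        g_Kur=g_Kur,
        g_K1_native=g_k1n,
        g_leak=g_leak,
        E_leak=_E_LEAK,
        tau_f=tau_f,
        tau_xr=tau_xr,
        seed=int(seed),
    )


def _grid_counts(protocol: StimulusProtocol, dt_sample: float) -> Tuple[int, int, int]:
    period_n = int(round(protocol.period_ms / dt_sample))
    pulse_n = int(round(protocol.pulse_duration / dt_sample))
    n_samples = period_n * protocol.n_beats
    return period_n, pulse_n, n_samples


def _check_failure(fail: int, dt_sample: float, period_ms: float, context: str) -> None:
    if fail >= 0:
        beat = int(fail * dt_sample // period_ms)
        raise SimulationError(
            f"membrane integration diverged at beat {beat} ({context})", beat_index=beat
        )


def simulate_ap(
    cell: VirtualCellParams,
    protocol: StimulusProtocol,
    injected: Optional[Callable[[float, float], float]] = None,
    dt_internal: float = 0.02,
    dt_sample: float = 0.2,
    v_init: float = -60.0,
) -> VoltageTrace:
    """Paced current-clamp simulation; returns the sampled voltage trace.

    ``injected(V, t) -> pA/pF`` (outward positive), when given, is
    evaluated once per sample from the sample-start voltage and held
    constant within the sample, like the dynamic-clamp loop. With no
    injection the fast whole-run kernel is used.
    """
    if dt_internal > dt_sample:
        raise ValueError("dt_internal must not exceed the sampling interval")
    n_sub = max(1, int(round(dt_sample / dt_internal)))
    period_n, pulse_n, n_samples = _grid_counts(protocol, dt_sample)
    p = cell.param_vector()
    y = K.init_state(v_init)
    if injected is None:
        Vm, _, _, fail = K.run_loop(
            y, p, K.F_NONE, 0.0, 4.0, -94.7, 0.0, 1.0,
            dt_sample, n_sub, n_samples, period_n, pulse_n,
            protocol.n_beats, protocol.pulse_amplitude, True,
        )
        _check_failure(fail, dt_sample, protocol.period_ms, f"{cell.phenotype} preset")
    else:
        Vm = np.empty(n_samples + 1)
        Vm[0] = y[0]
        dt = dt_sample / n_sub
        for k in range(n_samples):
            V = y[0]
            t = k * dt_sample
            i_inj = float(injected(V, t))
            beat = k // period_n
            on = beat < protocol.n_beats and (k - beat * period_n) < pulse_n
            i_stim = protocol.pulse_amplitude if on else 0.0
            K.cell_substeps(y, p, i_inj, i_stim, dt, n_sub)
            Vm[k + 1] = y[0]
            if not np.isfinite(y[0]) or abs(y[0]) > 200.0:
                _check_failure(k, dt_sample, protocol.period_ms, f"{cell.phenotype} preset")
    t = dt_sample * np.arange(n_samples + 1)
    stim_times = [i * period_n * dt_sample for i in range(protocol.n_beats)]
    return VoltageTrace(t=t, Vm=Vm, dt=dt_sample, stim_times=stim_times)


def generate_cohort(
    n: int,
    atrial_fraction: float,
    maturity_range: Tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
) -> List[VirtualCellParams]:
    """Seeded cohort with exactly round(n·atrial_fraction) atrial cells.

    Cell order is randomized (atrial and ventricular interleaved) but
    fully reproducible under ``seed``; per-cell jitter uses child seeds
    spawned from the cohort seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= atrial_fraction <= 1.0:
        raise ValueError("atrial_fraction must lie in [0, 1]")
    lo, hi = maturity_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("maturity_range must be an interval inside [0, 1]")
    n_atr = int(round(n * atrial_fraction))
    rng = np.random.default_rng(seed)
    phenos = np.array(["atrial"] * n_atr + ["ventricular"] * (n - n_atr))
    rng.shuffle(phenos)
    cells = []
    for i, ph in enumerate(phenos):
        maturity = float(rng.uniform(lo, hi))
        child_seed = int(rng.integers(0, 2**31 - 1))
        cells.append(make_preset(str(ph), maturity=maturity, seed=child_seed))
    return cells


def apply_ikur_block(cell: VirtualCellParams, block_fraction: float) -> VirtualCellParams:
    """Scale g_Kur by (1 − block_fraction), e.g. 0.9 for 50 µM 4-AP."""
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block_fraction must lie in [0, 1]")
    return dataclasses.replace(cell, g_Kur=cell.g_Kur * (1.0 - block_fraction))
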