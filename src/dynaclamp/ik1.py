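"""Inward-rectifier potassium current (I_K1) formulations.

Four formulations of the inward-rectifier current used for dynamic-clamp
injection into immature cardiomyocytes:

``ventr``
    The human ventricular formulation (O'Hara–Rudy lineage): a gated,
    strongly rectifying current ``I = G·√[K+]o·xK1·RK1·(V−EK)`` with a
    time-dependent activation gate ``xK1`` and an instantaneous
    rectification factor ``RK1``.
``atr``
    The human atrial formulation (Koivumäki/Nygren lineage): an
    instantaneous, weakly rectifying current
    ``I = G·[K+]o^0.4457·(V−EK) / (1 + exp(1.5·(V−EK+3.6)·F/(R·T)))``.
``test1``
    The ventricular formulation with the activation midpoint shifted so
    that the steady-state I/V peak moves to the atrial peak voltage
    (midpoint constant 57.836 instead of 144.59; G = 6.417 nS/pF).
``test2``
    The ventricular formulation with a shallower, more negative
    rectification (midpoint 135.8, slope 15.493; G = 6.258 nS/pF), which
    reshapes the decaying limb of the I/V relation.

Sign convention: outward current is positive; the membrane equation
consumes it with a minus sign (see :mod:`dynaclamp.cell`).

All potentials are in mV, currents in pA/pF, conductances in nS/pF,
times in ms.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "FORMULATIONS",
    "DEFAULT_G_BASE",
    "IK1Config",
    "GateState",
    "IK1Evaluation",
    "IVCurve",
    "xk1_inf",
    "xk1_tau",
    "rk1",
    "update_gate",
    "ik1_ventr",
    "ik1_atr",
    "ik1_variant",
    "ik1_current",
    "steady_current",
    "steady_evaluation",
    "steady_iv",
    "iv_peak",
]

FORMULATIONS = ("ventr", "atr", "test1", "test2")

#: Default maximal conductance per formulation, nS/pF.
DEFAULT_G_BASE = {"ventr": 1.908, "atr": 0.7, "test1": 6.417, "test2": 6.258}

# Activation midpoint constant of the gated formulations; test1 shifts it.
_XINF_C = {"ventr": 144.59, "test1": 57.836, "test2": 144.59}
# Rectification (midpoint, slope); test2 reshapes the decaying limb.
_RK1_MS = {"ventr": (105.8, 9.493), "test1": (105.8, 9.493), "test2": (135.8, 15.493)}

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class IK1Config:
    """Identity and constants of one I_K1 formulation.

    Parameters
    ----------
    formulation : {'ventr', 'atr', 'test1', 'test2'}
    G_base : float, optional
        Maximal conductance in nS/pF. Defaults to the formulation's
        published value (ventr 1.908, atr 0.7, test1 6.417, test2 6.258).
    scaling_DC : float
        Dimensionless conductance scaling applied during dynamic clamp.
        Applied to ventr/atr only; the test variants use their absolute
        conductances.
    Ko : float
        External K+ concentration, mM.
    EK : float
        K+ reversal potential, mV. Fixed at −94.7 mV (set by the bath and
        pipette K+), not recomputed by Nernst.
    T : float
        Absolute temperature, K (35 °C recordings → 308.15).
    """

    formulation: str = "ventr"
    G_base: float = None  # type: ignore[assignment]
    scaling_DC: float = 1.0
    Ko: float = 4.0
    EK: float = -94.7
    T: float = 308.15
    F: float = 96485.0
    R: float = 8.314

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(
                f"unknown formulation {self.formulation!r}; expected one of {FORMULATIONS}"
            )
        if self.G_base is None:
            object.__setattr__(self, "G_base", DEFAULT_G_BASE[self.formulation])
        if self.G_base <= 0:
            raise ValueError("G_base must be positive")
        if self.Ko <= 0:
            raise ValueError("Ko must be positive")
        if self.scaling_DC < 0:
            raise ValueError("scaling_DC must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def g_eff(self) -> float:
        """Effective conductance: G_base·scaling_DC for ventr/atr,
        G_base unscaled for the test variants."""
        if self.formulation in ("test1", "test2"):
            return self.G_base
        return self.G_base * self.scaling_DC

    @property
    def gated(self) -> bool:
        """Whether the formulation carries a time-dependent gate."""
        return self.formulation != "atr"

    @property
    def frt_per_mV(self) -> float:
        """F/(R·T) expressed per millivolt."""
        return self.F / (self.R * self.T) / 1000.0

    def with_scaling(self, scaling_DC: float) -> "IK1Config":
        return replace(self, scaling_DC=scaling_DC)


@dataclass(frozen=True)
class GateState:
    """State of the activation gate xK1 (open fraction in [0, 1])."""

    xk1: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xk1 <= 1.0:
            raise ValueError(f"xk1 must lie in [0, 1], got {self.xk1}")


@dataclass(frozen=True)
class IK1Evaluation:
    """Pointwise steady-state dissection of a formulation at one voltage."""

    V: float
    xk1_inf: float
    tau_ms: float
    rk1: float
    current: float


def xk1_inf(V: ArrayLike, Ko: float = 4.0, *, _c: float = 144.59) -> ArrayLike:
    """Steady-state activation of the ventricular-family xK1 gate.

    A rising sigmoid of V with midpoint −(2.5538·Ko + c) and slope
    1.5692·Ko + 3.8115 mV; c = 144.59 for ventr/test2, 57.836 for test1.
    """
    if Ko <= 0:
        raise ValueError("Ko must be positive")
    V = np.asarray(V, dtype=float)
    s = 1.5692 * Ko + 3.8115
    out = 1.0 / (1.0 + np.exp(-(V + 2.5538 * Ko + _c) / s))
    return float(out) if out.ndim == 0 else out


def xk1_tau(V: ArrayLike) -> ArrayLike:
    """Time constant of the xK1 gate in ms (always positive)."""
    V = np.asarray(V, dtype=float)
    out = 122.2 / (np.exp(-(V + 127.2) / 20.36) + np.exp((V + 236.8) / 69.33))
    return float(out) if out.ndim == 0 else out


def rk1(
    V: ArrayLike, Ko: float = 4.0, *, _mid: float = 105.8, _slope: float = 9.493
) -> ArrayLike:
    """Instantaneous inward-rectification factor in (0, 1).

    Falls with depolarization; midpoint at V = −(mid − 2.6·Ko). The
    ventricular formulation uses (105.8, 9.493); test2 uses the more
    negative, shallower (135.8, 15.493).
    """
    if Ko <= 0:
        raise ValueError("Ko must be positive")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V + _mid - 2.6 * Ko) / _slope))
    return float(out) if out.ndim == 0 else out


def _xinf_for(cfg: IK1Config, V: ArrayLike) -> ArrayLike:
    return xk1_inf(V, cfg.Ko, _c=_XINF_C[cfg.formulation])


def _rk1_for(cfg: IK1Config, V: ArrayLike) -> ArrayLike:
    mid, slope = _RK1_MS[cfg.formulation]
    return rk1(V, cfg.Ko, _mid=mid, _slope=slope)


def update_gate(state: GateState, V: float, dt: float, cfg: IK1Config) -> GateState:
    """Advance the xK1 gate by ``dt`` ms at fixed voltage (Rush–Larsen).

    The gate relaxes exponentially toward its steady state:
    ``x ← x∞ + (x − x∞)·exp(−dt/τ)``, which is exact for the linear gate
    equation dx/dt = (x∞ − x)/τ at constant V.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not cfg.gated:
        raise ValueError("the atrial formulation is instantaneous and has no gate")
    xinf = _xinf_for(cfg, V)
    tau = xk1_tau(V)
    x = xinf + (state.xk1 - xinf) * np.exp(-dt / tau)
    return GateState(xk1=float(min(max(x, 0.0), 1.0)))


def ik1_ventr(V: ArrayLike, gate: GateState, cfg: IK1Config) -> ArrayLike:
    """Ventricular I_K1: G·√Ko·xK1·RK1·(V−EK), pA/pF (outward positive)."""
    if cfg.formulation != "ventr":
        raise ValueError(f"expected a 'ventr' config, got {cfg.formulation!r}")
    V = np.asarray(V, dtype=float)
    out = cfg.g_eff * np.sqrt(cfg.Ko) * gate.xk1 * _rk1_for(cfg, V) * (V - cfg.EK)
    return float(out) if out.ndim == 0 else out


def ik1_atr(V: ArrayLike, cfg: IK1Config) -> ArrayLike:
    """Atrial I_K1 (instantaneous), pA/pF.

    ``I = G·Ko^0.4457·(V−EK) / (1 + exp(1.5·(V−EK+3.6)·F/(R·T)))`` with the
    exponent taken per-mV (V in mV), matching the parent atrial model.
    """
    if cfg.formulation != "atr":
        raise ValueError(f"expected an 'atr' config, got {cfg.formulation!r}")
    V = np.asarray(V, dtype=float)
    e = 1.5 * (V - cfg.EK + 3.6) * cfg.frt_per_mV
    out = cfg.g_eff * cfg.Ko**0.4457 * (V - cfg.EK) / (1.0 + np.exp(e))
    return float(out) if out.ndim == 0 else out


def ik1_variant(V: ArrayLike, gate: GateState, cfg: IK1Config) -> ArrayLike:
    """Test-variant I_K1 (test1: shifted peak; test2: reshaped decay)."""
    if cfg.formulation not in ("test1", "test2"):
        raise ValueError(f"expected a test1/test2 config, got {cfg.formulation!r}")
    V = np.asarray(V, dtype=float)
    out = cfg.g_eff * np.sqrt(cfg.Ko) * gate.xk1 * _rk1_for(cfg, V) * (V - cfg.EK)
    return float(out) if out.ndim == 0 else out


def ik1_current(V: ArrayLike, gate: GateState, cfg: IK1Config) -> ArrayLike:
    """Dispatch to the configured formulation (gate ignored for 'atr')."""
    if cfg.formulation == "ventr":
        return ik1_ventr(V, gate, cfg)
    if cfg.formulation == "atr":
        return ik1_atr(V, cfg)
    return ik1_variant(V, gate, cfg)


def steady_current(V: ArrayLike, cfg: IK1Config) -> ArrayLike:
    """Current with the gate at its steady state xK1 = x∞(V)."""
    V = np.asarray(V, dtype=float)
    if cfg.formulation == "atr":
        return ik1_atr(V, cfg)
    out = cfg.g_eff * np.sqrt(cfg.Ko) * _xinf_for(cfg, V) * _rk1_for(cfg, V) * (V - cfg.EK)
    return float(out) if out.ndim == 0 else out


def steady_evaluation(cfg: IK1Config, V: float) -> IK1Evaluation:
    """Dissect a formulation at one voltage with the gate at steady state.

    For the instantaneous atrial formulation the gate factor is reported
    as 1 and τ as +inf.
    """
    if cfg.formulation == "atr":
        return IK1Evaluation(
            V=V, xk1_inf=1.0, tau_ms=np.inf, rk1=1.0, current=float(ik1_atr(V, cfg))
        )
    return IK1Evaluation(
        V=V,
        xk1_inf=float(_xinf_for(cfg, V)),
        tau_ms=float(xk1_tau(V)),
        rk1=float(_rk1_for(cfg, V)),
        current=float(steady_current(V, cfg)),
    )


@dataclass
class IVCurve:
    """Steady-state current–voltage relation on a strictly increasing grid."""

    voltages: np.ndarray
    currents: np.ndarray
    formulation: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have equal length")
        if self.voltages.size and np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")

    def to_csv(self, path) -> None:
        header = "V_mV,I_pApF"
        np.savetxt(
            path,
            np.column_stack([self.voltages, self.currents]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.10g",
        )

    @classmethod
    def from_csv(cls, path, formulation: str = "") -> "IVCurve":
        data = np.genfromtxt(path, delimiter=",", names=True)
        if data.dtype.names is None or set(data.dtype.names) != {"V_mV", "I_pApF"}:
            raise ValueError("expected a two-column CSV with header 'V_mV,I_pApF'")
        return cls(
            voltages=np.atleast_1d(data["V_mV"]),
            currents=np.atleast_1d(data["I_pApF"]),
            formulation=formulation,
        )


def steady_iv(cfg: IK1Config, v_min: float, v_max: float, dv: float) -> IVCurve:
    """Steady-state I/V relation of ``cfg`` on the grid [v_min, v_max]."""
    if dv <= 0:
        raise ValueError("dv must be positive")
    if v_min >= v_max:
        raise ValueError("v_min must be below v_max")
    n = int(np.floor((v_max - v_min) / dv + 1e-9)) + 1
    grid = v_min + dv * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty voltage grid")
    return IVCurve(voltages=grid, currents=steady_current(grid, cfg), formulation=cfg.formulation)


def iv_peak(
    cfg: IK1Config, dv: float = 0.01, window: "tuple[float, float] | None" = None
) -> "tuple[float, float]":
    """Voltage and value of the maximal outward steady-state current.

    Searches the window [EK, −40] mV by default (the physiological limb of
    the I/V relation; weakly rectified variants can rise again at very
    depolarized potentials). Ties break toward the more negative voltage.
    """
    if dv <= 0:
        raise ValueError("dv must be positive")
    lo, hi = window if window is not None else (cfg.EK, -40.0)
    curve = steady_iv(cfg, lo, hi, dv)
    i = int(np.argmax(curve.currents))  # first max = most negative V
    return float(curve.voltages[i]), float(curve.currents[i])
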