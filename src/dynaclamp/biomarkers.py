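"""Action-potential biomarkers and beat-to-beat repolarization variability.

Nine per-cell biomarkers are measured from paced current-clamp traces:
membrane capacitance Cm (metadata carried from the cell), diastolic
potential without and with dynamic clamp (E_diast, E_diast_DC), action
potential durations at 90/50/20% repolarization (APD90/APD50/APD20), the
APD20/APD90 triangulation ratio, the maximal upstroke velocity
dV/dt_max, and the action-potential amplitude APA.

Beat-to-beat variability of APD90 is summarized by the short-term
variability STV = Σ|APD_{n+1} − APD_n| / (n_beats·√2), the mean
orthogonal deviation from the identity line of the Poincaré plot of
consecutive APDs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .cell import VoltageTrace

__all__ = [
    "APBiomarkers",
    "BeatMeasurement",
    "STVSeries",
    "STVResult",
    "RegressionBand",
    "NoAPError",
    "extract_biomarkers",
    "measure_beats",
    "stv",
    "stv_apd_regression",
]

logger = logging.getLogger(__name__)

#: Overshoot level (mV) a beat must reach to count as an action potential.
AP_DETECT_LEVEL = 0.0


class NoAPError(ValueError):
    """No beat in the trace qualifies as an action potential."""


@dataclass
class APBiomarkers:
    """The nine per-cell electrical biomarkers (median over beats)."""

    Cm: float = float("nan")  # pF
    E_diast: float = float("nan")  # mV, without injected I_K1
    E_diast_DC: float = float("nan")  # mV, with dynamic clamp
    APD90: float = float("nan")  # ms
    APD50: float = float("nan")
    APD20: float = float("nan")
    ratio_20_90: float = float("nan")
    dVdt_max: float = float("nan")  # V/s (== mV/ms)
    APA: float = float("nan")  # mV
    fiducial: str = "dvdt_max"  # APD onset definition used

    def as_row(self) -> dict:
        """Fixed CSV column mapping used across the package."""
        return {
            "Cm_pF": self.Cm,
            "Ediast_mV": self.E_diast,
            "EdiastDC_mV": self.E_diast_DC,
            "APD90_ms": self.APD90,
            "APD50_ms": self.APD50,
            "APD20_ms": self.APD20,
            "APD20_APD90": self.ratio_20_90,
            "dVdtmax_Vps": self.dVdt_max,
            "APA_mV": self.APA,
        }


@dataclass
class BeatMeasurement:
    """Per-beat fiducials and durations (ms, mV, V/s)."""

    beat: int
    E_diast: float
    V_peak: float
    APA: float
    dVdt_max: float
    APD90: float
    APD50: float
    APD20: float


def _crossing_time(t: np.ndarray, V: np.ndarray, i0: int, level: float) -> Optional[float]:
    """First downward crossing of ``level`` at or after index i0,
    linearly interpolated between samples; None if never reached."""
    seg = V[i0:]
    below = seg <= level
    if not below.any():
        return None
    j = int(np.argmax(below))  # first sample at/below level
    if j == 0:
        return float(t[i0])
    i = i0 + j - 1
    frac = (V[i] - level) / (V[i] - V[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def measure_beats(
    trace: VoltageTrace,
    discard_beats: int = 0,
    fiducial: str = "dvdt_max",
    threshold_mV: float = -20.0,
) -> List[BeatMeasurement]:
    """Measure every analyzable beat of a paced trace.

    Per beat: E_diast = mean Vm over [−10, −1] ms before the stimulus;
    APA = V_peak − E_diast; dV/dt_max = maximal forward-difference
    derivative in the upstroke; APDx runs from the fiducial (time of
    dV/dt_max by default, or the −20 mV upstroke crossing with
    ``fiducial='threshold'``) to the first downward crossing of
    V_peak − (x/100)·APA, located by linear interpolation.

    Beats that never reach 0 mV are not APs; beats whose repolarization
    never reaches the 90% level within the cycle are excluded with a
    warning. Raises :class:`NoAPError` if no analyzed beat is an AP.
    """
    if fiducial not in ("dvdt_max", "threshold"):
        raise ValueError("fiducial must be 'dvdt_max' or 'threshold'")
    if not trace.stim_times:
        raise ValueError("trace has no stimulus times; cannot segment beats")
    t, V, dt = trace.t, trace.Vm, trace.dt
    stim = sorted(trace.stim_times)
    edges = stim + [t[-1]]
    results: List[BeatMeasurement] = []
    any_ap = False
    for b in range(discard_beats, len(stim)):
        t0, t1 = edges[b], edges[b + 1]
        i0 = int(round(t0 / dt))
        i1 = min(int(round(t1 / dt)), len(V) - 1)
        if i1 - i0 < 10:
            continue
        # diastolic window [-10, -1] ms before the stimulus
        jd0 = max(0, i0 - int(round(10.0 / dt)))
        jd1 = max(jd0 + 1, i0 - int(round(1.0 / dt)))
        e_diast = float(np.mean(V[jd0:jd1]))
        seg = V[i0 : i1 + 1]
        ipk = i0 + int(np.argmax(seg))
        v_peak = float(V[ipk])
        if v_peak < AP_DETECT_LEVEL:
            continue
        any_ap = True
        apa = v_peak - e_diast
        # include the sample preceding the stimulus so an upstroke that
        # completes within one sample still has a defined derivative
        iu0 = max(i0 - 1, 0)
        dv = np.diff(V[iu0 : ipk + 1]) / dt  # mV/ms == V/s
        if dv.size == 0:
            continue
        iup = iu0 + int(np.argmax(dv))
        dvdt_max = float(dv.max())
        if fiducial == "dvdt_max":
            t_on = float(t[iup])
        else:
            up = _crossing_rising(t, V, i0, ipk, threshold_mV)
            t_on = up if up is not None else float(t[iup])
        apds = {}
        ok = True
        for frac, name in ((0.90, "APD90"), (0.50, "APD50"), (0.20, "APD20")):
            level = v_peak - frac * apa
            tc = _crossing_time(t[: i1 + 1], V[: i1 + 1], ipk, level)
            if tc is None:
                ok = False
                break
            apds[name] = tc - t_on
        if not ok:
            warnings.warn(
                f"beat {b}: repolarization did not reach the 90% level within "
                "the cycle; beat excluded",
                stacklevel=2,
            )
            continue
        results.append(
            BeatMeasurement(
                beat=b,
                E_diast=e_diast,
                V_peak=v_peak,
                APA=apa,
                dVdt_max=dvdt_max,
                APD90=apds["APD90"],
                APD50=apds["APD50"],
                APD20=apds["APD20"],
            )
        )
    if not any_ap:
        raise NoAPError("no AP detected (no beat reaches 0 mV overshoot)")
    return results


def _crossing_rising(
    t: np.ndarray, V: np.ndarray, i0: int, i1: int, level: float
) -> Optional[float]:
    for i in range(i0, i1):
        if V[i] < level <= V[i + 1]:
            frac = (level - V[i]) / (V[i + 1] - V[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def extract_biomarkers(
    trace: VoltageTrace,
    trace_dc: Optional[VoltageTrace] = None,
    Cm: float = float("nan"),
    discard_beats: int = 0,
    fiducial: str = "dvdt_max",
) -> APBiomarkers:
    """Aggregate the nine biomarkers from one cell's recordings.

    When ``trace_dc`` is given it is the dynamic-clamp recording and all
    AP-shape biomarkers (plus E_diast_DC) come from it, while ``trace``
    is the companion no-injection recording supplying E_diast. With a
    single trace the AP biomarkers and E_diast_DC come from it and
    E_diast is recorded as missing (NaN). Per-beat values are aggregated
    by the median for robustness to a single anomalous beat.
    """
    main = trace_dc if trace_dc is not None else trace
    beats = measure_beats(main, discard_beats=discard_beats, fiducial=fiducial)
    if not beats:
        raise NoAPError("no analyzable beat after exclusions")
    med = lambda attr: float(np.median([getattr(b, attr) for b in beats]))
    apd90, apd50, apd20 = med("APD90"), med("APD50"), med("APD20")
    if trace_dc is not None:
        e_diast = _diastolic_level(trace)
    else:
        e_diast = float("nan")
    return APBiomarkers(
        Cm=Cm,
        E_diast=e_diast,
        E_diast_DC=med("E_diast"),
        APD90=apd90,
        APD50=apd50,
        APD20=apd20,
        ratio_20_90=apd20 / apd90,
        dVdt_max=med("dVdt_max"),
        APA=med("APA"),
        fiducial=fiducial,
    )


def _diastolic_level(trace: VoltageTrace) -> float:
    """Diastolic potential of a companion trace.

    Uses the paced-beat diastolic windows when stimulus times are
    present and the final 100 ms of the trace otherwise (unpaced
    settling run).
    """
    if trace.stim_times:
        try:
            beats = measure_beats(trace, discard_beats=0)
            if beats:
                return float(np.median([b.E_diast for b in beats]))
        except NoAPError:
            pass
        # paced but no AP: use the pre-stimulus windows directly
        dt = trace.dt
        vals = []
        for t0 in trace.stim_times:
            i0 = int(round(t0 / dt))
            j0 = max(0, i0 - int(round(10.0 / dt)))
            j1 = max(j0 + 1, i0 - int(round(1.0 / dt)))
            if j1 > j0:
                vals.append(float(np.mean(trace.Vm[j0:j1])))
        if vals:
            return float(np.median(vals))
    n = max(1, int(round(100.0 / trace.dt)))
    return float(np.mean(trace.Vm[-n:]))


@dataclass
class STVSeries:
    """Consecutive-beat APD90 series: n_beats + 1 values give exactly
    n_beats consecutive differences."""

    apd_values: np.ndarray
    n_beats: int = 30

    def __post_init__(self) -> None:
        self.apd_values = np.asarray(self.apd_values, dtype=float)
        if self.apd_values.size != self.n_beats + 1:
            raise ValueError(
                f"need n_beats + 1 = {self.n_beats + 1} APD values for "
                f"n_beats = {self.n_beats} differences; got {self.apd_values.size}"
            )


@dataclass
class STVResult:
    stv: float  # ms
    poincare_pairs: List[Tuple[float, float]]


def stv(series: STVSeries) -> STVResult:
    """Short-term variability of APD: Σ|ΔAPD| / (n_beats·√2), ms."""
    a = series.apd_values
    diffs = np.abs(np.diff(a))
    value = float(diffs.sum() / (series.n_beats * math.sqrt(2.0)))
    pairs = list(zip(a[:-1].tolist(), a[1:].tolist()))
    return STVResult(stv=value, poincare_pairs=pairs)


@dataclass
class RegressionBand:
    """OLS fit with the pointwise 95% confidence band of the mean line."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    _x_mean: float
    _sxx: float
    _s: float  # residual standard error

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def ci_halfwidth(self, x) -> np.ndarray:
        """Half-width of the 95% confidence band at abscissa x."""
        x = np.asarray(x, dtype=float)
        tcrit = sps.t.ppf(0.975, self.n - 2) if self.n > 2 else float("inf")
        return tcrit * self._s * np.sqrt(1.0 / self.n + (x - self._x_mean) ** 2 / self._sxx)


def stv_apd_regression(points: Sequence[Tuple[float, float]]) -> RegressionBand:
    """Ordinary least squares of STV on APD90 with a 95% confidence band.

    ``points`` are (APD90, STV) pairs; at least 3 points with
    non-constant APD90 are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (APD90, STV) points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("APD90 values are constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    s = math.sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0
    return RegressionBand(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
        n=len(x),
        _x_mean=float(x.mean()),
        _sxx=sxx,
        _s=s,
    )
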