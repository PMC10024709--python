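# Methods

## Injected I_K1 formulations

Four formulations are implemented exactly as published (see README for
the equations): the gated, strongly rectifying ventricular current
(O'Hara–Rudy lineage; G = 1.908·scaling_DC nS/pF), the instantaneous,
weakly rectifying atrial current (Koivumäki/Nygren lineage;
G = 0.7·scaling_DC nS/pF), and two diagnostic hybrids — test1 shifts the
activation midpoint constant (144.59 → 57.836, G = 6.417 nS/pF fixed) so
the I/V peak lands on the atrial one, test2 reshapes the rectification
(midpoint 105.8 → 135.8 mV, slope 9.493 → 15.493 mV, G = 6.258 nS/pF
fixed). The test conductances are absolute: scaling_DC does not apply to
them.

Conventions and fixed constants:

- E_K = −94.7 mV, set by the bath (4 mM KCl Tyrode) and pipette K+; it is
  pinned, not recomputed by Nernst, because both values are specified
  independently.
- T = 308.15 K (35 °C recordings). The atrial exponent (F/R)/T is read as
  F/(R·T) and divided by 1000 so it applies to V in mV, matching the
  parent atrial model's dimensional convention.
- Outward current is positive; the membrane equation subtracts it.
- The activation gate x_K1 *increases* with depolarization (→0 at very
  negative V, →1 depolarized); all rectification comes from R_K1. Gated
  formulations advance by Rush–Larsen exponential updates, which are
  exact for the linear gate ODE at fixed V.
- `iv_peak` searches [E_K, −40] mV by default: the weakly rectified
  variants pass outward current again at strongly depolarized potentials
  and would otherwise alias the physiological peak.

Computed at defaults on a 0.01 mV grid, the steady-state I/V peaks fall
at −82.7 mV (ventr), −72.8 mV (atr), −70.8 mV (test1) and −78.5 mV
(test2).

## The virtual cell

No published hiPSC-CM model is reproduced; the surrogate is this
package's own minimal Hodgkin–Huxley-style membrane,
dV/dt = −(ΣI_ion + I_inj) + I_stim with currents in pA/pF:

| current | form | gates | role |
|---|---|---|---|
| I_Na | g_Na·m∞(V)³·h·(V−60) | h: τ 0.8–13 ms | upstroke |
| I_CaL | g_CaL·d·f·(V−45) | d: τ 2.5 ms; f: τ_f | plateau/dome |
| I_Krep | g_Krep·x_r·(V+94.7) | x_r: τ_xr | repolarization |
| I_Kur | g_Kur·a·(V+94.7) | a: τ 2 ms, sustained | atrial marker, 4-AP target |
| I_K1,native | g_K1n·(V+94.7)/(1+e^((V+30)/14)) | — | weak; sets immature diastole |
| I_leak | g_leak·(V+10) | — | depolarizing background |

Preset means (nS/pF; ms): ventricular g_Na 3, g_CaL 0.50, g_Krep 0.015,
g_Kur 0, τ_f 200, τ_xr 60 — a long plateau sitting close to the peak, so
APD20/APD90 ≈ 0.5–0.6; atrial g_Na 3, g_CaL 0.12, g_Krep 0.01, g_Kur
0.03, τ_f 80, τ_xr 40 — a triangular AP with ratio ≈ 0.1–0.2. Cm mean
45 pF. These values were chosen once so that, under atrial-formulation
dynamic clamp at scaling 1.0, the two presets fall on the expected sides
of the 0.44 triangulation cutoff with comfortable margin across the
log-normal parameter jitter (CV 0.15, the heterogeneity of a real
culture).

`make_preset` does not jitter g_K1,native directly: it draws a target
unassisted diastolic potential (−52 − 16·maturity mV ± 2.5 mV, clipped
to (−68.5, −51.5)) and solves g_K1,native from the diastolic current
balance. This guarantees the defining property of the surrogate — an
immature, depolarized diastole in (−70, −50) mV for every seeded cell —
rather than leaving it to jitter tails. Higher `maturity` gives more
native I_K1 and a more negative unassisted diastole.

Stimulation: 1 Hz, 3 ms, 30 pA/pF square pulses; the first 5 beats are
discarded as the settling transient. 4-AP at the atrial-selective dose is
mapped to an I_Kur block fraction of 0.9 (configurable; a dose is a dose,
not a fractional block).

What the generator emulates: depolarized immature diastole, chamber-typed
AP geometry, I_Kur sensitivity, cell-to-cell parameter spread,
atrial-enriched vs standard differentiation mixes (via `atrial_fraction`).
What it does not: calcium handling, spontaneous (nodal-like) activity,
beat-to-beat stochastic channel noise (traces are deterministic, so
simulated STV is ≈ 0), rate dependence beyond the single pacing
frequency, and any quantitative match to recorded hiPSC-CM biomarker
distributions. Passing cohort tests therefore demonstrates that the
pipeline recovers structure the generator put in — not performance on
real cells.

## The dynamic-clamp loop

The loop runs at 5 kHz (0.2 ms samples): at each sample the injected
current is computed from the sample-start membrane potential (after the
gate's Rush–Larsen step over the sample) and held constant within the
sample — a zero-order hold emulating a rig that computes the model
current within one sampling interval. Gate state persists across
samples; on a formulation switch it re-initializes to x∞ at the current
potential, and the switch is logged.

Integration is fixed-step inside each sample: forward Euler for V,
Rush–Larsen for every gate, default 10 substeps (dt_internal 0.02 ms).
A fixed-step scheme was preferred over an adaptive stiff solver because
the loop's contracts are sample-aligned: scaling_DC = 0 must reproduce
the no-injection trace bit-for-bit, and the stateful session must equal
the whole-run kernel exactly, both of which fall out naturally when all
paths share one arithmetic. Convergence is verified by step-halving
(APD90 changes < 1%) and the zero-order hold is validated against
continuous (per-substep) coupling (APD90 within 2%); the inner loop is
numba-compiled. Divergence (non-finite V or |V| > 200 mV) raises an
error naming the beat and configuration.

AP-clamp playback drives a formulation with a fixed recorded voltage
trace, integrating the gate along it. Over the AP itself (upstroke to
90% repolarization) the atrial formulation passes at least as much
charge as the ventricular one; over a full paced cycle the comparison
flips, because the diastolic interval sits ~6 mV from E_K where the
ventricular formulation's 2.7× larger conductance dominates — the
in-AP window is the meaningful one for plateau physiology and is what
the package's tests assert.

## Titration and the critical conductance

`titrate_gk1` sweeps the published scaling grids (atr 0.2–1.0 step 0.05,
ventr 0.4–2.0 step 0.1; 17 points each) with one dynamic-clamp run per
point and medians over the last 10 analyzed beats (defaults: 15 beats,
5 discarded). The critical conductance — the smallest injected
conductance that stabilizes the AP — is not quantitatively defined in
the wet-lab workflow, so this package defines it as a plateau criterion:
the smallest grid point from which E_diast, APD90, APD20/APD90 and APA
all change by less than rel_tol (default 3%) between every remaining
pair of consecutive points. Changes are measured relative to
max(|value|, 1), i.e. relatively for the mV/ms quantities and absolutely
for the dimensionless ratio, whose small values would otherwise never
register as stable. Both the tolerance and the beat aggregation are
configurable. On the default atrial preset the criterion converges at
scaling 0.3 (0.21 nS/pF); the wet-lab reference value for the atrial
formulation is 0.7 nS/pF — a different cell, so no numeric agreement is
asserted, only that the plateau exists inside the printed grid.

## Biomarkers

Per beat: E_diast = mean V over [−10, −1] ms before the stimulus;
APA = V_peak − E_diast; dV/dt_max = maximal forward-difference
derivative over the upstroke (the pre-stimulus sample is included so an
idealized one-sample upstroke still has a derivative); APDx = time from
the fiducial to the first downward crossing of V_peak − (x/100)·APA,
linearly interpolated between samples. The APD onset fiducial is the
time of dV/dt_max by default; a −20 mV threshold-crossing alternative is
available, and the choice is recorded in the output (`fiducial` field)
since the wet-lab convention is not pinned down. Beats that never reach
0 mV are not APs; beats whose repolarization never reaches the 90% level
within the cycle are excluded with a warning. Per-cell values are medians
across analyzed beats (robust to one anomalous beat). E_diast without DC
comes from a companion no-injection run; when only a single trace is
supplied, E_diast is recorded as missing.

STV = Σ|APD_{n+1} − APD_n|/(n_beats·√2) over 30 consecutive differences,
which requires 31 APD values — the divisor matches the number of
differences by construction. The STV–APD90 relation is fit by ordinary
least squares with the standard t-based pointwise 95% confidence band.

## Classification

Features are z-scored before PCA — the nine biomarkers span four orders
of magnitude in raw units, so an unstandardized projection would be
meaningless. PCA keeps two components (signs canonicalized: APD90 loads
non-negatively on PC1); k-means (k = 2, k-means++, 10 restarts, seeded)
clusters the scores; cluster semantics are assigned by mean APD90
(lower = atrial-like). Features missing in more than half the cells are
dropped, otherwise median-imputed with a logged warning.

ROC analysis computes AUC through the rank (Mann–Whitney) identity,
oriented so AUC ≥ 0.5, and picks the cutoff maximizing the Youden index
J = sensitivity + specificity − 1 over midpoints between consecutive
sorted unique values (ties toward the lower cutoff; with perfect
separation the cutoff falls strictly between the groups). The fixed-rule
classifier calls APD20/APD90 < 0.44 atrial-like and ≥ 0.44
ventricular-like (the boundary is ventricular). Group comparisons:
two-sided Mann–Whitney U (exact enumeration when both groups have n ≤ 8
and no ties, normal approximation with tie correction otherwise) and the
classic Levene test on absolute deviations from group means.

## Problem sizes and numerical defaults

Cohort analyses use 46 cells (50/50 atrial/ventricular unless stated),
8 beats per dynamic-clamp run with 5 discarded, plus a 2 s unpaced run
per cell for the unassisted diastole; titrations use 15 beats per grid
point. dt_sample 0.2 ms (5 kHz), dt_internal 0.02 ms. All randomness
flows from explicit integer seeds (cohorts spawn per-cell child seeds),
so every table and trace is bit-reproducible.

## Known limitations

- The surrogate's absolute biomarker values (APD magnitudes, dV/dt_max
  ≈ 130 V/s) are plausible but not calibrated to any recorded dataset;
  only the qualitative contrasts between presets are designed in.
- Deterministic dynamics mean beat-to-beat variability metrics are
  exercised on constructed APD series, not emergent noise.
- Forward Euler limits dt_internal; the default 0.02 ms is ~10× below
  the stability boundary for the preset conductances, but very large
  conductance choices would require a smaller step.
- The critical-conductance plateau rule is a package definition; other
  stabilization criteria would pick different (though nearby) values.
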