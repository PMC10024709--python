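"""Trace file formats and deterministic fixture generation.

Voltage traces travel as plain CSV with header ``t_ms,Vm_mV`` and an
optional leading comment ``# stim_times_ms=0,1000,...``; current traces
use ``t_ms,I_pApF``. Uniform sampling is verified on read. All times
are ms, potentials mV, currents pA/pF, conductances nS/pF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .cell import CurrentTrace, StimulusProtocol, VoltageTrace, generate_cohort, make_preset
from .clamp import run_dc, titrate_gk1
from .ik1 import FORMULATIONS, IK1Config
from .pipeline import build_cohort_table

__all__ = [
    "read_trace",
    "write_trace",
    "read_current",
    "write_current",
    "write_fixture_suite",
]

_GRID_JITTER_TOL = 1e-6  # ms


def write_trace(path, trace: VoltageTrace) -> None:
    """Write a voltage trace as CSV with a stim-times comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if trace.stim_times:
            stims = ",".join(f"{s:.6g}" for s in trace.stim_times)
            fh.write(f"# stim_times_ms={stims}\n")
        fh.write("t_ms,Vm_mV\n")
        for t, v in zip(trace.t, trace.Vm):
            fh.write(f"{t:.10g},{v:.10g}\n")


def read_trace(path) -> VoltageTrace:
    """Read a ``t_ms,Vm_mV`` CSV, verifying the uniform sampling grid."""
    path = Path(path)
    stim_times: list = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "stim_times_ms=" in first:
                payload = first.split("stim_times_ms=", 1)[1].strip()
                if payload:
                    stim_times = [float(x) for x in payload.split(",")]
            header = fh.readline()
        else:
            header = first
        cols = [c.strip() for c in header.strip().split(",")]
        if cols != ["t_ms", "Vm_mV"]:
            raise ValueError(f"{path}: expected columns 't_ms,Vm_mV', found {cols}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    t, vm = data[:, 0], data[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = t[1] - t[0]
    jitter = np.abs(np.diff(t) - dt)
    if jitter.max() > _GRID_JITTER_TOL:
        idx = int(np.argmax(jitter > _GRID_JITTER_TOL)) + 1
        raise ValueError(f"{path}: non-uniform sampling grid at row {idx}")
    return VoltageTrace(t=t, Vm=vm, dt=float(dt), stim_times=stim_times)


def write_current(path, trace: CurrentTrace) -> None:
    pd.DataFrame({"t_ms": trace.t, "I_pApF": trace.I}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_current(path) -> CurrentTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["t_ms", "I_pApF"]:
        raise ValueError(f"{path}: expected columns 't_ms,I_pApF'")
    return CurrentTrace(t=df["t_ms"].to_numpy(), I=df["I_pApF"].to_numpy())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_suite(outdir, seed: int = 0) -> Dict:
    """Deterministic synthetic fixture set; returns (and writes) a manifest.

    Emits one atrial and one ventricular preset trace under each of the
    four formulations (short 3-beat runs), a 46-cell cohort biomarker
    CSV and a coarse atrial titration table; the manifest lists every
    file with its SHA-256 hash. Identical seeds give byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proto = StimulusProtocol(n_beats=3, discard_beats=1)
    files = []
    for pheno in ("atrial", "ventricular"):
        cell = make_preset(pheno, maturity=0.5, seed=seed)
        for form in FORMULATIONS:
            cfg = IK1Config(formulation=form)
            vt, _ = run_dc(cell, cfg, proto)
            name = f"trace_{pheno}_{form}.csv"
            write_trace(outdir / name, vt)
            files.append(name)
    cohort = generate_cohort(46, atrial_fraction=0.5, seed=seed)
    table = build_cohort_table(cohort)
    table.to_csv(outdir / "cohort_biomarkers.csv", index=False, float_format="%.10g")
    files.append("cohort_biomarkers.csv")
    cell = make_preset("atrial", maturity=0.5, seed=seed)
    tit = titrate_gk1(
        cell, "atr", grid=np.round(np.arange(0.2, 1.0 + 1e-9, 0.2), 10),
        protocol=StimulusProtocol(n_beats=8, discard_beats=5), agg_beats=3,
    )
    tit.table.to_csv(outdir / "titration_atr.csv", index=False, float_format="%.10g")
    files.append("titration_atr.csv")
    manifest = {
        "seed": int(seed),
        "n_files": len(files),
        "files": {name: _sha256(outdir / name) for name in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
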