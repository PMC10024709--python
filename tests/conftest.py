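"""Shared fixtures: preset cells, dynamic-clamp runs and a 46-cell cohort.

Simulation-heavy objects are session-scoped so the expensive runs happen
once per test session.
"""

import numpy as np
import pytest

from dynaclamp import IK1Config, StimulusProtocol, make_preset, run_dc
from dynaclamp.cell import generate_cohort
from dynaclamp.pipeline import build_cohort_table

PROTO8 = StimulusProtocol(n_beats=8, discard_beats=5)


@pytest.fixture(scope="session")
def atrial_cell():
    return make_preset("atrial", maturity=0.5, seed=1)


@pytest.fixture(scope="session")
def ventricular_cell():
    return make_preset("ventricular", maturity=0.5, seed=1)


@pytest.fixture(scope="session")
def proto8():
    return PROTO8


@pytest.fixture(scope="session")
def atr_cfg():
    return IK1Config(formulation="atr", scaling_DC=1.0)


@pytest.fixture(scope="session")
def ventr_cfg():
    return IK1Config(formulation="ventr", scaling_DC=1.0)


@pytest.fixture(scope="session")
def atrial_dc_traces(atrial_cell, atr_cfg):
    """Atrial preset under atrial-formulation DC (voltage, current)."""
    return run_dc(atrial_cell, atr_cfg, PROTO8)


@pytest.fixture(scope="session")
def ventricular_dc_traces(ventricular_cell, atr_cfg):
    return run_dc(ventricular_cell, atr_cfg, PROTO8)


@pytest.fixture(scope="session")
def cohort_table():
    """46-cell 50/50 synthetic cohort, biomarkers under atrial DC."""
    cells = generate_cohort(46, atrial_fraction=0.5, seed=7)
    table = build_cohort_table(cells)
    return table[table["ok"]].reset_index(drop=True)
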