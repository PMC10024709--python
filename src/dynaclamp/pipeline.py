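"""End-to-end glue: cohort simulation → dynamic clamp → biomarker table.

Each cell of a cohort gets two virtual recordings: a paced dynamic-clamp
run under the configured I_K1 formulation (all AP-shape biomarkers and
E_diast_DC) and a short unpaced no-injection run supplying the
unassisted diastolic potential E_diast. The result is one row per cell
in the fixed nine-column biomarker layout, ready for the classification
pipeline.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import NoAPError, extract_biomarkers
from .cell import (
    SimulationError,
    StimulusProtocol,
    VirtualCellParams,
    simulate_ap,
)
from .clamp import run_dc
from .ik1 import IK1Config

__all__ = ["cell_biomarkers", "build_cohort_table"]

#: Unpaced settling run used to read the unassisted diastolic potential.
_REST_PROTOCOL = StimulusProtocol(n_beats=2, discard_beats=1, pulse_amplitude=0.0)


def cell_biomarkers(
    cell: VirtualCellParams,
    cfg: IK1Config,
    protocol: Optional[StimulusProtocol] = None,
    dt_internal: float = 0.02,
) -> dict:
    """Nine biomarkers of one cell under dynamic clamp (one table row)."""
    if protocol is None:
        protocol = StimulusProtocol(n_beats=8, discard_beats=5)
    vt_dc, _ = run_dc(cell, cfg, protocol, dt_internal=dt_internal)
    vt_rest = simulate_ap(cell, _REST_PROTOCOL, dt_internal=dt_internal)
    bio = extract_biomarkers(
        vt_rest, trace_dc=vt_dc, Cm=cell.Cm, discard_beats=protocol.discard_beats
    )
    return bio.as_row()


def build_cohort_table(
    cells: Sequence[VirtualCellParams],
    cfg: Optional[IK1Config] = None,
    protocol: Optional[StimulusProtocol] = None,
    dt_internal: float = 0.02,
) -> pd.DataFrame:
    """Biomarker table for a cohort (one row per cell).

    Default injection is the atrial formulation at scaling 1.0 — the
    configuration used to mature the AP waveform before phenotyping.
    Cells whose simulation fails or shows no AP are kept as all-NaN rows
    flagged ``ok=False``. Columns: cell_id, phenotype (ground truth),
    the nine biomarkers, ok.
    """
    if cfg is None:
        cfg = IK1Config(formulation="atr", scaling_DC=1.0)
    rows: List[dict] = []
    for i, cell in enumerate(cells):
        row = {"cell_id": i, "phenotype": cell.phenotype, "ok": True}
        try:
            row.update(cell_biomarkers(cell, cfg, protocol, dt_internal=dt_internal))
        except (SimulationError, NoAPError):
            row["ok"] = False
        rows.append(row)
    df = pd.DataFrame(rows)
    from .classify import FEATURE_COLUMNS  # avoid import cycle at module load

    for c in FEATURE_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[["cell_id", "phenotype"] + FEATURE_COLUMNS + ["ok"]]
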