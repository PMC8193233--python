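import numpy as np
import pandas as pd
import pytest

from peatnet.diversity import OtuTable
from peatnet.ecoplate import (
    N_WELLS,
    ColorResponse,
    PlateSeries,
    standard_ecoplate_layout,
)


@pytest.fixture(scope="session")
def layout():
    return standard_ecoplate_layout()


def make_response(values, sample_id="S1", time_h=72.0, control=0.0):
    """Build a ColorResponse directly from already-clamped per-substrate values."""
    if not isinstance(values, dict):
        values = {f"sub{i + 1}": float(v) for i, v in enumerate(values)}
    clamped = {k: max(float(v), 0.0) for k, v in values.items()}
    raw = {k: float(v) + control for k, v in values.items()}
    return ColorResponse(
        sample_id=sample_id, time_h=time_h, values=clamped,
        n=len(values), control_value=control, raw_ci=raw,
    )


def make_plate(layout, substrate_diff, control_diff=0.3, times=(72.0,),
               base750=0.1):
    """PlateSeries whose (A590-A750) differential equals the given values.

    ``substrate_diff`` maps substrate_id -> differential (same at every time
    unless a callable of t is given).
    """
    times = np.asarray(times, dtype=float)
    readings = np.zeros((len(times), 2, N_WELLS))
    readings[:, 1, :] = base750
    readings[:, 0, :] = base750
    for ti, t in enumerate(times):
        cd = control_diff(t) if callable(control_diff) else control_diff
        for w in layout.control.well_positions:
            readings[ti, 0, w] = base750 + cd
        for s in layout.non_control:
            v = substrate_diff.get(s.substrate_id, 0.0)
            v = v(t) if callable(v) else v
            for w in s.well_positions:
                readings[ti, 0, w] = base750 + v
    return PlateSeries("S1", times, readings, layout)


def toy_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"o{j + 1}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
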