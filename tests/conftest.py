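import numpy as np
import pandas as pd
import pytest

import trenchox as tx


@pytest.fixture(scope="session")
def small_tracks():
    """A small full-loading run under 100 uM covering both analysis epochs."""
    cfg = tx.SimConfig(n_trenches=8, t_start_min=-165.0, t_end_min=140.0, seed=42)
    df, meta = tx.simulate(cfg, tx.TreatmentSchedule.step(100.0))
    return df, meta, cfg


@pytest.fixture()
def tiny_table():
    """Hand-written two-cell trench over eleven frames (dt = 3 min).

    The mother (index 0) grows by an exactly representable 0.125 um per frame; the single barrier cell
    holds constant 3.0 um.  Reporter steps from 100 to 1100 at t = 3 min.
    """
    rows = []
    for k, t in enumerate(range(-15, 18, 3)):
        L0 = 2.0 + 0.125 * k
        rows.append(dict(trench_id=0, frame=k, time_min=float(t), cell_index=0,
                         cell_id=1, lineage_id=1, parent_id=-1, genotype="WT",
                         length_um=L0, area_um2=1.2 * L0, position_um=0.0,
                         reporter_au=100.0 if t <= 0 else 1100.0,
                         marker_au=3000.0, foci_count=0, alive=True,
                         external_c0_uM=100.0 if t >= 0 else 0.0))
        rows.append(dict(trench_id=0, frame=k, time_min=float(t), cell_index=1,
                         cell_id=2, lineage_id=2, parent_id=-1, genotype="WT",
                         length_um=3.0, area_um2=3.6, position_um=L0,
                         reporter_au=200.0, marker_au=3000.0, foci_count=1,
                         alive=True, external_c0_uM=100.0 if t >= 0 else 0.0))
    return pd.DataFrame(rows)


def naive_summary_stats(window):
    """Brute-force reference for the seven summary statistics."""
    y = np.asarray([v for v in window if np.isfinite(v)], dtype=float)
    n = len(y)
    mean = sum(y) / n
    med = float(np.median(y))
    d2 = sum((v - mean) ** 2 for v in y)
    d4 = sum((v - mean) ** 4 for v in y)
    if d2 == 0:
        kurt = skew = 0.0
    else:
        kurt = n * d4 / d2 ** 2
        skew = (mean - med) / (d2 / n) ** 0.5
    return (kurt, skew, med, mean, min(y), max(y), max(y) - min(y))
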