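"""Per-cell derived quantities and the 126-feature matrix for mother cells.

The feature matrix has one row per mother cell (the cell at the closed end of
a trench) and 7 summary statistics x 9 time series x 2 treatment epochs = 126
feature columns plus the response label ``grxa_peak`` (reporter peak within
the first hour of treatment minus the pre-treatment mean).

Five series describe the mother itself (length, area, per-frame elongation
and area rates, surface-area-to-volume ratio) and four describe its local
environment (number of barrier cells and their cumulative length, area and
surface-area-to-volume ratio).  Epochs are the 135 min before and the 135 min
after treatment start, half-open at the treatment time.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATS = ("kurtosis", "skewness", "median", "mean", "min", "max", "range")
MOTHER_SERIES = ("length", "area", "elong_rate", "area_rate", "sav")
BARRIER_SERIES = ("barrier_count", "barrier_length", "barrier_area", "barrier_sav")
SERIES = MOTHER_SERIES + BARRIER_SERIES
EPOCHS = ("untreated", "treated")
EPOCH_SPAN_MIN = 135.0
LABEL = "grxa_peak"
META_COLUMNS = ("trench_id", "external_c0_uM")


def surface_to_volume(length, area):
    """Surface-area-to-volume ratio of a hemisphere-capped cylinder, um^-1.

    The cell is a cylinder of radius r capped with two hemispheres, with
    total length L and projected area A = 2 r L, giving

        SA/V = 12 L^3 / (A (3 L^2 - A)).

    Valid for 0 < A < 3 L^2 (equivalently r < 3L/2).
    """
    L = np.asarray(length, dtype=float)
    A = np.asarray(area, dtype=float)
    if np.any(L <= 0) or np.any(A <= 0):
        raise ValueError("length and area must be positive")
    denom = A * (3.0 * L ** 2 - A)
    if np.any(denom <= 0):
        raise ValueError("area must be below 3*L^2 (geometric domain)")
    out = 12.0 * L ** 3 / denom
    return float(out) if out.ndim == 0 else out


def elongation_rate_log(lengths, dt_min: float):
    """Log-difference elongation rate (ln L_t - ln L_{t-1}) / dt, min^-1.

    The first element is NaN (undefined at a series start).  Lengths must be
    positive.
    """
    L = np.asarray(lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("lengths must be positive")
    out = np.full(L.shape, np.nan)
    out[1:] = np.diff(np.log(L)) / dt_min
    return out


def per_frame_rates(values):
    """Simple per-frame first difference Y_t - Y_{t-1} (per-frame units);
    NaN at the series start."""
    y = np.asarray(values, dtype=float)
    out = np.full(y.shape, np.nan)
    out[1:] = np.diff(y)
    return out


def barrier_stats(trench_frame: pd.DataFrame, cell_index: int,
                  width_um: float | None = None):
    """Barrier summary for one cell in one (trench, frame) record set.

    Barrier cells are those strictly between the focal cell and the open end
    (larger ``cell_index``).  Returns (count, sum length, sum area,
    sum SA/V).  The mother cell (index 0) of an n-cell trench has n - 1
    barriers.
    """
    idx = trench_frame["cell_index"].to_numpy()
    if cell_index not in idx:
        raise ValueError(f"cell_index {cell_index} not present in trench records")
    sel = trench_frame[idx > cell_index]
    if not len(sel):
        return 0, 0.0, 0.0, 0.0
    L = sel["length_um"].to_numpy()
    A = sel["area_um2"].to_numpy()
    sav = surface_to_volume(L, A)
    return int(len(sel)), float(L.sum()), float(A.sum()), float(np.sum(sav))


def summary_stats(window):
    """The seven summary statistics of a window of values.

    kurtosis: n * sum(d^4) / (sum(d^2))^2 (standard population kurtosis);
    skewness: (mean - median) / population SD (nonparametric skew);
    then median, mean, min, max and range.  Constant windows return
    kurtosis = skewness = 0 by convention.  NaNs are dropped; at least four
    finite values are required.
    """
    y = np.asarray(window, dtype=float)
    y = y[np.isfinite(y)]
    n = y.size
    if n < 4:
        raise ValueError(f"window too short ({n} finite values; need >= 4)")
    mean = y.mean()
    med = float(np.median(y))
    d = y - mean
    s2 = float(np.sum(d * d))
    if s2 == 0.0:
        kurt = skew = 0.0
    else:
        kurt = n * float(np.sum(d ** 4)) / s2 ** 2
        skew = (mean - med) / np.sqrt(s2 / n)
    ymin, ymax = float(y.min()), float(y.max())
    return (float(kurt), float(skew), med, float(mean), ymin, ymax, ymax - ymin)


def response_label(reporter, times, treatment_time: float = 0.0,
                   window_min: float = 60.0) -> float:
    """Reporter response peak: max over (0, window] min post-treatment minus
    the mean over all pre-treatment frames."""
    y = np.asarray(reporter, dtype=float)
    t = np.asarray(times, dtype=float)
    pre = y[t < treatment_time]
    post = y[(t > treatment_time) & (t <= treatment_time + window_min)]
    if pre.size == 0 or post.size == 0 or t.max() < treatment_time + window_min:
        raise ValueError("series must span pre-treatment and >= "
                         f"{window_min} min post-treatment")
    return float(np.nanmax(post) - np.nanmean(pre))


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def feature_name(series: str, stat: str, epoch: str) -> str:
    return f"{series}__{stat}__{epoch}"


def feature_manifest() -> dict:
    """Machine-readable description of every feature column.

    Maps column name -> {series, stat, epoch, group} where group is
    ``mother`` or ``barrier``.
    """
    manifest = {}
    for series in SERIES:
        group = "mother" if series in MOTHER_SERIES else "barrier"
        for stat in STATS:
            for epoch in EPOCHS:
                manifest[feature_name(series, stat, epoch)] = {
                    "series": series, "stat": stat, "epoch": epoch,
                    "group": group,
                }
    return manifest


FEATURE_COLUMNS = tuple(feature_manifest().keys())
assert len(FEATURE_COLUMNS) == 126


def _mother_environment_series(trench: pd.DataFrame) -> pd.DataFrame:
    """Per-frame mother and environment series for one trench.

    Input rows cover one trench, all frames.  Output is indexed by time with
    the nine feature series as columns.
    """
    trench = trench.sort_values(["frame", "cell_index"])
    g = trench.groupby("frame", sort=True)
    mother = trench[trench["cell_index"] == 0].set_index("frame")
    out = pd.DataFrame(index=mother.index)
    out["time_min"] = mother["time_min"]
    out["length"] = mother["length_um"]
    out["area"] = mother["area_um2"]
    out["sav"] = surface_to_volume(mother["length_um"].to_numpy(),
                                   mother["area_um2"].to_numpy())
    out["reporter"] = mother["reporter_au"]
    # environment: all cells with index > 0 are the mother's barriers
    barrier = trench[trench["cell_index"] > 0]
    bg = barrier.groupby("frame")
    out["barrier_count"] = g.size() - 1
    out["barrier_length"] = bg["length_um"].sum().reindex(out.index, fill_value=0.0)
    out["barrier_area"] = bg["area_um2"].sum().reindex(out.index, fill_value=0.0)
    sav_all = surface_to_volume(barrier["length_um"].to_numpy(),
                                barrier["area_um2"].to_numpy()) \
        if len(barrier) else np.array([])
    bsav = pd.Series(sav_all, index=barrier.index).groupby(barrier["frame"]).sum()
    out["barrier_sav"] = bsav.reindex(out.index, fill_value=0.0)
    out["elong_rate"] = per_frame_rates(out["length"].to_numpy())
    out["area_rate"] = per_frame_rates(out["area"].to_numpy())
    return out


def build_feature_matrix(tracks: pd.DataFrame, treatment_time: float = 0.0,
                         epoch_span: float = EPOCH_SPAN_MIN,
                         label_window: float = 60.0) -> pd.DataFrame:
    """Build the mother-cell feature matrix from a track table.

    Returns a DataFrame with 126 feature columns, the ``grxa_peak`` label and
    metadata columns (trench_id, external_c0_uM).  Mothers whose series do
    not cover both epochs (or whose label window is incomplete) are dropped
    and logged.  Raises if no mother survives filtering.
    """
    rows = []
    dropped = 0
    for trench_id, trench in tracks.groupby("trench_id", observed=True):
        series = _mother_environment_series(trench)
        t = series["time_min"].to_numpy()
        pre = (t >= treatment_time - epoch_span) & (t < treatment_time)
        post = (t >= treatment_time) & (t < treatment_time + epoch_span)
        n_expect = int(round(epoch_span / np.median(np.diff(t))))
        if pre.sum() < n_expect or post.sum() < n_expect:
            dropped += 1
            continue
        try:
            label = response_label(series["reporter"].to_numpy(), t,
                                   treatment_time, window_min=label_window)
        except ValueError:
            dropped += 1
            continue
        row = {"trench_id": trench_id, LABEL: label}
        c0 = trench.loc[trench["time_min"] >= treatment_time, "external_c0_uM"]
        row["external_c0_uM"] = float(c0.iloc[0]) if len(c0) else 0.0
        ok = True
        for name in SERIES:
            for epoch, mask in (("untreated", pre), ("treated", post)):
                y = series[name].to_numpy()[mask]
                try:
                    vals = summary_stats(y)
                except ValueError:
                    ok = False
                    break
                for stat, v in zip(STATS, vals):
                    row[feature_name(name, stat, epoch)] = v
            if not ok:
                break
        if ok:
            rows.append(row)
        else:
            dropped += 1
    if dropped:
        log.info("build_feature_matrix: dropped %d mothers with incomplete windows",
                 dropped)
    if not rows:
        raise ValueError("no mother cells with complete epochs")
    fm = pd.DataFrame(rows)
    cols = list(META_COLUMNS) + list(FEATURE_COLUMNS) + [LABEL]
    return fm[cols]


def write_feature_matrix(fm: pd.DataFrame, path, manifest_path=None) -> None:
    fm.to_csv(path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(feature_manifest(), fh, indent=1)
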