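"""Response timing/peak statistics, H2O2 calibration, shielding inference,
cross-correlation lag, lineage memory, decay and fate analyses.

Conventions
-----------
Treatment starts at time 0 min; pre-treatment frames carry negative times.
The induction threshold defaults to 1,480 a.u., i.e. 20% of the steady-state
reporter intensity of a fully exposed cell (about 7,400 a.u. at 100 uM).
Steady-state analysis windows (coefficient of variation 90 min-6 h,
calibration 1-3 h, cross-correlation from 2 h) are configurable arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import argrelextrema
from scipy import stats as sstats

from .metrics import surface_to_volume

log = logging.getLogger(__name__)

INDUCTION_THRESHOLD_AU = 1480.0
CALIBRATION_PANEL_UM = (12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 100.0)
DEAD_GROWTH_RATE = 0.012        # min^-1, length growth below this = no growth
DEAD_OBSERVATION_MIN = 600.0    # 10 h without regrowth = dead


# ---------------------------------------------------------------------------
# peaks, induction, CV
# ---------------------------------------------------------------------------

def detect_peak(reporter, times, treatment_time: float = 0.0,
                norm_threshold: float = 0.15, min_distance: int = 2):
    """First qualifying reporter peak after treatment.

    Candidate local maxima in the post-treatment trace are scanned in time
    order; a candidate within ``min_distance`` frames of an already accepted
    one is discarded, and the first whose height normalised to the
    post-treatment range reaches ``norm_threshold`` is reported.  The
    amplitude is baseline-subtracted (mean of all pre-treatment frames).
    Returns (peak_time, amplitude) or (nan, nan) when no peak qualifies.
    """
    y = np.asarray(reporter, dtype=float)
    t = np.asarray(times, dtype=float)
    pre = y[t < treatment_time]
    post_mask = t >= treatment_time
    yp, tp = y[post_mask], t[post_mask]
    if pre.size == 0 or tp.size == 0 or tp.max() - treatment_time < 60.0:
        raise ValueError("need pre-treatment frames and >= 60 min post-treatment")
    baseline = float(np.nanmean(pre))
    lo, hi = float(np.nanmin(yp)), float(np.nanmax(yp))
    if hi <= lo:
        log.info("detect_peak: flat trace, no peak")
        return float("nan"), float("nan")
    # interior local maxima (plateau-safe: >= on both sides)
    cand = [i for i in range(1, len(yp) - 1)
            if yp[i] >= yp[i - 1] and yp[i] >= yp[i + 1]]
    accepted: list[int] = []
    for i in cand:
        if accepted and i - accepted[-1] < min_distance:
            continue
        accepted.append(i)
    for i in accepted:
        if (yp[i] - lo) / (hi - lo) >= norm_threshold:
            return float(tp[i]), float(yp[i] - baseline)
    log.info("detect_peak: no peak above normalised threshold %.2f", norm_threshold)
    return float("nan"), float("nan")


def induction_time(reporter, times, threshold: float = INDUCTION_THRESHOLD_AU,
                   treatment_time: float = 0.0) -> float:
    """First post-treatment crossing of an intensity threshold, in minutes.

    The crossing is linearly interpolated between the last sub-threshold and
    the first supra-threshold frame.  Returns nan when the trace never
    crosses.
    """
    y = np.asarray(reporter, dtype=float)
    t = np.asarray(times, dtype=float)
    post = t >= treatment_time
    yp, tp = y[post], t[post]
    above = np.nonzero(yp >= threshold)[0]
    if above.size == 0:
        return float("nan")
    i = int(above[0])
    if i == 0:
        return float(tp[0])
    y0, y1 = yp[i - 1], yp[i]
    if y1 == y0:
        return float(tp[i])
    frac = (threshold - y0) / (y1 - y0)
    return float(tp[i - 1] + frac * (tp[i] - tp[i - 1]))


def cv(values) -> float:
    """Coefficient of variation, SD/mean (population SD)."""
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 2:
        raise ValueError("need at least two values")
    m = y.mean()
    if m == 0:
        raise ValueError("zero mean: CV undefined")
    return float(y.std(ddof=0) / m)


# ---------------------------------------------------------------------------
# calibration and shielding inference
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Linear intensity <-> concentration map, plus optional attenuation."""

    slope_au_per_uM: float
    intercept_au: float
    r_squared: float
    attenuation: float | None = None
    attenuation_ci: tuple | None = None

    def to_concentration(self, intensity):
        return (np.asarray(intensity, dtype=float) - self.intercept_au) \
            / self.slope_au_per_uM

    def to_intensity(self, concentration):
        return self.intercept_au + self.slope_au_per_uM \
            * np.asarray(concentration, dtype=float)

    def to_dict(self) -> dict:
        return {"slope_au_per_uM": self.slope_au_per_uM,
                "intercept_au": self.intercept_au,
                "r_squared": self.r_squared,
                "attenuation": self.attenuation,
                "attenuation_ci": list(self.attenuation_ci) if self.attenuation_ci else None}


def calibrate(panel: dict) -> CalibrationResult:
    """Least-squares line through (known c0, steady-state intensity) points.

    ``panel`` maps external concentration (uM) to the steady-state reporter
    intensity of fully exposed (outermost) cells: a scalar or an array whose
    mean is used.  At least three distinct concentrations are required.
    """
    concs = np.array(sorted(panel), dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("need >= 3 distinct concentrations to calibrate")
    means = np.array([np.mean(panel[c]) for c in sorted(panel)], dtype=float)
    res = sstats.linregress(concs, means)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationResult(float(res.slope), float(res.intercept),
                             float(res.rvalue ** 2))


def infer_attenuation(concentrations, barrier_counts, n_boot: int = 1000,
                      seed: int = 0) -> tuple[float, tuple]:
    """Per-barrier-cell attenuation fraction from calibrated concentrations.

    Fits ln c = ln c0 + B ln(1 - f) by least squares over (barrier count,
    concentration) pairs and returns ``f_hat = 1 - exp(slope)`` with a
    seeded bootstrap confidence interval (2.5/97.5 percentiles).  f_hat is
    clipped to [0, 1); constant concentrations give 0.
    """
    c = np.asarray(concentrations, dtype=float)
    b = np.asarray(barrier_counts, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive for log-linear fit")
    if np.unique(b).size < 3:
        raise ValueError("need >= 3 distinct barrier counts")

    def fhat(bb, cc):
        slope = np.polyfit(bb, np.log(cc), 1)[0]
        return float(np.clip(1.0 - np.exp(slope), 0.0, 1.0 - 1e-12))

    est = fhat(b, c)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    idx = np.arange(c.size)
    for i in range(n_boot):
        take = rng.choice(idx, size=c.size, replace=True)
        if np.unique(b[take]).size < 2:
            boots[i] = est
        else:
            boots[i] = fhat(b[take], c[take])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return est, ci


def steady_state_intensities(tracks: pd.DataFrame, window=(60.0, 180.0),
                             outermost_only: bool = False) -> pd.DataFrame:
    """Per-cell-slot mean steady-state intensity and barrier count.

    Averages the reporter over the window (minutes post-treatment), per
    trench and per cell position.  ``outermost_only`` restricts to the cell
    nearest the opening (used on calibration-panel runs).  Barrier count of
    a cell at index i in an n-cell trench is n - 1 - i.
    """
    sel = tracks[(tracks["time_min"] >= window[0])
                 & (tracks["time_min"] <= window[1])].copy()
    n_per = sel.groupby(["trench_id", "frame"], observed=True)["cell_index"] \
        .transform("max")
    sel["barrier_count"] = n_per - sel["cell_index"]
    if outermost_only:
        sel = sel[sel["cell_index"] == n_per]
    grouped = sel.groupby(["trench_id", "cell_index"], observed=True).agg(
        intensity=("reporter_au", "mean"),
        barrier_count=("barrier_count", "mean"),
        n_frames=("frame", "size"),
    ).reset_index()
    return grouped


def attenuation_from_tracks(tracks: pd.DataFrame, calibration: CalibrationResult,
                            window=(60.0, 180.0), n_boot: int = 1000,
                            seed: int = 0) -> CalibrationResult:
    """Full shielding inference: convert steady-state intensities to local
    concentrations with the calibration line, then fit the exponential decay
    against barrier count.  Returns the calibration with ``attenuation``
    (and its bootstrap CI) filled in.

    Only mother cells enter the fit: the reporter responds with a
    dilution-limited lag of tens of minutes, so cells moving through the
    gradient report concentrations from positions they occupied earlier,
    while the static mother at the closed end reads its local concentration
    faithfully.  Trench-to-trench variation in occupancy provides the spread
    of barrier counts.  Each mother's pre-treatment mean intensity is
    subtracted before conversion, so the induced intensity is proportional
    to the local concentration and the fitted decay per barrier cell is
    insensitive to the calibration intercept.
    """
    per_cell = steady_state_intensities(tracks, window=window)
    mothers = per_cell[per_cell["cell_index"] == 0].set_index("trench_id")
    pre = tracks[(tracks["time_min"] < 0) & (tracks["cell_index"] == 0)] \
        .groupby("trench_id", observed=True)["reporter_au"].mean()
    induced = mothers["intensity"] - pre.reindex(mothers.index)
    conc = induced.to_numpy() / calibration.slope_au_per_uM
    keep = np.isfinite(conc) & (conc > 0)
    est, ci = infer_attenuation(conc[keep],
                                mothers["barrier_count"].to_numpy()[keep],
                                n_boot=n_boot, seed=seed)
    return CalibrationResult(calibration.slope_au_per_uM,
                             calibration.intercept_au, calibration.r_squared,
                             attenuation=est, attenuation_ci=ci)


# ---------------------------------------------------------------------------
# cross-correlation lag
# ---------------------------------------------------------------------------

def _xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised cross-correlation r[k] = corr(x_t, y_{t+k}) for
    k = -max_lag..max_lag (positive k: x precedes y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(2 * max_lag + 1, np.nan)
    if x.std() == 0 or y.std() == 0:
        return out
    n = x.size
    for j, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if a.size >= 3 and a.std() > 0 and b.std() > 0:
            out[j] = float(np.corrcoef(a, b)[0, 1])
    return out


def cross_correlation_lag(reporter_series, barrier_series, dt_min: float,
                          max_lag: int | None = None,
                          min_frames: int = 20) -> tuple[float, float]:
    """Lag of the reporter behind barrier-count fluctuations, in minutes.

    Accepts a single pair of series or a list of per-trench pairs; per-trench
    normalised cross-correlations are averaged and the negative extremum is
    located by local-extrema search (falling back to the global minimum when
    no interior extremum exists).  A positive lag means barrier-count changes
    precede reporter changes.  Returns (lag_min, correlation at extremum).
    """
    first = reporter_series[0] if len(reporter_series) else None
    if np.ndim(first) >= 1:  # list of per-trench series
        pairs = [(np.asarray(r, float), np.asarray(b, float))
                 for r, b in zip(reporter_series, barrier_series)]
    else:
        pairs = [(np.asarray(reporter_series, float),
                  np.asarray(barrier_series, float))]
    lens = [r.size for r, _ in pairs]
    if min(lens) < min_frames:
        raise ValueError(f"steady-state window too short ({min(lens)} frames, "
                         f"need >= {min_frames})")
    if max_lag is None:
        max_lag = min(min(lens) // 3, 40)
    curves = [c for r, b in pairs
              if np.isfinite(c := _xcorr(b, r, max_lag)).any()]
    mean_curve = np.nanmean(np.vstack(curves), axis=0)
    lags = np.arange(-max_lag, max_lag + 1)
    minima = argrelextrema(mean_curve, np.less_equal, order=2)[0]
    minima = minima[(minima > 0) & (minima < len(mean_curve) - 1)]
    if minima.size:
        k = int(minima[np.argmin(mean_curve[minima])])
    else:
        k = int(np.nanargmin(mean_curve))
    return float(lags[k] * dt_min), float(mean_curve[k])


def reporter_barrier_lag(tracks: pd.DataFrame, steady_from_min: float = 120.0,
                         max_lag: int | None = None) -> tuple[float, float]:
    """Pipeline lag estimate between barrier-count and mother-reporter
    fluctuations at treatment steady state.

    The mother intensity integrates its production, which would bias a lag
    read directly from the intensity trace; the per-frame intensity increment
    is used instead, so the extremum falls at the sensing delay.  Per-trench
    curves are averaged as in :func:`cross_correlation_lag`.
    """
    sel = tracks[tracks["time_min"] >= steady_from_min]
    reporters, barriers = [], []
    dt = float(np.median(np.diff(np.sort(sel["time_min"].unique()))))
    for _, trench in sel.groupby("trench_id", observed=True):
        mother = trench[trench["cell_index"] == 0].sort_values("frame")
        counts = trench.groupby("frame").size().reindex(mother["frame"]) - 1
        dint = np.diff(mother["reporter_au"].to_numpy())
        if dint.size < 20:
            continue
        reporters.append(dint)
        barriers.append(counts.to_numpy()[1:].astype(float))
    if not reporters:
        raise ValueError("no trench with a long enough steady-state window")
    lag, corr = cross_correlation_lag(reporters, barriers, dt, max_lag=max_lag)
    # an increment over (t-1, t] is centred half a frame before its stamp
    return lag - dt / 2.0, corr


# ---------------------------------------------------------------------------
# lineage memory
# ---------------------------------------------------------------------------

def _relation(gen_a: int, gen_b: int) -> str:
    g = max(gen_a, gen_b)
    if g == 1:
        return "sister"
    if g == 2:
        return "cousin"
    return "unrelated"


def _generations_to_mrca(a: int, b: int, parent: dict) -> tuple[int, int] | None:
    """Generations separating cells a and b from their most recent common
    ancestor, or None when unrelated within the recorded genealogy."""
    anc_a = {}
    x, d = a, 0
    while x in parent or d == 0:
        anc_a[x] = d
        x = parent.get(x, -1)
        d += 1
        if x < 0:
            break
        anc_a[x] = d
    x, d = b, 0
    while True:
        if x in anc_a:
            return anc_a[x], d
        x = parent.get(x, -1)
        d += 1
        if x < 0:
            return None


def lineage_correlations(tracks: pd.DataFrame, steady_from_min: float = 120.0,
                         min_pairs: int = 30, frame_stride: int = 5,
                         barrier_strata: list | None = None) -> pd.DataFrame:
    """Pearson correlation of reporter intensity across adjacent cell pairs.

    Adjacent pairs in each trench at steady state are classified by the
    number of generations since their common ancestor: sisters (1), cousins
    (2) or unrelated (> 2 or no recorded ancestor).  Frames are subsampled
    every ``frame_stride`` to limit autocorrelation.  Strata with fewer than
    ``min_pairs`` pairs are skipped and logged.  Returns a tidy frame with
    relation, optional barrier stratum, r and n.
    """
    sel = tracks[tracks["time_min"] >= steady_from_min]
    parent = {}
    firsts = tracks[tracks["parent_id"] >= 0].groupby("cell_id")["parent_id"].first()
    parent.update(firsts.to_dict())
    samples: dict[tuple, list] = {}
    for (_, frame_no), grp in sel.groupby(["trench_id", "frame"], observed=True):
        if frame_no % frame_stride:
            continue
        grp = grp.sort_values("cell_index")
        ids = grp["cell_id"].to_numpy()
        vals = grp["reporter_au"].to_numpy()
        n = len(grp)
        for i in range(n - 1):
            gens = _generations_to_mrca(int(ids[i]), int(ids[i + 1]), parent)
            rel = "unrelated" if gens is None else _relation(*gens)
            b = n - 1 - (i + 1)  # barrier count of the outer cell of the pair
            if barrier_strata is not None:
                stratum = next((s for s in barrier_strata
                                if s[0] <= b <= s[1]), None)
                if stratum is None:
                    continue
            else:
                stratum = None
            samples.setdefault((rel, stratum), []).append((vals[i], vals[i + 1]))
    rows = []
    for (rel, stratum), pairs in sorted(samples.items(), key=lambda kv: str(kv[0])):
        if len(pairs) < min_pairs:
            log.info("lineage_correlations: stratum %s/%s skipped (%d pairs)",
                     rel, stratum, len(pairs))
            continue
        arr = np.asarray(pairs)
        r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        rows.append({"relation": rel, "barrier_stratum": stratum,
                     "r": r, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)


def sister_divergence(tracks: pd.DataFrame, follow_min: float = 30.0,
                      steady_from_min: float = 120.0,
                      barrier_edges=(0, 3, 6, 12)) -> pd.DataFrame:
    """Normalised intensity difference between sister cells after division.

    For each division at steady state the absolute reporter difference of the
    two daughters is followed for ``follow_min`` minutes and normalised by
    the parent's last intensity; curves are grouped by the outer sister's
    barrier count at division into strata given by ``barrier_edges``.
    Returns mean divergence per (stratum, minutes since division) plus the
    exponential growth rate of the divergence per stratum.
    """
    sel = tracks[tracks["time_min"] >= steady_from_min]
    recs = []
    for trench_id, trench in sel.groupby("trench_id", observed=True):
        by_frame = {f: g.sort_values("cell_index")
                    for f, g in trench.groupby("frame")}
        frames = sorted(by_frame)
        parent_last = trench.groupby("cell_id")["reporter_au"].last()
        dt = float(np.median(np.diff(trench["time_min"].unique())))
        horizon = int(round(follow_min / dt))
        for fi, f in enumerate(frames[:-1]):
            nxt = by_frame[frames[fi + 1]]
            pairs = nxt.groupby("parent_id")
            for pid, pair in pairs:
                if len(pair) != 2 or pid < 0 or pid not in parent_last.index:
                    continue
                if pid in by_frame[f]["cell_id"].values:
                    ids = pair["cell_id"].tolist()
                    b = int(len(nxt) - 1 - pair["cell_index"].max())
                    stratum = np.digitize(b, barrier_edges) - 1
                    norm = abs(parent_last[pid])
                    if norm == 0:
                        continue
                    for k in range(1, horizon + 1):
                        if fi + k >= len(frames):
                            break
                        fut = by_frame[frames[fi + k]]
                        sub = fut[fut["cell_id"].isin(ids)]
                        if len(sub) != 2:
                            break
                        diff = abs(sub["reporter_au"].iloc[0]
                                   - sub["reporter_au"].iloc[1]) / norm
                        recs.append({"stratum": stratum, "minutes": k * dt,
                                     "divergence": diff})
    df = pd.DataFrame(recs)
    if df.empty:
        return df
    curves = df.groupby(["stratum", "minutes"]).agg(
        divergence=("divergence", "mean"), n=("divergence", "size")).reset_index()
    rates = []
    for s, grp in curves.groupby("stratum"):
        if len(grp) >= 3 and (grp["divergence"] > 0).all():
            slope = np.polyfit(grp["minutes"], np.log(grp["divergence"]), 1)[0]
        else:
            slope = np.nan
        rates.append({"stratum": s, "rate_per_min": float(slope)})
    curves = curves.merge(pd.DataFrame(rates), on="stratum")
    return curves


# ---------------------------------------------------------------------------
# decay, fate, mutagenesis
# ---------------------------------------------------------------------------

def _masked_log_slope(values: np.ndarray, times: np.ndarray,
                      jump_threshold: float = -0.2) -> float:
    """Slope of ln(values) vs time with division drops masked out.

    Division halves a mother's length/area between frames; per-frame log
    differences below ``jump_threshold`` are treated as division events and
    excluded from the average rate.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(v) & (v > 0)
    v, t = v[ok], t[ok]
    if v.size < 3:
        return float("nan")
    d = np.diff(np.log(v)) / np.diff(t)
    keep = np.diff(np.log(v)) > jump_threshold
    if not keep.any():
        return float("nan")
    return float(np.mean(d[keep]))


def decay_analysis(tracks: pd.DataFrame, removal_time: float,
                   window_min: float = 60.0, skip_min: float = 3.0,
                   baseline: float | None = None) -> dict:
    """Per-mother reporter decay versus growth after stress removal.

    Fits an exponential decay to each mother's baseline-subtracted intensity
    over (removal + skip, removal + window] and a growth rate to its area
    over the same span (division drops masked).  The baseline defaults to
    each mother's pre-treatment mean intensity.  Returns the per-cell table,
    the Pearson correlation between decay and growth rates, and the
    population half-life versus the mean doubling time.
    """
    rows = []
    for trench_id, trench in tracks.groupby("trench_id", observed=True):
        mother = trench[trench["cell_index"] == 0].sort_values("frame")
        t = mother["time_min"].to_numpy()
        mask = (t > removal_time + skip_min) & (t <= removal_time + window_min)
        if mask.sum() < 5:
            continue
        y = mother["reporter_au"].to_numpy()[mask]
        base = baseline if baseline is not None else \
            float(np.nanmean(mother.loc[mother["time_min"] < 0, "reporter_au"]))
        yb = y - base
        tt = t[mask]
        ok = np.isfinite(yb)
        if ok.sum() < 5 or np.nanmax(yb) <= 0:
            log.info("decay_analysis: trench %s dropped (no usable decay "
                     "window)", trench_id)
            continue
        yb, tt = yb[ok], tt[ok]
        # fit the exponential in linear space: a log-space fit would need to
        # exclude noise-dominated tail points, and selecting points by their
        # noisy values biases the slope flat
        t0 = tt[0]
        amp0 = max(float(yb[0]), 1e-6)
        guess = (amp0, 0.02)
        try:
            (amp, decay), _ = curve_fit(
                lambda x, a, d: a * np.exp(-d * (x - t0)), tt, yb, p0=guess,
                bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=2000)
            decay = float(decay)
        except RuntimeError:
            log.info("decay_analysis: trench %s dropped (fit failure)",
                     trench_id)
            continue
        growth = _masked_log_slope(mother["area_um2"].to_numpy()[mask],
                                   t[mask])
        rows.append({"trench_id": trench_id, "decay_rate": decay,
                     "growth_rate": growth})
    per_cell = pd.DataFrame(rows).dropna()
    if len(per_cell) < 3:
        raise ValueError("too few mothers with usable decay fits")
    r = float(np.corrcoef(per_cell["decay_rate"], per_cell["growth_rate"])[0, 1])
    mean_growth = float(per_cell["growth_rate"].mean())
    mean_decay = float(per_cell["decay_rate"].mean())
    return {
        "per_cell": per_cell,
        "correlation": r,
        "half_life_min": float(np.log(2) / mean_decay),
        "doubling_time_min": float(np.log(2) / mean_growth),
    }


def classify_fate(lengths, times, removal_time: float,
                  threshold: float = DEAD_GROWTH_RATE,
                  observation_min: float = DEAD_OBSERVATION_MIN,
                  window_min: float = 45.0) -> tuple[str, float]:
    """Mother-cell fate after stress removal.

    The rolling length growth rate (log-slope over ``window_min``, division
    drops masked) is evaluated after ``removal_time``; the cell is dead if
    the rate never reaches ``threshold`` within ``observation_min``, else
    recovered with ``regrowth_time`` the first time the rolling rate exceeds
    the threshold.  Returns ("undetermined", nan) when the observation
    window is too short.
    """
    L = np.asarray(lengths, dtype=float)
    t = np.asarray(times, dtype=float)
    post = t >= removal_time
    L, t = L[post], t[post]
    if t.size < 3 or t[-1] - removal_time < observation_min:
        return "undetermined", float("nan")
    dt = float(np.median(np.diff(t)))
    w = max(int(round(window_min / dt)), 2)
    dlog = np.diff(np.log(L))
    rate = dlog / np.diff(t)
    rate[dlog <= -0.2] = np.nan  # division events
    # regrowth: instantaneous rate above threshold, confirmed by the mean
    # rate over the following window (rejects single-frame blips)
    for i in range(0, rate.size - w + 1):
        if t[i] - removal_time > observation_min:
            break
        r_now = rate[i]
        r_win = np.nanmean(rate[i:i + w])
        if np.isfinite(r_now) and r_now > threshold \
                and np.isfinite(r_win) and r_win > threshold:
            return "recovered", float(t[i] - removal_time)
    return "dead", float("nan")


def survival_by_barrier(tracks: pd.DataFrame, removal_time: float,
                        **fate_kw) -> pd.DataFrame:
    """Fraction of mothers that regrow after stress removal, by the number
    of barrier cells at the time of treatment (frame closest to t = 0)."""
    rows = []
    for trench_id, trench in tracks.groupby("trench_id", observed=True):
        mother = trench[trench["cell_index"] == 0].sort_values("frame")
        t0 = trench["time_min"].abs().min()
        at0 = trench[trench["time_min"].abs() == t0]
        b = int(len(at0.drop_duplicates("cell_index")) - 1)
        fate, regrow = classify_fate(mother["length_um"].to_numpy(),
                                     mother["time_min"].to_numpy(),
                                     removal_time, **fate_kw)
        rows.append({"trench_id": trench_id, "barrier_count": b,
                     "fate": fate, "regrowth_time_min": regrow})
    df = pd.DataFrame(rows)
    df = df[df["fate"] != "undetermined"]
    summary = df.groupby("barrier_count").agg(
        survival=("fate", lambda s: float(np.mean(s == "recovered"))),
        n=("fate", "size"),
        regrowth_time_min=("regrowth_time_min", "mean"),
    ).reset_index()
    summary.attrs["per_trench"] = df
    return summary


def mismatch_rate(tracks: pd.DataFrame, frame_interval: float | None = None
                  ) -> pd.DataFrame:
    """Population DNA-mismatch rate per frame: total foci / total cells,
    converted to foci per cell per minute."""
    if "foci_count" not in tracks.columns:
        raise ValueError("foci_count column required")
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(np.sort(
            tracks["time_min"].unique()))))
    g = tracks.groupby("frame")
    out = pd.DataFrame({
        "time_min": g["time_min"].first(),
        "rate": g["foci_count"].sum() / g.size() / frame_interval,
    }).reset_index()
    return out


def mismatch_burst_by_barrier(tracks: pd.DataFrame, burst_window: float = 15.0,
                              frame_interval: float | None = None) -> pd.DataFrame:
    """Post-treatment mismatch burst amplitude per barrier-count stratum.

    Cells are stratified by their per-frame barrier count; the burst
    amplitude is the stratum's mean rate over (0, burst_window] minutes
    minus its pre-treatment mean rate.  Averaging over the burst window
    rather than taking the noisy per-frame maximum keeps sparsely populated
    strata comparable.
    """
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(np.sort(
            tracks["time_min"].unique()))))
    df = tracks.copy()
    n_per = df.groupby(["trench_id", "frame"], observed=True)["cell_index"] \
        .transform("max")
    df["barrier_count"] = n_per - df["cell_index"]
    rows = []
    for b, grp in df.groupby("barrier_count"):
        g = grp.groupby("frame")
        rate = g["foci_count"].sum() / g.size() / frame_interval
        t = g["time_min"].first()
        pre = rate[t < 0]
        post = rate[(t > 0) & (t <= burst_window)]
        if len(pre) < 3 or len(post) < 3:
            continue
        rows.append({"barrier_count": int(b),
                     "amplitude": float(post.mean() - pre.mean()),
                     "n_cell_frames": int(grp.shape[0])})
    return pd.DataFrame(rows)
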