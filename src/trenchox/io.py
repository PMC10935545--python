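"""Read, validate and write track tables in a stable text format.

Tracks are CSV files with ``#``-prefixed header metadata lines (schema
version, seed, config digest, frame interval).  Rows are sorted by
(trench_id, frame, cell_index) and floats are written with Python's shortest
round-tripping representation, so write->read and read->write are identities
on valid tables and two writes of the same table are byte-identical.

Frames are 0-based from the start of the recording; the treatment defines
time zero, so pre-treatment frames carry negative times.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TRACK_COLUMNS

SCHEMA_VERSION = "1"

_DTYPES = {
    "trench_id": "int32", "frame": "int32", "time_min": "float64",
    "cell_index": "int16", "cell_id": "int64", "lineage_id": "int64",
    "parent_id": "int64", "genotype": "object", "length_um": "float64",
    "area_um2": "float64", "position_um": "float64", "reporter_au": "float64",
    "marker_au": "float64", "foci_count": "int32", "alive": "bool",
    "external_c0_uM": "float64",
}


class TrackValidationError(ValueError):
    """A track table violates the schema; ``violations`` lists the details."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations[:5])
                         + (f" (+{len(violations) - 5} more)" if len(violations) > 5 else ""))


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df[TRACK_COLUMNS].sort_values(["trench_id", "frame", "cell_index"],
                                       kind="mergesort").reset_index(drop=True)
    return df.astype({k: v for k, v in _DTYPES.items() if k != "genotype"})


def write_tracks(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a track table as CSV with ``#`` metadata header lines.

    Row order (trench, frame, cell_index) and column order are canonical, so
    repeated writes of the same table are byte-identical.  NaN intensities
    are serialised as empty fields.
    """
    df = _canonical(df)
    meta = dict(meta or {})
    meta.setdefault("schema_version", SCHEMA_VERSION)
    buf = _io.StringIO()
    for key in sorted(meta):
        buf.write(f"# {key}={meta[key]}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    return meta


def read_tracks(path, validate: bool = True) -> tuple[pd.DataFrame, dict]:
    """Read a track table; returns ``(tracks, meta)``.

    Structural problems (missing columns, duplicate (trench, frame,
    cell_index), dangling parent links) raise :class:`TrackValidationError`
    naming the offending rows.
    """
    meta = read_meta(path)
    version = meta.get("schema_version")
    if version is not None and version != SCHEMA_VERSION:
        raise TrackValidationError([f"unsupported schema version {version!r}"])
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError([f"missing column {c!r}" for c in missing])
    df = _canonical(df)
    if validate:
        problems = _structural_violations(df)
        if problems:
            raise TrackValidationError(problems)
    return df, meta


def _structural_violations(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    dup = df.duplicated(["trench_id", "frame", "cell_index"])
    if dup.any():
        rows = df.loc[dup, ["trench_id", "frame", "cell_index"]].head(5)
        problems.append(f"duplicate (trench, frame, cell_index) rows: "
                        f"{rows.to_records(index=False).tolist()}")
    # dangling lineage: a parent_id must appear as a cell_id in an earlier frame
    first_seen = df.groupby("cell_id")["frame"].min()
    nonroot = df[df["parent_id"] >= 0]
    if len(nonroot):
        firsts = nonroot.groupby("cell_id").agg(
            frame=("frame", "min"), parent_id=("parent_id", "first"),
            trench_id=("trench_id", "first"))
        parent_first = first_seen.reindex(firsts["parent_id"]).to_numpy()
        dangling = np.isnan(parent_first)
        late = ~dangling & (parent_first >= firsts["frame"].to_numpy())
        for cid, row in firsts[dangling].iterrows():
            problems.append(f"dangling parent_id {row['parent_id']} for cell "
                            f"{cid} (trench {row['trench_id']}, frame {row['frame']})")
        for cid, row in firsts[late].iterrows():
            problems.append(f"parent {row['parent_id']} of cell {cid} does not "
                            f"exist before frame {row['frame']}")
    return problems


def validate_tracks(df: pd.DataFrame, frame_interval: float | None = None,
                    position_tol: float = 1e-6) -> list[str]:
    """Invariant report for a parsed table; empty list iff all checks pass.

    Checks row ordering, per-trench position stacking (non-overlapping,
    ordered cells), uniform time grid and per-cell frame gaps, in addition to
    the structural checks applied on read.
    """
    problems: list[str] = []
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing column {c!r}" for c in missing]
    key = df[["trench_id", "frame", "cell_index"]].to_numpy()
    if not (np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
            == np.arange(len(df))).all():
        problems.append("rows not sorted by (trench_id, frame, cell_index)")
        df = _canonical(df)
    problems.extend(_structural_violations(df))
    # time grid: time must be affine in frame with a single interval
    frames = np.sort(df["frame"].unique())
    times = df.groupby("frame")["time_min"].first().reindex(frames).to_numpy()
    if len(frames) > 1:
        dt = np.diff(times) / np.diff(frames)
        if not np.allclose(dt, dt[0], atol=1e-9):
            problems.append("non-uniform time grid")
        elif frame_interval is not None and not np.isclose(dt[0], frame_interval):
            problems.append(f"frame interval {dt[0]} != declared {frame_interval}")
    # stacking: positions recompute as cumulative lengths from the closed end
    for (tr, fr), grp in df.groupby(["trench_id", "frame"], sort=False, observed=True):
        L = grp["length_um"].to_numpy()
        pos = grp["position_um"].to_numpy()
        expect = np.concatenate(([0.0], np.cumsum(L)[:-1]))
        if np.any(np.abs(pos - expect) > max(position_tol, 1e-9)):
            problems.append(f"overlapping/ill-stacked cells in trench {tr} frame {fr}")
    # per-cell frame gaps
    for cid, grp in df.groupby("cell_id", sort=False):
        f = grp["frame"].to_numpy()
        gaps = np.nonzero(np.diff(f) > 1)[0]
        for g in gaps:
            problems.append(f"gap in cell {cid} after frame {int(f[g])}")
    return problems
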