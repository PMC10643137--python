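"""Localization and trajectory I/O plus nearest-neighbour track linking.

Positions are in micrometres and times in seconds throughout the package.
A localization table is a per-frame list of (x, y[, z]) detections; linking
connects detections in *consecutive* frames whose separation does not exceed
a search radius (800 nm for 20 ms imaging, 500 nm for 500 ms imaging in the
regime this toolkit targets).  No gap closing is performed by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

log = logging.getLogger(__name__)

#: linking radius for 20 ms exposure data (µm)
MAX_JUMP_20MS = 0.8
#: linking radius for 500 ms exposure data (µm)
MAX_JUMP_500MS = 0.5

_LOC_COLUMNS = ("frame", "x", "y")
_TRAJ_COLUMNS = ("traj_id", "frame", "x", "y")


@dataclass
class Trajectory:
    """An ordered track of positions sampled at a uniform frame interval.

    Parameters
    ----------
    id : str
        Track identifier, unique within a dataset.
    dt : float
        Frame interval in seconds.
    frames : ndarray of int, shape (n,)
        Strictly increasing, consecutive frame indices (no gaps).
    xyz : ndarray, shape (n, dim)
        Positions in µm; ``dim`` is 2 or 3.
    intensity : ndarray or None
        Optional per-frame intensity proxy.
    """

    id: str
    dt: float
    frames: np.ndarray
    xyz: np.ndarray
    intensity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] not in (2, 3):
            raise FormatError(f"trajectory {self.id}: positions must be (n, 2|3)")
        n = len(self.frames)
        if n < 2 or self.xyz.shape[0] != n:
            raise FormatError(f"trajectory {self.id}: need >= 2 matched points")
        if np.any(np.diff(self.frames) != 1):
            raise FormatError(f"trajectory {self.id}: frames must be consecutive")
        if self.frames[0] < 0:
            raise FormatError(f"trajectory {self.id}: negative frame index")
        if not np.all(np.isfinite(self.xyz)):
            raise FormatError(f"trajectory {self.id}: non-finite coordinates")
        if self.dt <= 0:
            raise FormatError(f"trajectory {self.id}: dt must be > 0")

    @property
    def n(self) -> int:
        return len(self.frames)

    @property
    def dim(self) -> int:
        return self.xyz.shape[1]

    @property
    def duration(self) -> float:
        """Track duration in seconds, (n - 1) * dt."""
        return (self.n - 1) * self.dt


def filter_by_duration(trajs: list[Trajectory], min_seconds: float) -> list[Trajectory]:
    """Keep trajectories lasting strictly more than ``min_seconds``."""
    return [t for t in trajs if t.duration > min_seconds]


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_localizations(
    locs: pd.DataFrame,
    max_jump: float,
    dt: float = 0.02,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Link per-frame localizations into trajectories.

    Candidate pairs between consecutive frames are resolved greedily in
    ascending distance order, each endpoint used at most once.  Fragments
    shorter than two points are discarded.

    Parameters
    ----------
    locs : DataFrame
        Columns ``frame, x, y[, z][, intensity]``.
    max_jump : float
        Maximum allowed displacement between consecutive frames (µm).
    dt : float
        Frame interval in seconds, stored on the returned trajectories.
    max_gap : int
        Number of skipped frames tolerated between linked detections
        (default 0: only strictly consecutive frames are connected; a
        tolerated gap is filled by repeating nothing -- the track is split).

    Returns
    -------
    list of Trajectory
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be > 0")
    if locs.empty:
        return []
    locs = _validate_localizations(locs).reset_index(drop=True)
    if locs.empty:
        return []

    dims = ["x", "y"] + (["z"] if "z" in locs.columns else [])
    has_int = "intensity" in locs.columns
    frame_arr = locs["frame"].to_numpy()
    pos = locs[dims].to_numpy()
    by_frame: dict[int, np.ndarray] = {
        int(f): np.flatnonzero(frame_arr == f) for f in np.unique(frame_arr)
    }

    chains: list[list[int]] = []
    open_chain_of_row: dict[int, int] = {}
    for fa in sorted(by_frame):
        fb = fa + 1
        if fb not in by_frame:
            continue
        ra, rb = by_frame[fa], by_frame[fb]
        d = np.linalg.norm(pos[ra][:, None, :] - pos[rb][None, :, :], axis=2)
        ii, jj = np.nonzero(d <= max_jump)
        order = np.argsort(d[ii, jj], kind="stable")
        used_a: set[int] = set()
        used_b: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            row_a, row_b = int(ra[i]), int(rb[j])
            ci = open_chain_of_row.pop(row_a, None)
            if ci is None:
                chains.append([row_a])
                ci = len(chains) - 1
            chains[ci].append(row_b)
            open_chain_of_row[row_b] = ci

    assigned = {r for c in chains for r in c}
    for row in range(len(locs)):  # singletons become 1-point chains
        if row not in assigned:
            chains.append([row])

    if max_gap > 0:
        chains = _close_gaps(chains, frame_arr, pos, max_jump, max_gap)

    trajs: list[Trajectory] = []
    for rows in chains:
        if len(rows) < 2:
            continue
        frames = frame_arr[rows]
        xyz = pos[rows]
        # tolerated gap frames are filled by linear interpolation so the
        # consecutive-frame invariant holds
        full = np.arange(frames[0], frames[-1] + 1)
        if len(full) != len(frames):
            xyz = np.column_stack(
                [np.interp(full, frames, xyz[:, d]) for d in range(xyz.shape[1])]
            )
            frames = full
            inten = None
        else:
            inten = locs["intensity"].to_numpy()[rows] if has_int else None
        trajs.append(
            Trajectory(
                id=f"t{len(trajs):05d}", dt=dt, frames=frames, xyz=xyz, intensity=inten
            )
        )
    return trajs


def _close_gaps(
    chains: list[list[int]],
    frame_arr: np.ndarray,
    pos: np.ndarray,
    max_jump: float,
    max_gap: int,
) -> list[list[int]]:
    """Join chain ends to chain starts across <= max_gap skipped frames.

    Candidates are resolved greedily in ascending distance; the allowed
    distance scales with the number of frame steps bridged.
    """
    cand = []
    for a, ca in enumerate(chains):
        for b, cb in enumerate(chains):
            if a == b:
                continue
            step = frame_arr[cb[0]] - frame_arr[ca[-1]]
            if 2 <= step <= max_gap + 1:
                d = float(np.linalg.norm(pos[cb[0]] - pos[ca[-1]]))
                if d <= max_jump * step:
                    cand.append((d, a, b))
    parent = list(range(len(chains)))
    tail_used: set[int] = set()
    head_used: set[int] = set()
    merged: dict[int, list[int]] = {i: list(c) for i, c in enumerate(chains)}
    for d, a, b in sorted(cand):
        if a in tail_used or b in head_used:
            continue
        ra = a
        while parent[ra] != ra:
            ra = parent[ra]
        if ra == b:
            continue
        tail_used.add(a)
        head_used.add(b)
        merged[ra].extend(merged.pop(b))
        parent[b] = ra
    return list(merged.values())


def _validate_localizations(locs: pd.DataFrame) -> pd.DataFrame:
    for col in _LOC_COLUMNS:
        if col not in locs.columns:
            raise FormatError(f"localization table missing mandatory column {col!r}")
    dims = ["x", "y"] + (["z"] if "z" in locs.columns else [])
    finite = np.isfinite(locs[dims].to_numpy()).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        log.warning("rejected %d localization(s) with non-finite coordinates", n_bad)
    out = locs.loc[finite].copy()
    out["frame"] = out["frame"].astype(np.int64)
    if (out["frame"] < 0).any():
        raise FormatError("negative frame indices in localization table")
    return out


# ---------------------------------------------------------------------------
# file I/O (delimited text)
# ---------------------------------------------------------------------------

def read_localizations(path, unit: str = "um", sep: str = ",") -> pd.DataFrame:
    """Read a localization table; ``unit='nm'`` converts positions to µm.

    Non-finite coordinate rows are dropped with a logged warning; the count
    of rejected records is available as ``df.attrs['n_rejected']``.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in _LOC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    dims = ["x", "y"] + (["z"] if "z" in df.columns else [])
    n0 = len(df)
    out = _validate_localizations(df)
    if unit == "nm":
        out[dims] = out[dims] / 1000.0
    elif unit != "um":
        raise ValueError(f"unknown unit {unit!r}")
    out.attrs["n_rejected"] = n0 - len(out)
    return out


def write_trajectories(trajs: list[Trajectory], path, sep: str = ",") -> None:
    """Write trajectories as a flat table (traj_id, frame, x, y[, z][, intensity])."""
    if not trajs:
        pd.DataFrame(columns=list(_TRAJ_COLUMNS)).to_csv(path, sep=sep, index=False)
        return
    dim = trajs[0].dim
    rows = []
    for t in trajs:
        if t.dim != dim:
            raise FormatError("mixed 2D/3D trajectories in one file")
        d = {"traj_id": t.id, "frame": t.frames, "x": t.xyz[:, 0], "y": t.xyz[:, 1]}
        if dim == 3:
            d["z"] = t.xyz[:, 2]
        if t.intensity is not None:
            d["intensity"] = t.intensity
        d["dt"] = t.dt
        rows.append(pd.DataFrame(d))
    # %.17g round-trips float64 bit-exactly
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def read_trajectories(path, sep: str = ",", dt: float | None = None) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories`.

    ``dt`` overrides (or supplies, for foreign tables without a dt column)
    the frame interval.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in _TRAJ_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    has_z = "z" in df.columns
    if has_z:
        z_na = df["z"].isna()
        if z_na.any() and not z_na.all():
            raise FormatError(f"{path}: mixed 2D/3D rows within one file")
        if z_na.all():
            has_z = False
    dims = ["x", "y"] + (["z"] if has_z else [])
    trajs = []
    for tid, g in df.groupby("traj_id", sort=False):
        t_dt = dt if dt is not None else (float(g["dt"].iloc[0]) if "dt" in g else 0.02)
        trajs.append(
            Trajectory(
                id=str(tid),
                dt=t_dt,
                frames=g["frame"].to_numpy(),
                xyz=g[dims].to_numpy(),
                intensity=g["intensity"].to_numpy() if "intensity" in g else None,
            )
        )
    return trajs
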