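"""Sliding-window biophysical parameters of single-molecule trajectories.

For every position of an 11-frame sliding window, four parameters are
computed from the time-averaged mean squared displacement (TA-MSD) and the
raw positions:

``alpha``
    Anomalous diffusion exponent, the log-log slope of TA-MSD versus lag
    time over lags 1..``msd_max_lag`` (MSD proportional to t**alpha;
    alpha ~ 1 free diffusion, alpha < 1 subdiffusive/condensed, alpha > 1
    directed).
``d_app``
    Apparent diffusion coefficient from the lag-1 MSD,
    ``MSD(1) / (2 * dim * dt)`` (µm²/s).
``lc``
    Localization length: RMS distance of the window's points from their
    centroid (µm) -- the spatial scale explored within the window.
``drift_norm``
    Magnitude of the window-averaged velocity vector (µm/s); large values
    indicate directed motion.

All four are computed in the trajectory's native dimensionality, which is
recorded on the output so 2D locus-tracking data and 3D single-molecule
data are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import WindowError
from .trajio import Trajectory

FEATURE_NAMES = ("alpha", "d_app", "lc", "drift_norm")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window settings.

    window_len must be odd (so a window has a centre frame) and >= 5;
    MSD lags run from 1 to msd_max_lag (default 5, roughly half the
    default 11-frame window -- a standard bias/variance compromise).
    """

    window_len: int = 11
    msd_max_lag: int = 5
    min_traj_len: int = 11
    #: known static localization precision (µm, per axis).  When > 0, the
    #: constant MSD offset 2*dim*loc_sd**2 is subtracted before the alpha
    #: log-log fit (standard static-error correction); d_app, lc and drift
    #: are reported uncorrected.  Windows whose corrected MSD is not
    #: positive at every fitted lag are flagged degenerate.
    loc_sd: float = 0.0
    #: apply the two-pass fGn delta-method bias correction to the window
    #: alpha estimates (the raw log-log slope is biased low because the
    #: TA-MSD sampling variance grows with lag)
    alpha_bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 5 or self.window_len % 2 == 0:
            raise ValueError("window_len must be odd and >= 5")
        if not (1 <= self.msd_max_lag <= self.window_len - 1):
            raise ValueError("msd_max_lag must be in [1, window_len - 1]")
        if self.loc_sd < 0:
            raise ValueError("loc_sd must be >= 0")


@dataclass
class FeatureSeries:
    """Window features for one trajectory (one row per window position)."""

    traj_id: str
    dim: int
    dt: float
    n_frames: int
    center_frames: np.ndarray  # absolute frame index of each window centre
    table: pd.DataFrame  # columns: alpha, d_app, lc, drift_norm, valid

    def __len__(self) -> int:
        return len(self.center_frames)


def ta_msd(points: np.ndarray, dt: float, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one window at lags 1..max_lag (µm²).

    ``MSD(l)`` averages the squared Euclidean displacement over all pairs of
    in-window points separated by ``l`` frames.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise WindowError("window points must be a (n, dim) array")
    n = points.shape[0]
    if n < max_lag + 1:
        raise WindowError(f"window of {n} points too short for max_lag={max_lag}")
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = points[lag:] - points[:-lag]
        out[lag - 1] = np.mean(np.sum(disp * disp, axis=1))
    return out


def estimate_alpha(msd: np.ndarray, dt: float) -> float:
    """Anomalous exponent: least-squares slope of log MSD vs log lag time.

    Returns NaN for degenerate windows (any zero MSD at a fitted lag);
    such windows are excluded from downstream mixture fitting.
    """
    msd = np.asarray(msd, dtype=float)
    if np.any(msd <= 0):
        return float("nan")
    lags = np.arange(1, len(msd) + 1)
    u = np.log(lags * dt)
    v = np.log(msd)
    uc = u - u.mean()
    return float(np.dot(uc, v - v.mean()) / np.dot(uc, uc))


def estimate_dapp(msd: np.ndarray, dt: float, dim: int) -> float:
    """Apparent diffusion coefficient, MSD(1) / (2 dim dt), in µm²/s."""
    return float(msd[0] / (2.0 * dim * dt))


def estimate_lc(points: np.ndarray) -> float:
    """Localization length: RMS distance of window points from their centroid."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise WindowError("lc needs >= 2 points")
    dev = points - points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def estimate_drift(points: np.ndarray, dt: float) -> tuple[np.ndarray, float]:
    """Window drift vector V (mean per-frame displacement / dt) and its norm."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise WindowError("drift needs >= 2 points")
    v = (points[-1] - points[0]) / ((points.shape[0] - 1) * dt)
    return v, float(np.linalg.norm(v))


def _log_msd_bias(alpha: float, window_len: int, max_lag: int, dim: int) -> np.ndarray:
    """Delta-method bias of log TA-MSD per lag for fractional Brownian motion.

    With overlapping displacement pairs the window TA-MSD m(l) is a noisy,
    correlated average, so E[log m] = log M - Var(m)/(2 M^2) to first order.
    The relative variance follows from the exact fGn covariance: for
    displacements X_i at lag l, corr(X_i, X_j) = (|d+l|^a + |d-l|^a
    - 2|d|^a) / (2 l^a) with d = i - j, and Var(m)/M^2 =
    (2/dim) * mean of corr^2 over all pair combinations.  Returns the
    per-lag additive correction (to be *added* to log m before the slope
    fit).
    """
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        n = window_len - lag
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        corr = (
            np.abs(d + lag) ** alpha + np.abs(d - lag) ** alpha - 2 * d**alpha
        ) / (2.0 * lag**alpha)
        r = (2.0 / dim) * np.mean(corr**2)
        out[lag - 1] = r / 2.0
    return out


_BIAS_GRID = np.linspace(0.05, 2.0, 40)
_bias_tables: dict[tuple[int, int, int], np.ndarray] = {}


def _bias_table(window_len: int, max_lag: int, dim: int) -> np.ndarray:
    key = (window_len, max_lag, dim)
    if key not in _bias_tables:
        _bias_tables[key] = np.array(
            [_log_msd_bias(a, window_len, max_lag, dim) for a in _BIAS_GRID]
        )
    return _bias_tables[key]


def precision_floor(sigma: float, exposure: float) -> float:
    """Lower measurability bound on the effective diffusion coefficient.

    With localization precision ``sigma`` (µm) and exposure time (s), any
    measured diffusion coefficient below ``sigma**2 / exposure`` (µm²/s,
    displacement squared over time) has no biophysical interpretation.
    For instance 60 nm precision at 20 ms exposure gives a floor of
    0.18 µm²/s, and 34 nm at 500 ms gives ~0.002 µm²/s.
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma * sigma / exposure


def sliding_features(traj: Trajectory, config: WindowConfig | None = None) -> FeatureSeries:
    """Compute the four window parameters at every window position (stride 1).

    A trajectory of n frames yields ``n - window_len + 1`` windows; shorter
    trajectories yield an empty series.  Windows with a zero MSD at any
    fitted lag carry ``alpha = NaN`` and ``valid = False``.
    """
    cfg = config or WindowConfig()
    w = cfg.window_len
    n = traj.n
    if n < max(w, cfg.min_traj_len):
        return FeatureSeries(
            traj.id, traj.dim, traj.dt, n,
            np.empty(0, dtype=np.int64),
            pd.DataFrame(columns=[*FEATURE_NAMES, "valid"]),
        )
    P = traj.xyz
    n_win = n - w + 1
    half = (w - 1) // 2

    # windowed TA-MSD per lag via cumulative sums of squared displacements
    msd = np.empty((n_win, cfg.msd_max_lag))
    for lag in range(1, cfg.msd_max_lag + 1):
        disp = P[lag:] - P[:-lag]
        sq = np.sum(disp * disp, axis=1)
        c = np.concatenate(([0.0], np.cumsum(sq)))
        npairs = w - lag
        msd[:, lag - 1] = (c[npairs : npairs + n_win] - c[:n_win]) / npairs

    msd_fit = msd - 2.0 * traj.dim * cfg.loc_sd**2
    valid = np.all(msd_fit > 0, axis=1)
    lags = np.arange(1, cfg.msd_max_lag + 1)
    u = np.log(lags * traj.dt)
    uc = u - u.mean()
    wts = uc / np.dot(uc, uc)
    alpha = np.full(n_win, np.nan)
    if valid.any():
        lv = np.log(msd_fit[valid])
        raw = (lv - lv.mean(axis=1, keepdims=True)) @ wts
        if cfg.alpha_bias_correction:
            # two-pass small-sample bias correction: the raw log-log slope
            # is biased low because Var(TA-MSD) grows with lag; correct
            # with the fGn delta-method bias at the first-pass exponent
            table = _bias_table(w, cfg.msd_max_lag, traj.dim)
            gi = np.clip(
                np.searchsorted(
                    _BIAS_GRID, np.clip(raw, _BIAS_GRID[0], _BIAS_GRID[-1])
                ),
                0, len(_BIAS_GRID) - 1,
            )
            lv_c = lv + table[gi]
            raw = (lv_c - lv_c.mean(axis=1, keepdims=True)) @ wts
        alpha[valid] = raw

    d_app = msd[:, 0] / (2.0 * traj.dim * traj.dt)

    # windowed RMS radius about the centroid: E[x^2] - E[x]^2 summed over axes
    cs = np.concatenate([np.zeros((1, traj.dim)), np.cumsum(P, axis=0)])
    cs2 = np.concatenate([np.zeros((1, traj.dim)), np.cumsum(P * P, axis=0)])
    mean = (cs[w : w + n_win] - cs[:n_win]) / w
    mean2 = (cs2[w : w + n_win] - cs2[:n_win]) / w
    var = np.maximum(mean2 - mean * mean, 0.0)
    lc = np.sqrt(var.sum(axis=1))

    vvec = (P[w - 1 :] - P[: n_win]) / ((w - 1) * traj.dt)
    drift_norm = np.linalg.norm(vvec, axis=1)

    table = pd.DataFrame(
        {
            "alpha": alpha,
            "d_app": d_app,
            "lc": lc,
            "drift_norm": drift_norm,
            "valid": valid,
        }
    )
    centers = traj.frames[half : half + n_win]
    return FeatureSeries(traj.id, traj.dim, traj.dt, n, centers, table)


def pool_features(series: list[FeatureSeries]) -> pd.DataFrame:
    """Stack per-trajectory feature tables into one table with provenance.

    Raises if the series mix dimensionalities: 2D and 3D parameters are not
    comparable and must never be pooled.
    """
    if not series:
        return pd.DataFrame(columns=["traj_id", "center_frame", *FEATURE_NAMES, "valid"])
    dims = {s.dim for s in series if len(s)}
    if len(dims) > 1:
        raise ValueError(f"refusing to pool features of mixed dimensionality {sorted(dims)}")
    frames = []
    for s in series:
        if not len(s):
            continue
        t = s.table.copy()
        t.insert(0, "traj_id", s.traj_id)
        t.insert(1, "center_frame", s.center_frames)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["dim"] = dims.pop()
    return out
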