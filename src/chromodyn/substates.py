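"""Two-stage substate analysis of chromatin-bound (500 ms exposure) tracks.

Stage 1 splits chromatin-bound windows into slow-moving/immobile (S) and
fast-moving classes with the 4D Gaussian mixture (the slow class is the
mixture component with the smaller mean D_app).  Stage 2 fits a
two-component Gaussian mixture to the anomalous-exponent (alpha) values of
the *fast* windows only, resolving a fast-condensed state F1 (lower alpha)
from a rarer fast-decondensed state F2 (higher alpha, typically with high
drift).  The drift parameter is reported alongside F2 calls but does not
enter the Stage-2 fit, which acts on alpha alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .exceptions import InsufficientDataError
from .features import FeatureSeries
from .segmentation import CONFINED, StateModel, classify_windows

log = logging.getLogger(__name__)

S, F1, F2 = "S", "F1", "F2"


@dataclass
class AlphaMixtureFit:
    """Stage-2 1D Gaussian mixture over fast-window alpha values.

    Components are ordered by mean: F1 = lower alpha, F2 = higher alpha.
    ``proportions`` is a simplex over (S, F1, F2): the S share is the slow
    fraction from the Stage-1 split; F1/F2 split the fast share by the
    fitted mixture weights.
    """

    means: np.ndarray  # (2,) alpha, ordered ascending
    sds: np.ndarray
    weights: np.ndarray  # within the fast class, sums to 1
    slow_share: float
    proportions: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_fast: int = 0
    n_slow: int = 0
    #: BIC(2 components) - BIC(1 component); >= 0 flags a degenerate split
    bic_delta: float = float("-inf")

    @property
    def degenerate(self) -> bool:
        """Overlap diagnostic: fires when the two-component fit does not
        beat a single Gaussian on BIC."""
        return self.bic_delta >= 0


def split_slow_fast(
    model: StateModel, series_list: list[FeatureSeries]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition bound windows into slow and fast by the Stage-1 component.

    Returns (slow, fast) window tables, each carrying traj_id, center_frame,
    the four features and the slow posterior.  Counts are conserved:
    len(slow) + len(fast) = number of assigned (valid) windows.
    """
    rows_slow, rows_fast = [], []
    for s in series_list:
        if not len(s):
            continue
        cls = classify_windows(model, s)
        t = s.table.copy()
        t.insert(0, "traj_id", s.traj_id)
        t.insert(1, "center_frame", s.center_frames)
        t["p_slow"] = cls["p_confined"].to_numpy()
        assigned = t[t["valid"].astype(bool) & ~t["p_slow"].isna()]
        is_slow = (cls["label"] == CONFINED).to_numpy()[assigned.index]
        rows_slow.append(assigned[is_slow])
        rows_fast.append(assigned[~is_slow])
    slow = pd.concat(rows_slow, ignore_index=True) if rows_slow else pd.DataFrame()
    fast = pd.concat(rows_fast, ignore_index=True) if rows_fast else pd.DataFrame()
    if len(slow) + len(fast) == 0:
        raise InsufficientDataError("no assigned windows after filtering")
    return slow, fast


def fit_alpha_mixture(
    fast_alphas: np.ndarray,
    n_slow: int,
    k: int = 2,
    seed: int = 0,
    n_boot: int = 1000,
) -> AlphaMixtureFit:
    """Fit the Stage-2 alpha mixture and assemble S/F1/F2 proportions.

    Bootstrap confidence intervals (percentile, default 1,000 resamples,
    seeded) cover the component means, SDs, weights and the three state
    proportions; pass ``n_boot=0`` to skip them.
    """
    alphas = np.asarray(fast_alphas, dtype=float)
    alphas = np.sort(alphas[np.isfinite(alphas)])  # canonical order
    if len(alphas) < 50:
        raise InsufficientDataError(f"need >= 50 fast alpha values, got {len(alphas)}")

    def _fit(
        a: np.ndarray, rs: int, init: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        kw = (
            dict(means_init=init.reshape(-1, 1), n_init=1)
            if init is not None
            else dict(init_params="k-means++", n_init=10)
        )
        g = GaussianMixture(
            n_components=k, covariance_type="full", random_state=rs, **kw
        ).fit(a.reshape(-1, 1))
        order = np.argsort(g.means_.ravel())
        return (
            g.means_.ravel()[order],
            np.sqrt(g.covariances_.ravel()[order]),
            g.weights_[order],
        )

    means, sds, weights = _fit(alphas, seed)
    a2 = alphas.reshape(-1, 1)
    g2 = GaussianMixture(k, covariance_type="full", n_init=10,
                         init_params="k-means++", random_state=seed).fit(a2)
    g1 = GaussianMixture(1, covariance_type="full").fit(a2)
    bic_delta = float(g2.bic(a2) - g1.bic(a2))
    n_fast = len(alphas)
    slow_share = n_slow / (n_slow + n_fast)
    fast_share = 1.0 - slow_share
    props = {
        S: slow_share,
        F1: fast_share * float(weights[0]),
        F2: fast_share * float(weights[1]),
    }

    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        stats = {key: [] for key in
                 ["mean_F1", "mean_F2", "sd_F1", "sd_F2", "w_F1", "w_F2",
                  "prop_S", "prop_F1", "prop_F2"]}
        n_total = n_slow + n_fast
        for b in range(n_boot):
            ns_b = int(rng.binomial(n_total, slow_share))
            nf_b = n_total - ns_b
            if nf_b < 50:
                continue
            a_b = rng.choice(alphas, size=nf_b, replace=True)
            try:
                # bootstrap refits start from the point estimate
                m_b, s_b, w_b = _fit(a_b, seed, init=means)
            except Exception:  # pragma: no cover - sklearn failure on odd resample
                continue
            fs_b = nf_b / n_total
            stats["mean_F1"].append(m_b[0])
            stats["mean_F2"].append(m_b[1])
            stats["sd_F1"].append(s_b[0])
            stats["sd_F2"].append(s_b[1])
            stats["w_F1"].append(w_b[0])
            stats["w_F2"].append(w_b[1])
            stats["prop_S"].append(1 - fs_b)
            stats["prop_F1"].append(fs_b * w_b[0])
            stats["prop_F2"].append(fs_b * w_b[1])
        for key, vals in stats.items():
            if vals:
                lo, hi = np.percentile(vals, [2.5, 97.5])
                ci[key] = (float(lo), float(hi))

    fit = AlphaMixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        slow_share=slow_share,
        proportions=props,
        ci=ci,
        n_fast=n_fast,
        n_slow=n_slow,
        bic_delta=bic_delta,
    )
    if fit.degenerate:
        log.warning("alpha mixture components overlap (degenerate split)")
    return fit


def classify_alpha(fit: AlphaMixtureFit, alphas: np.ndarray) -> np.ndarray:
    """Posterior-based F1/F2 call for each alpha (> 0.5 rule, ties to F1)."""
    from scipy.stats import norm

    a = np.asarray(alphas, dtype=float)
    p1 = fit.weights[0] * norm.pdf(a, fit.means[0], fit.sds[0])
    p2 = fit.weights[1] * norm.pdf(a, fit.means[1], fit.sds[1])
    with np.errstate(invalid="ignore"):
        post2 = p2 / (p1 + p2)
    return np.where(post2 > 0.5, F2, F1)


def assign_substates(
    model: StateModel, series: FeatureSeries, fit: AlphaMixtureFit
) -> pd.DataFrame:
    """Per-frame S/F1/F2 labels for one trajectory.

    Slow frames are S; fast frames are split F1/F2 by the posterior of the
    alpha mixture evaluated on the frame's window alpha.  A single
    trajectory may carry all three labels (state switching).
    """
    cls = classify_windows(model, series)
    win_alpha = series.table["alpha"].to_numpy()
    win_label = np.where(
        cls["label"] == CONFINED,
        S,
        np.where(cls["label"] == "unassigned", "unassigned", ""),
    ).astype(object)
    fast_mask = (cls["label"] == "unconfined").to_numpy()
    if fast_mask.any():
        win_label[fast_mask] = classify_alpha(fit, win_alpha[fast_mask])

    n = series.n_frames
    centers = series.center_frames
    half = (n - len(series)) // 2
    frames = np.arange(centers[0] - half, centers[0] - half + n)
    idx = np.clip(frames - centers[0], 0, len(series) - 1)
    return pd.DataFrame(
        {
            "traj_id": series.traj_id,
            "frame": frames,
            "state": np.asarray(win_label, dtype=object)[idx],
            "drift_norm": series.table["drift_norm"].to_numpy()[idx],
        }
    )
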