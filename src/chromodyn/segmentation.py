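"""Two-component Gaussian-mixture segmentation of trajectories.

Window feature vectors (alpha, D_app, Lc, drift norm) pooled across all
trajectories are standardized and fitted with a full-covariance Gaussian
mixture; each window receives the posterior probability of belonging to the
confined (chromatin-bound) component, and each trajectory frame inherits
the posterior of the window centred on it (frames near the ends take the
nearest window).  A frame is labelled confined when its posterior strictly
exceeds one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .exceptions import InsufficientDataError
from .features import FEATURE_NAMES, FeatureSeries

log = logging.getLogger(__name__)

CONFINED = "confined"
UNCONFINED = "unconfined"
UNASSIGNED = "unassigned"


@dataclass
class StateModel:
    """Fitted mixture over the standardized 4D feature space.

    ``confined_component`` is the component with the smaller mean apparent
    diffusion coefficient (ties broken by the smaller mean alpha), making
    labels canonical under component relabelling.
    """

    gmm: GaussianMixture = field(repr=False)
    scale_mean: np.ndarray
    scale_std: np.ndarray
    confined_component: int
    dim: int
    n_windows: int
    #: BIC(k components) - BIC(1 component); >= 0 flags a degenerate split
    bic_delta: float = float("-inf")

    @property
    def n_components(self) -> int:
        return self.gmm.n_components

    @property
    def weights(self) -> np.ndarray:
        return self.gmm.weights_

    def component_means(self) -> pd.DataFrame:
        """Component means in original (unstandardized) feature units."""
        m = self.gmm.means_ * self.scale_std + self.scale_mean
        return pd.DataFrame(m, columns=list(FEATURE_NAMES))

    def component_sds(self) -> pd.DataFrame:
        sd = np.sqrt(np.diagonal(self.gmm.covariances_, axis1=1, axis2=2))
        return pd.DataFrame(sd * self.scale_std, columns=list(FEATURE_NAMES))

    @property
    def degenerate(self) -> bool:
        """Overlap diagnostic: the multi-component fit is degenerate when it
        does not beat a single Gaussian on BIC (the components carve one
        population rather than separating two)."""
        return self.bic_delta >= 0


@dataclass
class LabelSeries:
    """Per-frame confined/unconfined labels for one trajectory."""

    traj_id: str
    dt: float
    frames: np.ndarray
    p_confined: np.ndarray  # NaN where unassigned
    labels: np.ndarray  # of {confined, unconfined, unassigned}

    def __len__(self) -> int:
        return len(self.frames)


def fit_state_model(
    features: pd.DataFrame,
    n_components: int = 2,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> StateModel:
    """Fit the Stage-1 Gaussian mixture on pooled window features.

    ``features`` is the table from :func:`chromodyn.features.pool_features`
    (invalid windows are excluded).  The fit is deterministic given ``seed``
    (k-means++ initialization, ``n_init`` restarts, best likelihood kept).
    """
    valid = features[features["valid"].astype(bool)] if "valid" in features else features
    X = valid[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if len(X) < 10 * n_components:
        raise InsufficientDataError(
            f"need >= {10 * n_components} valid windows, got {len(X)}"
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    # canonical row order makes the fit invariant to input permutation
    Z = Z[np.lexsort(Z.T)]
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        reg_covar=reg_covar,
    ).fit(Z)
    single = GaussianMixture(1, covariance_type="full", reg_covar=reg_covar).fit(Z)
    bic_delta = float(gmm.bic(Z) - single.bic(Z))
    means = gmm.means_ * std + mean
    dapp_idx = FEATURE_NAMES.index("d_app")
    alpha_idx = FEATURE_NAMES.index("alpha")
    order = np.lexsort((means[:, alpha_idx], means[:, dapp_idx]))
    confined = int(order[0])
    model = StateModel(
        gmm=gmm,
        scale_mean=mean,
        scale_std=std,
        confined_component=confined,
        dim=int(features.attrs.get("dim", 3)),
        n_windows=len(X),
        bic_delta=bic_delta,
    )
    if model.degenerate:
        log.warning("state model components overlap (degenerate split)")
    return model


def classify_windows(model: StateModel, series: FeatureSeries) -> pd.DataFrame:
    """Posterior of confined membership and label for each window.

    Invalid windows (degenerate alpha) are labelled unassigned with a NaN
    posterior.  Label rule: confined iff P > 0.5 (a tie is unconfined).
    """
    t = series.table
    p = np.full(len(t), np.nan)
    valid = t["valid"].to_numpy(dtype=bool)
    if valid.any():
        X = t.loc[valid, list(FEATURE_NAMES)].to_numpy(dtype=float)
        Z = (X - model.scale_mean) / model.scale_std
        resp = model.gmm.predict_proba(Z)
        p[valid] = resp[:, model.confined_component]
    labels = np.where(np.isnan(p), UNASSIGNED, np.where(p > 0.5, CONFINED, UNCONFINED))
    return pd.DataFrame(
        {"center_frame": series.center_frames, "p_confined": p, "label": labels}
    )


def windows_to_timepoints(
    window_df: pd.DataFrame, series: FeatureSeries
) -> LabelSeries:
    """Propagate window posteriors to per-frame posteriors.

    Each frame takes the posterior of the window centred on it; the first
    and last (window_len - 1)/2 frames take the nearest window's posterior.
    """
    if not len(series):
        raise InsufficientDataError(f"trajectory {series.traj_id}: no windows")
    n = series.n_frames
    centers = series.center_frames  # consecutive (stride-1 windows)
    half = (n - len(series)) // 2  # (window_len - 1) / 2
    traj_frames = np.arange(centers[0] - half, centers[0] - half + n)
    idx = np.clip(traj_frames - centers[0], 0, len(centers) - 1)
    p = window_df["p_confined"].to_numpy()[idx]
    labels = np.where(np.isnan(p), UNASSIGNED, np.where(p > 0.5, CONFINED, UNCONFINED))
    return LabelSeries(series.traj_id, series.dt, traj_frames, p, labels)


def state_fractions(
    collection: list[LabelSeries], by: str = "windows"
) -> dict[str, float]:
    """Fraction of material per state.

    by='windows' (the default): share of assigned frames per state.
    by='trajectories': a trajectory counts toward a state when at least half
    of its assigned frames carry that label (majority rule).
    """
    if by not in ("windows", "trajectories"):
        raise ValueError("by must be 'windows' or 'trajectories'")
    if by == "windows":
        counts = {CONFINED: 0, UNCONFINED: 0}
        for s in collection:
            counts[CONFINED] += int(np.sum(s.labels == CONFINED))
            counts[UNCONFINED] += int(np.sum(s.labels == UNCONFINED))
        total = sum(counts.values())
    else:
        counts = {CONFINED: 0, UNCONFINED: 0}
        for s in collection:
            n_c = int(np.sum(s.labels == CONFINED))
            n_u = int(np.sum(s.labels == UNCONFINED))
            if n_c + n_u == 0:
                continue
            counts[CONFINED if n_c >= n_u else UNCONFINED] += 1
        total = sum(counts.values())
    if total == 0:
        raise InsufficientDataError("no assigned material; fractions undefined")
    return {k: v / total for k, v in counts.items()}
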