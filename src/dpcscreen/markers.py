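"""Morphology-marker correlation and condition-profile PCA.

Relates DPC morphology features to an activation-marker intensity
(alpha-SMA surrogate): per-feature ordinary least squares on
condition-level means, selection of features with r^2 above a threshold
(default 0.3, strict inequality), intersection of the selections across
experimental contexts ("common parameters"), and PCA of condition
profiles with Mahalanobis membership relative to the control cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import StatisticsError


@dataclass(frozen=True)
class FeatureMarkerResult:
    feature_name: str
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class PcaProjection:
    """Scores/loadings of a condition-profile PCA.

    ``control_distance`` holds, per condition, the Mahalanobis distance
    to the control-condition centroid in the retained component space
    (NaN when no control conditions were given).
    """

    scores: pd.DataFrame  # conditions x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # features x components
    control_distance: pd.Series | None = None


def feature_marker_regression(
    feature_values: pd.DataFrame, marker_values
) -> list[FeatureMarkerResult]:
    """Per-feature OLS of marker intensity on condition-level feature means.

    ``feature_values`` is conditions x features; ``marker_values`` the
    aligned per-condition marker intensities.  r^2 is the squared Pearson
    correlation; a zero-variance feature has r^2 = 0 by definition.
    """
    marker = np.asarray(marker_values, dtype=float)
    if len(feature_values) != marker.size:
        raise StatisticsError("feature and marker condition vectors must align")
    if marker.size < 3:
        raise StatisticsError("need at least 3 conditions for regression")
    out = []
    for name in feature_values.columns:
        x = feature_values[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(marker) == 0:
            out.append(FeatureMarkerResult(str(name), 0.0, float(np.mean(marker)), 0.0, marker.size))
            continue
        res = stats.linregress(x, marker)
        out.append(
            FeatureMarkerResult(
                feature_name=str(name),
                slope=float(res.slope),
                intercept=float(res.intercept),
                r_squared=float(res.rvalue**2),
                n=marker.size,
            )
        )
    return out


def select_correlated(
    results: list[FeatureMarkerResult], threshold: float = 0.3
) -> set[str]:
    """Features whose r^2 strictly exceeds the threshold."""
    return {r.feature_name for r in results if r.r_squared > threshold}


def common_parameters(*feature_sets: set[str]) -> set[str]:
    """Strict intersection of context-specific feature selections."""
    if not feature_sets:
        return set()
    out = set(feature_sets[0])
    for s in feature_sets[1:]:
        out &= set(s)
    return out


def _zscore(profiles: pd.DataFrame) -> pd.DataFrame:
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (profiles - mu) / sd


def pca_profiles(
    condition_profiles: pd.DataFrame,
    n_components: int = 2,
    control_conditions=None,
) -> PcaProjection:
    """PCA of z-scored condition profiles (conditions x features).

    When ``control_conditions`` (index labels) is given, each condition's
    Mahalanobis distance to the control centroid is computed in the
    retained component space, using the control replicates' covariance
    (regularised; falls back to per-component variances when controls
    are too few for a stable covariance).
    """
    if len(condition_profiles) < 2:
        raise ValueError("need at least 2 conditions")
    if n_components > min(condition_profiles.shape):
        raise ValueError("n_components exceeds the data dimensions")
    z = _zscore(condition_profiles.astype(float))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=condition_profiles.index, columns=comp_names)
    loadings = pd.DataFrame(pca.components_.T, index=condition_profiles.columns, columns=comp_names)
    dist = None
    if control_conditions is not None:
        ctrl = scores_df.loc[list(control_conditions)].to_numpy()
        centroid = ctrl.mean(axis=0)
        if ctrl.shape[0] > n_components + 1:
            cov = np.cov(ctrl, rowvar=False)
        else:
            cov = np.diag(np.var(ctrl, axis=0))
        cov = np.atleast_2d(cov) + 1e-9 * np.eye(n_components) * max(1.0, np.trace(np.atleast_2d(cov)))
        vi = np.linalg.inv(cov)
        d = scores_df.to_numpy() - centroid
        dist = pd.Series(
            np.sqrt(np.einsum("ij,jk,ik->i", d, vi, d)), index=condition_profiles.index
        )
    return PcaProjection(
        scores=scores_df,
        explained_variance_fraction=pca.explained_variance_ratio_,
        loadings=loadings,
        control_distance=dist,
    )


def control_membership(
    projection: PcaProjection, control_conditions, quantile: float = 0.975
) -> pd.Series:
    """Boolean control-cluster membership per condition.

    The threshold is the given empirical quantile of the control
    conditions' own distances to their centroid.
    """
    if projection.control_distance is None:
        raise ValueError("projection was computed without control conditions")
    d = projection.control_distance
    thr = float(np.quantile(d.loc[list(control_conditions)].to_numpy(), quantile))
    return d <= thr
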