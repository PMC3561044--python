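"""Smooth / abrupt / hybrid classification of response curves.

Abrupt transcripts show a kink: the current J(alpha) rises and then saturates
suddenly once initiation outpaces an interior bottleneck, where a ribosome
queue forms.  Smooth transcripts (bottleneck at the 5' edge, or none) saturate
gradually.  Shape features are computed on the smoothed current (the kink is
defined on J) with the density jump as a confirmatory feature, then clustered
with 2-means; genes near the midpoint between centroids are called hybrid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .response import ResponseCurve, SaturationSummary

__all__ = ["CurveFeatures", "curve_features", "classify_curves"]

SMOOTH = "SMOOTH"
ABRUPT = "ABRUPT"
HYBRID = "HYBRID"

#: relative assignment-margin below which a gene is called HYBRID
DEFAULT_HYBRID_BAND = 0.2


@dataclass(frozen=True)
class CurveFeatures:
    """Shape features of one J(alpha)/rho(alpha) response curve.

    kink_score: knee-sharpness ratio J_max / alpha_95, where alpha_95 is the
    initiation rate at which the smoothed current first reaches 95% of J_max.
    An abrupt transcript rides the initiation-limited line J = alpha until a
    queue forms at an interior bottleneck, so its current meets saturation at
    alpha ~ J_max and the ratio approaches 1; a gradually saturating curve
    needs alpha >> J_max and the ratio is small.  Zero when the curve is
    already saturated at the grid start (no knee).
    sat_sharpness: width of the alpha interval over which J rises from 50% to
    95% of J_max, normalized by alpha at 95% — small for abrupt saturation.
    rho_jump: largest single-step increase of the smoothed density, relative
    to rho_max; a ribosome queue forming at the transition makes the density
    jump to its high branch.
    """

    gene_id: str
    kink_score: float
    sat_sharpness: float
    rho_jump: float

    def __post_init__(self) -> None:
        vals = (self.kink_score, self.sat_sharpness, self.rho_jump)
        if not all(np.isfinite(vals)):
            raise ValueError(f"{self.gene_id}: non-finite curve features")
        if self.kink_score < 0 or self.sat_sharpness <= 0:
            raise ValueError(f"{self.gene_id}: invalid feature signs")

    def as_array(self) -> np.ndarray:
        return np.array([self.kink_score, self.sat_sharpness, self.rho_jump])


def _alpha_at_fraction(grid: np.ndarray, J: np.ndarray, target: float) -> float:
    """Smallest alpha where the smoothed current first reaches ``target``."""
    above = np.nonzero(J >= target)[0]
    if above.size == 0:
        return float(grid[-1])
    i = int(above[0])
    if i == 0:
        return float(grid[0])
    lo, hi = J[i - 1], J[i]
    if hi == lo:
        return float(grid[i])
    return float(grid[i - 1] + (target - lo) / (hi - lo) * (grid[i] - grid[i - 1]))


def curve_features(curve: ResponseCurve, sat: SaturationSummary) -> CurveFeatures:
    """Compute kink/sharpness/jump features over the sub-saturation range."""
    if not sat.J_max > 0:
        raise ValueError(f"{curve.gene_id}: J_max = 0, untranslatable profile")
    grid = curve.alpha_grid
    J = curve.J_smooth
    J_max = sat.J_max

    a95 = _alpha_at_fraction(grid, J, 0.95 * J_max)
    a50 = _alpha_at_fraction(grid, J, 0.50 * J_max)
    sat_sharpness = max((a95 - a50) / a95, 1e-9) if a95 > 0 else 1e-9

    # knee sharpness: saturated from the very first grid point means no knee
    if J[0] >= 0.95 * J_max or a95 <= 0:
        kink = 0.0
    else:
        kink = float(J_max / a95)

    rho = curve.rho_smooth
    rho_max = max(sat.rho_max, 1e-12)
    steps = np.diff(rho)
    rho_jump = float(steps.max() / rho_max) if steps.size else 0.0

    return CurveFeatures(
        gene_id=curve.gene_id,
        kink_score=kink,
        sat_sharpness=sat_sharpness,
        rho_jump=rho_jump,
    )


def classify_curves(
    features: Sequence[CurveFeatures],
    seed: int = 0,
    hybrid_band: float = DEFAULT_HYBRID_BAND,
) -> dict[str, str]:
    """2-means clustering of standardized features into SMOOTH/ABRUPT.

    The centroid with the larger kink score (original units) is ABRUPT.  A
    gene whose relative margin |d_near - d_far| / (d_near + d_far) between
    the two centroid distances is below ``hybrid_band`` is HYBRID.
    Deterministic given ``seed``; single-gene input uses a fixed threshold
    (knee ratio above 0.3 is abrupt).
    """
    if len(features) == 0:
        raise ValueError("no features to classify")
    if len(features) == 1:
        f = features[0]
        return {f.gene_id: ABRUPT if f.kink_score > 0.3 else SMOOTH}

    X = np.vstack([f.as_array() for f in features])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.all(sd < 1e-12):
        warnings.warn("degenerate (identical) curve features; labelling all HYBRID")
        return {f.gene_id: HYBRID for f in features}
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd

    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % 2**31)
    assign = km.fit_predict(Z)

    # orient labels: higher mean kink score (original units) -> ABRUPT
    kink = X[:, 0]
    mean_kink = [kink[assign == c].mean() for c in (0, 1)]
    abrupt_cluster = int(np.argmax(mean_kink))

    dists = np.linalg.norm(Z[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    d_sorted = np.sort(dists, axis=1)
    margin = (d_sorted[:, 1] - d_sorted[:, 0]) / np.maximum(
        d_sorted[:, 1] + d_sorted[:, 0], 1e-12
    )

    labels: dict[str, str] = {}
    for f, a, m in zip(features, assign, margin):
        if m < hybrid_band:
            labels[f.gene_id] = HYBRID
        else:
            labels[f.gene_id] = ABRUPT if a == abrupt_cluster else SMOOTH
    return labels


def features_frame(features: Sequence[CurveFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": f.gene_id,
                "kink_score": f.kink_score,
                "sat_sharpness": f.sat_sharpness,
                "rho_jump": f.rho_jump,
            }
            for f in features
        ]
    )
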