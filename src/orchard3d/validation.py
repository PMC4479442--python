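"""Accuracy formulas and estimate-vs-reference comparison statistics.

Overall classification accuracy is the percentage of image area whose
class (tree vs non-tree) matches a reference delineation. Feature errors
are mean absolute differences between estimated and observed per-tree
values, reported both in feature units and as a percentage of the observed
mean. The ellipsoid crown model is the conventional field estimate
``pi/6 * (mean canopy diameter)^2 * height`` used as the on-ground
reference for crown volume.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import Orchard3DError, PairingError, SceneAlignmentError, SingularFitError


def overall_accuracy(
    predicted_mask: np.ndarray,
    reference_mask: np.ndarray,
    valid: np.ndarray | None = None,
) -> float:
    """Percent of (valid) pixels whose predicted class equals the reference."""
    predicted_mask = np.asarray(predicted_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if predicted_mask.shape != reference_mask.shape:
        raise SceneAlignmentError(
            f"mask shapes differ: {predicted_mask.shape} vs {reference_mask.shape}"
        )
    agree = predicted_mask == reference_mask
    if valid is not None:
        agree = agree[valid]
    return 100.0 * float(np.count_nonzero(agree)) / agree.size


def ellipsoid_volume(length_axis: float, width_axis: float, height: float) -> float:
    """Crown volume (m³) assuming an ellipsoid: pi/6 * ((L+W)/2)^2 * H."""
    if length_axis < 0 or width_axis < 0 or height < 0:
        raise Orchard3DError("ellipsoid_volume requires non-negative inputs")
    mean_diam = (length_axis + width_axis) / 2.0
    return math.pi / 6.0 * mean_diam**2 * height


def average_feature_error(estimated, observed) -> tuple[float, float, float]:
    """Mean absolute estimate error, its sample std, and the mean error as
    a percentage of the observed mean.

    With a single pair the std is undefined and returned as NaN.
    """
    est = np.asarray(estimated, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if est.shape != obs.shape or est.ndim != 1:
        raise PairingError(f"cannot pair {est.shape} with {obs.shape}")
    if est.size == 0:
        raise PairingError("need at least one pair")
    errors = np.abs(est - obs)
    mean_err = float(errors.mean())
    std_err = float(errors.std(ddof=1)) if est.size > 1 else float("nan")
    obs_mean = float(obs.mean())
    pct = 100.0 * mean_err / obs_mean if obs_mean != 0 else float("nan")
    return mean_err, std_err, pct


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


def regression_fit(estimated, observed) -> RegressionFit:
    """OLS fit of estimated on observed, with residual RMSE and R²."""
    est = np.asarray(estimated, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if est.shape != obs.shape or est.ndim != 1:
        raise PairingError(f"cannot pair {est.shape} with {obs.shape}")
    if est.size < 3:
        raise PairingError("regression needs n >= 3 pairs")
    if np.ptp(obs) == 0:
        raise SingularFitError("observed values have zero variance")
    res = stats.linregress(obs, est)
    resid = est - (res.intercept + res.slope * obs)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=int(est.size),
    )


def pair_by_position(
    est_xy: np.ndarray,
    obs_xy: np.ndarray,
    max_dist: float,
) -> list[tuple[int, int]]:
    """Match estimated entities to reference trees by nearest centroid.

    Greedy one-to-one matching within ``max_dist`` metres; returns
    (estimated index, observed index) pairs.
    """
    est_xy = np.atleast_2d(np.asarray(est_xy, dtype=np.float64))
    obs_xy = np.atleast_2d(np.asarray(obs_xy, dtype=np.float64))
    if est_xy.size == 0 or obs_xy.size == 0:
        return []
    tree = cKDTree(obs_xy)
    dists, nearest = tree.query(est_xy)
    order = np.argsort(dists, kind="stable")
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i in order:
        j = int(nearest[i])
        if dists[i] <= max_dist and j not in used:
            pairs.append((int(i), j))
            used.add(j)
    return pairs


@dataclass
class ValidationReport:
    """Bundle of the accuracy statistics for one scenario."""

    overall_accuracy: float
    feature: str = ""
    avg_error: float = float("nan")
    error_std: float = float("nan")
    error_pct: float = float("nan")
    rmse: float = float("nan")
    r_squared: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    n: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        lines = [f"overall accuracy: {self.overall_accuracy:.1f} %"]
        if self.n:
            lines += [
                f"{self.feature}: mean abs error {self.avg_error:.3f} "
                f"(sd {self.error_std:.3f}, {self.error_pct:.2f} % of observed mean)",
                f"regression: slope {self.slope:.3f}, intercept {self.intercept:.3f}, "
                f"R^2 {self.r_squared:.3f}, RMSE {self.rmse:.3f} (n={self.n})",
            ]
        return "\n".join(lines)


def validation_report(
    predicted_mask: np.ndarray,
    reference_mask: np.ndarray,
    estimated=None,
    observed=None,
    feature: str = "height",
    valid: np.ndarray | None = None,
) -> ValidationReport:
    """Compose the full report: mask accuracy plus paired feature statistics."""
    report = ValidationReport(
        overall_accuracy=overall_accuracy(predicted_mask, reference_mask, valid),
        feature=feature,
    )
    if estimated is not None and observed is not None and len(estimated):
        report.avg_error, report.error_std, report.error_pct = average_feature_error(
            estimated, observed
        )
        if len(estimated) >= 3 and np.ptp(observed) > 0:
            fit = regression_fit(estimated, observed)
            report.rmse = fit.rmse
            report.r_squared = fit.r_squared
            report.slope = fit.slope
            report.intercept = fit.intercept
        report.n = len(estimated)
    return report
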