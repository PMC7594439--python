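"""ROC curves of the risk score against dichotomized tympanic temperature.

Cut-points are selected as the threshold whose (sensitivity, specificity)
operating point lies nearest the ideal (1, 1) corner.  The default
tympanic boundaries 37.5 / 38.0 / 38.5 degC split the cohort into the four
risk bands.  The predicted-positive rule is score >= threshold; a tympanic
value counts positive strictly above its boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_index import IndexSpec, RiskBand
from .errors import CalibrationError, InputError

DEFAULT_BOUNDARIES = (37.5, 38.0, 38.5)


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity sweep over candidate score thresholds.

    Thresholds are ordered increasing and include -inf/+inf sentinels, so the
    sweep always contains the (1, 0) and (0, 1) endpoints.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    distance: float
    auc: float
    auc_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "distance_to_ideal": self.distance,
            "auc": self.auc,
            "auc_ci95": list(self.auc_ci),
        }


def dichotomize(tympanic, boundary: float) -> np.ndarray:
    """Binary outcome: 1 where tympanic temperature strictly exceeds the boundary."""
    if not np.isfinite(boundary):
        raise InputError(f"boundary must be finite, got {boundary}")
    t = np.asarray(tympanic, dtype=float)
    if not np.isfinite(t).all():
        raise InputError("tympanic values must be finite")
    return (t > boundary).astype(int)


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError(
            f"ROC needs both classes: {n_pos} positive, {n_neg} negative"
        )
    return n_pos, n_neg


def roc_curve(scores, labels) -> RocCurve:
    """Operating points at every distinct score, their midpoints, and sentinels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise InputError(f"scores and labels differ in length: {s.shape} vs {y.shape}")
    n_pos, n_neg = _check_classes(y)

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], distinct, mids, [np.inf]])
    thresholds = np.unique(thresholds)

    # predicted positive iff score >= threshold; count via sorted class scores
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    return RocCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        n_positive=n_pos, n_negative=n_neg,
    )


def auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """Mann-Whitney AUC (ties count 1/2) with a Hanley-McNeil normal CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(y)
    ranks = stats.rankdata(s)
    a = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AucResult(
        auc=float(a), se=se,
        ci_low=float(max(0.0, a - z * se)), ci_high=float(min(1.0, a + z * se)),
    )


def trapezoid_auc(curve: RocCurve) -> float:
    """Area under the ROC polygon (independent check of the pair-count AUC)."""
    fpr = 1.0 - curve.specificity
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def optimal_cutpoint(scores, labels) -> CutpointResult:
    """Threshold minimizing the distance to the (sens=1, spec=1) corner.

    Ties go to higher sensitivity, then to the lower threshold.
    """
    curve = roc_curve(scores, labels)
    dist = np.sqrt((1 - curve.sensitivity) ** 2 + (1 - curve.specificity) ** 2)
    # lexicographic: distance asc, sensitivity desc, threshold asc;
    # distances rounded so floating noise cannot defeat the declared tie-breaks
    order = np.lexsort((curve.thresholds, -curve.sensitivity, np.round(dist, 12)))
    best = order[0]
    a = auc(scores, labels)
    return CutpointResult(
        threshold=float(curve.thresholds[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        distance=float(dist[best]),
        auc=a.auc,
        auc_ci=(a.ci_low, a.ci_high),
    )


def derive_risk_bands(
    scores,
    tympanic,
    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES,
    base_spec: IndexSpec | None = None,
    labels: tuple[str, ...] = ("Low", "Moderate", "High", "Very high"),
) -> tuple[IndexSpec, list[CutpointResult]]:
    """Calibrate the risk bands from one cut-point per tympanic boundary.

    Returns the spec with refreshed bands plus the per-boundary cut-point
    diagnostics.  Cut-points that are not strictly increasing raise a
    :class:`CalibrationError` rather than being silently reordered.
    """
    if len(boundaries) != len(labels) - 1:
        raise InputError(
            f"{len(labels)} bands need {len(labels) - 1} boundaries, got {len(boundaries)}"
        )
    if sorted(boundaries) != list(boundaries):
        raise InputError(f"boundaries must be increasing: {boundaries}")
    base_spec = base_spec or IndexSpec()

    results = []
    for boundary in boundaries:
        y = dichotomize(tympanic, boundary)
        results.append(optimal_cutpoint(scores, y))
    cuts = [r.threshold for r in results]
    if sorted(cuts) != cuts or len(set(cuts)) != len(cuts):
        raise CalibrationError(
            f"cut-points are not strictly increasing: {cuts} "
            f"(boundaries {boundaries}); refusing to build bands"
        )
    bands = (RiskBand(labels[0], -math.inf),) + tuple(
        RiskBand(label, cut) for label, cut in zip(labels[1:], cuts)
    )
    return replace(base_spec, bands=bands), results
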