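"""Synthetic worker cohorts with the published moment structure.

The generator draws multivariate-normal records for the six exposure
variables plus tympanic temperature, calibrated to the study's printed
means, standard deviations and correlation matrix, so that every pipeline
stage (scoring, calibration, validation) is exercisable without field
data.  Demographics (age, heart rate) are drawn independently of the
thermal block and serve only the screening rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_index import VARIABLES, hrmax
from .errors import InputError, NumericalError

logger = logging.getLogger(__name__)

COHORT_VARIABLES: tuple[str, ...] = VARIABLES + ("tympanic",)

# published pooled moments (six exposures + working tympanic temperature)
_MEANS = (24.78, 22.01, 39.89, 0.58, 248.47, 0.83, 37.70)
_SDS = (6.01, 6.60, 9.73, 0.39, 103.70, 0.14, 0.56)
_CORR = (
    (1.000, 0.626, 0.907, 0.296, 0.318, 0.454, 0.751),
    (0.626, 1.000, 0.511, 0.152, 0.131, 0.054, 0.685),
    (0.907, 0.511, 1.000, 0.347, 0.332, 0.530, 0.766),
    (0.296, 0.152, 0.347, 1.000, 0.082, 0.135, 0.258),
    (0.318, 0.131, 0.332, 0.082, 1.000, 0.321, 0.509),
    (0.454, 0.054, 0.530, 0.135, 0.321, 1.000, 0.388),
    (0.751, 0.685, 0.766, 0.258, 0.509, 0.388, 1.000),
)
_RANGES = (
    (21.97, 48.20), (12.10, 37.57), (23.40, 62.43), (0.0, 4.20),
    (130.0, 490.0), (0.50, 1.35), (36.7, 39.1),
)

# per-site climatic overrides (mean, sd) for the three temperatures,
# with the two-site head counts 111 : 90
_SITE_OVERRIDES = {
    "hot_dry": {"t_dry": (33.58, 5.21), "t_wet": (17.63, 2.04), "t_globe": (39.01, 9.63)},
    "hot_humid": {"t_dry": (36.26, 6.61), "t_wet": (27.43, 6.26), "t_globe": (40.97, 9.80)},
}
_SITE_WEIGHTS = {"hot_dry": 111, "hot_humid": 90}

_AGE = (36.62, 8.24, 22.0, 55.0)        # mean, sd, low, high
_HEART_RATE = (121.0, 28.45, 70.0, 189.0)


def nearest_pd_correlation(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal.

    Printed correlation tables are rounded and can be slightly indefinite;
    the repair is logged so the shift is never silent.
    """
    C = np.asarray(corr, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise InputError("correlation matrix is not symmetric")
    w, V = np.linalg.eigh(C)
    if w.min() > 0:
        return C
    logger.warning("correlation matrix indefinite (min eigenvalue %.3g); repairing", w.min())
    w = np.clip(w, floor, None)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


@dataclass(frozen=True)
class CohortModel:
    """Moments and screening context of the synthetic generator."""

    names: tuple[str, ...] = COHORT_VARIABLES
    means: tuple[float, ...] = _MEANS
    sds: tuple[float, ...] = _SDS
    corr: tuple[tuple[float, ...], ...] = _CORR
    ranges: tuple[tuple[float, float], ...] = _RANGES
    site_overrides: dict = field(default_factory=lambda: dict(_SITE_OVERRIDES))
    site_weights: dict = field(default_factory=lambda: dict(_SITE_WEIGHTS))

    def __post_init__(self) -> None:
        p = len(self.names)
        if not (len(self.means) == len(self.sds) == p):
            raise InputError("means/sds length must match variable names")
        if any(s <= 0 for s in self.sds):
            raise InputError(f"standard deviations must be positive: {self.sds}")
        C = np.asarray(self.corr, dtype=float)
        if C.shape != (p, p):
            raise InputError(f"correlation matrix must be {p}x{p}, got {C.shape}")
        if not np.allclose(np.diag(C), 1.0):
            raise InputError("correlation matrix must have a unit diagonal")

    def pd_corr(self) -> np.ndarray:
        return nearest_pd_correlation(np.asarray(self.corr, dtype=float))

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pd_corr(), index=list(self.names), columns=list(self.names))

    def sd_series(self) -> pd.Series:
        return pd.Series(self.sds, index=list(self.names))


def calibrate_from_tables() -> CohortModel:
    """The shipped, publication-calibrated cohort model."""
    return CohortModel()


def _draw_block(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    chol: np.ndarray,
) -> np.ndarray:
    z = rng.standard_normal((n, len(means)))
    return (z @ chol.T) * sds + means


def sample_cohort(
    model: CohortModel | None = None,
    n: int = 201,
    seed: int | None = None,
    truncate: bool = False,
    two_site: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` synthetic worker records (reproducible under ``seed``).

    ``truncate=True`` rejects draws outside the calibrated ranges; this
    deliberately distorts the calibrated moments and is off by default.
    ``two_site=True`` mixes the two climatic sites (same correlation
    structure, site-specific temperature means/SDs) at the published head
    counts instead of the pooled single-site model.
    """
    model = model or CohortModel()
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    corr = model.pd_corr()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repaired above
        raise NumericalError("correlation matrix not positive definite") from exc

    names = list(model.names)
    base_means = np.asarray(model.means, dtype=float)
    base_sds = np.asarray(model.sds, dtype=float)

    if two_site:
        sites = list(model.site_weights)
        weights = np.asarray([model.site_weights[s] for s in sites], dtype=float)
        site_draw = rng.choice(len(sites), size=n, p=weights / weights.sum())
        rows = np.empty((n, len(names)))
        site_labels = np.empty(n, dtype=object)
        for k, site in enumerate(sites):
            means, sds = base_means.copy(), base_sds.copy()
            for var, (m, s) in model.site_overrides[site].items():
                j = names.index(var)
                means[j], sds[j] = m, s
            idx = np.flatnonzero(site_draw == k)
            rows[idx] = _draw_block(rng, len(idx), means, sds, chol)
            site_labels[idx] = site
    else:
        rows = _draw_block(rng, n, base_means, base_sds, chol)
        site_labels = np.full(n, "pooled", dtype=object)

    if truncate:
        lo = np.asarray([r[0] for r in model.ranges])
        hi = np.asarray([r[1] for r in model.ranges])
        keep = ((rows >= lo) & (rows <= hi)).all(axis=1)
        attempts, drawn = int(n), int(keep.sum())
        while keep.sum() < n:
            extra = _draw_block(rng, n, base_means, base_sds, chol)
            ok = ((extra >= lo) & (extra <= hi)).all(axis=1)
            rows = np.vstack([rows[keep], extra[ok]])
            site_labels = np.concatenate(
                [site_labels[keep], np.full(int(ok.sum()), "pooled", dtype=object)]
            )
            keep = np.ones(len(rows), dtype=bool)
            attempts += n
            drawn = len(rows)
            if attempts >= 100 * n and drawn < attempts / 100:
                raise NumericalError(
                    f"truncation rejection rate above 99% ({drawn}/{attempts} kept)"
                )
        rows, site_labels = rows[:n], site_labels[:n]

    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "subject_id", [f"S{i + 1:06d}" for i in range(n)])
    df.insert(1, "site", site_labels)

    # demographics: independent of the thermal block, used only for screening
    age_mean, age_sd, age_lo, age_hi = _AGE
    df["age"] = np.clip(rng.normal(age_mean, age_sd, size=n), age_lo, age_hi)
    hr_mean, hr_sd, hr_lo, hr_hi = _HEART_RATE
    df["heart_rate"] = np.clip(rng.normal(hr_mean, hr_sd, size=n), hr_lo, hr_hi)
    return df


def apply_screening(
    cohort: pd.DataFrame,
    tympanic_limit: float = 39.0,
    use_hrmax: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records failing the physiological screens; log per-rule counts.

    Rules: tympanic temperature above the limit, and heart rate above the
    age-predicted maximum (when age and heart rate columns are present).
    """
    exclusions: dict[str, int] = {}
    keep = pd.Series(True, index=cohort.index)

    if "tympanic" in cohort.columns:
        bad = cohort["tympanic"] > tympanic_limit
        exclusions["tympanic_above_limit"] = int(bad.sum())
        keep &= ~bad
    if use_hrmax and {"age", "heart_rate"}.issubset(cohort.columns):
        limit = cohort["age"].map(hrmax)
        bad = cohort["heart_rate"] > limit
        exclusions["heart_rate_above_hrmax"] = int(bad.sum())
        keep &= ~bad

    filtered = cohort.loc[keep].reset_index(drop=True)
    logger.info("screening removed %d of %d records: %s",
                len(cohort) - len(filtered), len(cohort), exclusions)
    return filtered, exclusions
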