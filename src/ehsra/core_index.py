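"""Heat-strain risk score: normalization, weighted sum, risk banding, screening.

The score is a scaled weighted sum of six min-max normalized workplace
variables (dry, natural wet-bulb and globe temperatures, air velocity,
total metabolism, clothing insulation).  The air-velocity term switches
sign below a skin-temperature threshold: moving air cools the body only
while ambient dry temperature stays below skin temperature.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import CalibrationWarning, InputError

#: Canonical order of the six fundamental variables.
VARIABLES: tuple[str, ...] = ("t_dry", "t_wet", "t_globe", "v_air", "metabolism", "clo")

#: Physiological variables aggregated by maximum instead of mean.
PHYSIO_VARIABLES: tuple[str, ...] = ("tympanic", "heart_rate")

#: Tympanic temperature above which a subject is screened out (°C).
TYMPANIC_SCREEN_LIMIT = 39.0


@dataclass(frozen=True)
class ThermalSample:
    """One worker-period's exposure record.

    Temperatures in °C, air velocity in m/s, metabolism in W, clothing
    insulation in clo.  Physiology and demographics are optional and used
    only for screening/validation.
    """

    t_dry: float
    t_wet: float
    t_globe: float
    v_air: float
    metabolism: float
    clo: float
    tympanic: float | None = None
    heart_rate: float | None = None
    age: float | None = None
    subject_id: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if self.v_air is not None and np.isfinite(self.v_air) and self.v_air < 0:
            raise InputError(f"v_air must be >= 0, got {self.v_air}")
        if self.metabolism is not None and np.isfinite(self.metabolism) and self.metabolism <= 0:
            raise InputError(f"metabolism must be > 0, got {self.metabolism}")
        if self.clo is not None and np.isfinite(self.clo) and self.clo <= 0:
            raise InputError(f"clo must be > 0, got {self.clo}")
        # dry > globe is physically odd (negative radiant load) but valid input
        if (
            self.t_dry is not None
            and self.t_globe is not None
            and np.isfinite(self.t_dry)
            and np.isfinite(self.t_globe)
            and self.t_dry > self.t_globe
        ):
            warnings.warn(
                f"dry temperature ({self.t_dry}) exceeds globe temperature "
                f"({self.t_globe}); unusual but accepted",
                CalibrationWarning,
                stacklevel=2,
            )

    def values(self) -> tuple[float, ...]:
        """The six fundamental variables in canonical order."""
        return tuple(getattr(self, name) for name in VARIABLES)


@dataclass(frozen=True)
class RiskBand:
    label: str
    lower: float  # lower bound of the band on the score scale


@dataclass(frozen=True)
class IndexSpec:
    """Coefficients, normalization constants and risk bands of the index.

    ``bands`` is ordered by lower bound; the first band is unbounded below.
    Band convention: a score falls in the highest band whose lower bound it
    reaches, where every band includes its lower bound except the last,
    which is entered only strictly above its bound (the calibrated upper
    cut-off itself still counts as the second-highest band).
    """

    coefficients: tuple[float, ...] = (0.752, 0.686, 0.774, 0.244, 0.491, 0.387)
    norm_min: tuple[float, ...] = (21.97, 12.10, 23.40, 0.0, 130.0, 0.50)
    norm_range: tuple[float, ...] = (26.23, 25.47, 39.30, 4.20, 360.0, 0.85)
    scale_factor: float = 10.0
    skin_temp_threshold: float = 35.0
    bands: tuple[RiskBand, ...] = (
        RiskBand("Low", -math.inf),
        RiskBand("Moderate", 12.02),
        RiskBand("High", 15.88),
        RiskBand("Very high", 17.56),
    )

    def __post_init__(self) -> None:
        for group in (self.coefficients, self.norm_min, self.norm_range):
            if len(group) != len(VARIABLES):
                raise InputError(
                    f"expected {len(VARIABLES)} values per variable, got {len(group)}"
                )
        if any(r <= 0 for r in self.norm_range):
            raise InputError(f"normalization ranges must be positive: {self.norm_range}")
        lowers = [b.lower for b in self.bands]
        if sorted(lowers) != lowers or len(set(lowers)) != len(lowers):
            raise InputError(f"band lower bounds must be strictly increasing: {lowers}")
        if not self.bands:
            raise InputError("at least one risk band is required")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "norm_min": list(self.norm_min),
            "norm_range": list(self.norm_range),
            "scale_factor": self.scale_factor,
            "skin_temp_threshold": self.skin_temp_threshold,
            "bands": [
                {"label": b.label, "lower": None if math.isinf(b.lower) else b.lower}
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndexSpec":
        bands = tuple(
            RiskBand(b["label"], -math.inf if b.get("lower") is None else float(b["lower"]))
            for b in d["bands"]
        )
        return cls(
            coefficients=tuple(float(x) for x in d["coefficients"]),
            norm_min=tuple(float(x) for x in d["norm_min"]),
            norm_range=tuple(float(x) for x in d["norm_range"]),
            scale_factor=float(d["scale_factor"]),
            skin_temp_threshold=float(d["skin_temp_threshold"]),
            bands=bands,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "IndexSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "IndexSpec":
        """The shipped calibration (packaged JSON, identical to the defaults)."""
        ref = resources.files("ehsra.data").joinpath("default_spec.json")
        return cls.from_dict(json.loads(ref.read_text(encoding="utf-8")))


def _check_finite(sample: ThermalSample) -> None:
    bad = []
    for name in VARIABLES:
        value = getattr(sample, name)
        if value is None or not np.isfinite(value):
            bad.append(f"{name}={value}")
    if bad:
        raise InputError("non-finite or missing variable(s): " + ", ".join(bad))


def normalize(sample: ThermalSample, spec: IndexSpec | None = None) -> np.ndarray:
    """Min-max normalize the six variables: (x - min) / range.

    Values outside [0, 1] are allowed (the input lies outside the
    calibration range) but raise a :class:`CalibrationWarning`.
    """
    spec = spec or IndexSpec()
    _check_finite(sample)
    x = np.asarray(sample.values(), dtype=float)
    normed = (x - np.asarray(spec.norm_min)) / np.asarray(spec.norm_range)
    outside = (normed < 0) | (normed > 1)
    if outside.any():
        names = [VARIABLES[i] for i in np.flatnonzero(outside)]
        warnings.warn(
            f"variable(s) outside calibration range: {', '.join(names)}",
            CalibrationWarning,
            stacklevel=2,
        )
    return normed


def air_velocity_sign(t_dry: float, spec: IndexSpec | None = None) -> float:
    """-1 while dry temperature is below the skin threshold, +1 at or above."""
    spec = spec or IndexSpec()
    return -1.0 if t_dry < spec.skin_temp_threshold else 1.0


def compute_ehsra(sample: ThermalSample, spec: IndexSpec | None = None) -> float:
    """The scaled weighted sum of normalized variables.

    The air-velocity term is subtracted when dry temperature is below the
    skin-temperature threshold (moving air then removes heat).
    """
    spec = spec or IndexSpec()
    normed = normalize(sample, spec)
    weights = np.asarray(spec.coefficients, dtype=float).copy()
    weights[VARIABLES.index("v_air")] *= air_velocity_sign(sample.t_dry, spec)
    return float(spec.scale_factor * weights @ normed)


def classify_risk(score: float, spec: IndexSpec | None = None) -> str:
    """Map a score to its risk band label (total, order preserving)."""
    spec = spec or IndexSpec()
    if not np.isfinite(score):
        raise InputError(f"score must be finite, got {score}")
    bands = spec.bands
    if score > bands[-1].lower:
        return bands[-1].label
    for band in reversed(bands[:-1]):
        if score >= band.lower:
            return band.label
    return bands[0].label


def hrmax(age: float) -> float:
    """Age-predicted maximum heart rate: 208 - 0.7 x age."""
    if age < 0:
        raise InputError(f"age must be >= 0, got {age}")
    return 208.0 - 0.7 * age


def hrmax_screen(age: float, observed_hr: float) -> bool:
    """True (pass) unless the observed heart rate exceeds the age-predicted max."""
    return observed_hr <= hrmax(age)


def tympanic_screen(tympanic: float, limit: float = TYMPANIC_SCREEN_LIMIT) -> bool:
    """True (pass) unless tympanic temperature exceeds the screening limit."""
    return tympanic <= limit


def aggregate_repeats(
    thermal: Mapping[str, Sequence[float]],
    physio: Mapping[str, Sequence[float]] | None = None,
    **passthrough,
) -> ThermalSample:
    """Collapse repeated measurements to one representative sample.

    Thermal variables take the arithmetic mean of their repeats; the
    physiological variables (tympanic, heart rate) take the maximum.
    """
    physio = physio or {}
    unknown = set(thermal) - set(VARIABLES)
    if unknown:
        raise InputError(f"unknown thermal variable(s): {sorted(unknown)}")
    unknown = set(physio) - set(PHYSIO_VARIABLES)
    if unknown:
        raise InputError(f"unknown physiological variable(s): {sorted(unknown)}")
    missing = set(VARIABLES) - set(thermal)
    if missing:
        raise InputError(f"missing thermal variable(s): {sorted(missing)}")

    kwargs: dict = dict(passthrough)
    for name, repeats in thermal.items():
        if len(repeats) == 0:
            raise InputError(f"empty repeat list for {name}")
        kwargs[name] = float(np.mean(repeats))
    for name, repeats in physio.items():
        if len(repeats) == 0:
            raise InputError(f"empty repeat list for {name}")
        kwargs[name] = float(np.max(repeats))
    return ThermalSample(**kwargs)


def score_frame(df, spec: IndexSpec | None = None):
    """Score every row of a cohort table; returns (scores, labels) arrays.

    ``df`` must contain the six variable columns.  Vectorized equivalent of
    :func:`compute_ehsra` + :func:`classify_risk` per row.
    """
    spec = spec or IndexSpec()
    missing = [c for c in VARIABLES if c not in df.columns]
    if missing:
        raise InputError(f"missing required column(s): {missing}")
    x = df.loc[:, list(VARIABLES)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        rows = np.flatnonzero(~np.isfinite(x).all(axis=1))
        raise InputError(f"non-finite values in rows {rows[:10].tolist()}")
    normed = (x - np.asarray(spec.norm_min)) / np.asarray(spec.norm_range)
    w = np.tile(np.asarray(spec.coefficients, dtype=float), (len(df), 1))
    j = VARIABLES.index("v_air")
    w[:, j] *= np.where(x[:, VARIABLES.index("t_dry")] < spec.skin_temp_threshold, -1.0, 1.0)
    scores = spec.scale_factor * (w * normed).sum(axis=1)
    labels = np.array([classify_risk(s, spec) for s in scores])
    return scores, labels
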