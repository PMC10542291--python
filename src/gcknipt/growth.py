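"""Fetal abdominal-circumference (AC) percentiles and genotype classification.

An affected (N/M) fetus senses maternal hyperglycaemia as normal and grows
normally; an unaffected (N/N) fetus secretes extra insulin and grows large.
Clinical practice therefore proxies fetal genotype by the AC percentile on
the 28-week growth scan: below the threshold percentile predicts N/M,
at/above predicts N/N.

Percentiles are computed on a Gaussian z-score scale against a growth
standard given as polynomial mean and SD curves over gestational age.  The
standard is data, not code: coefficients are loaded from JSON, so real
INTERGROWTH-21st coefficients can be dropped in; a synthetic standard is
bundled for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from ._exceptions import InvalidInputError, NoEligibleScanError

__all__ = [
    "GrowthStandard",
    "Scan",
    "ACClassification",
    "load_growth_standard",
    "bundled_growth_standard",
    "ac_percentile",
    "ac_from_percentile",
    "classify_by_ac",
    "select_scan",
]

SCAN_WINDOW = (26.0, 30.0)  # inclusive gestational-age window, weeks
SCAN_TARGET = 28.0


@dataclass(frozen=True)
class GrowthStandard:
    """Parameterised mean/SD curves of AC (mm) against gestational age (weeks).

    ``mean_coeffs`` and ``sd_coeffs`` are polynomial coefficients in
    ascending order: c0 + c1*ga + c2*ga**2 + ...
    """

    name: str
    mean_coeffs: tuple[float, ...]
    sd_coeffs: tuple[float, ...]
    ga_range: tuple[float, float]

    def mean(self, ga: float) -> float:
        return float(np.polynomial.polynomial.polyval(ga, self.mean_coeffs))

    def sd(self, ga: float) -> float:
        return float(np.polynomial.polynomial.polyval(ga, self.sd_coeffs))

    def _check_ga(self, ga: float) -> None:
        lo, hi = self.ga_range
        if not lo <= ga <= hi:
            raise InvalidInputError(
                f"gestational age {ga} outside the standard's range [{lo}, {hi}]"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "mean_coeffs": list(self.mean_coeffs),
            "sd_coeffs": list(self.sd_coeffs),
            "ga_range": list(self.ga_range),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass(frozen=True)
class Scan:
    """One ultrasound AC measurement."""

    pregnancy_id: str
    ga: float
    ac_mm: float
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.ac_mm <= 0:
            raise InvalidInputError(f"ac_mm must be positive, got {self.ac_mm}")


@dataclass(frozen=True)
class ACClassification:
    threshold: int
    predicted: str  # "NM" or "NN"


def load_growth_standard(path: str | Path) -> GrowthStandard:
    data = json.loads(Path(path).read_text())
    return GrowthStandard(
        name=data["name"],
        mean_coeffs=tuple(data["mean_coeffs"]),
        sd_coeffs=tuple(data["sd_coeffs"]),
        ga_range=tuple(data["ga_range"]),
    )


def bundled_growth_standard() -> GrowthStandard:
    """The synthetic growth standard shipped with the package (for tests and
    simulation; replace with real INTERGROWTH-21st coefficients for clinical
    data)."""
    ref = resources.files("gcknipt").joinpath("data/synthetic_growth_standard.json")
    data = json.loads(ref.read_text())
    return GrowthStandard(
        name=data["name"],
        mean_coeffs=tuple(data["mean_coeffs"]),
        sd_coeffs=tuple(data["sd_coeffs"]),
        ga_range=tuple(data["ga_range"]),
    )


def ac_percentile(ac_mm: float, ga: float, std: GrowthStandard) -> float:
    """AC percentile for exact gestational age: 100 * Phi((ac - mean)/sd)."""
    std._check_ga(ga)
    z = (ac_mm - std.mean(ga)) / std.sd(ga)
    return float(100.0 * stats.norm.cdf(z))


def ac_from_percentile(percentile: float, ga: float, std: GrowthStandard) -> float:
    """Inverse of :func:`ac_percentile`: the AC (mm) at a given percentile."""
    std._check_ga(ga)
    if not 0.0 < percentile < 100.0:
        raise InvalidInputError("percentile must be in (0, 100) for inversion")
    z = stats.norm.ppf(percentile / 100.0)
    return float(std.mean(ga) + z * std.sd(ga))


def classify_by_ac(percentile: float, threshold: int) -> ACClassification:
    """Predict fetal genotype from an AC percentile.

    Test positivity (predicted N/M) is strictly below the threshold
    percentile; a percentile exactly at the threshold is predicted N/N.
    """
    if threshold not in (75, 90) and not 0 < threshold < 100:
        raise InvalidInputError(f"threshold must be a percentile in (0, 100), got {threshold}")
    if not 0.0 <= percentile <= 100.0:
        raise InvalidInputError(f"percentile must be in [0, 100], got {percentile}")
    predicted = "NM" if percentile < threshold else "NN"
    return ACClassification(threshold=threshold, predicted=predicted)


def select_scan(
    scans: list[Scan],
    window: tuple[float, float] = SCAN_WINDOW,
    target: float = SCAN_TARGET,
) -> Scan:
    """Pick the analysis scan: the in-window scan closest to the target
    gestational age, ties broken toward the earlier scan."""
    eligible = [s for s in scans if window[0] <= s.ga <= window[1]]
    if not eligible:
        raise NoEligibleScanError(
            f"no scan within [{window[0]}, {window[1]}] weeks among {len(scans)} scans"
        )
    return min(eligible, key=lambda s: (abs(s.ga - target), s.ga))
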