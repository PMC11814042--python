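"""Pollution assessment indices.

Covers the Dutch soil-quality threshold system (target and intervention
values corrected for clay and organic-matter content), three-band sample
classification against those thresholds, the Hakanson individual
ecological risk index Er = Tr * Cn / GB, and Table-style descriptive
statistics (mean, median, range, SD, CV%).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .sampletable import SampleTable

__all__ = [
    "ThresholdConstants",
    "EcoRiskConfig",
    "adjusted_threshold",
    "band_samples",
    "ecological_risk",
    "ER_CATEGORIES",
    "summarize",
]

# Hakanson toxicity coefficients for the three focus elements; GB background
# values are site-specific config, not defaults.
DEFAULT_TR = {"As": 10.0, "Pb": 5.0, "Sb": 7.0}

ER_CATEGORIES = (
    (40.0, "low"),
    (80.0, "medium"),
    (160.0, "significant"),
    (320.0, "high"),
    (np.inf, "very high"),
)

BAND_LABELS = ("below_target", "between", "above_intervention")


@dataclass(frozen=True)
class ThresholdConstants:
    """Per-element base thresholds and clay/OM correction constants.

    ``sw``/``iw`` are the base target and intervention values (mg/kg) for
    the reference soil (25% clay, 10% organic matter); ``a``, ``b``, ``c``
    are the element-specific correction constants.
    """

    sw: float
    iw: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.sw < self.iw:
            raise ValueError("target value must be below intervention value")
        if self.a + 25 * self.b + 10 * self.c <= 0:
            raise ValueError("reference-soil denominator must be positive")


@dataclass(frozen=True)
class EcoRiskConfig:
    """Toxicity coefficient Tr and background value GB for one element."""

    tr: float
    gb: float

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("Tr must be positive")
        if self.gb <= 0:
            raise ValueError("GB must be positive")


def adjusted_threshold(
    base: float,
    constants: ThresholdConstants,
    clay: float,
    om: float,
    dialect: str = "standard",
) -> float:
    """Soil-property-adjusted target or intervention value (mg/kg).

    The ``standard`` dialect applies the Dutch multiplicative correction

        base * (A + B*clay + C*om) / (A + 25B + 10C),

    which returns ``base`` unchanged for the reference soil (clay 25%,
    OM 10%). The ``literal`` dialect evaluates
    ``(base*A + B*clay + C*om) / (A + 25B + 10C)`` instead, reproducing a
    published variant whose numerator adds the scaled base to raw soil
    percentages.
    """
    if base < 0:
        raise ValueError("base threshold must be non-negative")
    if not (0 <= clay <= 100 and 0 <= om <= 100):
        raise ValueError("clay and om must be percentages in [0, 100]")
    a, b, c = constants.a, constants.b, constants.c
    denom = a + 25.0 * b + 10.0 * c
    if denom == 0:
        raise ZeroDivisionError("zero reference-soil denominator")
    if dialect == "standard":
        return base * (a + b * clay + c * om) / denom
    if dialect == "literal":
        return (base * a + b * clay + c * om) / denom
    raise ValueError(f"unknown dialect {dialect!r}")


def band_samples(
    conc: np.ndarray | pd.Series, target: float, intervention: float
) -> tuple[np.ndarray, dict[str, float]]:
    """Classify samples against target/intervention thresholds.

    Values equal to a threshold fall in the higher band. Returns the
    per-sample band labels and the band percentages; the percentages are
    computed in exact rational arithmetic and sum to 100 before rounding.
    """
    if not target < intervention:
        raise ValueError("target must be below intervention")
    values = np.asarray(conc, dtype=float)
    labels = np.where(
        values >= intervention,
        BAND_LABELS[2],
        np.where(values >= target, BAND_LABELS[1], BAND_LABELS[0]),
    )
    n = len(values)
    pct = {
        band: Fraction(int((labels == band).sum()) * 100, n) for band in BAND_LABELS
    }
    assert sum(pct.values()) == 100
    return labels, {band: float(v) for band, v in pct.items()}


def ecological_risk(cn: float, cfg: EcoRiskConfig) -> tuple[float, str]:
    """Individual ecological risk Er = Tr * Cn / GB and its category.

    Bands: < 40 low; 40-80 medium; 80-160 significant; 160-320 high;
    > 320 very high (left-closed: a value exactly at a boundary takes the
    higher category).
    """
    if cn < 0:
        raise ValueError("concentration must be non-negative")
    er = cfg.tr * cn / cfg.gb
    for upper, label in ER_CATEGORIES:
        if er < upper:
            return er, label
    raise AssertionError("unreachable")  # pragma: no cover


def summarize(table: SampleTable) -> pd.DataFrame:
    """Per-element descriptive statistics (Table-1 style).

    CV% = 100 * SD / mean with the n-1 sample standard deviation.
    Censored cells enter at their substitute value. Requires at least two
    uncensored values per element.
    """
    uncensored_counts = (~table.censored).sum(axis=0)
    bad = uncensored_counts[uncensored_counts < 2]
    if len(bad):
        raise ValueError(
            f"fewer than 2 uncensored values for: {', '.join(bad.index)}"
        )
    conc = table.conc
    stats = pd.DataFrame(
        {
            "mean": conc.mean(),
            "median": conc.median(),
            "max": conc.max(),
            "min": conc.min(),
            "sd": conc.std(ddof=1),
        }
    )
    stats["cv"] = 100.0 * stats["sd"] / stats["mean"]
    stats.index.name = "element"
    return stats
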