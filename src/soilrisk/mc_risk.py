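"""Probabilistic (Monte Carlo) health risk.

Per-element concentration distributions are fitted to the observed
concentrations (lognormal by moment matching by default, maximum
likelihood or empirical bootstrap as alternatives); each Monte Carlo
iteration draws a concentration per element, evaluates the deterministic
risk equations, and accumulates HI and TCR draws. Reported are the mean,
a configurable percentile (95th by default), exceedance probabilities for
the classification boundaries (HI > 1; CR at 1e-6 and 1e-4), and the
per-element share of total mean risk. Only concentrations are stochastic
by default; exposure parameters stay at their deterministic values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hra
from .hra import ExposureParams, ToxicityValues

__all__ = [
    "McConfig",
    "ConcentrationDistribution",
    "RiskDistribution",
    "fit_concentration_distribution",
    "monte_carlo_risk",
    "contribution_shares",
]

HI_THRESHOLD = 1.0
CR_BANDS = {"ignorable": 1e-6, "unacceptable": 1e-4}


@dataclass(frozen=True)
class McConfig:
    n_iter: int = 1000
    seed: int = 0
    confidence: float = 95.0  # reporting percentile
    distribution: str = "lognormal"  # or "empirical"
    fit_method: str = "moments"  # or "mle"

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be at least 100")
        if not 0 < self.confidence < 100:
            raise ValueError("confidence must lie in (0, 100)")


@dataclass(frozen=True)
class ConcentrationDistribution:
    """Fitted marginal for one element's concentration (mg/kg)."""

    family: str  # "lognormal" | "degenerate" | "empirical"
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "degenerate":
            return np.full(size, self.params["value"])
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size=size)
        if self.family == "empirical":
            values = np.asarray(self.params["values"], float)
            return rng.choice(values, size=size, replace=True)
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "degenerate":
            return float(self.params["value"])
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2))
        return float(np.mean(self.params["values"]))


def fit_concentration_distribution(
    conc: np.ndarray, family: str = "lognormal", method: str = "moments"
) -> ConcentrationDistribution:
    """Fit a marginal distribution to an element's concentration vector.

    ``moments`` matches the lognormal's arithmetic mean and SD exactly
    (closed form); ``mle`` fits on the log scale; ``empirical`` keeps the
    observed values for bootstrap resampling. A constant vector yields a
    degenerate (point-mass) distribution in every family.
    """
    x = np.asarray(conc, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 uncensored values")
    if x.std(ddof=1) == 0:
        return ConcentrationDistribution("degenerate", {"value": float(x[0])})
    if family == "empirical":
        return ConcentrationDistribution("empirical", {"values": x.copy()})
    if family != "lognormal":
        raise ValueError(f"unknown family {family!r}")
    if (x <= 0).any():
        raise ValueError("lognormal fit requires strictly positive values")
    if method == "moments":
        mean, sd = x.mean(), x.std(ddof=1)
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return ConcentrationDistribution(
            "lognormal", {"mu": float(mu), "sigma": float(np.sqrt(sigma2))}
        )
    if method == "mle":
        logs = np.log(x)
        return ConcentrationDistribution(
            "lognormal", {"mu": float(logs.mean()), "sigma": float(logs.std(ddof=0))}
        )
    raise ValueError(f"unknown method {method!r}")


@dataclass
class RiskDistribution:
    """Monte Carlo HI or TCR distribution for one population."""

    kind: str  # "HI" | "TCR"
    population: str
    element_draws: pd.DataFrame  # n_iter x elements
    total_draws: np.ndarray  # n_iter
    confidence: float

    @property
    def mean(self) -> float:
        # fsum: correctly rounded, so degenerate draws average exactly
        return math.fsum(self.total_draws) / len(self.total_draws)

    @property
    def percentile(self) -> float:
        return float(np.percentile(self.total_draws, self.confidence))

    def exceedance(self, threshold: float) -> float:
        """P(total risk > threshold)."""
        return float((self.total_draws > threshold).mean())

    def band_probabilities(self) -> dict[str, float]:
        if self.kind == "HI":
            p = self.exceedance(HI_THRESHOLD)
            return {"acceptable": 1.0 - p, "unacceptable": p}
        lo = self.exceedance(CR_BANDS["ignorable"])
        hi = self.exceedance(CR_BANDS["unacceptable"])
        return {"ignorable": 1.0 - lo, "notable": lo - hi, "unacceptable": hi}

    def contribution_pct(self) -> pd.Series:
        return contribution_shares(self.element_draws)

    def summary(self) -> pd.DataFrame:
        rows = []
        for el in self.element_draws.columns:
            d = self.element_draws[el].to_numpy()
            rows.append(
                (self.population, el, d.mean(), np.percentile(d, self.confidence))
            )
        rows.append(
            (self.population, "total", self.mean, self.percentile)
        )
        return pd.DataFrame(
            rows, columns=["population", "element", "mean", f"p{self.confidence:g}"]
        )


def monte_carlo_risk(
    distributions: dict[str, ConcentrationDistribution],
    params: ExposureParams,
    toxicity: dict[str, ToxicityValues],
    config: McConfig,
    kind: str = "HI",
) -> RiskDistribution:
    """Propagate fitted concentration distributions through the risk model.

    Draws one concentration per element per iteration, evaluates the
    deterministic equations (linear in concentration), and returns the
    draws; deterministic given ``config.seed``. ``kind`` selects the
    non-carcinogenic (HI) or carcinogenic (TCR) endpoint. Elements
    without the required toxicity values are skipped for that endpoint.
    """
    rng = np.random.default_rng(config.seed)
    per_element: dict[str, np.ndarray] = {}
    for el in distributions:
        tox = toxicity.get(el)
        if tox is None:
            continue
        if kind == "TCR" and not tox.is_carcinogen:
            continue
        if kind == "HI" and tox.RfDo is None and tox.RfC is None:
            continue
        draws = distributions[el].sample(rng, config.n_iter)
        if kind == "HI":
            per_element[el] = np.asarray(hra.hazard_quotients(draws, params, tox).total)
        elif kind == "TCR":
            per_element[el] = np.asarray(hra.cancer_risks(draws, params, tox).total)
        else:
            raise ValueError(f"unknown kind {kind!r}")
    if not per_element:
        raise ValueError("no element has the toxicity values required for " + kind)
    frame = pd.DataFrame(per_element)
    return RiskDistribution(
        kind=kind,
        population=params.population,
        element_draws=frame,
        total_draws=frame.to_numpy().sum(axis=1),
        confidence=config.confidence,
    )


def contribution_shares(element_draws: pd.DataFrame) -> pd.Series:
    """Per-element share (%) of the total mean risk, same-draw accounting;
    shares sum to 100 exactly."""
    means = element_draws.mean(axis=0)
    total = means.sum()
    if total <= 0:
        raise ValueError("zero total risk")
    return 100.0 * means / total
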