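"""Deterministic USEPA-style human health risk assessment.

Non-carcinogenic hazard quotients per exposure route (soil ingestion,
dermal contact, dust inhalation) and their hazard index

    HQing = (C * IRS * RBA * EF * ED) / (BW * AT * RfDo) * 1e-6
    HQder = (C * SA * AF * ABSd * EF * ED) / (BW * AT * RfDo * GIABS) * 1e-6
    HQinh = (C * EF * ED) / (AT * RfC * PEF)
    HI    = HQing + HQder + HQinh

and incremental lifetime cancer risks with age-adjusted intake factors

    IFS   = EF*EDa*IRSa/BWa + EF*EDc*IRSc/BWc
    DFS   = EF*EDa*SAa*AFa/BWa + EF*EDc*SAc*AFc/BWc
    CRing = (C * IFS * RBA * CSFo / AT) * 1e-6
    CRder = (C * DFS * ABSd * CSFo / (AT * GIABS)) * 1e-6
    CRinh = C * EF * ED * IUR * 1000 / (AT * PEF)
    TCR   = CRing + CRder + CRinh.

Units: C in mg/kg, the 1e-6 factor converts mg soil to kg, PEF (m^3/kg)
carries the soil-to-air conversion for inhalation, and the 1000 factor
converts mg to ug for the inhalation unit risk (per ug/m^3). All risks
are linear in C, which the Monte Carlo and source-apportionment layers
rely on. Default parameter values follow the USEPA Regional Screening
Level (RSL) resident scenario and are fully overridable via config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ExposureParams",
    "ToxicityValues",
    "RouteResult",
    "hazard_quotients",
    "intake_factors",
    "cancer_risks",
    "classify_risk",
    "CHILD",
    "ADULT",
    "AGE_ADJUSTED",
    "DEFAULT_TOXICITY",
]


@dataclass(frozen=True)
class ExposureParams:
    """Exposure scenario for one population (RSL resident conventions).

    All quantities strictly positive. For the age-adjusted carcinogenic
    pathway the child/adult sub-parameters (suffix c/a) are combined into
    the intake factors IFS and DFS.
    """

    population: str  # "child" | "adult" | "age-adjusted"
    IRS: float  # soil ingestion rate, mg/day
    EF: float  # exposure frequency, days/year
    ED: float  # exposure duration, years
    BW: float  # body weight, kg
    AT_nc: float  # averaging time, non-carcinogenic, days
    AT_ca: float  # averaging time, carcinogenic, days
    SA: float  # exposed skin surface, cm^2/day
    AF: float  # soil adherence factor, mg/cm^2
    PEF: float  # particulate emission factor, m^3/kg
    # child/adult components for age-adjusted intake factors
    IRSc: float | None = None
    IRSa: float | None = None
    EDc: float | None = None
    EDa: float | None = None
    BWc: float | None = None
    BWa: float | None = None
    SAc: float | None = None
    SAa: float | None = None
    AFc: float | None = None
    AFa: float | None = None

    def __post_init__(self) -> None:
        for name in ("IRS", "EF", "ED", "BW", "AT_nc", "AT_ca", "SA", "AF", "PEF"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ToxicityValues:
    """Per-element toxicity inputs; optional fields mark absent endpoints."""

    element: str
    RfDo: float | None = None  # oral reference dose, mg/kg-day
    RfC: float | None = None  # inhalation reference concentration, mg/m^3
    GIABS: float = 1.0  # gastrointestinal absorption fraction
    ABSd: float = 0.0  # dermal absorption fraction
    RBA: float = 1.0  # relative bioavailability
    CSFo: float | None = None  # oral cancer slope factor, (mg/kg-day)^-1
    IUR: float | None = None  # inhalation unit risk, (ug/m^3)^-1

    def __post_init__(self) -> None:
        for name in ("GIABS", "RBA"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.ABSd <= 1:
            raise ValueError("ABSd must lie in [0, 1]")

    @property
    def is_carcinogen(self) -> bool:
        return self.CSFo is not None or self.IUR is not None


@dataclass
class RouteResult:
    """Per-route risk values; a route is None when the toxicity input for
    it is absent (flagged, never silently zeroed)."""

    ingestion: ArrayLike | None
    dermal: ArrayLike | None
    inhalation: ArrayLike | None
    total: ArrayLike
    missing_routes: tuple[str, ...] = ()

    def routes(self) -> dict[str, ArrayLike]:
        return {
            "ingestion": self.ingestion,
            "dermal": self.dermal,
            "inhalation": self.inhalation,
        }


# -- RSL resident defaults -------------------------------------------------

CHILD = ExposureParams(
    population="child", IRS=200.0, EF=350.0, ED=6.0, BW=15.0,
    AT_nc=6.0 * 365.0, AT_ca=70.0 * 365.0, SA=2373.0, AF=0.2, PEF=1.36e9,
)
ADULT = ExposureParams(
    population="adult", IRS=100.0, EF=350.0, ED=20.0, BW=80.0,
    AT_nc=20.0 * 365.0, AT_ca=70.0 * 365.0, SA=6032.0, AF=0.07, PEF=1.36e9,
)
AGE_ADJUSTED = ExposureParams(
    population="age-adjusted", IRS=100.0, EF=350.0, ED=26.0, BW=80.0,
    AT_nc=26.0 * 365.0, AT_ca=70.0 * 365.0, SA=6032.0, AF=0.07, PEF=1.36e9,
    IRSc=200.0, IRSa=100.0, EDc=6.0, EDa=20.0, BWc=15.0, BWa=80.0,
    SAc=2373.0, SAa=6032.0, AFc=0.2, AFa=0.07,
)

# RSL-style toxicity defaults for the three focus carcinogens/toxicants and
# common companions; site configs override these.
DEFAULT_TOXICITY = {
    "As": ToxicityValues("As", RfDo=3.0e-4, RfC=1.5e-5, GIABS=1.0, ABSd=0.03,
                         RBA=0.6, CSFo=1.5, IUR=4.3e-3),
    "Pb": ToxicityValues("Pb", RfDo=3.5e-3, RfC=None, GIABS=1.0, ABSd=0.0,
                         RBA=1.0, CSFo=8.5e-3, IUR=1.2e-5),
    "Sb": ToxicityValues("Sb", RfDo=4.0e-4, RfC=None, GIABS=0.15, ABSd=0.0,
                         RBA=1.0),
    "Cd": ToxicityValues("Cd", RfDo=1.0e-3, RfC=1.0e-5, GIABS=0.025, ABSd=0.001,
                         RBA=1.0, IUR=1.8e-3),
    "Cr": ToxicityValues("Cr", RfDo=3.0e-3, RfC=1.0e-4, GIABS=0.025, ABSd=0.0,
                         RBA=1.0, CSFo=0.5, IUR=8.4e-2),
    "Ni": ToxicityValues("Ni", RfDo=2.0e-2, RfC=9.0e-5, GIABS=0.04, ABSd=0.0,
                         RBA=1.0, IUR=2.6e-4),
}


def hazard_quotients(
    C: ArrayLike, params: ExposureParams, tox: ToxicityValues
) -> RouteResult:
    """Non-carcinogenic hazard quotients and HI for one element.

    Routes whose toxicity input (RfDo for oral/dermal, RfC for inhalation)
    is absent are reported as None and excluded from HI, with the route
    names recorded in ``missing_routes``.
    """
    C = np.asarray(C, dtype=float) if np.ndim(C) else float(C)
    if np.any(np.asarray(C) < 0):
        raise ValueError("concentration must be non-negative")
    p, t = params, tox
    missing: list[str] = []
    hq_ing = hq_der = hq_inh = None
    if t.RfDo is not None:
        hq_ing = (C * p.IRS * t.RBA * p.EF * p.ED) / (p.BW * p.AT_nc * t.RfDo) * 1e-6
        if t.ABSd > 0:
            hq_der = (C * p.SA * p.AF * t.ABSd * p.EF * p.ED) / (
                p.BW * p.AT_nc * t.RfDo * t.GIABS
            ) * 1e-6
        else:
            hq_der = 0.0 * C
    else:
        missing += ["ingestion", "dermal"]
    if t.RfC is not None:
        hq_inh = (C * p.EF * p.ED) / (p.AT_nc * t.RfC * p.PEF)
    else:
        missing.append("inhalation")
    hi = sum(v for v in (hq_ing, hq_der, hq_inh) if v is not None)
    return RouteResult(hq_ing, hq_der, hq_inh, hi, tuple(missing))


def intake_factors(params: ExposureParams) -> tuple[float, float]:
    """Age-adjusted ingestion (IFS) and dermal (DFS) intake factors.

    IFS in mg*yr/(kg*day); DFS in mg*yr/(kg*day) via cm^2*mg/cm^2.
    Requires the child/adult sub-parameters.
    """
    p = params
    needed = ("IRSc", "IRSa", "EDc", "EDa", "BWc", "BWa", "SAc", "SAa", "AFc", "AFa")
    if any(getattr(p, name) is None for name in needed):
        raise ValueError("age-adjusted factors need child and adult sub-parameters")
    ifs = p.EF * p.EDa * p.IRSa / p.BWa + p.EF * p.EDc * p.IRSc / p.BWc
    dfs = p.EF * p.EDa * p.SAa * p.AFa / p.BWa + p.EF * p.EDc * p.SAc * p.AFc / p.BWc
    return ifs, dfs


def cancer_risks(
    C: ArrayLike, params: ExposureParams, tox: ToxicityValues
) -> RouteResult:
    """Incremental lifetime cancer risks per route and their total (TCR).

    Oral/dermal routes use the age-adjusted intake factors and CSFo;
    inhalation uses IUR with the 1000 ug/mg conversion. Routes lacking
    toxicity values contribute zero and are flagged.
    """
    if not tox.is_carcinogen:
        raise ValueError(f"{tox.element}: not a carcinogen in config")
    C = np.asarray(C, dtype=float) if np.ndim(C) else float(C)
    if np.any(np.asarray(C) < 0):
        raise ValueError("concentration must be non-negative")
    p, t = params, tox
    missing: list[str] = []
    if t.CSFo is not None:
        ifs, dfs = intake_factors(p)
        cr_ing = (C * ifs * t.RBA * t.CSFo / p.AT_ca) * 1e-6
        cr_der = (C * dfs * t.ABSd * t.CSFo / (p.AT_ca * t.GIABS)) * 1e-6
    else:
        cr_ing = cr_der = 0.0 * C
        missing += ["ingestion", "dermal"]
    if t.IUR is not None:
        cr_inh = C * p.EF * p.ED * t.IUR * 1000.0 / (p.AT_ca * p.PEF)
    else:
        cr_inh = 0.0 * C
        missing.append("inhalation")
    tcr = cr_ing + cr_der + cr_inh
    return RouteResult(cr_ing, cr_der, cr_inh, tcr, tuple(missing))


def classify_risk(value: float, kind: str) -> str:
    """Risk band for a hazard index or cancer risk value.

    HI: acceptable < 1, unacceptable >= 1. CR/TCR: ignorable < 1e-6,
    notable in [1e-6, 1e-4], unacceptable > 1e-4.
    """
    if value < 0:
        raise ValueError("risk value must be non-negative")
    if kind == "HI":
        return "acceptable" if value < 1.0 else "unacceptable"
    if kind in ("CR", "TCR"):
        if value < 1e-6:
            return "ignorable"
        if value <= 1e-4:
            return "notable"
        return "unacceptable"
    raise ValueError(f"unknown risk kind {kind!r}")
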