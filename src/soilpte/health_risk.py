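"""USEPA-style human health risk from soil PTE exposure.

Average daily doses (ADD, mg per kg body weight per day) are computed for
three routes — incidental soil ingestion, inhalation of resuspended
particulate, and dermal contact — for adults and children separately:

    ADD_ing  = C * IngR * EF * ED / (BW * AT) * 1e-6
    ADD_inh  = C * InhR * EF * ED / (PEF * BW * AT)
    ADD_derm = C * SA * SL * ABS * EF * ED / (BW * AT) * 1e-6

Non-carcinogenic risk divides each route dose by that route's reference
dose (hazard quotient, HQ) and sums over routes and elements (hazard
index, HI; HI < 1 means no significant risk). Carcinogenic risk multiplies
doses — averaged over a 70-year lifetime (AT = 25550 d) — by route slope
factors, available for As and Cd only; the total (TCR) is conventionally
acceptable between 1e-6 and 1e-4. A lifetime-averaged dose (LADD)
combining the childhood and adult exposure windows is also provided.

Exposure constants default to the values in wide use for Chinese soil
risk assessment; every one can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .survey_io import ReferenceData

Group = Literal["adult", "child"]
ROUTES = ("ingestion", "inhalation", "dermal")

TCR_ACCEPTABLE = (1e-6, 1e-4)


@dataclass(frozen=True)
class GroupParams:
    """Exposure constants for one population group."""

    IngR: float   # soil ingestion rate, mg/d
    InhR: float   # inhalation rate, m^3/d
    EF: float     # exposure frequency, d/a
    ED: float     # exposure duration, a
    BW: float     # body weight, kg
    SA: float     # exposed skin area, cm^2
    SL: float     # soil adherence, mg/(cm^2*d)
    ABS: float    # dermal absorption fraction, unitless

    def __post_init__(self) -> None:
        for name in ("IngR", "InhR", "EF", "ED", "BW", "SA", "SL", "ABS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exposure parameter {name} must be positive")

    @property
    def AT_nc(self) -> float:
        """Non-carcinogenic averaging time, days (ED * 365)."""
        return self.ED * 365.0


@dataclass(frozen=True)
class ExposureParams:
    """Adult and child exposure constants plus shared terms."""

    adult: GroupParams
    child: GroupParams
    PEF: float = 1.36e9          # particulate emission factor, m^3/kg
    AT_ca: float = 70 * 365.0    # carcinogenic averaging time, days

    def group(self, group: Group) -> GroupParams:
        if group not in ("adult", "child"):
            raise ValueError(f"unknown population group {group!r}")
        return getattr(self, group)


DEFAULT_EXPOSURE = ExposureParams(
    adult=GroupParams(IngR=100.0, InhR=14.5, EF=350.0, ED=24.0, BW=61.8,
                      SA=5075.0, SL=0.07, ABS=0.001),
    child=GroupParams(IngR=200.0, InhR=7.63, EF=350.0, ED=6.0, BW=15.9,
                      SA=2448.0, SL=0.2, ABS=0.001),
)


def _dose(c, numerator: float, bw: float, at: float, scale: float) -> float:
    if bw <= 0 or at <= 0:
        raise ValueError("BW and AT must be positive")
    return np.asarray(c, dtype=float) * numerator / (bw * at) * scale if np.ndim(c) \
        else float(c) * numerator / (bw * at) * scale


def add_ingestion(c, p: ExposureParams, group: Group, at: float | None = None):
    """Soil-ingestion ADD, mg/(kg*d). ``at`` overrides the averaging time."""
    g = p.group(group)
    return _dose(c, g.IngR * g.EF * g.ED, g.BW, at or g.AT_nc, 1e-6)


def add_inhalation(c, p: ExposureParams, group: Group, at: float | None = None):
    """Particulate-inhalation ADD, mg/(kg*d)."""
    g = p.group(group)
    return _dose(c, g.InhR * g.EF * g.ED / p.PEF, g.BW, at or g.AT_nc, 1.0)


def add_dermal(c, p: ExposureParams, group: Group, at: float | None = None):
    """Dermal-contact ADD, mg/(kg*d)."""
    g = p.group(group)
    return _dose(c, g.SA * g.SL * g.ABS * g.EF * g.ED, g.BW, at or g.AT_nc, 1e-6)


_ADD = {"ingestion": add_ingestion, "inhalation": add_inhalation, "dermal": add_dermal}


def ladd(c, p: ExposureParams, route: str):
    """Lifetime-averaged daily dose combining child and adult windows.

    LADD = C * EF / AT_ca * (term_child + term_adult) with the route's
    intake term ED/BW-weighted per group; e.g. for ingestion the group term
    is IngR * ED / BW * 1e-6, and for dermal SA * SL * ABS * ED / BW * 1e-6
    (per-group adherence and absorption).
    """
    a, ch = p.adult, p.child
    if a.EF != ch.EF:
        raise ValueError("LADD assumes a common exposure frequency")
    if route == "ingestion":
        terms = sum(g.IngR * g.ED / g.BW for g in (ch, a)) * 1e-6
    elif route == "inhalation":
        terms = sum(g.InhR * g.ED / g.BW for g in (ch, a)) / p.PEF
    elif route == "dermal":
        terms = sum(g.SA * g.SL * g.ABS * g.ED / g.BW for g in (ch, a)) * 1e-6
    else:
        raise ValueError(f"unknown route {route!r}")
    c = np.asarray(c, dtype=float) if np.ndim(c) else float(c)
    return c * a.EF / p.AT_ca * terms


@dataclass(frozen=True)
class DoseResult:
    """Route-resolved doses and risk quotients.

    ``hq``: (element, group, route) hazard quotients (NaN where no RfD for
    the route exists); ``hi``: hazard index per group; ``cr``/``tcr``
    analogous carcinogenic quantities; ``classification`` per group.
    """

    add: pd.DataFrame
    hq: pd.DataFrame | None = None
    hi: pd.Series | None = None
    cr: pd.DataFrame | None = None
    tcr: pd.Series | None = None
    classification: dict[str, str] = field(default_factory=dict)


def _rfd_for(ref: ReferenceData, el: str, route: str) -> float | None:
    return ref.rfd.get(el, {}).get(route)


def hazard(conc: Mapping[str, float], p: ExposureParams, ref: ReferenceData,
           per_route_rfd: bool = True) -> DoseResult:
    """Non-carcinogenic hazard quotients and hazard index.

    ``conc`` maps element -> concentration (mg/kg), typically study means.
    With ``per_route_rfd`` (default) each route's dose is divided by that
    route's RfD; otherwise the summed dose is divided by the ingestion RfD
    (single-RfD reading). Routes with no RfD contribute nothing and are
    reported as NaN. Raises ``KeyError`` naming any element without an
    ingestion RfD.
    """
    rows_add, rows_hq = [], []
    hi = {g: 0.0 for g in ("adult", "child")}
    for el, c in conc.items():
        if _rfd_for(ref, el, "ingestion") is None:
            raise KeyError(f"no reference dose for element {el!r}")
        for g in ("adult", "child"):
            doses = {r: _ADD[r](c, p, g) for r in ROUTES}
            if per_route_rfd:
                hqs = {}
                for r in ROUTES:
                    rfd = _rfd_for(ref, el, r)
                    hqs[r] = doses[r] / rfd if rfd is not None else np.nan
                hq_el = float(np.nansum(list(hqs.values())))
            else:
                rfd = _rfd_for(ref, el, "ingestion")
                hq_el = sum(doses.values()) / rfd
                hqs = {r: doses[r] / rfd for r in ROUTES}
            hi[g] += hq_el
            for r in ROUTES:
                rows_add.append((el, g, r, doses[r]))
                rows_hq.append((el, g, r, hqs[r]))
    add = pd.DataFrame(rows_add, columns=["element", "group", "route", "add"])
    hq = pd.DataFrame(rows_hq, columns=["element", "group", "route", "hq"])
    hi = pd.Series(hi, name="HI")
    cls = {g: ("no significant non-carcinogenic risk" if v < 1.0
               else "potential non-carcinogenic risk") for g, v in hi.items()}
    return DoseResult(add=add, hq=hq, hi=hi, classification=cls)


def carcinogenic(conc: Mapping[str, float], p: ExposureParams,
                 ref: ReferenceData) -> DoseResult:
    """Carcinogenic risk per group for elements with slope factors.

    Doses use the lifetime averaging time AT_ca so each group's risk is
    averaged over the 70-year lifetime. Elements without slope factors are
    reported with CR = NaN ("not available"), never silently zero.
    """
    rows_add, rows_cr = [], []
    tcr = {g: 0.0 for g in ("adult", "child")}
    for el, c in conc.items():
        sfs = ref.sf.get(el)
        for g in ("adult", "child"):
            doses = {r: _ADD[r](c, p, g, at=p.AT_ca) for r in ROUTES}
            for r in ROUTES:
                rows_add.append((el, g, r, doses[r]))
                if sfs is None:
                    rows_cr.append((el, g, r, np.nan))
                else:
                    sf = sfs.get(r)
                    cr = doses[r] * sf if sf is not None else np.nan
                    rows_cr.append((el, g, r, cr))
                    if sf is not None:
                        tcr[g] += cr
    add = pd.DataFrame(rows_add, columns=["element", "group", "route", "add"])
    cr = pd.DataFrame(rows_cr, columns=["element", "group", "route", "cr"])
    tcr = pd.Series(tcr, name="TCR")
    cls = {}
    for g, v in tcr.items():
        if v < TCR_ACCEPTABLE[0]:
            cls[g] = "negligible"
        elif v <= TCR_ACCEPTABLE[1]:
            cls[g] = "acceptable"
        else:
            cls[g] = "significant"
    return DoseResult(add=add, cr=cr, tcr=tcr, classification=cls)


def hq_by_element(result: DoseResult, group: Group) -> pd.Series:
    """Per-element HQ (routes summed) for one group, from a hazard result."""
    sub = result.hq[result.hq["group"] == group]
    return sub.groupby("element")["hq"].sum(min_count=1).fillna(0.0)


def cr_by_element(result: DoseResult, group: Group) -> pd.Series:
    """Per-element CR (routes summed) for one group; NaN-only elements dropped."""
    if result.cr is None:
        raise ValueError("not a carcinogenic result")
    sub = result.cr[result.cr["group"] == group]
    per = sub.groupby("element")["cr"].sum(min_count=1)
    return per.dropna()
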