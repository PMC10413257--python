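"""Batch-culture kinetics: growth, productivity and nutrient-uptake rates.

All calculators work on daily sampled series. The default analysis
window for growth and consumption is the log phase, days 1-4.
Removal is previous-minus-current concentration so a declining nutrient
yields a positive rate. Concentrations for phosphate and ammonium are
element-mass based (mg P/L, mg N/L), as colorimetric assays report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .containers import PhysiologySeries
from .errors import DomainError

MOLAR_MASS = {"P": 30.97, "Mg": 24.31, "N": 14.01}  # g/mol
NUTRIENT_FIELDS = {"P": "pe", "Mg": "mg", "N": "nh4n"}

DEFAULT_WINDOW = (1, 4)  # log phase, days


def mg_per_l_to_mm(value: float, nutrient: str) -> float:
    """mg element/L -> mmol/L (mM)."""
    return value / _molar_mass(nutrient)


def mm_to_mg_per_l(value: float, nutrient: str) -> float:
    return value * _molar_mass(nutrient)


def _molar_mass(nutrient: str) -> float:
    try:
        return MOLAR_MASS[nutrient]
    except KeyError:
        raise DomainError(
            f"unknown nutrient {nutrient!r}; supported: {sorted(MOLAR_MASS)}"
        )


def specific_growth_rate(
    series: PhysiologySeries, line: str, t0: int = DEFAULT_WINDOW[0], t1: int = DEFAULT_WINDOW[1]
) -> float:
    """mu = ln(y1/y0)/(t1-t0) over the exponential window."""
    biomass = series.series(line, "biomass")
    if t1 <= t0:
        raise DomainError("t1 must exceed t0")
    try:
        y0, y1 = float(biomass[t0]), float(biomass[t1])
    except KeyError as e:
        raise DomainError(f"day {e} not in series for line {line}")
    if y0 <= 0 or y1 <= 0:
        raise DomainError("biomass must be positive at both window endpoints")
    return math.log(y1 / y0) / (t1 - t0)


def doubling_time(mu: float) -> float:
    """ln(2)/mu, in days."""
    if mu <= 0:
        raise DomainError("doubling time undefined for mu <= 0")
    return math.log(2.0) / mu


def biomass_productivity(series: PhysiologySeries, line: str, t: int = 7) -> float:
    """(final - initial biomass) / cultivation time, g dw/L/day."""
    biomass = series.series(line, "biomass")
    days = biomass.index
    first, last = days.min(), days.max()
    return (float(biomass[last]) - float(biomass[first])) / t


def max_removal_rate(
    series: PhysiologySeries, line: str, nutrient: str, molar: bool = True
) -> tuple[float, int]:
    """Highest daily concentration drop and the day it occurred.

    Daily removal is concentration(d-1) - concentration(d); with
    ``molar`` the rate is converted from mg/L/day to mM/day using the
    element's molar mass.
    """
    fieldname = NUTRIENT_FIELDS.get(nutrient)
    if fieldname is None:
        raise DomainError(
            f"unknown nutrient {nutrient!r}; supported: {sorted(NUTRIENT_FIELDS)}"
        )
    conc = series.series(line, fieldname)
    if len(conc) < 2:
        raise DomainError("need at least two days")
    removal = -conc.diff().dropna()  # previous minus current
    day = int(removal.idxmax())
    rate = float(removal.max())
    if molar:
        rate = mg_per_l_to_mm(rate, nutrient)
    return rate, day


def molar_ratio(rmax_p: float, rmax_mg: float) -> float:
    """Ratio of two removal rates expressed in the same molar units."""
    if rmax_mg == 0:
        raise DomainError("Mg removal rate is zero; ratio undefined")
    return rmax_p / rmax_mg


def nutrient_consumption(
    series: PhysiologySeries,
    line: str,
    nutrient: str,
    t0: int = DEFAULT_WINDOW[0],
    t1: int = DEFAULT_WINDOW[1],
) -> float:
    """V = (CN0 - CN1) / (Bc1 - Bc0): mg nutrient consumed per g dw formed."""
    fieldname = NUTRIENT_FIELDS.get(nutrient)
    if fieldname is None:
        raise DomainError(
            f"unknown nutrient {nutrient!r}; supported: {sorted(NUTRIENT_FIELDS)}"
        )
    conc = series.series(line, fieldname)
    biomass = series.series(line, "biomass")
    try:
        dn = float(conc[t0]) - float(conc[t1])
        db = float(biomass[t1]) - float(biomass[t0])
    except KeyError as e:
        raise DomainError(f"day {e} not in series for line {line}")
    if db <= 0:
        raise DomainError("biomass gain must be positive over the window")
    return dn / db


def uptake_rate(
    v: float,
    mu: float,
    t0: int = DEFAULT_WINDOW[0],
    t1: int = DEFAULT_WINDOW[1],
    mode: str = "times_mu",
) -> float:
    """Specific uptake rate k from consumption V.

    Modes: ``times_mu`` (V*mu; per-biomass daily uptake during balanced
    exponential growth — the only form whose units are amount per g dw
    per day), ``per_day`` (V/(t1-t0)) and ``paper`` (V/mu).
    """
    if mode == "times_mu":
        if mu <= 0:
            raise DomainError("mu must be positive")
        return v * mu
    if mode == "per_day":
        if t1 <= t0:
            raise DomainError("t1 must exceed t0")
        return v / (t1 - t0)
    if mode == "paper":
        if mu <= 0:
            raise DomainError("mu must be positive")
        return v / mu
    raise DomainError(f"unknown mode {mode!r}; use times_mu, per_day or paper")


@dataclass
class RateSummary:
    """Derived kinetics for one line."""

    line: str
    mu: float
    doubling_time: float
    productivity: float
    v_p: float  # mg P per g dw
    v_mg: float
    k_p: float  # mmol per g dw per day (default mode)
    k_mg: float
    rmax_p: float  # mM/day
    rmax_p_day: int
    rmax_mg: float
    rmax_mg_day: int
    p_mg_molar_ratio: float


def summarize_line(
    series: PhysiologySeries,
    line: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
    total_time: int = 7,
    mode: str = "times_mu",
) -> RateSummary:
    t0, t1 = window
    mu = specific_growth_rate(series, line, t0, t1)
    v_p = nutrient_consumption(series, line, "P", t0, t1)
    v_mg = nutrient_consumption(series, line, "Mg", t0, t1)
    k_p = uptake_rate(mg_per_l_to_mm(v_p, "P"), mu, t0, t1, mode)
    k_mg = uptake_rate(mg_per_l_to_mm(v_mg, "Mg"), mu, t0, t1, mode)
    rmax_p, day_p = max_removal_rate(series, line, "P")
    rmax_mg, day_mg = max_removal_rate(series, line, "Mg")
    return RateSummary(
        line=line,
        mu=mu,
        doubling_time=doubling_time(mu),
        productivity=biomass_productivity(series, line, total_time),
        v_p=v_p,
        v_mg=v_mg,
        k_p=k_p,
        k_mg=k_mg,
        rmax_p=rmax_p,
        rmax_p_day=day_p,
        rmax_mg=rmax_mg,
        rmax_mg_day=day_mg,
        p_mg_molar_ratio=molar_ratio(rmax_p, rmax_mg),
    )


def summarize(series: PhysiologySeries, **kw) -> pd.DataFrame:
    """One RateSummary row per line."""
    rows = [summarize_line(series, line, **kw).__dict__ for line in series.lines]
    return pd.DataFrame(rows).set_index("line")
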