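"""Microbial physiology from headspace CO2 and 18O-DNA incubation data.

The conversion chain implemented here turns raw 24-hr soil incubation
measurements into gross microbial rates:

* headspace CO2 accumulation -> respiration (ideal gas law, per g soil dry
  weight and per day),
* 18O enrichment of extracted DNA -> newly produced DNA -> growth (via the
  per-sample biomass-C : DNA conversion factor f_DNA),
* growth + respiration -> organic carbon uptake and carbon use efficiency
  (CUE = growth / uptake),
* rates per unit microbial biomass C (qGrowth, qCO2, qUptake) and microbial
  biomass turnover time (the reciprocal of qGrowth at steady state).

All rates are expressed per day via an explicit hour->day factor (24/t); the
gas-law step works in SI units internally (kPa * L = J, so p*V/(R*T) is in
moles directly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import MeasurementError, SchemaError, UndefinedValueError

__all__ = [
    "IncubationMeasurement",
    "IsotopeMeasurement",
    "respiration_rate",
    "dna_produced",
    "growth_rate",
    "carbon_uptake",
    "cue",
    "biomass_specific",
    "turnover_time",
    "derive_physiology",
]


@dataclass(frozen=True)
class IncubationMeasurement:
    """One headspace-CO2 incubation.

    DCO2 is the increase in headspace CO2 (ppm) over the incubation, DW the
    soil dry mass (g), t the incubation time (hr), p the atmospheric
    pressure (kPa), T the gas temperature (K) and Vhs the headspace volume
    (L).
    """

    sample_id: str
    DCO2: float
    DW: float
    t: float = 24.0
    p: float = 101.325
    T: float = 295.15
    Vhs: float = 0.02

    def __post_init__(self) -> None:
        for name in ("DW", "t", "p", "T", "Vhs"):
            if getattr(self, name) <= 0:
                raise MeasurementError(
                    f"{self.sample_id}: {name} must be strictly positive"
                )
        if self.DCO2 < 0:
            raise MeasurementError(f"{self.sample_id}: negative CO2 flux (DCO2 < 0)")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """18O content of a DNA extract from a labeled incubation.

    O_total is the total oxygen of the dried DNA extract (ug),
    atpct_labeled / atpct_NA the at% 18O of the labeled sample and of the
    natural-abundance controls, and atpct_label the 18O enrichment of soil
    water during the incubation (at%).
    """

    sample_id: str
    O_total: float
    atpct_labeled: float
    atpct_NA: float
    atpct_label: float = 97.0

    def __post_init__(self) -> None:
        if not 0 < self.atpct_label <= 100:
            raise MeasurementError(
                f"{self.sample_id}: label enrichment must be in (0, 100] at%"
            )
        if self.atpct_NA < 0:
            raise MeasurementError(f"{self.sample_id}: negative natural abundance")
        if self.O_total < 0:
            raise MeasurementError(f"{self.sample_id}: negative O_total")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def respiration_rate(
    DCO2,
    DW=None,
    t=24.0,
    p=101.325,
    T=295.15,
    Vhs=0.02,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Microbial respiration, ug CO2-C g^-1 soil DW day^-1.

    The headspace gas amount is n = p*Vhs/(R*T) mol (kPa * L = J).  The
    carbon respired is n * DCO2e-6 * M_C grams = n * DCO2 * M_C micrograms,
    normalised by soil dry mass and scaled from the t-hour incubation to a
    per-day rate.

    Accepts scalars or aligned arrays; an ``IncubationMeasurement`` can be
    passed as the single first argument.
    """
    if isinstance(DCO2, IncubationMeasurement):
        m = DCO2
        return respiration_rate(m.DCO2, m.DW, m.t, m.p, m.T, m.Vhs, consts)
    if DW is None:
        raise MeasurementError("DW is required")
    DCO2, DW, t, p, T, Vhs = map(_as_array, (DCO2, DW, t, p, T, Vhs))
    for name, v in (("DW", DW), ("t", t), ("p", p), ("T", T), ("Vhs", Vhs)):
        if np.any(v <= 0):
            raise MeasurementError(f"{name} must be strictly positive")
    if np.any(DCO2 < 0):
        raise MeasurementError("negative CO2 flux (DCO2 < 0)")
    n_gas = p * Vhs / (consts.R * T)  # mol of headspace gas
    ug_c = n_gas * DCO2 * consts.M_C  # 1e-6 (ppm) and 1e6 (g->ug) cancel
    out = ug_c / DW * (24.0 / t)
    return float(out) if out.ndim == 0 else out


def dna_produced(
    O_total,
    atpct_labeled,
    atpct_NA,
    atpct_label=97.0,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: str = "lenient",
):
    """Mass of newly synthesised dsDNA (ug) from 18O incorporation.

    DNA = O_total * (at%_excess/100) * (100/at%_label) * (100/f_O_DNA) with
    at%_excess = at%_labeled - at%_NA.  A negative excess (measurement noise
    below natural abundance) is clamped to zero with a warning in lenient
    mode and raises in strict mode.
    """
    if isinstance(O_total, IsotopeMeasurement):
        m = O_total
        return dna_produced(
            m.O_total, m.atpct_labeled, m.atpct_NA, m.atpct_label, consts, mode
        )
    O_total, atpct_labeled, atpct_NA, atpct_label = map(
        _as_array, (O_total, atpct_labeled, atpct_NA, atpct_label)
    )
    if np.any(atpct_label <= 0):
        raise MeasurementError("label enrichment must be strictly positive")
    if np.any(O_total < 0):
        raise MeasurementError("O_total must be nonnegative")
    excess = atpct_labeled - atpct_NA
    if np.any(excess < 0):
        if mode == "strict":
            raise MeasurementError("at% excess below natural abundance")
        warnings.warn(
            "negative at% excess clamped to 0 (below natural abundance)",
            stacklevel=2,
        )
        excess = np.clip(excess, 0.0, None)
    out = O_total * (excess / 100.0) * (100.0 / atpct_label) * (100.0 / consts.f_O_DNA)
    return float(out) if out.ndim == 0 else out


def growth_rate(dna_prod, f_dna, DW, t=24.0):
    """Microbial growth, ug C g^-1 soil DW day^-1.

    f_DNA (ug biomass C per ug DNA) converts the DNA produced during the
    incubation into biomass-C production, normalised by soil dry mass and
    scaled to a per-day rate.
    """
    dna_prod, f_dna, DW, t = map(_as_array, (dna_prod, f_dna, DW, t))
    for name, v in (("f_dna", f_dna), ("DW", DW), ("t", t)):
        if np.any(v <= 0):
            raise MeasurementError(f"{name} must be strictly positive")
    if np.any(dna_prod < 0):
        raise MeasurementError("dna_prod must be nonnegative")
    out = f_dna * dna_prod / DW * (24.0 / t)
    return float(out) if out.ndim == 0 else out


def carbon_uptake(growth, respiration):
    """Organic carbon uptake: the exact sum growth + respiration."""
    growth, respiration = _as_array(growth), _as_array(respiration)
    if np.any(growth < 0) or np.any(respiration < 0):
        raise MeasurementError("rates must be nonnegative")
    out = growth + respiration
    return float(out) if out.ndim == 0 else out


def cue(growth, respiration):
    """Carbon use efficiency: growth / (growth + respiration), in [0, 1).

    Undefined (raises) when both rates are zero; never silently 0.
    """
    growth, respiration = _as_array(growth), _as_array(respiration)
    if np.any(growth < 0) or np.any(respiration < 0):
        raise MeasurementError("rates must be nonnegative")
    total = growth + respiration
    if np.any(total == 0):
        raise UndefinedValueError("CUE undefined: growth and respiration both zero")
    out = growth / total
    return float(out) if out.ndim == 0 else out


def biomass_specific(rate, cmic):
    """Biomass-specific rate, ng C ug^-1 microbial biomass C day^-1.

    rate is in ug C g^-1 DW day^-1 and cmic in ug C g^-1 DW; the ratio is
    reported on a ng-per-ug basis (x1000).
    """
    rate, cmic = _as_array(rate), _as_array(cmic)
    if np.any(cmic <= 0):
        raise MeasurementError("microbial biomass must be strictly positive")
    out = rate / cmic * 1000.0
    return float(out) if out.ndim == 0 else out


def turnover_time(q_growth):
    """Microbial biomass turnover time in days.

    q_growth (ng C ug^-1 Cmic day^-1) divided by 1000 is the fraction of
    biomass renewed per day; turnover time is its reciprocal, 1000/q_growth.
    """
    q_growth = _as_array(q_growth)
    if np.any(q_growth <= 0):
        raise UndefinedValueError("turnover time undefined for q_growth <= 0")
    out = 1000.0 / q_growth
    return float(out) if out.ndim == 0 else out


_INCUBATION_COLS = ["sample_id", "DCO2_ppm", "DW_g", "t_hr", "p_kPa", "T_K", "Vhs_L"]
_ISOTOPE_COLS = ["sample_id", "O_total_ug", "atpct_labeled", "atpct_NA", "atpct_label"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def derive_physiology(
    incubation: pd.DataFrame,
    isotope: pd.DataFrame,
    f_dna: pd.Series,
    cmic: pd.Series,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: str = "lenient",
) -> pd.DataFrame:
    """Full physiology table from the two raw instrument tables.

    Parameters
    ----------
    incubation, isotope
        Raw tables in the ``incubation.csv`` / ``isotope.csv`` schemas.
    f_dna, cmic
        Per-sample conversion factor (ug biomass C / ug DNA) and microbial
        biomass C (ug C g^-1 DW), indexed by sample_id (from the fumigation
        and DNA tables, see :mod:`microsoc.stoichiometry`).

    Returns
    -------
    DataFrame indexed by sample_id with respiration, growth, uptake, cue,
    q_growth, q_resp, q_uptake and turnover_time.
    """
    _require_columns(incubation, _INCUBATION_COLS, "incubation")
    _require_columns(isotope, _ISOTOPE_COLS, "isotope")
    inc = incubation.set_index("sample_id")
    iso = isotope.set_index("sample_id")
    ids = inc.index.intersection(iso.index)
    inc, iso = inc.loc[ids], iso.loc[ids]
    f_dna = f_dna.reindex(ids)
    cmic = cmic.reindex(ids)
    if f_dna.isna().any() or cmic.isna().any():
        raise SchemaError("f_dna / cmic missing for some incubation samples")

    resp = respiration_rate(
        inc["DCO2_ppm"].values, inc["DW_g"].values, inc["t_hr"].values,
        inc["p_kPa"].values, inc["T_K"].values, inc["Vhs_L"].values, consts,
    )
    dna = dna_produced(
        iso["O_total_ug"].values, iso["atpct_labeled"].values,
        iso["atpct_NA"].values, iso["atpct_label"].values, consts, mode,
    )
    grw = growth_rate(dna, f_dna.values, inc["DW_g"].values, inc["t_hr"].values)
    upt = carbon_uptake(grw, resp)
    eff = cue(grw, resp)
    qg = biomass_specific(grw, cmic.values)
    qr = biomass_specific(resp, cmic.values)
    qu = biomass_specific(upt, cmic.values)
    # zero growth (e.g. clamped excess) has no defined turnover time
    qg_arr = np.asarray(qg, dtype=float)
    tt = np.full_like(qg_arr, np.nan)
    pos = qg_arr > 0
    if not pos.all():
        warnings.warn("turnover time undefined for samples with zero growth",
                      stacklevel=2)
    tt[pos] = turnover_time(qg_arr[pos])
    return pd.DataFrame(
        {
            "respiration": resp,
            "growth": grw,
            "uptake": upt,
            "cue": eff,
            "q_growth": qg,
            "q_resp": qr,
            "q_uptake": qu,
            "turnover_time": tt,
        },
        index=pd.Index(ids, name="sample_id"),
    )
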