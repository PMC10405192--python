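"""Reactor performance metrics.

Loading and retention parameters (OLR, SLR, HRT, SRT), removal efficiencies,
acidification degree, ammonification efficiency, COD-equivalent conversions
and the COD-to-methane conversion efficiency, plus per-phase aggregation of
the resulting daily series.

Conventions
-----------
* Concentrations in mg L^-1, volumes in L, sludge masses in g.
* OLR in g COD L^-1 d^-1; SLR in g COD gVSS^-1 d^-1; HRT/SRT in days.
* Efficiencies are percentages. An effluent concentration above the influent
  yields a *negative* removal efficiency, which is reported as-is (flagged by
  the caller if desired) rather than clipped, so mass balances stay auditable.
* Methane is equivalent to 64 g COD per mole (complete oxidation
  CH4 + 2 O2 -> CO2 + 2 H2O); gas volumes are converted to moles with the
  ideal-gas law at a configurable reference temperature and pressure.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Analyte,
    DailyOperation,
    MeasurementRecord,
    PhaseDefinition,
    PhaseSummary,
    ReactorConfig,
    Tank,
    DEFAULT_PHASES,
    assign_phase,
)
from .errors import DomainError, OutOfRangeError

logger = logging.getLogger(__name__)

#: Ideal gas constant in L atm mol^-1 K^-1.
R_L_ATM = 0.082057366080960

#: g COD per mole of CH4 (2 mol O2 x 32 g/mol).
COD_PER_MOL_CH4 = 64.0

#: Molar mass of methane, g/mol.
CH4_MOLAR_MASS = 16.043

#: COD equivalents, g COD per g compound. Protein is measured as BSA and
#: carbohydrate as glucose; methane follows from oxidation stoichiometry.
COD_EQUIVALENT_FACTORS: Mapping[str, float] = {
    "protein_BSA": 1.5,
    "carbohydrate_glucose": 1.1,
    "methane": COD_PER_MOL_CH4 / CH4_MOLAR_MASS,
}


def olr(influent_tcod: float, fed_volume: float, reactor_volume: float) -> float:
    """Organic loading rate, g COD L^-1 d^-1.

    Daily COD load (influent TCOD concentration x fed volume) divided by the
    reactor working volume.
    """
    if reactor_volume <= 0:
        raise DomainError(f"reactor_volume must be > 0, got {reactor_volume}")
    return (influent_tcod / 1000.0) * fed_volume / reactor_volume


def slr(olr_value: float, reactor_vss: float) -> float:
    """Solids loading rate, g COD per g VSS per day."""
    if reactor_vss <= 0:
        raise DomainError(f"reactor VSS concentration must be > 0, got {reactor_vss}")
    return olr_value / reactor_vss


def hrt(volume: float, daily_flow: float) -> float:
    """Hydraulic retention time in days: tank volume over average daily flow."""
    if daily_flow <= 0:
        raise DomainError(f"HRT undefined: daily_flow must be > 0, got {daily_flow}")
    return volume / daily_flow


def srt(total_sludge: float, wasted_per_day: float) -> float:
    """Solids retention time in days: total sludge mass over daily wastage."""
    if wasted_per_day <= 0:
        raise DomainError(f"SRT undefined: wasted_per_day must be > 0, got {wasted_per_day}")
    return total_sludge / wasted_per_day


def removal_efficiency(influent: float, effluent: float) -> float:
    """Removal efficiency in percent: 100 x (influent - effluent) / influent.

    May be negative when the effluent exceeds the influent; the value is
    returned unmodified.
    """
    if influent <= 0:
        raise DomainError(f"influent concentration must be > 0, got {influent}")
    return 100.0 * (influent - effluent) / influent


def acidification_degree(vfa_as_cod: float, reference_cod: float) -> float:
    """VFA production (as COD) as a percentage of a reference COD (TCOD or SCOD)."""
    if reference_cod <= 0:
        raise DomainError(f"reference COD must be > 0, got {reference_cod}")
    return 100.0 * vfa_as_cod / reference_cod


def ammonification_efficiency(nh4_n: float, tkn: float) -> float:
    """Ammonium-N as a percentage of TKN; a proxy for protein degradation extent.

    NH4-N above TKN is physically inconsistent but can occur through
    measurement noise; it is reported (> 100%) with a warning, not rejected.
    """
    if tkn <= 0:
        raise DomainError(f"TKN must be > 0, got {tkn}")
    if nh4_n > tkn:
        logger.warning("NH4-N (%.1f) exceeds TKN (%.1f); efficiency > 100%%", nh4_n, tkn)
    return 100.0 * nh4_n / tkn


def cod_equivalent(mass: float, compound: str) -> float:
    """Convert a compound mass (g) to g COD using fixed equivalence factors."""
    if mass < 0:
        raise DomainError(f"mass must be >= 0, got {mass}")
    try:
        factor = COD_EQUIVALENT_FACTORS[compound]
    except KeyError:
        raise DomainError(
            f"unknown compound {compound!r}; choose from {sorted(COD_EQUIVALENT_FACTORS)}"
        )
    return mass * factor


def glucose_cod_factor() -> float:
    """g COD per g glucose from oxidation stoichiometry.

    C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O: six moles of O2 (32 g each) per mole of
    glucose (180.156 g).
    """
    glucose_molar_mass = 6 * 12.011 + 12 * 1.008 + 6 * 15.999
    return 6 * 2 * 15.999 / glucose_molar_mass


def methane_cod_factor() -> float:
    """g COD per g CH4 from oxidation stoichiometry (CH4 + 2 O2)."""
    return COD_PER_MOL_CH4 / CH4_MOLAR_MASS


def ch4_cod_production_rate(
    biogas_volume: float,
    ch4_fraction: float,
    temperature_K: float = 273.15,
    pressure_atm: float = 1.0,
) -> float:
    """Daily methane production expressed as g COD d^-1.

    The measured biogas volume (L d^-1) times the CH4 fraction gives the CH4
    volume; the ideal-gas law converts it to moles at the stated reference
    conditions, and each mole of CH4 is worth 64 g COD.
    """
    if not 0.0 <= ch4_fraction <= 1.0:
        raise DomainError(f"ch4_fraction must lie in [0, 1], got {ch4_fraction}")
    if temperature_K <= 0 or pressure_atm <= 0:
        raise DomainError("temperature and pressure must be > 0")
    if biogas_volume < 0:
        raise DomainError(f"biogas volume must be >= 0, got {biogas_volume}")
    moles = pressure_atm * (biogas_volume * ch4_fraction) / (R_L_ATM * temperature_K)
    return moles * COD_PER_MOL_CH4


def cod_ch4_conversion_efficiency(ch4_cod_rate: float, cod_fed_rate: float) -> float:
    """COD-to-methane conversion efficiency in percent."""
    if cod_fed_rate <= 0:
        raise DomainError(f"COD fed rate must be > 0, got {cod_fed_rate}")
    return 100.0 * ch4_cod_rate / cod_fed_rate


# ---------------------------------------------------------------------------
# Daily series assembly and per-phase aggregation
# ---------------------------------------------------------------------------

def _daily_means(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        {"day": r.day, "tank": r.tank.value, "analyte": r.analyte.value, "value": r.value}
        for r in records
        if r.size_fraction.value == "total"
    ]
    if not rows:
        return pd.DataFrame(columns=["day"])
    df = pd.DataFrame(rows)
    wide = df.pivot_table(index="day", columns=["tank", "analyte"], values="value", aggfunc="mean")
    wide.columns = [f"{t}.{a}" for t, a in wide.columns]
    return wide


def compute_performance_series(
    records: Sequence[MeasurementRecord],
    operations: Sequence[DailyOperation],
    config: ReactorConfig = ReactorConfig(),
    acidification_reference_tank: Tank = Tank.influent,
) -> pd.DataFrame:
    """Assemble the per-day performance series from raw measurements.

    Returns a DataFrame indexed by day with columns: olr, slr, hrt, srt,
    tcod_removal, scod_removal, acidification_tcod, acidification_scod,
    ammonification_bt, ammonification_reactor, codch4_efficiency,
    biogas_production. Days missing an ingredient carry NaN (no
    interpolation); zero-feed days have NaN loading/efficiency entries.

    ``acidification_reference_tank`` selects the COD denominator for the
    acidification degree: the raw influent (default) or the buffer tank.
    """
    wide = _daily_means(records)
    ops = {op.day: op for op in operations}
    days = sorted(set(wide.index) | set(ops))
    out = pd.DataFrame(index=pd.Index(days, name="day"), dtype=float)

    def get(day: float, tank: str, analyte: str) -> float:
        col = f"{tank}.{analyte}"
        if col in wide.columns and day in wide.index:
            return wide.at[day, col]
        return math.nan

    ref_tank = acidification_reference_tank.value
    for day in days:
        op = ops.get(day)
        if op is not None and op.fed_volume > 0:
            out.at[day, "olr"] = olr(op.influent_tcod, op.fed_volume, config.reactor_volume)
            vss_conc = op.reactor_vss_mass / config.reactor_volume
            out.at[day, "slr"] = slr(out.at[day, "olr"], vss_conc) if vss_conc > 0 else math.nan
            out.at[day, "hrt"] = hrt(config.reactor_volume, op.fed_volume)
            out.at[day, "hrt_bt"] = hrt(config.buffer_tank_volume, op.fed_volume)
            if op.wasted_sludge > 0:
                out.at[day, "srt"] = srt(op.total_sludge, op.wasted_sludge)
        inf_tcod = get(day, "influent", "TCOD")
        eff_tcod = get(day, "effluent", "TCOD")
        if inf_tcod > 0 and not math.isnan(eff_tcod):
            out.at[day, "tcod_removal"] = removal_efficiency(inf_tcod, eff_tcod)
        inf_scod = get(day, "influent", "SCOD")
        eff_scod = get(day, "effluent", "SCOD")
        if inf_scod > 0 and not math.isnan(eff_scod):
            out.at[day, "scod_removal"] = removal_efficiency(inf_scod, eff_scod)
        vfa_bt = get(day, "buffer_tank", "VFA_COD")
        ref_tcod = get(day, ref_tank, "TCOD")
        ref_scod = get(day, ref_tank, "SCOD")
        if not math.isnan(vfa_bt):
            if ref_tcod > 0:
                out.at[day, "acidification_tcod"] = acidification_degree(vfa_bt, ref_tcod)
            if ref_scod > 0:
                out.at[day, "acidification_scod"] = acidification_degree(vfa_bt, ref_scod)
        for tank, col in (("buffer_tank", "ammonification_bt"), ("reactor", "ammonification_reactor")):
            nh4 = get(day, tank, "NH4_N")
            tkn = get(day, tank, "TKN")
            if tkn > 0 and not math.isnan(nh4):
                out.at[day, col] = ammonification_efficiency(nh4, tkn)
        gas = get(day, "reactor", "biogas_volume")
        frac = get(day, "reactor", "ch4_fraction")
        if not math.isnan(gas):
            out.at[day, "biogas_production"] = gas
        if op is not None and op.fed_volume > 0 and not (math.isnan(gas) or math.isnan(frac)):
            rate = ch4_cod_production_rate(
                gas, frac, config.gas_reference_temperature, config.gas_reference_pressure
            )
            fed = (op.influent_tcod / 1000.0) * op.fed_volume
            out.at[day, "codch4_efficiency"] = cod_ch4_conversion_efficiency(rate, fed)
    return out


def phase_aggregate(
    series: pd.DataFrame,
    phases: Sequence[PhaseDefinition] = DEFAULT_PHASES,
) -> list[PhaseSummary]:
    """Per-phase mean +/- sample standard deviation (ddof=1) for each metric.

    Metrics with a single observation report sd = 0 with n = 1; metrics with
    no observations in a phase are omitted with a warning.
    """
    summaries = []
    phase_of = {}
    for day in series.index:
        try:
            phase_of[day] = assign_phase(day, phases)
        except OutOfRangeError:
            logger.warning("day %s outside all phases; excluded from aggregation", day)
    for phase in phases:
        days = [d for d, p in phase_of.items() if p == phase.name]
        sub = series.loc[days] if days else series.iloc[0:0]
        metrics: dict[str, tuple[float, float, int]] = {}
        for col in series.columns:
            vals = sub[col].dropna().to_numpy() if not sub.empty else np.array([])
            n = len(vals)
            if n == 0:
                logger.warning("phase %s: no observations for %s; omitted", phase.name, col)
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            metrics[col] = (mean, sd, n)
        summaries.append(PhaseSummary(phase=phase.name, metrics=metrics))
    return summaries


def phase_summary_frame(summaries: Sequence[PhaseSummary]) -> pd.DataFrame:
    """Flatten PhaseSummary objects into a tidy DataFrame for CSV export."""
    rows = []
    for s in summaries:
        for metric, (mean, sd, n) in s.metrics.items():
            rows.append({"phase": s.phase, "metric": metric, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows, columns=["phase", "metric", "mean", "sd", "n"])
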