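"""Convert raw instrument readings into microbial physiology metrics.

The measurement chain of the ¹⁸O-water stable-isotope-probing assay:

1. ¹⁸O-labelled water is mixed into field-moist soil; the realised ¹⁸O
   enrichment of the total soil water follows from isotope mass balance
   (:func:`soil_water_enrichment`).
2. After a 24-h incubation, DNA is extracted; the at% ¹⁸O excess of the
   DNA relative to a natural-abundance control, divided by the at% excess
   of the soil water, gives the fraction of DNA that is newly synthesised.
   Multiplying by the total oxygen content of the DNA pool and dividing by
   the mean oxygen weight fraction of DNA (31.21 %) converts that oxygen
   into micrograms of new DNA per gram dry soil and hour
   (:func:`dna_production`).
3. Growth in carbon units uses the microbial biomass C to DNA ratio:
   G = DNA_p * MBC / DNA (:func:`growth_rate`).
4. Respiration comes from headspace CO₂ accumulation over the same
   incubation, with a correction for the air replaced after the first gas
   sampling, converted to µg C via the ideal gas law
   (:func:`respiration_rate`).
5. Carbon use efficiency is CUE = G / (G + R) (:func:`cue`); biomass-
   specific rates are G_m = 1000 G / MBC (:func:`biomass_specific`).

Microbial biomass carbon is estimated by chloroform fumigation-extraction:
MBC = (EOC_fumigated - EOC_unfumigated) / k_EC with k_EC = 0.45
(:func:`mbc_from_cfe`).

Negative intermediate values (negative isotope excess, negative fumigation
difference, CO₂ depletion) are physically impossible but can arise from
instrument noise; they are *reported as computed* and marked with QC flags
rather than silently clipped, so that exclusion decisions stay explicit and
auditable downstream.

All scalar functions also accept numpy arrays; :func:`compute_physiology`
applies the whole chain to the five raw tables of a study in vectorised
form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NATURAL_ABUNDANCE_18O",
    "DNA_OXYGEN_WEIGHT_PERCENT",
    "KEC_DEFAULT",
    "MeasurementError",
    "LabelingSetup",
    "IsotopeSample",
    "HeadspaceSeries",
    "FumigationPair",
    "soil_water_enrichment",
    "label_enrichment_for_target",
    "mbc_from_cfe",
    "dna_production",
    "growth_rate",
    "respiration_rate",
    "cue",
    "biomass_specific",
    "compute_physiology",
]

#: Natural ¹⁸O abundance of VSMOW water, at%.
NATURAL_ABUNDANCE_18O = 0.2005
#: Mean oxygen content of DNA, weight percent.
DNA_OXYGEN_WEIGHT_PERCENT = 31.21
#: Default extractable-C efficiency factor of chloroform fumigation-extraction.
KEC_DEFAULT = 0.45
#: Ideal gas constant, L atm K⁻¹ mol⁻¹.
R_GAS_L_ATM = 0.082057
#: Molar mass of carbon, g mol⁻¹.
MOLAR_MASS_C = 12.011

# QC flag codes attached to physiology records.
FLAG_NEGATIVE_MBC = "NEGATIVE_MBC"
FLAG_NEGATIVE_DNA_P = "NEGATIVE_DNA_P"
FLAG_NEGATIVE_RESPIRATION = "NEGATIVE_RESPIRATION"
FLAG_MISSING_IRMS = "MISSING_IRMS"
FLAG_MISSING_DNA = "MISSING_DNA"
FLAG_MISSING_RESPIRATION = "MISSING_RESPIRATION"
FLAG_MISSING_MBC = "MISSING_MBC"
FLAG_MISSING_GRAVIMETRY = "MISSING_GRAVIMETRY"
FLAG_UNDEFINED_CUE = "UNDEFINED_CUE"


class MeasurementError(ValueError):
    """Raised for physically impossible or inconsistent inputs."""


@dataclass(frozen=True)
class LabelingSetup:
    """Soil-water labelling of one incubation vial.

    fresh_soil_mass, label_water_mass in g; gravimetric_water_content in g
    water per g fresh soil; enrichments in at% ¹⁸O.
    """

    fresh_soil_mass: float
    gravimetric_water_content: float
    label_water_mass: float
    label_enrichment: float
    natural_abundance: float = NATURAL_ABUNDANCE_18O
    incubation_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.fresh_soil_mass < 0 or self.label_water_mass < 0:
            raise MeasurementError("masses must be non-negative")
        if not 0 < self.natural_abundance <= self.label_enrichment <= 100:
            raise MeasurementError(
                "need 0 < natural_abundance <= label_enrichment <= 100 at%"
            )
        if self.incubation_hours <= 0:
            raise MeasurementError("incubation_hours must be positive")

    @property
    def native_water_mass(self) -> float:
        return self.fresh_soil_mass * self.gravimetric_water_content

    @property
    def dry_mass(self) -> float:
        return self.fresh_soil_mass * (1.0 - self.gravimetric_water_content)


@dataclass(frozen=True)
class IsotopeSample:
    """IRMS reading of one DNA extract: at% ¹⁸O, total oxygen (µg O per g
    dry soil, already scaled from the measured aliquot to the whole
    extract) and fluorometric DNA concentration (µg DNA per g dry soil)."""

    dna_at_percent: float
    total_oxygen: float = np.nan
    dna_total: float = np.nan

    def __post_init__(self) -> None:
        if not 0 < self.dna_at_percent < 100:
            raise MeasurementError("dna_at_percent must be in (0, 100)")


@dataclass(frozen=True)
class HeadspaceSeries:
    """Two-point headspace CO₂ record of one incubation vial."""

    headspace_volume: float  # ml
    co2_t0: float  # ppm, right after amendment
    co2_t_end: float  # ppm, end of incubation
    temperature: float  # °C
    dry_mass: float  # g
    sampled_volume: float = 5.0  # ml removed at t0 and replaced
    co2_replacement: float = 0.0  # ppm of the replacement air
    duration: float = 24.0  # h
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.sampled_volume < self.headspace_volume:
            raise MeasurementError("need 0 < sampled_volume < headspace_volume")
        if self.duration <= 0 or self.dry_mass <= 0:
            raise MeasurementError("duration and dry_mass must be positive")
        if self.temperature <= -273.15:
            raise MeasurementError("temperature below absolute zero")
        if min(self.co2_t0, self.co2_t_end, self.co2_replacement) < 0:
            raise MeasurementError("ppm values must be non-negative")


@dataclass(frozen=True)
class FumigationPair:
    """Fumigated / unfumigated extractable-organic-carbon pair (µg C g⁻¹ DM)."""

    eoc_fumigated: float
    eoc_unfumigated: float
    kec: float = KEC_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.kec <= 1:
            raise MeasurementError("kec must be in (0, 1]")


def soil_water_enrichment(setup: LabelingSetup) -> float:
    """Realised at% ¹⁸O of the total soil water after label addition.

    Two-pool isotope mass balance of native soil water (at natural
    abundance) and added label water.
    """
    m_nat = setup.native_water_mass
    m_lab = setup.label_water_mass
    total = m_nat + m_lab
    if total <= 0:
        raise MeasurementError("total water mass is zero; enrichment undefined")
    return (m_nat * setup.natural_abundance + m_lab * setup.label_enrichment) / total


def label_enrichment_for_target(
    m_native: float,
    m_label: float,
    target: float,
    natural_abundance: float = NATURAL_ABUNDANCE_18O,
) -> float:
    """Label at% needed so the mixed soil water reaches ``target`` at%.

    Inverse of :func:`soil_water_enrichment`.  Raises if the required
    enrichment exceeds 100 at% (the target is unreachable by dilution), with
    the infeasible value included in the message.
    """
    if m_label <= 0:
        raise MeasurementError("label water mass must be positive")
    if target < natural_abundance:
        raise MeasurementError("target below natural abundance")
    required = (target * (m_native + m_label) - m_native * natural_abundance) / m_label
    if required > 100.0:
        raise MeasurementError(
            f"target {target} at% infeasible: would need {required:.2f} at% label"
        )
    return required


def mbc_from_cfe(pair: FumigationPair) -> float:
    """Microbial biomass carbon (µg C g⁻¹ DM) from a fumigation pair.

    (EOC_fumigated − EOC_unfumigated) / k_EC.  A negative value (noise in
    the two extractions) is returned as computed; callers flag it.
    """
    return (pair.eoc_fumigated - pair.eoc_unfumigated) / pair.kec


def dna_production(
    labeled: IsotopeSample,
    natural_control: IsotopeSample,
    water_at: float,
    natural_abundance: float = NATURAL_ABUNDANCE_18O,
    incubation_hours: float = 24.0,
) -> float:
    """DNA production rate DNA_p (µg DNA h⁻¹ g⁻¹ DM).

    The fraction of the DNA pool synthesised during the incubation is the
    at% excess of the labelled DNA over the control, divided by the at%
    excess of the soil water over natural abundance (oxygen in new DNA
    derives from soil water).  Oxygen mass in new DNA is converted to DNA
    mass with the mean DNA oxygen weight fraction of 31.21 %.
    """
    if water_at <= natural_abundance:
        raise MeasurementError("soil water not enriched; no label signal possible")
    f_new = (labeled.dna_at_percent - natural_control.dna_at_percent) / (
        water_at - natural_abundance
    )
    oxygen_new = labeled.total_oxygen * f_new
    dna_new = oxygen_new / (DNA_OXYGEN_WEIGHT_PERCENT / 100.0)
    return dna_new / incubation_hours


def growth_rate(dna_p: float, mbc: float, dna_total: float):
    """Microbial growth G (µg C h⁻¹ g⁻¹ DM): G = DNA_p * MBC / DNA."""
    mbc = np.asarray(mbc, dtype=float) if np.ndim(mbc) else mbc
    if np.any(np.asarray(dna_total) <= 0):
        raise MeasurementError("DNA_total must be positive")
    if np.any(np.asarray(mbc) <= 0):
        raise MeasurementError("MBC must be positive")
    return dna_p * mbc / dna_total


def respiration_rate(series: HeadspaceSeries) -> float:
    """Respiration R (µg C h⁻¹ g⁻¹ DM) from two-point headspace CO₂.

    The first gas sample (``sampled_volume``) is replaced with air of known
    CO₂ concentration, so the effective start concentration is the
    volume-weighted mixture of what remained and the replacement air.  The
    accumulated ppm difference is converted to moles via the ideal gas law
    (default 1 atm) and to µg C via the molar mass of carbon.
    """
    v = series.headspace_volume
    c_start = (
        series.co2_t0 * (v - series.sampled_volume)
        + series.co2_replacement * series.sampled_volume
    ) / v
    delta_ppm = series.co2_t_end - c_start
    t_kelvin = series.temperature + 273.15
    moles = (delta_ppm * 1e-6) * series.pressure_atm * (v / 1000.0) / (
        R_GAS_L_ATM * t_kelvin
    )
    micrograms_c = moles * MOLAR_MASS_C * 1e6
    return micrograms_c / (series.duration * series.dry_mass)


def cue(g, r):
    """Carbon use efficiency CUE = G / (G + R); uptake U = G + R.

    Defined only for non-negative G and R with G + R > 0; raises otherwise
    (vector callers pre-filter and flag instead).
    """
    g_arr, r_arr = np.asarray(g, dtype=float), np.asarray(r, dtype=float)
    if np.any(g_arr < 0) or np.any(r_arr < 0):
        raise MeasurementError("CUE requires G >= 0 and R >= 0")
    u = g_arr + r_arr
    if np.any(u == 0):
        raise MeasurementError("CUE undefined: G + R = 0")
    out = g_arr / u
    return float(out) if out.ndim == 0 else out


def biomass_specific(rate, mbc):
    """Biomass-specific rate in mg C h⁻¹ g⁻¹ MBC: 1000 * rate / MBC."""
    if np.any(np.asarray(mbc) <= 0):
        raise MeasurementError("MBC must be positive")
    return 1000.0 * rate / mbc


# ---------------------------------------------------------------------------
# Vectorised pipeline over the five raw tables
# ---------------------------------------------------------------------------

_KEYS = ["plot_id", "date"]


def _merge_flag(flags: pd.Series, mask: pd.Series, code: str) -> pd.Series:
    return flags.where(~mask, flags.str.cat([code] * len(flags), sep=";").str.strip(";"))


def compute_physiology(
    bundle,
    natural_abundance: float = NATURAL_ABUNDANCE_18O,
    incubation_hours: float = 24.0,
    kec: float = KEC_DEFAULT,
) -> pd.DataFrame:
    """Apply the full measurement chain to a raw study bundle.

    ``bundle`` carries the five raw tables (``irms``, ``dna``, ``gc``,
    ``cfe``, ``gravimetry``) keyed by (plot_id, date); see
    :mod:`soilcue.io` for schemas.  Returns one physiology row per
    (plot_id, date) present in any table, with QC flags accumulated in a
    semicolon-separated ``qc_flags`` column.  Rows with missing or negative
    ingredients are retained and flagged; CUE is computed only where both G
    and R are non-negative and their sum is positive.
    """
    irms, dna, gc, cfe, grav = (
        bundle.irms, bundle.dna, bundle.gc, bundle.cfe, bundle.gravimetry,
    )

    # Pair each labelled IRMS reading with its natural-abundance control.
    labeled = irms.loc[irms["labeled"]].set_index(_KEYS)
    control = irms.loc[~irms["labeled"]].set_index(_KEYS)
    missing_ctrl = labeled.index.difference(control.index)
    if len(missing_ctrl):
        raise MeasurementError(
            f"labelled samples without natural-abundance control: "
            f"{sorted(missing_ctrl.tolist())[:5]}"
        )

    base = pd.MultiIndex.from_tuples(
        sorted(
            set(labeled.index)
            | set(dna.set_index(_KEYS).index)
            | set(gc.set_index(_KEYS).index)
            | set(cfe.set_index(_KEYS).index)
        ),
        names=_KEYS,
    )
    out = pd.DataFrame(index=base).reset_index()
    flags = pd.Series([""] * len(out), index=out.index)

    # Soil water enrichment from gravimetry (isotope mass balance).
    g = grav.set_index(_KEYS).reindex(base)
    native = g["fresh_soil_g"] * g["gwc_g_per_g"]
    water_total = native + g["label_water_g"]
    water_at = (
        native * natural_abundance + g["label_water_g"] * g["label_atpct"]
    ) / water_total
    flags = _merge_flag(flags, water_at.isna().reset_index(drop=True), FLAG_MISSING_GRAVIMETRY)

    lab = labeled.reindex(base)
    ctl = control.reindex(base)
    f_new = (lab["dna_at_percent"].to_numpy() - ctl["dna_at_percent"].to_numpy()) / (
        water_at.to_numpy() - natural_abundance
    )
    dna_p = (
        lab["total_oxygen_ug_per_gdm"].to_numpy()
        * f_new
        / (DNA_OXYGEN_WEIGHT_PERCENT / 100.0)
        / incubation_hours
    )
    out["DNA_p"] = dna_p
    flags = _merge_flag(flags, pd.Series(np.isnan(dna_p)), FLAG_MISSING_IRMS)
    flags = _merge_flag(flags, pd.Series(dna_p < 0), FLAG_NEGATIVE_DNA_P)

    d = dna.set_index(_KEYS).reindex(base)
    out["DNA_total"] = d["dna_ug_per_gdm"].to_numpy()
    flags = _merge_flag(flags, out["DNA_total"].isna(), FLAG_MISSING_DNA)

    c = cfe.set_index(_KEYS).reindex(base)
    mbc = (c["eoc_fum"] - c["eoc_unfum"]).to_numpy() / kec
    out["MBC"] = mbc
    flags = _merge_flag(flags, pd.Series(np.isnan(mbc)), FLAG_MISSING_MBC)
    flags = _merge_flag(flags, pd.Series(mbc < 0), FLAG_NEGATIVE_MBC)

    with np.errstate(invalid="ignore", divide="ignore"):
        g_rate = np.where(
            (out["DNA_total"].to_numpy() > 0) & (mbc > 0),
            dna_p * mbc / out["DNA_total"].to_numpy(),
            np.nan,
        )
    out["G"] = g_rate

    h = gc.set_index(_KEYS).reindex(base)
    v = h["headspace_ml"]
    c_start = (
        h["co2_t0_ppm"] * (v - h["sampled_ml"]) + h["co2_repl_ppm"] * h["sampled_ml"]
    ) / v
    delta = h["co2_tend_ppm"] - c_start
    moles = (delta * 1e-6) * (v / 1000.0) / (R_GAS_L_ATM * (h["temp_c"] + 273.15))
    r_rate = (moles * MOLAR_MASS_C * 1e6 / (h["duration_h"] * h["dry_mass_g"])).to_numpy()
    out["R"] = r_rate
    flags = _merge_flag(flags, pd.Series(np.isnan(r_rate)), FLAG_MISSING_RESPIRATION)
    flags = _merge_flag(flags, pd.Series(r_rate < 0), FLAG_NEGATIVE_RESPIRATION)

    out["U"] = out["G"] + out["R"]
    cue_ok = (out["G"] >= 0) & (out["R"] >= 0) & (out["U"] > 0)
    out["CUE"] = np.where(cue_ok, out["G"] / out["U"], np.nan)
    flags = _merge_flag(flags, ~cue_ok.fillna(False), FLAG_UNDEFINED_CUE)

    with np.errstate(invalid="ignore", divide="ignore"):
        out["G_m"] = np.where(mbc > 0, 1000.0 * out["G"] / mbc, np.nan)
        out["R_m"] = np.where(mbc > 0, 1000.0 * out["R"] / mbc, np.nan)

    out["qc_flags"] = flags.values
    return out
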