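"""Forward simulation of the climate-manipulation study.

The generator works in three layers:

1. **Latent physiology** (:func:`simulate_latent`): per sampling date, log
   biomass-specific growth (G_m) and respiration (R_m) follow a
   second-order response surface in the coded treatment factors
   eT, eCO2 ∈ {−1, 0, +1}, plus a within-plot random effect shared across
   dates (correlation ``rho``) and date-specific residual noise
   (heteroscedastic, largest in May).  Sheltered plots receive additive
   drought shifts (on the log scale) in July, separately for the ambient
   and future-climate corner of the design.  Microbial biomass carbon and
   the DNA pool are lognormal.
2. **Raw instrument tables** (:func:`latent_to_raw`): the latent rates are
   pushed backwards through the measurement chain to the IRMS at% values,
   headspace CO₂ concentrations, fumigation-extraction pairs, fluorometric
   DNA concentrations and gravimetry that would have produced them, then
   optional instrument noise is added.  At zero noise the raw tables
   reproduce the latent physiology exactly through
   :func:`soilcue.measurement.compute_physiology` — the round-trip identity
   the test suite relies on.
3. **Study bundles** (:func:`generate_study`) and the Monte-Carlo
   harness (:func:`parameter_recovery_experiment`).

All randomness flows from one root seed; each table draws from its own
child stream (fixed spawn key), so adding a new table never shifts the
draws of an existing one.

Default surface coefficients are realistic for temperate managed-grassland
topsoil: centre-of-design G_m around 0.4 mg C h⁻¹ g⁻¹ MBC with respiration
about 1.6-fold higher, giving CUE near 0.39, seasonal intercepts declining
from May to October, and treatment effects of a few tenths on the log
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import measurement as meas
from .design import SAMPLING_DATES, DesignConfig, build_design, coded_units

__all__ = [
    "SimulationParams",
    "RawBundle",
    "StudyData",
    "InfeasibleLatentError",
    "simulate_latent",
    "latent_to_raw",
    "generate_study",
    "parameter_recovery_experiment",
]

SURFACE_TERMS = ("intercept", "eCO2", "eT", "eCO2:eT", "eCO2^2", "eT^2")

# Fixed bench constants of the simulated assay (per vial).
FRESH_SOIL_G = 0.4
GWC_G_PER_G = 0.25          # g water per g fresh soil -> 0.3 g dry mass
LABEL_WATER_G = 0.04
TARGET_WATER_ATPCT = 25.0   # target 18O enrichment of total soil water
HEADSPACE_ML = 25.0
SAMPLED_ML = 5.0
CO2_AMBIENT_PPM = 420.0
EOC_UNFUM_BASE = 60.0       # µg C g⁻¹ DM in the unfumigated extract
INCUBATION_H = 24.0
#: Field/assay temperature per date at ambient warming, °C.
DATE_BASE_TEMP = {"May": 15.0, "July": 20.0, "October": 10.0}


class InfeasibleLatentError(ValueError):
    """Latent physiology outside the range the instruments could produce."""


def _default_surface_gm() -> dict:
    return {
        "May": {"intercept": -0.90, "eCO2": 0.51, "eT": -0.56,
                "eCO2:eT": 0.12, "eCO2^2": -0.30, "eT^2": 0.24},
        "July": {"intercept": -1.10, "eCO2": 0.05, "eT": -0.23,
                 "eCO2:eT": 0.0, "eCO2^2": 0.0, "eT^2": 0.0},
        "October": {"intercept": -1.50, "eCO2": 0.01, "eT": 0.10,
                    "eCO2:eT": 0.0, "eCO2^2": 0.0, "eT^2": 0.0},
    }


def _default_surface_rm() -> dict:
    return {
        "May": {"intercept": -0.45, "eCO2": 0.19, "eT": 0.06,
                "eCO2:eT": 0.0, "eCO2^2": 0.0, "eT^2": 0.0},
        "July": {"intercept": -0.65, "eCO2": 0.27, "eT": -0.52,
                 "eCO2:eT": 0.0, "eCO2^2": 0.0, "eT^2": 0.0},
        "October": {"intercept": -1.05, "eCO2": 0.01, "eT": 0.26,
                    "eCO2:eT": 0.0, "eCO2^2": 0.0, "eT^2": 0.0},
    }


@dataclass
class SimulationParams:
    """Truth values and variance components of the simulated study.

    Surface coefficients are on the natural-log scale in coded design
    units.  ``sigma`` is the residual SD of log G_m / log R_m per date;
    ``rho`` the within-plot correlation of residuals across dates.
    Drought shifts apply in July only.  Instrument noise: ``irms_at_sd``
    is absolute (at% ¹⁸O), the rest are relative SDs.
    """

    surface_gm: dict = field(default_factory=_default_surface_gm)
    surface_rm: dict = field(default_factory=_default_surface_rm)
    sigma: dict = field(default_factory=lambda: {"May": 0.45, "July": 0.12, "October": 0.10})
    rho: float = 0.3
    drought_gm: dict = field(default_factory=lambda: {"ambient": -0.15, "future": 0.80})
    drought_rm: dict = field(default_factory=lambda: {"ambient": 0.0, "future": 1.00})
    mbc_log_mean: float = float(np.log(600.0))
    mbc_log_sd: float = 0.25
    dna_log_mean: float = float(np.log(40.0))
    dna_log_sd: float = 0.25
    irms_at_sd: float = 0.005
    gc_rel_sd: float = 0.01
    eoc_rel_sd: float = 0.05
    dna_rel_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for d in SAMPLING_DATES:
            if self.sigma[d] < 0:
                raise ValueError("sigma must be >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        for s in (self.irms_at_sd, self.gc_rel_sd, self.eoc_rel_sd, self.dna_rel_sd):
            if s < 0:
                raise ValueError("noise SDs must be >= 0")

    def null(self) -> "SimulationParams":
        """Copy with all treatment and drought effects set to zero
        (intercepts and variance components kept) — the null model used in
        type-I-error simulations."""
        p = SimulationParams(**{**asdict(self)})
        for surf in (p.surface_gm, p.surface_rm):
            for d in surf:
                for term in surf[d]:
                    if term != "intercept":
                        surf[d][term] = 0.0
        p.drought_gm = {"ambient": 0.0, "future": 0.0}
        p.drought_rm = {"ambient": 0.0, "future": 0.0}
        return p


@dataclass
class RawBundle:
    """The five raw measurement tables of one study (see :mod:`soilcue.io`)."""

    irms: pd.DataFrame
    dna: pd.DataFrame
    gc: pd.DataFrame
    cfe: pd.DataFrame
    gravimetry: pd.DataFrame


@dataclass
class StudyData:
    design: pd.DataFrame
    latent: pd.DataFrame
    bundle: RawBundle
    params: SimulationParams


def _rng(seed: int, key: int) -> np.random.Generator:
    """Child generator ``key`` of root ``seed`` (PCG64, fixed spawn key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _surface_mean(surf: dict, et: np.ndarray, eco2: np.ndarray) -> np.ndarray:
    return (
        surf["intercept"]
        + surf["eCO2"] * eco2
        + surf["eT"] * et
        + surf["eCO2:eT"] * eco2 * et
        + surf["eCO2^2"] * eco2**2
        + surf["eT^2"] * et**2
    )


def simulate_latent(
    params: SimulationParams,
    design: pd.DataFrame,
    dates: tuple[str, ...] = SAMPLING_DATES,
) -> pd.DataFrame:
    """Draw the latent physiology table for all analysed plots × dates.

    Returns columns plot_id, date, eT, eCO2, drought, G_m, R_m, MBC,
    DNA_total, G, R, CUE (rates in the units of
    :mod:`soilcue.measurement`).
    """
    params.validate()
    plots = coded_units(design_mod.analysed_subset(design)).sort_values(
        "plot_id", ignore_index=True
    )
    n = len(plots)
    rng_plot = _rng(params.seed, 0)
    rng_gm = _rng(params.seed, 1)
    rng_rm = _rng(params.seed, 2)
    rng_mbc = _rng(params.seed, 3)
    rng_dna = _rng(params.seed, 4)

    # Plot random effects shared across dates (one per response).
    z_gm = rng_plot.standard_normal(n)
    z_rm = rng_plot.standard_normal(n)
    sr, se = np.sqrt(params.rho), np.sqrt(1.0 - params.rho)

    frames = []
    for date in dates:
        sig = params.sigma[date]
        et, eco2 = plots["eT"].to_numpy(), plots["eCO2"].to_numpy()
        mu_gm = _surface_mean(params.surface_gm[date], et, eco2)
        mu_rm = _surface_mean(params.surface_rm[date], et, eco2)
        if date == "July":
            shelter = plots["drought"].to_numpy(dtype=bool)
            future = (plots["warming_delta_C"].to_numpy() == 3.0) & (
                plots["co2_delta_ppm"].to_numpy() == 300.0
            )
            mu_gm = mu_gm + shelter * np.where(
                future, params.drought_gm["future"], params.drought_gm["ambient"]
            )
            mu_rm = mu_rm + shelter * np.where(
                future, params.drought_rm["future"], params.drought_rm["ambient"]
            )
        log_gm = mu_gm + sig * (sr * z_gm + se * rng_gm.standard_normal(n))
        log_rm = mu_rm + sig * (sr * z_rm + se * rng_rm.standard_normal(n))
        mbc = np.exp(params.mbc_log_mean + params.mbc_log_sd * rng_mbc.standard_normal(n))
        dna = np.exp(params.dna_log_mean + params.dna_log_sd * rng_dna.standard_normal(n))

        gm, rm = np.exp(log_gm), np.exp(log_rm)
        g = gm * mbc / 1000.0  # mg C / g MBC -> µg C / g DM
        r = rm * mbc / 1000.0
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": plots["plot_id"],
                    "date": date,
                    "warming_delta_C": plots["warming_delta_C"],
                    "co2_delta_ppm": plots["co2_delta_ppm"],
                    "eT": et,
                    "eCO2": eco2,
                    "drought": plots["drought"],
                    "G_m": gm,
                    "R_m": rm,
                    "MBC": mbc,
                    "DNA_total": dna,
                    "G": g,
                    "R": r,
                    "CUE": g / (g + r),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def latent_to_raw(
    latent: pd.DataFrame,
    params: SimulationParams,
    noise: bool = True,
) -> RawBundle:
    """Invert the measurement chain: latent physiology → raw instrument tables.

    Computes, per (plot, date), the IRMS at% and total oxygen, headspace
    CO₂ concentrations, fumigation pair, DNA concentration and gravimetry
    that reproduce the latent G, R, MBC and DNA pool exactly through
    :func:`soilcue.measurement.compute_physiology`, then adds instrument
    noise when ``noise`` is true.  Raises :class:`InfeasibleLatentError`
    when the implied DNA labelling would exceed the soil-water enrichment
    (fraction of new DNA ≥ 1).
    """
    nat = meas.NATURAL_ABUNDANCE_18O
    label_at = meas.label_enrichment_for_target(
        FRESH_SOIL_G * GWC_G_PER_G, LABEL_WATER_G, TARGET_WATER_ATPCT, nat
    )
    native = FRESH_SOIL_G * GWC_G_PER_G
    water_at = (native * nat + LABEL_WATER_G * label_at) / (native + LABEL_WATER_G)
    dry_mass = FRESH_SOIL_G * (1.0 - GWC_G_PER_G)

    g = latent["G"].to_numpy()
    r = latent["R"].to_numpy()
    mbc = latent["MBC"].to_numpy()
    dna_total = latent["DNA_total"].to_numpy()

    # DNA production implied by growth; fraction of pool newly synthesised.
    dna_p = g * dna_total / mbc
    f_new = dna_p * INCUBATION_H / dna_total
    if np.any(f_new >= 1.0):
        raise InfeasibleLatentError(
            "implied fraction of new DNA >= 1; latent growth too large for "
            "the labelling window"
        )
    total_ox = dna_total * meas.DNA_OXYGEN_WEIGHT_PERCENT / 100.0
    at_labeled = nat + f_new * (water_at - nat)

    # Headspace CO2 accumulation implied by respiration (ideal gas, 1 atm).
    temp_c = latent["date"].map(DATE_BASE_TEMP).to_numpy() + latent[
        "warming_delta_C"
    ].to_numpy()
    moles = r * INCUBATION_H * dry_mass / (meas.MOLAR_MASS_C * 1e6)
    delta_ppm = moles * meas.R_GAS_L_ATM * (temp_c + 273.15) / (HEADSPACE_ML / 1000.0) / 1e-6
    co2_tend = CO2_AMBIENT_PPM + delta_ppm  # t0 == replacement air -> C_start = t0

    eoc_fum = EOC_UNFUM_BASE + mbc * meas.KEC_DEFAULT

    n = len(latent)
    at_control = np.full(n, nat)
    eoc_unfum = np.full(n, EOC_UNFUM_BASE)
    co2_t0 = np.full(n, CO2_AMBIENT_PPM)
    dna_conc = dna_total.copy()

    if noise:
        r_ir = _rng(params.seed, 10)
        r_gc = _rng(params.seed, 11)
        r_eoc = _rng(params.seed, 12)
        r_dna = _rng(params.seed, 13)
        at_labeled = at_labeled + params.irms_at_sd * r_ir.standard_normal(n)
        at_control = at_control + params.irms_at_sd * r_ir.standard_normal(n)
        total_ox = total_ox * (1.0 + params.dna_rel_sd * r_dna.standard_normal(n))
        dna_conc = dna_conc * (1.0 + params.dna_rel_sd * r_dna.standard_normal(n))
        co2_t0 = co2_t0 * (1.0 + params.gc_rel_sd * r_gc.standard_normal(n))
        co2_tend = co2_tend * (1.0 + params.gc_rel_sd * r_gc.standard_normal(n))
        eoc_fum = eoc_fum * (1.0 + params.eoc_rel_sd * r_eoc.standard_normal(n))
        eoc_unfum = eoc_unfum * (1.0 + params.eoc_rel_sd * r_eoc.standard_normal(n))
        at_labeled = np.clip(at_labeled, 1e-4, None)
        at_control = np.clip(at_control, 1e-4, None)

    keys = latent[["plot_id", "date"]]
    irms = pd.concat(
        [
            keys.assign(
                labeled=True,
                dna_at_percent=at_labeled,
                total_oxygen_ug_per_gdm=total_ox,
            ),
            keys.assign(
                labeled=False,
                dna_at_percent=at_control,
                total_oxygen_ug_per_gdm=np.nan,
            ),
        ],
        ignore_index=True,
    )
    dna = keys.assign(dna_ug_per_gdm=dna_conc)
    gc = keys.assign(
        headspace_ml=HEADSPACE_ML,
        sampled_ml=SAMPLED_ML,
        co2_t0_ppm=co2_t0,
        co2_repl_ppm=co2_t0,  # replacement air sampled from the same source
        co2_tend_ppm=co2_tend,
        temp_c=temp_c,
        duration_h=INCUBATION_H,
        dry_mass_g=dry_mass,
    )
    cfe = keys.assign(eoc_fum=eoc_fum, eoc_unfum=eoc_unfum)
    gravimetry = keys.assign(
        fresh_soil_g=FRESH_SOIL_G,
        gwc_g_per_g=GWC_G_PER_G,
        label_water_g=LABEL_WATER_G,
        label_atpct=label_at,
    )
    return RawBundle(irms=irms, dna=dna, gc=gc, cfe=cfe, gravimetry=gravimetry)


def generate_study(
    params: SimulationParams | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    design_config: DesignConfig | None = None,
    noise: bool = True,
) -> StudyData:
    """Simulate a complete study: design, latent truth and raw tables.

    With defaults this yields 34 analysed plots × 3 dates = 102 physiology
    rows.  If ``outdir`` is given, writes ``design.csv``, the five raw
    CSVs, ``truth.csv`` and a ``params.json`` provenance file; output is
    byte-identical across runs with the same seed.
    """
    params = params or SimulationParams()
    if seed is not None:
        params = SimulationParams(**{**asdict(params), "seed": int(seed)})
    design = build_design(design_config)
    latent = simulate_latent(params, design)
    bundle = latent_to_raw(latent, params, noise=noise)
    study = StudyData(design=design, latent=latent, bundle=bundle, params=params)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from . import io as io_mod

        io_mod.write_design(design, out / "design.csv")
        io_mod.write_bundle(bundle, out)
        latent.to_csv(out / "truth.csv", index=False)
        (out / "params.json").write_text(json.dumps(asdict(params), indent=2) + "\n")
    return study


def parameter_recovery_experiment(
    params: SimulationParams,
    replicates: int,
    seed: int,
    dates: tuple[str, ...] = SAMPLING_DATES,
    response: str = "G_m",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo check of the whole chain: simulate → measure → fit.

    For each replicate, a full study is generated, pushed through
    :func:`compute_physiology`, and the per-date second-order response
    surface is fitted on the non-drought subset.  Returns one row per
    (date, term) with the truth, mean bias, RMSE, coverage of the 95 %
    Wald (t) confidence interval, and the rejection rate of the term's
    t-test at ``alpha``.
    """
    from . import io as io_mod
    from .stats import fit_surface_model

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    design = build_design()
    rsm_design = design_mod.rsm_subset(design)
    root = np.random.SeedSequence(entropy=seed)
    child_seeds = root.generate_state(replicates, dtype=np.uint32) % (2**31)

    surf_key = "surface_gm" if response == "G_m" else "surface_rm"
    truth = getattr(params, surf_key)
    records = []
    for rep in range(replicates):
        p = SimulationParams(**{**asdict(params), "seed": int(child_seeds[rep])})
        latent = simulate_latent(p, design, dates=dates)
        bundle = latent_to_raw(latent, p, noise=True)
        phys = meas.compute_physiology(bundle)
        phys = io_mod.attach_design(phys, design)
        for date in dates:
            fit = fit_surface_model(phys.loc[~phys["drought"]], response, date)
            tab = fit.table.set_index("term")
            for term in SURFACE_TERMS:
                if term == "intercept":
                    continue
                est = tab.loc[term, "estimate"]
                se = tab.loc[term, "se"]
                records.append(
                    {
                        "replicate": rep,
                        "date": date,
                        "term": term,
                        "truth": truth[date][term],
                        "estimate": est,
                        "se": se,
                        "p": tab.loc[term, "p"],
                        "df_resid": fit.df_resid,
                    }
                )

    from scipy import stats as sps

    raw = pd.DataFrame(records)
    tcrit = sps.t.ppf(1 - alpha / 2, raw["df_resid"])
    raw["covered"] = np.abs(raw["estimate"] - raw["truth"]) <= tcrit * raw["se"]
    raw["rejected"] = raw["p"] < alpha
    raw["err"] = raw["estimate"] - raw["truth"]
    raw["sq_err"] = raw["err"] ** 2
    summary = (
        raw.groupby(["date", "term"], sort=False)
        .agg(
            truth=("truth", "first"),
            bias=("err", "mean"),
            rmse=("sq_err", "mean"),
            coverage=("covered", "mean"),
            rejection_rate=("rejected", "mean"),
        )
        .reset_index()
    )
    summary["rmse"] = np.sqrt(summary["rmse"])
    return summary
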