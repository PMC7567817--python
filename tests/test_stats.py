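"""Statistics: OLS surfaces vs a normal-equation oracle, marginality
reduction, feasible GLS limits and closed forms, drought ANOVA vs a
brute-force sum-of-squares oracle, Tukey HSD identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilcue import io as io_mod
from soilcue.design import build_design
from soilcue.measurement import compute_physiology
from soilcue.simulate import SimulationParams, generate_study, simulate_latent
from soilcue.stats import (
    SURFACE_TERMS,
    _fit_one_structure,
    anova_drought,
    fit_seasonal_gls,
    fit_surface_model,
    reduce_by_marginality,
    summarize_cue,
    tukey_hsd,
)

# ---------------------------------------------------------------------------
# Response surface OLS
# ---------------------------------------------------------------------------


def _random_surface_frame(rng, n):
    """Random plot x response frame over the 3 x 3 factor grid."""
    et = rng.choice([-1.0, 0.0, 1.0], size=n)
    eco2 = rng.choice([-1.0, 0.0, 1.0], size=n)
    y = rng.normal(size=n) + 0.5 * et - 0.3 * eco2 + 0.2 * et * eco2
    return pd.DataFrame(
        {"plot_id": [f"P{i}" for i in range(n)], "date": "May",
         "eT": et, "eCO2": eco2, "CUE": y}
    )


def _normal_equations(df, terms):
    """Independent brute-force OLS oracle: solve (X'X)^-1 X'y directly."""
    cols = {
        "intercept": np.ones(len(df)),
        "eCO2": df["eCO2"].to_numpy(),
        "eT": df["eT"].to_numpy(),
        "eCO2:eT": (df["eCO2"] * df["eT"]).to_numpy(),
        "eCO2^2": (df["eCO2"] ** 2).to_numpy(),
        "eT^2": (df["eT"] ** 2).to_numpy(),
    }
    x = np.column_stack([cols[t] for t in terms])
    xtx = x.T @ x
    return np.linalg.solve(xtx, x.T @ df["CUE"].to_numpy())


def test_surface_fit_matches_normal_equation_oracle_on_random_designs():
    """100 random small designs: coefficients agree with the explicit
    (X'X)^-1 X'y solution to <= 1e-8."""
    rng = np.random.default_rng(12345)
    checked = 0
    while checked < 100:
        df = _random_surface_frame(rng, n=int(rng.integers(9, 30)))
        # need all 9 cells represented for full rank of the quadratic model
        if df.groupby(["eT", "eCO2"]).ngroups < 9:
            continue
        fit = fit_surface_model(df, "CUE", "May")
        oracle = _normal_equations(df, SURFACE_TERMS)
        assert np.max(np.abs(fit.table["estimate"].to_numpy() - oracle)) < 1e-8
        checked += 1


def test_surface_fit_nine_point_factorial_hand_design():
    """A 9-point full factorial with hand-set responses is interpolated
    exactly when responses follow the quadratic surface."""
    grid = [(et, ec) for et in (-1.0, 0.0, 1.0) for ec in (-1.0, 0.0, 1.0)]
    truth = dict(zip(SURFACE_TERMS, [0.4, 0.51, -0.56, 0.12, -0.30, 0.24]))
    rows = []
    for i, (et, ec) in enumerate(grid):
        y = (truth["intercept"] + truth["eCO2"] * ec + truth["eT"] * et
             + truth["eCO2:eT"] * ec * et + truth["eCO2^2"] * ec**2
             + truth["eT^2"] * et**2)
        rows.append({"plot_id": f"P{i}", "date": "May", "eT": et, "eCO2": ec, "CUE": y})
    fit = fit_surface_model(pd.DataFrame(rows), "CUE", "May")
    for term, value in truth.items():
        assert fit.table.set_index("term").loc[term, "estimate"] == pytest.approx(
            value, abs=1e-10
        )


def test_surface_fit_errors():
    df = _random_surface_frame(np.random.default_rng(0), 30)
    with pytest.raises(ValueError, match="rows"):
        fit_surface_model(df.head(5), "CUE", "May")
    collinear = df.copy()
    collinear["eCO2"] = collinear["eT"]
    with pytest.raises(ValueError, match="rank"):
        fit_surface_model(collinear, "CUE", "May")


def test_log_transform_applied_to_biomass_specific_rates():
    df = _random_surface_frame(np.random.default_rng(1), 27)
    df["G_m"] = np.exp(df["CUE"])
    log_fit = fit_surface_model(df, "G_m", "May")
    raw_fit = fit_surface_model(df, "CUE", "May")
    assert np.allclose(log_fit.table["estimate"], raw_fit.table["estimate"])


def test_marginality_reduction_keeps_main_effects_only():
    """Truth with only linear effects: every higher-order term is dropped,
    the main effects survive.  Replicate noise is constructed orthogonal to
    all surface terms (within-cell +/- pairs) so the higher-order estimates
    are exactly zero with a positive residual SE."""
    rows = []
    i = 0
    for et in (-1.0, 0.0, 1.0):
        for ec in (-1.0, 0.0, 1.0):
            for eps in (+0.01, -0.01):
                i += 1
                rows.append(
                    {"plot_id": f"P{i}", "date": "May", "eT": et, "eCO2": ec,
                     "CUE": 0.4 - 0.5 * et + 0.4 * ec + eps}
                )
    fit = fit_surface_model(pd.DataFrame(rows), "CUE", "May")
    reduced, log = reduce_by_marginality(fit)
    assert set(reduced.terms) == {"intercept", "eCO2", "eT"}
    assert {entry["dropped"] for entry in log} == {"eCO2:eT", "eCO2^2", "eT^2"}
    assert all(entry["p"] > 0.05 for entry in log)
    assert (reduced.table.set_index("term").loc[["eCO2", "eT"], "p"] < 0.05).all()


def test_marginality_reduction_noop_when_all_terms_significant():
    p = SimulationParams(seed=22, sigma={"May": 0.02, "July": 0.02, "October": 0.02})
    latent = simulate_latent(p, build_design())
    fit = fit_surface_model(latent.loc[~latent["drought"]], "G_m", "May")
    assert (fit.table.set_index("term").loc[list(SURFACE_TERMS[3:]), "p"] < 0.05).all()
    reduced, log = reduce_by_marginality(fit)
    assert reduced.terms == fit.terms and log == []


# ---------------------------------------------------------------------------
# Seasonal feasible GLS
# ---------------------------------------------------------------------------


def test_gls_equal_variance_mode_reduces_to_ols(noisy_physiology):
    """With forced-equal variances and no correlation the GLS estimator is
    ordinary least squares."""
    sub = noisy_physiology.loc[~noisy_physiology["drought"]]
    fit = fit_seasonal_gls(sub, "G_m", structures=("none",), equal_variances=True)

    from soilcue.stats import _prepare_response, _seasonal_design

    prep = _prepare_response(sub, "G_m")
    prep = prep.sort_values(
        ["plot_id", "date"],
        key=lambda s: s.map({"May": 0, "July": 1, "October": 2}) if s.name == "date" else s,
    )
    x, names, _ = _seasonal_design(prep, ["May", "July", "October"])
    ols = np.linalg.lstsq(x, prep["_y"].to_numpy(), rcond=None)[0]
    assert np.max(np.abs(fit.coefficients.to_numpy() - ols)) < 1e-6


def test_two_group_feasible_gls_closed_form():
    """Intercept-only model, two variance strata: the FGLS fixed point is
    the variance-weighted mean; oracle iterated from scalar closed forms."""
    rng = np.random.default_rng(42)
    y1 = rng.normal(0.0, 1.0, 40)
    y2 = rng.normal(1.0, 3.0, 40)
    y = np.concatenate([y1, y2])
    codes = np.array([0] * 40 + [1] * 40)
    x = np.ones((80, 1))
    slices = [slice(i, i + 1) for i in range(80)]
    beta, _, sigma2, rho, *_ = _fit_one_structure(y, x, codes, slices, "none", 2)

    mu = y.mean()
    for _ in range(200):  # scalar fixed-point oracle
        s1 = np.mean((y1 - mu) ** 2)
        s2 = np.mean((y2 - mu) ** 2)
        mu = (y1.sum() / s1 + y2.sum() / s2) / (len(y1) / s1 + len(y2) / s2)
    assert beta[0] == pytest.approx(mu, abs=1e-8)
    assert sigma2[0] == pytest.approx(np.mean((y1 - mu) ** 2), rel=1e-6)
    assert sigma2[1] == pytest.approx(np.mean((y2 - mu) ** 2), rel=1e-6)
    assert rho == 0.0


def test_gls_recovers_within_plot_correlation():
    """Strong equicorrelated plot effects: AIC prefers a correlated
    structure and the estimated rho is near the truth."""
    p = SimulationParams(
        seed=33, rho=0.6, sigma={"May": 0.3, "July": 0.3, "October": 0.3},
        irms_at_sd=0.0, gc_rel_sd=0.0, eoc_rel_sd=0.0, dna_rel_sd=0.0,
    )
    study = generate_study(p, noise=False)
    phys = io_mod.attach_design(compute_physiology(study.bundle), study.design)
    fit = fit_seasonal_gls(phys.loc[~phys["drought"]], "G_m")
    assert fit.structure in ("CS", "AR1")
    assert fit.rho == pytest.approx(0.6, abs=0.25)
    assert fit.converged


def test_gls_date_effect_power():
    """Seasonal intercept differences of the default magnitude are detected
    by the date F-test in at least 95% of 200 replicates."""
    root = np.random.SeedSequence(entropy=2020)
    seeds = root.generate_state(200, dtype=np.uint32) % (2**31)
    design = build_design()
    hits = 0
    for s in seeds:
        p = SimulationParams(seed=int(s))
        latent = simulate_latent(p, design)
        bundle_phys = latent  # latent already carries the analysis columns
        fit = fit_seasonal_gls(
            bundle_phys.loc[~bundle_phys["drought"]], "G_m", structures=("CS",)
        )
        date_p = fit.anova.set_index("term").loc["date", "p"]
        hits += date_p < 0.05
    assert hits / 200 >= 0.95


def test_gls_anova_table_shape(noisy_physiology):
    fit = fit_seasonal_gls(noisy_physiology.loc[~noisy_physiology["drought"]], "G_m")
    assert list(fit.anova["term"]) == [
        "date", "eCO2", "eT", "eCO2^2", "date:eCO2", "date:eT",
        "eCO2:eT", "date:eCO2:eT",
    ]
    assert (fit.anova["F"] >= 0).all()
    assert fit.anova["p"].between(0, 1).all()
    assert np.isfinite(fit.aic)
    assert set(fit.candidates["structure"]) == {"none", "CS", "AR1"}


# ---------------------------------------------------------------------------
# Drought factorial ANOVA + Tukey
# ---------------------------------------------------------------------------


def _drought_phys(cell_values: dict) -> pd.DataFrame:
    """Physiology-like frame for the 2 x 2 drought factorial, July.

    ``cell_values`` maps (climate, sheltered) to a list of CUE values.
    """
    rows = []
    i = 0
    for (climate, sheltered), values in cell_values.items():
        w, c = (3.0, 300.0) if climate == "future" else (0.0, 0.0)
        for v in values:
            i += 1
            rows.append(
                {"plot_id": f"P{i:03d}", "date": "July", "warming_delta_C": w,
                 "co2_delta_ppm": c, "drought": sheltered == "drought", "CUE": v}
            )
    return pd.DataFrame(rows)


def _brute_force_type1_ss(df):
    """Sequential sums of squares by explicit group-mean enumeration
    (balanced design): climate, drought, interaction, residual."""
    y = df["CUE"].to_numpy()
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    climate = np.where(df["warming_delta_C"] == 3.0, "future", "ambient")
    shelter = np.where(df["drought"], "drought", "control")
    ss_climate = sum(
        (y[climate == g].size) * (y[climate == g].mean() - grand) ** 2
        for g in np.unique(climate)
    )
    ss_drought = sum(
        (y[shelter == g].size) * (y[shelter == g].mean() - grand) ** 2
        for g in np.unique(shelter)
    )
    cell = pd.Series([f"{c}|{s}" for c, s in zip(climate, shelter)])
    ss_cells = sum(
        (y[cell == g].size) * (y[cell == g].mean() - grand) ** 2
        for g in cell.unique()
    )
    ss_inter = ss_cells - ss_climate - ss_drought
    ss_resid = ss_total - ss_cells
    return ss_climate, ss_drought, ss_inter, ss_resid, ss_total


def test_anova_matches_brute_force_ss_oracle():
    rng = np.random.default_rng(7)
    cells = {
        ("ambient", "control"): 0.40 + 0.02 * rng.standard_normal(5),
        ("ambient", "drought"): 0.35 + 0.02 * rng.standard_normal(5),
        ("future", "control"): 0.42 + 0.02 * rng.standard_normal(5),
        ("future", "drought"): 0.55 + 0.02 * rng.standard_normal(5),
    }
    df = _drought_phys({k: list(v) for k, v in cells.items()})
    table = anova_drought(df, "July", "CUE").set_index("term")
    ss_c, ss_d, ss_i, ss_r, ss_t = _brute_force_type1_ss(df)
    assert table.loc["climate", "SS"] == pytest.approx(ss_c, rel=1e-9)
    assert table.loc["drought", "SS"] == pytest.approx(ss_d, rel=1e-9)
    assert table.loc["climate:drought", "SS"] == pytest.approx(ss_i, rel=1e-9)
    assert table.loc["Residual", "SS"] == pytest.approx(ss_r, rel=1e-9)
    # SS decomposition: components add up to the total
    assert table["SS"].sum() == pytest.approx(ss_t, rel=1e-9)
    # MS = SS / df throughout
    assert np.allclose(table["MS"], table["SS"] / table["df"])


def test_anova_drought_f_equals_squared_t():
    """Balanced 2 x 2: the 1-df drought F equals the squared two-sample t
    computed with the ANOVA's residual mean square."""
    rng = np.random.default_rng(11)
    df = _drought_phys(
        {
            ("ambient", "control"): list(0.4 + 0.03 * rng.standard_normal(6)),
            ("ambient", "drought"): list(0.5 + 0.03 * rng.standard_normal(6)),
            ("future", "control"): list(0.4 + 0.03 * rng.standard_normal(6)),
            ("future", "drought"): list(0.5 + 0.03 * rng.standard_normal(6)),
        }
    )
    table = anova_drought(df, "July", "CUE").set_index("term")
    ms_res = table.loc["Residual", "MS"]
    sheltered = df.loc[df["drought"], "CUE"]
    control = df.loc[~df["drought"], "CUE"]
    t = (sheltered.mean() - control.mean()) / np.sqrt(
        ms_res * (1 / len(sheltered) + 1 / len(control))
    )
    assert table.loc["drought", "F"] == pytest.approx(t**2, rel=1e-9)


def test_anova_empty_cell_errors():
    df = _drought_phys(
        {("ambient", "control"): [0.4, 0.41], ("future", "drought"): [0.5, 0.52],
         ("future", "control"): [0.45, 0.44]}
    )
    with pytest.raises(ValueError, match="empty cells"):
        anova_drought(df, "July", "CUE")


def test_tukey_two_groups_equals_t_test():
    """k = 2: the studentized range reduces to |t| sqrt(2), so the adjusted
    p equals the unadjusted pooled two-sample p."""
    rng = np.random.default_rng(5)
    df = _drought_phys(
        {
            ("ambient", "control"): list(0.40 + 0.05 * rng.standard_normal(8)),
            ("ambient", "drought"): list(0.47 + 0.05 * rng.standard_normal(8)),
        }
    )
    hsd = tukey_hsd(df, "July", "CUE")
    assert len(hsd) == 1
    t_res = sps.ttest_ind(
        df.loc[~df["drought"], "CUE"], df.loc[df["drought"], "CUE"]
    )
    assert hsd["q"].iloc[0] == pytest.approx(abs(t_res.statistic) * np.sqrt(2), rel=1e-9)
    assert hsd["p_adj"].iloc[0] == pytest.approx(t_res.pvalue, rel=1e-6)


def test_tukey_null_case_one_letter():
    df = _drought_phys(
        {
            ("ambient", "control"): [0.40, 0.41, 0.40, 0.39],
            ("ambient", "drought"): [0.40, 0.41, 0.39, 0.40],
            ("future", "control"): [0.41, 0.40, 0.40, 0.39],
            ("future", "drought"): [0.40, 0.39, 0.41, 0.40],
        }
    )
    hsd = tukey_hsd(df, "July", "CUE")
    assert not hsd["significant"].any()
    assert set(hsd.attrs["letters"].values()) == {"a"}


def test_tukey_shifted_group_gets_unique_letter():
    rng = np.random.default_rng(9)
    base = lambda: list(0.40 + 0.01 * rng.standard_normal(6))  # noqa: E731
    df = _drought_phys(
        {
            ("ambient", "control"): base(),
            ("ambient", "drought"): base(),
            ("future", "control"): base(),
            ("future", "drought"): list(0.70 + 0.01 * rng.standard_normal(6)),
        }
    )
    hsd = tukey_hsd(df, "July", "CUE")
    letters = hsd.attrs["letters"]
    shifted = letters["future:drought"]
    others = {letters[g] for g in letters if g != "future:drought"}
    assert len(shifted) == 1 and shifted not in "".join(others)
    assert len(others) == 1


def test_tukey_adjusted_p_not_below_unadjusted(noisy_physiology):
    """For k = 4 groups the Tukey-adjusted p is >= the unadjusted pairwise
    t-test p (computed with the same pooled MS and df)."""
    hsd = tukey_hsd(noisy_physiology, "July", "G_m")
    df_err = hsd.attrs["df_error"]
    for _, row in hsd.iterrows():
        p_unadj = 2 * sps.t.sf(row["q"] / np.sqrt(2), df_err)
        assert row["p_adj"] >= p_unadj - 1e-12


def test_tukey_matches_statsmodels_cross_check():
    """Balanced example against statsmodels' Tukey HSD implementation."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(17)
    cells = {
        ("ambient", "control"): list(0.40 + 0.05 * rng.standard_normal(5)),
        ("ambient", "drought"): list(0.48 + 0.05 * rng.standard_normal(5)),
        ("future", "control"): list(0.42 + 0.05 * rng.standard_normal(5)),
        ("future", "drought"): list(0.60 + 0.05 * rng.standard_normal(5)),
    }
    df = _drought_phys(cells)
    hsd = tukey_hsd(df, "July", "CUE")
    groups = [
        f"{'future' if w == 3.0 else 'ambient'}:{'drought' if d else 'control'}"
        for w, d in zip(df["warming_delta_C"], df["drought"])
    ]
    sm_res = pairwise_tukeyhsd(df["CUE"].to_numpy(), groups)
    sm_table = pd.DataFrame(
        sm_res._results_table.data[1:], columns=sm_res._results_table.data[0]
    )
    ours = hsd.set_index(hsd["group1"] + "|" + hsd["group2"])
    for _, row in sm_table.iterrows():
        key = f"{row['group1']}|{row['group2']}"
        # statsmodels' summary table rounds to 4 decimals
        assert ours.loc[key, "p_adj"] == pytest.approx(float(row["p-adj"]), abs=2e-3)
        assert -ours.loc[key, "diff"] == pytest.approx(float(row["meandiff"]), abs=1e-3)


def test_summarize_cue_single_row_and_grand_stats(noisy_physiology):
    single = pd.DataFrame({"CUE": [0.5], "date": ["May"]})
    s = summarize_cue(single)
    assert s["grand_mean"] == s["min"] == s["max"] == 0.5

    full = summarize_cue(noisy_physiology)
    assert 0 < full["min"] <= full["grand_mean"] <= full["max"] < 1
    assert full["n"] == 102
    assert {"treatment_mean_min", "treatment_mean_max"} <= set(full)

    with pytest.raises(ValueError, match="no valid CUE"):
        summarize_cue(pd.DataFrame({"CUE": [np.nan], "date": ["May"]}))
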