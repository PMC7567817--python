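"""Statistical analyses of the physiology table.

Three analyses mirror the study design:

* **Per-date response surfaces** (:func:`fit_surface_model`): ordinary
  least squares of log G_m, log R_m or raw CUE on the full second-order
  polynomial in the coded factors eT and eCO2, with backward elimination of
  non-significant higher-order terms under the marginality principle
  (:func:`reduce_by_marginality`) — linear main effects are never dropped.

* **Seasonal model** (:func:`fit_seasonal_gls`): feasible generalised
  least squares across all three dates with a separate residual variance
  per date and an optional within-plot correlation structure (compound
  symmetry or AR(1) over the date order); candidate structures are
  compared by Gaussian AIC and each fixed-effect term gets a Wald F test.

* **Drought factorial** (:func:`anova_drought`): two-way ANOVA
  (climate x drought, Type-I sums of squares in that order) on the 2 x 2
  corner-cell subset, with Tukey's HSD as post-hoc test
  (:func:`tukey_hsd`) including a compact letter display.

Responses: biomass-specific rates are natural-log transformed before
fitting (they are positive and right-skewed); CUE is analysed on its
original scale.  Rows carrying QC flags that invalidate the response are
excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SURFACE_TERMS",
    "SurfaceFit",
    "SeasonalGlsFit",
    "GlsConvergenceError",
    "fit_surface_model",
    "reduce_by_marginality",
    "fit_seasonal_gls",
    "anova_drought",
    "tukey_hsd",
    "summarize_cue",
]

SURFACE_TERMS = ("intercept", "eCO2", "eT", "eCO2:eT", "eCO2^2", "eT^2")
#: Terms that backward elimination may drop (order-2); main effects stay.
_REDUCIBLE = ("eCO2:eT", "eCO2^2", "eT^2")
#: Responses fitted on the natural-log scale.
LOG_RESPONSES = ("G_m", "R_m", "G", "R")


class GlsConvergenceError(RuntimeError):
    """Feasible-GLS iteration failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


def _term_column(term: str, et: np.ndarray, eco2: np.ndarray) -> np.ndarray:
    return {
        "intercept": np.ones_like(et),
        "eCO2": eco2,
        "eT": et,
        "eCO2:eT": eco2 * et,
        "eCO2^2": eco2**2,
        "eT^2": et**2,
    }[term]


def _prepare_response(df: pd.DataFrame, response: str) -> pd.DataFrame:
    """Drop QC-flagged / non-finite rows and log-transform if applicable."""
    out = df.copy()
    y = out[response].astype(float)
    ok = np.isfinite(y)
    if response in LOG_RESPONSES:
        ok &= y > 0
    out = out.loc[ok].copy()
    out["_y"] = (
        np.log(out[response].astype(float))
        if response in LOG_RESPONSES
        else out[response].astype(float)
    )
    return out


@dataclass
class SurfaceFit:
    """A fitted response surface: coefficient table plus fit diagnostics."""

    response: str
    date: str
    terms: tuple[str, ...]
    table: pd.DataFrame  # columns: term, estimate, se, t, p
    r2: float
    f_overall: float
    f_p: float
    n: int
    df_resid: int
    data: pd.DataFrame = field(repr=False)

    def params(self) -> pd.Series:
        return self.table.set_index("term")["estimate"]


def fit_surface_model(
    physiology: pd.DataFrame,
    response: str,
    date: str,
    terms: tuple[str, ...] = SURFACE_TERMS,
) -> SurfaceFit:
    """OLS second-order response surface for one date.

    ``physiology`` must carry coded ``eT``/``eCO2`` columns (see
    :func:`soilcue.io.attach_design`).  G_m/R_m are fitted on the natural
    log scale, CUE untransformed.
    """
    sub = _prepare_response(physiology.loc[physiology["date"] == date], response)
    et = sub["eT"].to_numpy(dtype=float)
    eco2 = sub["eCO2"].to_numpy(dtype=float)
    x = np.column_stack([_term_column(t, et, eco2) for t in terms])
    y = sub["_y"].to_numpy()
    n, p = x.shape
    if n < p + 1:
        raise ValueError(f"{n} rows after QC filtering; need at least {p + 1}")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("rank-deficient design for the requested terms")

    import statsmodels.api as sm

    res = sm.OLS(y, x).fit()
    table = pd.DataFrame(
        {
            "term": terms,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return SurfaceFit(
        response=response,
        date=date,
        terms=tuple(terms),
        table=table,
        r2=float(res.rsquared),
        f_overall=float(res.fvalue),
        f_p=float(res.f_pvalue),
        n=n,
        df_resid=int(res.df_resid),
        data=sub,
    )


def reduce_by_marginality(
    fit: SurfaceFit, alpha: float = 0.05
) -> tuple[SurfaceFit, list[dict]]:
    """Backward elimination respecting marginality.

    Only the interaction and the two quadratic terms are candidates; the
    linear main effects (and the intercept) are kept regardless of their
    p-values.  At each step the candidate with the largest p-value above
    ``alpha`` is dropped and the model refitted.  Ties are broken by
    dropping the interaction first, then alphabetically.  Returns the
    final fit and an elimination log (term, p, step).
    """
    current = fit
    log: list[dict] = []
    priority = {t: i for i, t in enumerate(_REDUCIBLE)}
    step = 0
    while True:
        tab = current.table.set_index("term")
        candidates = [t for t in _REDUCIBLE if t in current.terms]
        droppable = [(t, float(tab.loc[t, "p"])) for t in candidates if tab.loc[t, "p"] > alpha]
        if not droppable:
            return current, log
        droppable.sort(key=lambda tp: (-tp[1], priority[tp[0]]))
        worst, worst_p = droppable[0]
        step += 1
        log.append({"step": step, "dropped": worst, "p": worst_p})
        new_terms = tuple(t for t in current.terms if t != worst)
        current = fit_surface_model(current.data, current.response, current.date, new_terms)


# ---------------------------------------------------------------------------
# Seasonal heteroscedastic GLS
# ---------------------------------------------------------------------------

#: Fixed-effect term groups of the seasonal model, in testing order.
SEASONAL_TERMS = (
    "date",
    "eCO2",
    "eT",
    "eCO2^2",
    "date:eCO2",
    "date:eT",
    "eCO2:eT",
    "date:eCO2:eT",
)


@dataclass
class SeasonalGlsFit:
    response: str
    structure: str  # none | CS | AR1
    coefficients: pd.Series
    cov_params: pd.DataFrame
    anova: pd.DataFrame  # term, df, F, p
    sigma_by_date: dict
    rho: float
    loglik: float
    aic: float
    n: int
    n_iter: int
    converged: bool
    candidates: pd.DataFrame  # structure, aic, loglik, rho


def _seasonal_design(sub: pd.DataFrame, dates: list[str]):
    """Design matrix with date dummies (first date is the reference level)."""
    et = sub["eT"].to_numpy(dtype=float)
    eco2 = sub["eCO2"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    groups: dict[str, list[int]] = {t: [] for t in SEASONAL_TERMS}
    dummies = {d: (sub["date"] == d).to_numpy(dtype=float) for d in dates[1:]}

    def add(name: str, col: np.ndarray, group: str) -> None:
        groups[group].append(len(names))
        names.append(name)
        cols.append(col)

    for d in dates[1:]:
        add(f"date[{d}]", dummies[d], "date")
    add("eCO2", eco2, "eCO2")
    add("eT", et, "eT")
    add("eCO2^2", eco2**2, "eCO2^2")
    for d in dates[1:]:
        add(f"date[{d}]:eCO2", dummies[d] * eco2, "date:eCO2")
    for d in dates[1:]:
        add(f"date[{d}]:eT", dummies[d] * et, "date:eT")
    add("eCO2:eT", eco2 * et, "eCO2:eT")
    for d in dates[1:]:
        add(f"date[{d}]:eCO2:eT", dummies[d] * eco2 * et, "date:eCO2:eT")
    return np.column_stack(cols), names, groups


def _correlation_matrix(structure: str, rho: float, m: int) -> np.ndarray:
    idx = np.arange(m)
    if structure == "CS":
        r = np.full((m, m), rho)
        np.fill_diagonal(r, 1.0)
        return r
    if structure == "AR1":
        return rho ** np.abs(idx[:, None] - idx[None, :])
    return np.eye(m)


def _fit_one_structure(
    y: np.ndarray,
    x: np.ndarray,
    date_codes: np.ndarray,
    plot_slices: list[slice],
    structure: str,
    n_dates: int,
    tol: float = 1e-8,
    max_iter: int = 100,
    equal_variances: bool = False,
):
    """Iterative feasible GLS for one correlation structure.

    Rows must be sorted by (plot, date-order) with complete blocks.
    Returns (beta, cov_beta, sigma2 per date, rho, loglik, n_iter,
    converged, trace).
    """
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    sigma2 = np.ones(n_dates)
    rho = 0.0
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - x @ beta
        if equal_variances:
            new_sigma2 = np.full(n_dates, np.mean(resid**2))
        else:
            new_sigma2 = np.array(
                [np.mean(resid[date_codes == d] ** 2) for d in range(n_dates)]
            )
        u = resid / np.sqrt(new_sigma2[date_codes])
        if structure == "none":
            new_rho = 0.0
        else:
            num = 0.0
            den = 0
            for sl in plot_slices:
                ub = u[sl]
                m = len(ub)
                if structure == "CS":
                    for i in range(m):
                        for j in range(i + 1, m):
                            num += ub[i] * ub[j]
                            den += 1
                else:  # AR1: lag-1 products
                    num += float(np.sum(ub[:-1] * ub[1:]))
                    den += m - 1
            new_rho = num / den if den else 0.0
            lo = -0.95 if structure == "AR1" else max(-1.0 / (3 - 1) + 0.05, -0.45)
            new_rho = float(np.clip(new_rho, lo, 0.95))

        # Whiten per plot block and refit.
        xw = np.empty_like(x)
        yw = np.empty_like(y)
        chol_cache: dict[int, np.ndarray] = {}
        for sl in plot_slices:
            dc = date_codes[sl]
            key = hash(dc.tobytes())
            if key not in chol_cache:
                dvec = np.sqrt(new_sigma2[dc])
                cov = np.outer(dvec, dvec) * _correlation_matrix(
                    structure, new_rho, len(dc)
                )
                chol_cache[key] = np.linalg.inv(np.linalg.cholesky(cov))
            linv = chol_cache[key]
            xw[sl] = linv @ x[sl]
            yw[sl] = linv @ y[sl]
        new_beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)

        old = np.concatenate([beta, sigma2, [rho]])
        new = np.concatenate([new_beta, new_sigma2, [new_rho]])
        delta = np.max(np.abs(new - old) / (np.abs(old) + 1.0))
        trace.append({"iter": it, "delta": float(delta), "rho": new_rho})
        beta, sigma2, rho = new_beta, new_sigma2, new_rho
        if delta < tol:
            converged = True
            break
    if not converged:
        raise GlsConvergenceError(
            f"feasible GLS ({structure}) did not converge in {max_iter} iterations",
            trace,
        )

    # Final whitened quantities for covariance and likelihood.
    xw = np.empty_like(x)
    yw = np.empty_like(y)
    logdet = 0.0
    for sl in plot_slices:
        dc = date_codes[sl]
        dvec = np.sqrt(sigma2[dc])
        cov = np.outer(dvec, dvec) * _correlation_matrix(structure, rho, len(dc))
        chol = np.linalg.cholesky(cov)
        logdet += 2.0 * float(np.sum(np.log(np.diag(chol))))
        linv = np.linalg.inv(chol)
        xw[sl] = linv @ x[sl]
        yw[sl] = linv @ y[sl]
    cov_beta = np.linalg.inv(xw.T @ xw)
    rw = yw - xw @ beta
    loglik = -0.5 * (n * np.log(2 * np.pi) + logdet + float(rw @ rw))
    return beta, cov_beta, sigma2, rho, loglik, it, converged, trace


def fit_seasonal_gls(
    physiology: pd.DataFrame,
    response: str,
    structures: tuple[str, ...] = ("none", "CS", "AR1"),
    dates: tuple[str, ...] = ("May", "July", "October"),
    equal_variances: bool = False,
) -> SeasonalGlsFit:
    """Heteroscedastic feasible GLS across sampling dates.

    Model: response ~ date + eCO2 + eT + eCO2² + date:eCO2 + date:eT +
    eCO2:eT + date:eCO2:eT, with a separate residual variance per date and
    a within-plot correlation across dates under each candidate structure.
    Variances, the correlation parameter and the coefficients are updated
    alternately until the relative parameter change falls below 1e-8.  The
    structure with the lowest Gaussian AIC wins.  Each term group is
    tested with a Wald F statistic using residual denominator df (n − p).
    """
    sub = _prepare_response(physiology, response)
    sub = sub.loc[sub["date"].isin(dates)].copy()
    order = {d: i for i, d in enumerate(dates)}
    sub["_dorder"] = sub["date"].map(order)
    # keep only plots observed on every date so blocks are complete
    counts = sub.groupby("plot_id")["date"].nunique()
    full_plots = counts.index[counts == len(dates)]
    sub = sub.loc[sub["plot_id"].isin(full_plots)]
    sub = sub.sort_values(["plot_id", "_dorder"], ignore_index=True)
    if sub["plot_id"].nunique() < 2:
        raise ValueError("need at least two plots observed on all dates")

    x, names, groups = _seasonal_design(sub, list(dates))
    y = sub["_y"].to_numpy()
    date_codes = sub["_dorder"].to_numpy()
    n, p = x.shape

    plot_slices = []
    start = 0
    for _, grp in sub.groupby("plot_id", sort=True):
        plot_slices.append(slice(start, start + len(grp)))
        start += len(grp)

    results = {}
    rows = []
    for structure in structures:
        beta, cov_beta, sigma2, rho, loglik, n_iter, conv, _ = _fit_one_structure(
            y, x, date_codes, plot_slices, structure, len(dates),
            equal_variances=equal_variances,
        )
        k = p + len(dates) + (0 if structure == "none" else 1)
        aic = -2.0 * loglik + 2.0 * k
        results[structure] = (beta, cov_beta, sigma2, rho, loglik, aic, n_iter, conv)
        rows.append({"structure": structure, "aic": aic, "loglik": loglik, "rho": rho})
    candidates = pd.DataFrame(rows)
    best = candidates.loc[candidates["aic"].idxmin(), "structure"]
    beta, cov_beta, sigma2, rho, loglik, aic, n_iter, conv = results[best]

    anova_rows = []
    for term in SEASONAL_TERMS:
        idx = groups[term]
        q = len(idx)
        lb = beta[idx]
        lcov = cov_beta[np.ix_(idx, idx)]
        fstat = float(lb @ np.linalg.solve(lcov, lb)) / q
        pval = float(sps.f.sf(fstat, q, n - p))
        anova_rows.append({"term": term, "df": q, "F": fstat, "p": pval})

    return SeasonalGlsFit(
        response=response,
        structure=str(best),
        coefficients=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        anova=pd.DataFrame(anova_rows),
        sigma_by_date={d: float(np.sqrt(sigma2[order[d]])) for d in dates},
        rho=float(rho),
        loglik=float(loglik),
        aic=float(aic),
        n=n,
        n_iter=n_iter,
        converged=conv,
        candidates=candidates,
    )


# ---------------------------------------------------------------------------
# Drought factorial: two-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------


def _drought_frame(physiology: pd.DataFrame, date: str, response: str) -> pd.DataFrame:
    """Corner-cell subset with climate/drought factors and transformed y."""
    sub = _prepare_response(physiology.loc[physiology["date"] == date], response)
    ambient = (sub["warming_delta_C"] == 0.0) & (sub["co2_delta_ppm"] == 0.0)
    future = (sub["warming_delta_C"] == 3.0) & (sub["co2_delta_ppm"] == 300.0)
    sub = sub.loc[ambient | future].copy()
    sub["climate"] = np.where(sub["warming_delta_C"] == 3.0, "future", "ambient")
    sub["sheltered"] = np.where(sub["drought"], "drought", "control")
    return sub


def anova_drought(physiology: pd.DataFrame, date: str, response: str) -> pd.DataFrame:
    """Two-way ANOVA of the drought factorial for one date.

    Factors: climate (ambient vs future), drought (sheltered vs not) and
    their interaction, with Type-I sums of squares in that order.  Returns
    a table with term, df, SS, MS, F, p (Residual row included).
    """
    sub = _drought_frame(physiology, date, response)
    cells = sub.groupby(["climate", "sheltered"]).size()
    if len(cells) < 4:
        raise ValueError(f"empty cells in the 2x2 drought factorial: {dict(cells)}")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("_y ~ C(climate) * C(sheltered)", data=sub).fit()
    raw = anova_lm(model, typ=1)
    rename = {
        "C(climate)": "climate",
        "C(sheltered)": "drought",
        "C(climate):C(sheltered)": "climate:drought",
        "Residual": "Residual",
    }
    table = raw.rename(index=rename).reset_index(names="term")
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    table["MS"] = table["SS"] / table["df"]
    return table[["term", "df", "SS", "MS", "F", "p"]]


def tukey_hsd(
    physiology: pd.DataFrame,
    date: str,
    response: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD over the four climate x drought groups.

    Uses the studentized-range distribution with the residual mean square
    and df of the factorial ANOVA (Tukey-Kramer correction for unequal
    group sizes).  The returned frame has one row per pair (group1,
    group2, diff, q, p_adj, significant) and carries the compact letter
    display in ``.attrs['letters']`` (groups sharing a letter do not
    differ at ``alpha``; letters are assigned greedily from the largest
    mean).
    """
    sub = _drought_frame(physiology, date, response)
    sub["group"] = sub["climate"] + ":" + sub["sheltered"]
    stats = sub.groupby("group")["_y"].agg(["mean", "count"])
    if (stats["count"] < 2).any():
        small = stats.index[stats["count"] < 2].tolist()
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    k = len(stats)
    n = len(sub)
    resid = sub["_y"] - sub["group"].map(stats["mean"])
    df_err = n - k
    ms_err = float((resid**2).sum()) / df_err

    names = list(stats.index)
    rows = []
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = float(stats.loc[a, "mean"] - stats.loc[b, "mean"])
            se = np.sqrt(ms_err / 2.0 * (1.0 / stats.loc[a, "count"] + 1.0 / stats.loc[b, "count"]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_err))
            rows.append(
                {"group1": a, "group2": b, "diff": diff, "q": float(q),
                 "p_adj": p_adj, "significant": p_adj < alpha}
            )
            sig[frozenset((a, b))] = p_adj < alpha

    # Compact letter display by insert-and-absorb: start from one class of
    # all groups, split on each significant pair, drop classes that became
    # subsets of others.  Guarantees: share a letter <=> not significantly
    # different.  Letters are ordered from the class with the largest mean.
    classes: list[set[str]] = [set(names)]
    for pair, is_sig in sig.items():
        if not is_sig:
            continue
        a, b = tuple(pair)
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.extend([cls - {a}, cls - {b}])
            else:
                new_classes.append(cls)
        classes = [
            cls
            for cls in new_classes
            if not any(cls < other for other in new_classes)
        ]
        # drop exact duplicates, keeping first occurrence
        seen: list[set[str]] = []
        for cls in classes:
            if cls not in seen:
                seen.append(cls)
        classes = seen
    classes.sort(key=lambda cls: -max(stats.loc[g, "mean"] for g in cls))
    letters = {g: "" for g in names}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in sorted(cls):
            letters[g] += letter

    out = pd.DataFrame(rows)
    out.attrs["letters"] = letters
    out.attrs["ms_error"] = ms_err
    out.attrs["df_error"] = df_err
    out.attrs["means"] = stats["mean"].to_dict()
    return out


def summarize_cue(physiology: pd.DataFrame) -> dict:
    """CUE summary: grand mean, per-row range and per-treatment means.

    Only rows with a defined (QC-passing) CUE enter.  Per-treatment means
    are computed over warming x CO2 x date cells when the design columns
    are attached.
    """
    ok = physiology["CUE"].notna()
    if not ok.any():
        raise ValueError("no valid CUE rows")
    sub = physiology.loc[ok]
    summary = {
        "grand_mean": float(sub["CUE"].mean()),
        "min": float(sub["CUE"].min()),
        "max": float(sub["CUE"].max()),
        "n": int(ok.sum()),
    }
    if {"warming_delta_C", "co2_delta_ppm"} <= set(sub.columns):
        per = (
            sub.groupby(["warming_delta_C", "co2_delta_ppm", "date"])["CUE"]
            .mean()
            .reset_index(name="mean_cue")
        )
        summary["per_treatment"] = per
        summary["treatment_mean_min"] = float(per["mean_cue"].min())
        summary["treatment_mean_max"] = float(per["mean_cue"].max())
    return summary
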