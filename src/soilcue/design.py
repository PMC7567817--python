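"""Experimental layout of the multifactorial climate-manipulation grassland study.

The field experiment crosses three warming levels (ambient, +1.5 °C, +3 °C)
with three atmospheric CO2 levels (ambient, +150 ppm, +300 ppm) in a
surface-response design, and superimposes a summer drought (automated
rain-out shelters) on a subset of plots in the two "corner" cells: ambient
climate (0 °C, 0 ppm) and future climate (+3 °C, +300 ppm).

Two analysis subsets are derived from the analysed plots:

* the *surface-response subset* — all analysed plots that were never
  sheltered, used to fit second-order response surfaces per sampling date;
* the *drought factorial* — a 2 x 2 layout (ambient vs future climate,
  sheltered vs unsheltered) restricted to the two corner cells.

Tables are plain :class:`pandas.DataFrame` objects with a fixed schema
(:data:`DESIGN_COLUMNS`) so they can be written to / read from ``design.csv``
without any custom container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "WARMING_LEVELS",
    "CO2_LEVELS",
    "DROUGHT_CELLS",
    "SAMPLING_DATES",
    "DESIGN_COLUMNS",
    "TreatmentLevel",
    "DesignConfig",
    "DesignError",
    "build_design",
    "analysed_subset",
    "rsm_subset",
    "drought_subset",
    "coded_units",
]

#: Allowed warming offsets above ambient air temperature (deg C).
WARMING_LEVELS = (0.0, 1.5, 3.0)
#: Allowed CO2 offsets above ambient concentration (ppm).
CO2_LEVELS = (0.0, 150.0, 300.0)
#: Treatment cells in which rain-out shelters may be installed.
DROUGHT_CELLS = ((0.0, 0.0), (3.0, 300.0))
#: Sampling dates of the growing season, in temporal order.
SAMPLING_DATES = ("May", "July", "October")

DESIGN_COLUMNS = ["plot_id", "warming_delta_C", "co2_delta_ppm", "drought", "in_study"]


class DesignError(ValueError):
    """Raised for invalid design configurations or malformed design tables."""


@dataclass(frozen=True)
class TreatmentLevel:
    """A plot's treatment assignment.

    Parameters
    ----------
    warming_delta : float
        Warming offset in deg C above ambient; one of 0, 1.5, 3.
    co2_delta : float
        CO2 offset in ppm above ambient; one of 0, 150, 300.
    drought : bool
        Whether the plot is under a rain-out shelter.  Only permitted in the
        ambient (0, 0) and future-climate (3, 300) cells.
    """

    warming_delta: float
    co2_delta: float
    drought: bool = False

    def __post_init__(self) -> None:
        if self.warming_delta not in WARMING_LEVELS:
            raise DesignError(
                f"warming_delta must be one of {WARMING_LEVELS}, got {self.warming_delta}"
            )
        if self.co2_delta not in CO2_LEVELS:
            raise DesignError(
                f"co2_delta must be one of {CO2_LEVELS}, got {self.co2_delta}"
            )
        if self.drought and (self.warming_delta, self.co2_delta) not in DROUGHT_CELLS:
            raise DesignError(
                "drought plots are only allowed in cells "
                f"{DROUGHT_CELLS}, got ({self.warming_delta}, {self.co2_delta})"
            )

    @property
    def cell(self) -> tuple[float, float]:
        return (self.warming_delta, self.co2_delta)


# Default allocation of the 34 analysed plots over the 9 treatment cells.
# Every cell carries at least two surface-response replicates; the corner
# cells of the drought factorial carry six each so that, together with the
# 4 + 4 sheltered plots, the 2 x 2 drought layout has 20 plots.  The exact
# per-cell replicate numbers of the field site are not published in the
# article text, so this table is a documented, overridable assumption.
_DEFAULT_ANALYSED = {
    (0.0, 0.0): 6,
    (0.0, 150.0): 2,
    (0.0, 300.0): 2,
    (1.5, 0.0): 2,
    (1.5, 150.0): 2,
    (1.5, 300.0): 2,
    (3.0, 0.0): 2,
    (3.0, 150.0): 2,
    (3.0, 300.0): 6,
}

# Plots that exist in the field (54 in total) but were not sampled for this
# assay; the split over cells is arbitrary and not used by any analysis.
_DEFAULT_UNUSED = {
    (0.0, 0.0): 1,
    (0.0, 150.0): 3,
    (0.0, 300.0): 2,
    (1.5, 0.0): 3,
    (1.5, 150.0): 2,
    (1.5, 300.0): 3,
    (3.0, 0.0): 2,
    (3.0, 150.0): 3,
    (3.0, 300.0): 1,
}

_DEFAULT_DROUGHT = {(0.0, 0.0): 4, (3.0, 300.0): 4}


@dataclass
class DesignConfig:
    """Per-cell replicate counts for the plot layout.

    ``analysed`` counts unsheltered analysed plots per (warming, co2) cell,
    ``drought`` counts sheltered analysed plots (restricted to
    :data:`DROUGHT_CELLS`) and ``unused`` counts plots that exist in the
    field layout but are not part of the analysed subset.
    """

    analysed: dict[tuple[float, float], int] = field(
        default_factory=lambda: dict(_DEFAULT_ANALYSED)
    )
    drought: dict[tuple[float, float], int] = field(
        default_factory=lambda: dict(_DEFAULT_DROUGHT)
    )
    unused: dict[tuple[float, float], int] = field(
        default_factory=lambda: dict(_DEFAULT_UNUSED)
    )

    def validate(self) -> None:
        for table_name, table in (
            ("analysed", self.analysed),
            ("drought", self.drought),
            ("unused", self.unused),
        ):
            for cell, n in table.items():
                if cell[0] not in WARMING_LEVELS or cell[1] not in CO2_LEVELS:
                    raise DesignError(f"invalid treatment cell {cell} in '{table_name}'")
                if n < 0 or int(n) != n:
                    raise DesignError(
                        f"replicate count for cell {cell} in '{table_name}' must be a"
                        f" non-negative integer, got {n}"
                    )
        for cell, n in self.drought.items():
            if n > 0 and cell not in DROUGHT_CELLS:
                raise DesignError(
                    f"drought plots assigned to disallowed cell {cell}; "
                    f"allowed cells: {DROUGHT_CELLS}"
                )


def build_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Construct the validated plot table.

    The default configuration reproduces the study layout: 54 plots in
    total, 34 analysed, of which 8 are sheltered (drought) plots.

    Returns a DataFrame with columns :data:`DESIGN_COLUMNS`, one row per
    plot, sorted lexicographically by ``plot_id`` (ids are zero-padded so
    lexicographic equals numeric order).  Construction is deterministic.
    """
    config = config or DesignConfig()
    config.validate()

    rows = []
    counter = 0

    def add(cell: tuple[float, float], n: int, drought: bool, in_study: bool) -> None:
        nonlocal counter
        for _ in range(n):
            counter += 1
            rows.append(
                {
                    "plot_id": f"P{counter:03d}",
                    "warming_delta_C": cell[0],
                    "co2_delta_ppm": cell[1],
                    "drought": drought,
                    "in_study": in_study,
                }
            )

    cells = [(w, c) for w in WARMING_LEVELS for c in CO2_LEVELS]
    for cell in cells:
        add(cell, config.analysed.get(cell, 0), drought=False, in_study=True)
        add(cell, config.drought.get(cell, 0), drought=True, in_study=True)
        add(cell, config.unused.get(cell, 0), drought=False, in_study=False)

    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    if design["plot_id"].duplicated().any():
        raise DesignError("duplicate plot ids")  # pragma: no cover - ids generated
    return design.sort_values("plot_id", ignore_index=True)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a design table's schema and invariants; return it unchanged."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    if design["plot_id"].duplicated().any():
        dupes = design.loc[design["plot_id"].duplicated(), "plot_id"].tolist()
        raise DesignError(f"duplicate plot ids: {dupes}")
    for _, row in design.iterrows():
        TreatmentLevel(
            float(row["warming_delta_C"]), float(row["co2_delta_ppm"]), bool(row["drought"])
        )
    return design


def analysed_subset(design: pd.DataFrame) -> pd.DataFrame:
    """Plots included in the physiological assays (34 with defaults)."""
    return design.loc[design["in_study"]].reset_index(drop=True)


def rsm_subset(design: pd.DataFrame) -> pd.DataFrame:
    """Analysed, never-sheltered plots used for the per-date response
    surfaces (26 with defaults)."""
    keep = design["in_study"] & ~design["drought"]
    return design.loc[keep].reset_index(drop=True)


def drought_subset(design: pd.DataFrame) -> pd.DataFrame:
    """Plots of the 2 x 2 drought factorial: analysed plots in the ambient
    and future-climate corner cells, sheltered or not (20 with defaults)."""
    cells = design[["warming_delta_C", "co2_delta_ppm"]].apply(tuple, axis=1)
    keep = design["in_study"] & cells.isin(set(DROUGHT_CELLS))
    return design.loc[keep].reset_index(drop=True)


def coded_units(design: pd.DataFrame) -> pd.DataFrame:
    """Append coded predictors eT, eCO2 in design units {-1, 0, +1}.

    eT = warming/1.5 - 1 and eCO2 = co2/150 - 1, so the centre of the
    design maps to the origin and the second-order surface coefficients are
    on a comparable scale for both factors.
    """
    out = design.copy()
    out["eT"] = out["warming_delta_C"] / 1.5 - 1.0
    out["eCO2"] = out["co2_delta_ppm"] / 150.0 - 1.0
    return out
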