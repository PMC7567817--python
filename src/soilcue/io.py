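"""Schema-validated CSV input/output for the pipeline.

All files are UTF-8, comma-separated, "." decimal, with an exact header
row.  Dates are the sampling labels May/July/October.  Missing values are
empty fields.  Unknown extra columns are accepted with a warning (forward
compatibility); missing or misspelled required columns are hard errors
naming the column and file.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import pandas as pd

from .design import DESIGN_COLUMNS, coded_units, validate_design
from .simulate import RawBundle

logger = logging.getLogger("soilcue")

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "load_raw_tables",
    "write_bundle",
    "read_design",
    "write_design",
    "attach_design",
    "write_physiology",
]

#: Required columns per raw table file.
SCHEMAS = {
    "irms.csv": [
        "plot_id", "date", "labeled", "dna_at_percent", "total_oxygen_ug_per_gdm",
    ],
    "dna.csv": ["plot_id", "date", "dna_ug_per_gdm"],
    "gc.csv": [
        "plot_id", "date", "headspace_ml", "sampled_ml", "co2_t0_ppm",
        "co2_repl_ppm", "co2_tend_ppm", "temp_c", "duration_h", "dry_mass_g",
    ],
    "cfe.csv": ["plot_id", "date", "eoc_fum", "eoc_unfum"],
    "gravimetry.csv": [
        "plot_id", "date", "fresh_soil_g", "gwc_g_per_g", "label_water_g",
        "label_atpct",
    ],
}

PHYSIOLOGY_COLUMNS = [
    "plot_id", "date", "DNA_p", "DNA_total", "MBC", "G", "R", "U", "CUE",
    "G_m", "R_m", "qc_flags",
]


class SchemaError(ValueError):
    """A raw table violates its schema (missing column, duplicate keys)."""


def _check_schema(df: pd.DataFrame, filename: str, path: Path) -> pd.DataFrame:
    required = SCHEMAS[filename]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)
    keys = ["plot_id", "date"] + (["labeled"] if "labeled" in required else [])
    dupes = df.loc[df.duplicated(keys), keys]
    if len(dupes):
        raise SchemaError(f"{path}: duplicate keys\n{dupes.head().to_string()}")
    return df[required]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_raw_tables(directory: str | Path) -> RawBundle:
    """Load and validate the five raw tables from ``directory``."""
    directory = Path(directory)
    tables = {}
    for filename in SCHEMAS:
        path = directory / filename
        if not path.exists():
            raise SchemaError(f"missing raw table: {path}")
        df = pd.read_csv(path)
        tables[filename.removesuffix(".csv")] = _check_schema(df, filename, path)
        logger.info("loaded %s: %d rows, sha256=%s", path, len(df), _sha256(path))
    return RawBundle(**tables)


def write_bundle(bundle: RawBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        getattr(bundle, name.removesuffix(".csv")).to_csv(directory / name, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return validate_design(design[DESIGN_COLUMNS])


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def attach_design(physiology: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Merge treatment columns (including coded eT/eCO2) onto physiology rows."""
    coded = coded_units(design)[
        ["plot_id", "warming_delta_C", "co2_delta_ppm", "drought", "in_study", "eT", "eCO2"]
    ]
    return physiology.merge(coded, on="plot_id", how="left", validate="many_to_one")


def write_physiology(physiology: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PHYSIOLOGY_COLUMNS if c in physiology.columns]
    physiology[cols].to_csv(path, index=False)


def read_physiology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHYSIOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df
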