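"""CSV readers/writers with schema validation, plus run reports.

All dialects are comma-separated UTF-8 with a mandatory header row and
'.' decimal separator.  Readers fail with messages naming the offending
column or row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .mechanics import ForceCurve, ModulusSample
from .spectra import ExtinctionTable, Spectrum

log = logging.getLogger("ferrohem")

#: Column schemas, by table kind.
SCHEMAS = {
    "spectrum": ["wavelength_nm", "optical_density"],
    "extinction": ["wavelength_nm", "eps_hbo2", "eps_hb", "eps_methb"],
    "methb_timeseries": ["time_min", "methb"],
    "kinetic_timeseries": ["time_min", "methb_um", "fe_um", "hbo2_um", "rate_um_per_min"],
    "force_curve": ["indentation_nm", "force_nN"],
    "modulus_sample": ["e_kpa"],
}

#: Table kinds whose first column must increase monotonically.
_MONOTONE = {"spectrum": "wavelength_nm", "extinction": "wavelength_nm"}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`ValidationError` naming the missing column or the
    first non-numeric cell.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema '{schema}'")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    for col in SCHEMAS[schema]:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column '{col}', row {bad[0] + 2}"
            )
        if numeric.isna().any():
            raise ValidationError(
                f"{path}: empty cell in column '{col}', row {int(numeric.index[numeric.isna()][0]) + 2}"
            )
        df[col] = numeric
    mono_col = _MONOTONE.get(schema)
    if mono_col is not None and not np.all(np.diff(df[mono_col].to_numpy()) > 0):
        raise ValidationError(f"{path}: column '{mono_col}' must be strictly increasing")
    return df[SCHEMAS[schema]]


def read_spectrum(path, path_length_cm: float = 1.0) -> Spectrum:
    df = read_table(path, "spectrum")
    return Spectrum(
        df["wavelength_nm"].to_numpy(), df["optical_density"].to_numpy(), path_length_cm
    )


def read_extinction(path) -> ExtinctionTable:
    return ExtinctionTable.from_frame(read_table(path, "extinction"))


def read_force_curve(path) -> ForceCurve:
    df = read_table(path, "force_curve")
    return ForceCurve(df["indentation_nm"].to_numpy(), df["force_nN"].to_numpy())


def read_modulus_sample(path, label: str = "") -> ModulusSample:
    df = read_table(path, "modulus_sample")
    return ModulusSample(df["e_kpa"].to_numpy(), label or Path(path).stem)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def write_report(results: dict, path, seed=None, config=None) -> None:
    """Write a human-readable run report.

    ``results`` maps section names to printable values (numbers, strings,
    or objects with a ``summary()`` method).  The report always records
    the package version and, when given, the seed and a config echo.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"ferrohem v{__version__}"]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if config is not None:
        lines.append(f"config: {config}")
    for name, value in results.items():
        if hasattr(value, "summary"):
            lines.append(f"[{name}]")
            lines.append(value.summary())
        else:
            lines.append(f"{name}: {value}")
    text = "\n".join(lines) + "\n"
    path.write_text(text, encoding="utf-8")
    log.info("wrote report to %s", path)
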