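"""Exposure-experiment degradability index δ.

A polymer film of weight ``W_film`` (mg), carbon mass fraction ``M_c`` (%),
and surface area ``S_film`` (cm²) is immersed in ``V_water`` (mL) of
artificial seawater; after exposure, the total organic carbon concentration
``TOC`` (mg/L) in the water measures how much of the film's carbon was
released.  The degradability index normalizes the released carbon mass by
the carbon content and surface area of the film:

    δ = (TOC · V_water/1000) / (W_film · M_c/100 · S_film)

The mL→L and %→fraction conversions are internal and fixed; they are the
unit convention that reproduces the published measurement tables.  TOC is
either measured directly or obtained from the total and inorganic carbon
readings as TOC = TC − IC; replicate TOC readings are averaged.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError


def toc(tc: float, ic: float) -> float:
    """Total organic carbon from total and inorganic carbon, mg/L."""
    if ic < 0 or tc < 0:
        raise ValidationError(f"TC and IC must be >= 0 (got TC={tc}, IC={ic})")
    if ic > tc:
        raise ValidationError(
            f"IC={ic} exceeds TC={tc}: negative organic carbon is impossible"
        )
    return tc - ic


def mean_toc(readings: Sequence[float]) -> float:
    """Average replicate TOC readings (instrument triplicates), mg/L."""
    readings = list(readings)
    if not readings:
        raise ValidationError("no TOC readings")
    if any(r < 0 for r in readings):
        raise ValidationError("TOC readings must be >= 0")
    return float(sum(readings)) / len(readings)


@dataclass(frozen=True)
class ExposureRecord:
    """One film-exposure measurement.

    Give either ``toc_mg_per_l`` directly or both ``tc`` and ``ic``.
    ``density_g_per_cm3`` is recorded metadata only (films are assumed unit
    density when surface area is derived from mass); it does not enter δ.
    """

    w_film_mg: float
    v_water_ml: float
    m_c_percent: float
    s_film_cm2: float
    toc_mg_per_l: float | None = None
    tc: float | None = None
    ic: float | None = None
    density_g_per_cm3: float = 1.0

    def resolved_toc(self) -> float:
        if self.toc_mg_per_l is not None:
            if self.toc_mg_per_l < 0:
                raise ValidationError(f"TOC must be >= 0, got {self.toc_mg_per_l}")
            return self.toc_mg_per_l
        if self.tc is None or self.ic is None:
            raise ValidationError("give either TOC or both TC and IC")
        return toc(self.tc, self.ic)


def compute_delta(
    w_film_mg: float,
    toc_mg_per_l: float,
    v_water_ml: float,
    m_c_percent: float,
    s_film_cm2: float,
) -> float:
    """δ from raw quantities; see the module docstring for the convention."""
    if toc_mg_per_l < 0 or v_water_ml < 0:
        raise ValidationError("TOC and V_water must be >= 0")
    for label, val in (
        ("W_film", w_film_mg),
        ("M_c", m_c_percent),
        ("S_film", s_film_cm2),
    ):
        if not val > 0:
            raise ValidationError(f"{label} must be > 0, got {val}")
    return (toc_mg_per_l * v_water_ml / 1000.0) / (
        w_film_mg * m_c_percent / 100.0 * s_film_cm2
    )


def delta(record: ExposureRecord) -> float:
    """δ of one exposure record."""
    return compute_delta(
        record.w_film_mg,
        record.resolved_toc(),
        record.v_water_ml,
        record.m_c_percent,
        record.s_film_cm2,
    )


_COLUMNS = {
    "w_film": "W_film",
    "toc": "TOC",
    "tc": "TC",
    "ic": "IC",
    "v_water": "V_water",
    "m_c": "M_c",
    "s_film": "S_film",
}


def deltas_from_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Compute δ for every row of a measurement table.

    Expects columns W_film, V_water, M_c, S_film and either TOC or TC+IC
    (matching the exposure-table headers); returns the table with a
    ``delta`` column appended.
    """
    cols = set(frame.columns)
    needed = {"W_film", "V_water", "M_c", "S_film"}
    if not needed <= cols:
        raise ConfigurationError(f"missing columns: {sorted(needed - cols)}")
    if "TOC" not in cols and not {"TC", "IC"} <= cols:
        raise ConfigurationError("need a TOC column or both TC and IC columns")
    out = frame.copy()
    values = []
    for _, row in frame.iterrows():
        rec = ExposureRecord(
            w_film_mg=float(row["W_film"]),
            v_water_ml=float(row["V_water"]),
            m_c_percent=float(row["M_c"]),
            s_film_cm2=float(row["S_film"]),
            toc_mg_per_l=float(row["TOC"]) if "TOC" in cols else None,
            tc=float(row["TC"]) if "TC" in cols else None,
            ic=float(row["IC"]) if "IC" in cols else None,
        )
        values.append(delta(rec))
    out["delta"] = values
    return out
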