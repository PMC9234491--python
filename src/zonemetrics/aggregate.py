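"""Per-placenta aggregation and the analysis-ready table.

Section-level measurements are summed across the (typically four)
representative sections of each placenta to damp single-section noise;
extensive quantities (areas, border length) are summed, intensive ones
(tissue percentages, tortuosity) averaged.  Areas are additionally
min–max rescaled across placentas so downstream mixed models see
comparable scales.  Model fitting itself is out of scope here — the
output is the table those models consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import SectionMeasurements

__all__ = [
    "PlacentaMeta",
    "PlacentaSummary",
    "sum_sections",
    "rescale_minmax",
    "build_analysis_table",
    "EXPECTED_SECTIONS",
    "RESCALE_COLUMNS",
]

#: Number of representative sections expected per placenta.
EXPECTED_SECTIONS = 4

#: Area-like columns rescaled by default in the analysis table.
RESCALE_COLUMNS = ("total_area", "lz_area", "jz_area", "decidua_area",
                   "border_length")


@dataclass
class PlacentaMeta:
    placenta_id: str
    dam_id: str = ""
    treatment: str = ""
    fetal_sex: str = "unknown"  # F, M or unknown
    fetal_mass: float | None = None  # grams; developmental-stage proxy


@dataclass
class PlacentaSummary:
    placenta_id: str
    dam_id: str
    treatment: str
    fetal_sex: str
    fetal_mass: float | None
    total_area: float
    lz_area: float
    jz_area: float
    decidua_area: float
    border_length: float
    excluded_area: float
    lz_tissue_pct: float
    jz_tissue_pct: float
    decidua_tissue_pct: float
    tortuosity: float
    n_sections: int
    section_ids: list = field(default_factory=list)


_REQUIRED = ("total_area", "lz_area", "jz_area", "decidua_area",
             "border_length", "excluded_area", "lz_tissue_pct",
             "jz_tissue_pct", "decidua_tissue_pct", "tortuosity")


def sum_sections(
    records: list[SectionMeasurements], meta: PlacentaMeta
) -> PlacentaSummary:
    """Collapse one placenta's section records into a summary row.

    Areas and border length are summed exactly; tissue percentages and
    tortuosity are averaged with equal weights.  A warning is issued
    when the number of sections differs from the expected four.
    """
    if not records:
        raise ValueError("need at least one section record")
    for rec in records:
        for name in _REQUIRED:
            value = getattr(rec, name, None)
            if value is None:
                raise ValueError(
                    f"section {rec.image_id!r} is missing field {name!r}")
    ids = {rec.provenance.get("placenta_id", meta.placenta_id)
           for rec in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple placenta ids: {sorted(ids)}")
    n = len(records)
    if n != EXPECTED_SECTIONS:
        warnings.warn(
            f"placenta {meta.placenta_id}: expected {EXPECTED_SECTIONS} "
            f"sections, got {n}",
            stacklevel=2,
        )

    def total(name):  # fsum: exact, hence permutation-invariant
        return math.fsum(getattr(r, name) for r in records)

    def mean(name):
        return math.fsum(getattr(r, name) for r in records) / n

    return PlacentaSummary(
        placenta_id=meta.placenta_id,
        dam_id=meta.dam_id,
        treatment=meta.treatment,
        fetal_sex=meta.fetal_sex,
        fetal_mass=meta.fetal_mass,
        total_area=total("total_area"),
        lz_area=total("lz_area"),
        jz_area=total("jz_area"),
        decidua_area=total("decidua_area"),
        border_length=total("border_length"),
        excluded_area=total("excluded_area"),
        lz_tissue_pct=mean("lz_tissue_pct"),
        jz_tissue_pct=mean("jz_tissue_pct"),
        decidua_tissue_pct=mean("decidua_tissue_pct"),
        tortuosity=mean("tortuosity"),
        n_sections=n,
        section_ids=[r.image_id for r in records],
    )


def rescale_minmax(values) -> np.ndarray:
    """(x − min) / (max − min), mapping the range onto [0, 1].

    A constant vector maps every element to 0.5 (warning); non-finite
    entries are an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries cannot be rescaled")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant vector: rescaled to all 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


#: Fixed column order of the analysis table.
TABLE_COLUMNS = [
    "placenta_id", "dam_id", "treatment", "fetal_sex", "fetal_mass",
    "n_sections", "total_area", "lz_area", "jz_area", "decidua_area",
    "border_length", "excluded_area", "lz_tissue_pct", "jz_tissue_pct",
    "decidua_tissue_pct", "tortuosity",
]


def build_analysis_table(
    summaries: list[PlacentaSummary],
    rescale_cols: tuple = RESCALE_COLUMNS,
) -> pd.DataFrame:
    """One row per placenta, raw plus ``<col>_rescaled`` columns.

    Missing fetal mass is kept as NaN (explicit missing marker).
    Column order is fixed and deterministic; duplicate placenta ids are
    an error.
    """
    if not summaries:
        raise ValueError("need at least one placenta summary")
    ids = [s.placenta_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate placenta ids: {dupes}")
    rows = []
    for s in summaries:
        rows.append({
            "placenta_id": s.placenta_id,
            "dam_id": s.dam_id,
            "treatment": s.treatment,
            "fetal_sex": s.fetal_sex,
            "fetal_mass": (math.nan if s.fetal_mass is None else s.fetal_mass),
            "n_sections": s.n_sections,
            "total_area": s.total_area,
            "lz_area": s.lz_area,
            "jz_area": s.jz_area,
            "decidua_area": s.decidua_area,
            "border_length": s.border_length,
            "excluded_area": s.excluded_area,
            "lz_tissue_pct": s.lz_tissue_pct,
            "jz_tissue_pct": s.jz_tissue_pct,
            "decidua_tissue_pct": s.decidua_tissue_pct,
            "tortuosity": s.tortuosity,
        })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    for col in rescale_cols:
        if col not in df.columns:
            raise KeyError(f"unknown rescale column {col!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df[f"{col}_rescaled"] = rescale_minmax(df[col].to_numpy())
    return df
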