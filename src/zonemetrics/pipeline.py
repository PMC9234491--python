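"""Batch orchestration: many sections, many placentas, one table.

The study design this serves: four randomly chosen sections per
placenta are measured independently, then aggregated per placenta.
Failures are per-section — one corrupt image does not abort the run,
it is reported and the exit status reflects it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aggregate import PlacentaMeta, build_analysis_table, sum_sections
from .config import RunConfig, SessionSpec
from .io import (
    load_image,
    measurements_to_row,
    save_mask_png,
    write_section_csv,
)
from .morphometry import measure_section
from .segmentation import ZONES

__all__ = ["SectionJob", "PipelineResult", "run_pipeline"]

log = logging.getLogger("zonemetrics")


@dataclass
class SectionJob:
    """One section to process: an image plus its session file."""

    image: str
    session: str
    placenta_id: str = ""
    dam_id: str = ""
    treatment: str = ""
    fetal_sex: str = "unknown"
    fetal_mass: float | None = None


@dataclass
class PipelineResult:
    section_rows: list = field(default_factory=list)
    summaries: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # (image, message)
    table: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def run_pipeline(
    jobs: list[SectionJob],
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Measure every section, aggregate per placenta, write CSVs.

    Writes ``sections.csv`` (one row per section, with config/session
    hashes and collected warnings) and, when placenta ids are present,
    ``placentas.csv`` via the aggregation module.  Rerunning with
    identical inputs and config reproduces the outputs byte for byte.
    """
    cfg = config if config is not None else RunConfig()
    out = Path(output_dir) if output_dir is not None else Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = PipelineResult()
    per_placenta: dict[str, list] = {}
    meta_by_placenta: dict[str, PlacentaMeta] = {}

    for job in jobs:
        try:
            image = load_image(job.image, pixel_size=cfg.pixel_size)
            session = SessionSpec.load(job.session)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                if cfg.save_masks:
                    meas, ctx = measure_section(image, session, cfg,
                                                return_context=True)
                    for zone in ZONES:
                        save_mask_png(
                            ctx.zone_masks[zone] & ~ctx.exclusion,
                            out / f"{image.id}_{zone}_mask.png")
                    save_mask_png(~ctx.background,
                                  out / f"{image.id}_tissue_mask.png")
                else:
                    meas = measure_section(image, session, cfg)
            wtext = "; ".join(sorted({str(w.message) for w in caught}))
            log.info("measured %s (placenta %s)", image.id, job.placenta_id)
        except Exception as exc:
            log.error("section %s failed: %s", job.image, exc)
            result.failures.append((job.image, str(exc)))
            continue
        result.section_rows.append(
            measurements_to_row(meas, placenta_id=job.placenta_id,
                                warnings_text=wtext))
        if job.placenta_id:
            per_placenta.setdefault(job.placenta_id, []).append(meas)
            meta_by_placenta.setdefault(job.placenta_id, PlacentaMeta(
                placenta_id=job.placenta_id, dam_id=job.dam_id,
                treatment=job.treatment, fetal_sex=job.fetal_sex,
                fetal_mass=job.fetal_mass))

    write_section_csv(result.section_rows, out / "sections.csv")

    if per_placenta:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for pid in per_placenta:
                result.summaries.append(
                    sum_sections(per_placenta[pid], meta_by_placenta[pid]))
            result.table = build_analysis_table(result.summaries)
        for w in caught:
            log.warning("%s", w.message)
        result.table.to_csv(out / "placentas.csv", index=False)
    log.info("pipeline done: %d sections ok, %d failed (config %s, seed %d)",
             len(result.section_rows), len(result.failures),
             cfg.digest(), cfg.seed)
    return result
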