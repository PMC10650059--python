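"""Per-sample, per-compartment cell densities and cohort summaries.

Density is count of matching cells divided by compartment area (cells/mm²).
``total`` pools counts over pooled area — the only definition consistent
with cells/mm² semantics (never the mean of the two compartment densities).
Cohort statistics are medians across samples with (min–max) ranges; the
tumor-vs-stroma comparison uses the Kruskal–Wallis rank test on the
per-sample density vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cell_table import Cohort, SampleTable
from .hypothesis_tests import kruskal_wallis
from .phenotyping import PhenotypeCatalogue, PhenotypeDefinition, match_mask

COMPARTMENT_CHOICES = ("tumor", "stroma", "total")


class DensityError(ValueError):
    pass


def phenotype_count(sample: SampleTable, definition: PhenotypeDefinition,
                    compartment: str = "total") -> int:
    """Number of cells matching a phenotype in a compartment."""
    mask = match_mask(sample.cells, definition)
    if compartment == "total":
        return int(mask.sum())
    if compartment not in COMPARTMENT_CHOICES:
        raise DensityError(f"unknown compartment {compartment!r}")
    in_comp = sample.cells["compartment"].to_numpy() == compartment
    return int((mask & in_comp).sum())


def density(sample: SampleTable, phenotype: str,
            compartment: str, catalogue: PhenotypeCatalogue) -> float:
    """Cells/mm² of one phenotype in ``tumor``/``stroma``/``total``."""
    if compartment not in COMPARTMENT_CHOICES:
        raise DensityError(f"compartment must be one of {COMPARTMENT_CHOICES}")
    definition = catalogue[phenotype]
    area = sample.area_mm2(compartment)
    if not area > 0:
        raise DensityError(f"sample {sample.sample_id}: zero {compartment} area")
    return phenotype_count(sample, definition, compartment) / area


@dataclass
class DensitySummary:
    """Cohort summary for one phenotype (one published-table row)."""

    phenotype: str
    per_sample: pd.DataFrame  # index sample_id; columns total/tumor/stroma
    cohort_median: dict[str, float]
    cohort_range: dict[str, tuple[float, float]]
    tumor_vs_stroma_p: float


def sample_density_frame(cohort: Cohort,
                         catalogue: PhenotypeCatalogue) -> pd.DataFrame:
    """Long-format per-sample densities: one row per (sample, phenotype),
    columns total/tumor/stroma (cells/mm²)."""
    rows = []
    for sample in cohort:
        areas = {c: sample.area_mm2(c) for c in COMPARTMENT_CHOICES}
        in_tumor = sample.cells["compartment"].to_numpy() == "tumor"
        for d in catalogue:
            mask = match_mask(sample.cells, d)
            n_tumor = int((mask & in_tumor).sum())
            n_total = int(mask.sum())
            rows.append({
                "sample_id": sample.sample_id,
                "phenotype": d.name,
                "total": n_total / areas["total"],
                "tumor": n_tumor / areas["tumor"],
                "stroma": (n_total - n_tumor) / areas["stroma"],
            })
    return pd.DataFrame(rows)


def cohort_density_table(
    cohort: Cohort, catalogue: PhenotypeCatalogue
) -> list[DensitySummary]:
    """Median (range) densities per phenotype and compartment across the
    cohort, with a tumor-vs-stroma rank-test p per phenotype. Row order
    follows the catalogue."""
    if len(cohort) < 2:
        raise DensityError("cohort summaries require >= 2 samples")
    long = sample_density_frame(cohort, catalogue)
    out = []
    for d in catalogue:
        block = (long[long["phenotype"] == d.name]
                 .set_index("sample_id")[["total", "tumor", "stroma"]])
        med = {c: float(block[c].median()) for c in block.columns}
        rng = {c: (float(block[c].min()), float(block[c].max()))
               for c in block.columns}
        p = kruskal_wallis(block["tumor"].to_numpy(),
                           block["stroma"].to_numpy()).p
        out.append(DensitySummary(
            phenotype=d.name, per_sample=block,
            cohort_median=med, cohort_range=rng, tumor_vs_stroma_p=p))
    return out


def density_table_frame(summaries: list[DensitySummary]) -> pd.DataFrame:
    """Render cohort summaries as the published-table layout:
    ``median (min–max)`` strings per compartment plus the p column."""
    rows = []
    for s in summaries:
        row = {"phenotype": s.phenotype}
        for comp in ("total", "tumor", "stroma"):
            lo, hi = s.cohort_range[comp]
            row[comp] = f"{s.cohort_median[comp]:.2f} ({lo:.2f}–{hi:.2f})"
        row["tumor_vs_stroma_p"] = round(s.tumor_vs_stroma_p, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_of_total(numerator: float, denominator: float, *,
                      ndigits: Optional[int] = None,
                      truncate: bool = False) -> float:
    """Percentage ``100 * numerator / denominator`` with the reporting
    convention requested by the caller.

    ``ndigits=0`` rounds to an integer percent; ``truncate=True`` cuts (does
    not round) to ``ndigits`` decimals — both conventions occur in published
    composition statements.
    """
    if not denominator > 0:
        raise DensityError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    if ndigits is None:
        return pct
    if truncate:
        scale = 10 ** ndigits
        return math.trunc(pct * scale) / scale
    return round(pct, ndigits) if ndigits else float(round(pct))
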