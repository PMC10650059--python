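"""Nearest-neighbor distances from malignant cells to macrophage phenotypes.

For every CK+ reference cell the Euclidean distance (µm) to the closest cell
of a target phenotype is computed with a k-d tree; the per-sample statistic
is the median over reference cells, and the cohort statistic is the median
of per-sample medians (samples have very different cell counts, so pooling
cells would let large cores dominate). Distances are only ever computed
within a sample.

A sample where the target phenotype has no cells is *not computable*
(NaN sentinel, mirroring the "--" cells of published distance tables) and is
excluded listwise per phenotype. Self-matches are excluded by cell id, not
by nonzero distance — coincident centroids are legal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_table import Cohort, SampleTable
from .hypothesis_tests import kruskal_wallis
from .phenotyping import PhenotypeCatalogue, match_mask

logger = logging.getLogger(__name__)

#: sentinel for "target phenotype absent in this sample"
NOT_COMPUTABLE = float("nan")

LOW_OR_CLOSE = "low_or_close"
HIGH_OR_LONG = "high_or_long"


class SpatialError(ValueError):
    pass


def is_computable(value: float) -> bool:
    return value is not None and not math.isnan(value)


def nn_distances(
    reference_xy: np.ndarray,
    target_xy: np.ndarray,
    reference_ids: Optional[Sequence[str]] = None,
    target_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Per-reference-cell distance to the nearest *other* target cell (µm).

    Returns an array of length ``len(reference_xy)``; if the target set is
    empty every entry is the NOT_COMPUTABLE NaN sentinel. When ids are given,
    a cell present in both sets is matched to its nearest other target, not
    itself.
    """
    ref = np.asarray(reference_xy, dtype=float).reshape(-1, 2)
    tgt = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    if ref.shape[0] == 0:
        raise SpatialError("reference set must be non-empty")
    if tgt.shape[0] == 0:
        return np.full(ref.shape[0], NOT_COMPUTABLE)

    tree = cKDTree(tgt)
    if reference_ids is None or target_ids is None:
        d, _ = tree.query(ref, k=1)
        return np.asarray(d, dtype=float)

    reference_ids = np.asarray(reference_ids, dtype=object)
    target_ids = np.asarray(target_ids, dtype=object)
    shared = set(reference_ids) & set(target_ids)
    if not shared:
        d, _ = tree.query(ref, k=1)
        return np.asarray(d, dtype=float)

    k = min(2, tgt.shape[0])
    d, idx = tree.query(ref, k=k)
    d = np.atleast_2d(np.asarray(d, dtype=float).reshape(ref.shape[0], k))
    idx = np.atleast_2d(np.asarray(idx).reshape(ref.shape[0], k))
    out = np.empty(ref.shape[0], dtype=float)
    for i in range(ref.shape[0]):
        rid = reference_ids[i]
        picked = NOT_COMPUTABLE
        for j in range(k):
            if target_ids[idx[i, j]] != rid:
                picked = d[i, j]
                break
        out[i] = picked  # NaN iff the only target is the cell itself
    return out


def _phenotype_xy(sample: SampleTable, phenotype: str,
                  catalogue: PhenotypeCatalogue
                  ) -> tuple[np.ndarray, np.ndarray]:
    mask = match_mask(sample.cells, catalogue[phenotype])
    cells = sample.cells.loc[mask]
    return (cells[["x_um", "y_um"]].to_numpy(dtype=float),
            cells["cell_id"].astype(str).to_numpy())


def sample_median_nn(
    sample: SampleTable, target_phenotype: str,
    catalogue: PhenotypeCatalogue, reference_phenotype: str = "Total CK+",
) -> float:
    """Median over CK+ reference cells of the NN distance to the target
    phenotype; NOT_COMPUTABLE NaN if the target is absent."""
    ref_xy, ref_ids = _phenotype_xy(sample, reference_phenotype, catalogue)
    if ref_xy.shape[0] == 0:
        logger.warning("sample %s: no %s reference cells; excluded from "
                       "distance analysis", sample.sample_id,
                       reference_phenotype)
        return NOT_COMPUTABLE
    tgt_xy, tgt_ids = _phenotype_xy(sample, target_phenotype, catalogue)
    if tgt_xy.shape[0] == 0:
        return NOT_COMPUTABLE
    d = nn_distances(ref_xy, tgt_xy, ref_ids, tgt_ids)
    return float(np.nanmedian(d)) if np.any(np.isfinite(d)) else NOT_COMPUTABLE


@dataclass
class DistanceSummary:
    """Cohort distance summary for one phenotype."""

    phenotype: str
    per_sample_median_um: dict[str, float]  # NaN = not computable
    cohort_median_um: float
    subgroup_medians: dict[str, dict[str, float]]  # grouping -> level -> µm
    subgroup_p: dict[str, float]


def per_sample_distance_frame(
    cohort: Cohort, catalogue: PhenotypeCatalogue,
    phenotypes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample median NN distances, samples × phenotypes (µm, NaN where
    not computable). Default targets: the catalogue's macrophage
    phenotypes plus total CD68+."""
    if phenotypes is None:
        phenotypes = ["Total CD68+"] + [
            d.name for d in catalogue.macrophage_phenotypes]
    data = {
        name: {s.sample_id: sample_median_nn(s, name, catalogue)
               for s in cohort}
        for name in phenotypes
    }
    return pd.DataFrame(data)


def cohort_distance_table(
    cohort: Cohort, catalogue: PhenotypeCatalogue,
    groupings: Sequence[str] = ("histology", "asbestos"),
    phenotypes: Optional[Sequence[str]] = None,
) -> list[DistanceSummary]:
    """Cohort and clinical-subgroup median NN distances per phenotype.

    Cohort/subgroup values are medians of per-sample medians over samples
    where the distance is computable; subgroup p-values come from the
    Kruskal–Wallis rank test on per-sample medians.
    """
    if len(cohort) < 2:
        raise SpatialError("cohort summaries require >= 2 samples")
    frame = per_sample_distance_frame(cohort, catalogue, phenotypes)
    clin = pd.DataFrame({
        g: {s.sample_id: s.clinical.get(g) for s in cohort}
        for g in groupings})
    out = []
    for name in frame.columns:
        col = frame[name]
        computable = col.dropna()
        cohort_median = (float(computable.median()) if len(computable)
                         else NOT_COMPUTABLE)
        sub_medians: dict[str, dict[str, float]] = {}
        sub_p: dict[str, float] = {}
        for g in groupings:
            levels = clin[g].dropna().unique()
            sub_medians[g] = {}
            vectors = []
            for level in levels:
                vals = computable[clin.loc[computable.index, g] == level]
                sub_medians[g][str(level)] = (
                    float(vals.median()) if len(vals) else NOT_COMPUTABLE)
                if len(vals):
                    vectors.append(vals.to_numpy())
            enough = (len(vectors) >= 2
                      and sum(len(v) for v in vectors) >= 3)
            sub_p[g] = kruskal_wallis(*vectors).p if enough \
                else NOT_COMPUTABLE
        out.append(DistanceSummary(
            phenotype=name,
            per_sample_median_um=col.to_dict(),
            cohort_median_um=cohort_median,
            subgroup_medians=sub_medians,
            subgroup_p=sub_p))
    return out


def distance_table_frame(summaries: list[DistanceSummary]) -> pd.DataFrame:
    """Wide rendering of the distance summaries (published-table layout)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"phenotype": s.phenotype,
                                  "overall_um": s.cohort_median_um}
        for g, levels in s.subgroup_medians.items():
            for level, v in levels.items():
                row[f"{g}:{level}_um"] = v
            row[f"{g}_p"] = s.subgroup_p[g]
        rows.append(row)
    return pd.DataFrame(rows)


def dichotomize(values: Mapping[str, float]) -> dict[str, str]:
    """Median split: strictly above the median → ``high_or_long``, at or
    below → ``low_or_close``. Missing/not-computable samples are excluded.
    All-equal input puts everyone in the low/close group (ties go low)."""
    clean = {k: float(v) for k, v in values.items()
             if v is not None and np.isfinite(v)}
    if len(clean) < 2:
        raise SpatialError("dichotomize needs >= 2 non-missing values")
    med = float(np.median(list(clean.values())))
    return {k: (HIGH_OR_LONG if v > med else LOW_OR_CLOSE)
            for k, v in clean.items()}
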