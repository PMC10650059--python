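"""Expression-matrix computations for the exploratory arm: DEG threshold
screening, gene–gene Spearman co-expression, and third-quartile survival
splits.

Fold changes are log2 of group mean TPM with a pseudocount of 1 (avoids
log 0); a gene is called differentially expressed iff |log2FC| >= 1 (gate
inclusive) AND BH-adjusted p < 0.05 (gate strict). The quartile convention
is linear interpolation (type 7), and "high expression" means strictly
above Q3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypothesis_tests import CorrelationResult, bh_adjust, spearman
from .survival_stats import LogRankResult, SurvivalRecord, logrank


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of non-negative TPM values."""

    values: pd.DataFrame  # index = gene names, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ExpressionError("gene names must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("TPM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass(frozen=True)
class DEGCriteria:
    min_abs_log2fc: float = 1.0
    max_adj_p: float = 0.05

    def __post_init__(self) -> None:
        if not (self.min_abs_log2fc > 0 and self.max_adj_p > 0):
            raise ExpressionError("criteria must be positive")


def screen_degs(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    criteria: DEGCriteria = DEGCriteria(),
) -> pd.DataFrame:
    """Per-gene differential-expression screen between sample groups.

    log2FC compares the first two group levels' mean TPM (+1 pseudocount);
    the p-value is Welch-free two-sample t for two groups or one-way ANOVA
    for more, BH-adjusted across genes. A gene passes iff
    |log2FC| >= min_abs_log2fc and adj_p < max_adj_p.
    """
    labels = pd.Series(groups).astype(str)
    labels = labels.loc[[s for s in matrix.sample_ids if s in labels.index]]
    if set(labels.index) != set(matrix.sample_ids):
        raise ExpressionError("group labels must cover every sample")
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ExpressionError("need >= 2 groups")
    blocks = {lv: matrix.values.loc[:, labels.index[labels == lv]]
              for lv in levels}
    for lv, block in blocks.items():
        if block.shape[1] < 2:
            raise ExpressionError(f"group {lv!r} has < 2 samples")

    mean_a = blocks[levels[0]].mean(axis=1).to_numpy()
    mean_b = blocks[levels[1]].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)

    arrays = [blocks[lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        p = stats.ttest_ind(arrays[0], arrays[1], axis=1).pvalue
    else:
        p = stats.f_oneway(*arrays, axis=1).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    adj = bh_adjust(p)
    passed = (np.abs(log2fc) >= criteria.min_abs_log2fc) & \
        (adj < criteria.max_adj_p)
    return pd.DataFrame({
        "gene": matrix.genes,
        "log2fc": log2fc,
        "p": p,
        "adj_p": adj,
        "pass": passed,
    }).set_index("gene")


def coexpression_matrix(
    matrix: ExpressionMatrix, gene_set: Sequence[str],
) -> pd.DataFrame:
    """All pairwise Spearman correlations among ``gene_set`` (long format:
    gene_a, gene_b, rho, p, strength; symmetric with unit diagonal)."""
    missing = [g for g in gene_set if g not in matrix.genes]
    if missing:
        raise ExpressionError(f"genes not in matrix: {missing}")
    if matrix.values.shape[1] < 3:
        raise ExpressionError("need >= 3 samples")
    rows = []
    for a in gene_set:
        for b in gene_set:
            if a == b:
                res = CorrelationResult(rho=1.0, p=0.0,
                                        n=matrix.values.shape[1],
                                        strength="strong")
            else:
                res = spearman(matrix.values.loc[a].to_numpy(),
                               matrix.values.loc[b].to_numpy())
            rows.append({"gene_a": a, "gene_b": b, "rho": res.rho,
                         "p": res.p, "strength": res.strength})
    return pd.DataFrame(rows)


def quartile_split_survival(
    expression: Mapping[str, float] | pd.Series,
    survival: Sequence[SurvivalRecord],
) -> tuple[LogRankResult, dict[str, str]]:
    """Compare survival between samples with expression strictly above the
    third quartile ("high") and the rest ("low_medium")."""
    expr = pd.Series(expression).astype(float).dropna()
    if len(expr) < 4:
        raise ExpressionError("quartile split needs >= 4 samples")
    if expr.nunique() == 1:
        raise ExpressionError("constant expression: no split possible")
    q3 = float(np.quantile(expr.to_numpy(), 0.75))  # type-7 interpolation
    labels = {s: ("high" if v > q3 else "low_medium")
              for s, v in expr.items()}
    rec_by_id = {r.sample_id: r for r in survival}
    groups: dict[str, list[SurvivalRecord]] = {"high": [], "low_medium": []}
    for s, g in labels.items():
        if s in rec_by_id:
            groups[g].append(rec_by_id[s])
    if not groups["high"]:
        raise ExpressionError("no samples above Q3 (degenerate upper tail)")
    return logrank(groups), labels
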