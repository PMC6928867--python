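"""Region-specific expression filtering and two-group differential expression.

Three operations:

* a median-expression filter that keeps genes substantially expressed in one
  CNS region (>= 5 TPM by default) while essentially silent elsewhere
  (< 1 TPM in every other region);
* a low-expression check that classifies each cell of a matrix against a
  detection threshold (0.1 FPKM in cultured-cell expression resources);
* Welch's unequal-variance two-sided t-test per gene across two sample
  groups, Bonferroni-corrected, with the linear-scale fold ratio of group
  means.

Replicate columns of the same biological specimen can be collapsed by mean
before testing via a replicate map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_bonferroni
from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class RegionFilterConfig:
    """Thresholds for region-specific filtering (units follow the matrix).

    ``min_target`` is inclusive on the target region; ``max_other`` is an
    exclusive upper bound on every other region.
    """

    target_label: str
    min_target: float = 5.0
    max_other: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_target > self.max_other >= 0:
            raise ValueError(
                f"require min_target > max_other >= 0, got {self.min_target}, {self.max_other}")


def region_specific_filter(matrix: ExpressionMatrix, cfg: RegionFilterConfig) -> list[str]:
    """Genes with target-region value >= min_target and every other region < max_other.

    Returns genes in the matrix's row order.
    """
    labels = [c.label for c in matrix.columns]
    if cfg.target_label not in labels:
        raise ValueError(f"target column {cfg.target_label!r} not in matrix columns {labels}")
    others = [l for l in labels if l != cfg.target_label]
    if not others:
        raise ValueError("need at least one non-target column")
    df = matrix.values
    mask = (df[cfg.target_label] >= cfg.min_target) & (df[others] < cfg.max_other).all(axis=1)
    return [g for g in matrix.genes if mask[g]]


@dataclass(frozen=True)
class LowExpressionReport:
    """Per-cell classification against a detection threshold."""

    flags: pd.DataFrame  # values in {"below", "at", "above"}
    threshold: float
    tolerance: float
    fraction_at_or_below: float


def low_expression_check(matrix: ExpressionMatrix, threshold: float = 0.1,
                         tolerance: float = 1.0) -> LowExpressionReport:
    """Classify each cell as below/at/above a detection threshold.

    A cell is "at" the threshold when it lies in [threshold, (1+tolerance)*threshold],
    i.e. equal to or slightly above detection; the summary fraction counts
    cells at or below that band.
    """
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    vals = matrix.values
    upper = threshold * (1.0 + tolerance)
    flags = pd.DataFrame(
        np.where(vals < threshold, "below", np.where(vals <= upper, "at", "above")),
        index=vals.index, columns=vals.columns)
    frac = float((vals.to_numpy() <= upper).mean())
    return LowExpressionReport(flags=flags, threshold=threshold,
                               tolerance=tolerance, fraction_at_or_below=frac)


@dataclass(frozen=True)
class DEResult:
    """Per-gene Welch test outcome with linear-scale fold ratio group1/group2."""

    gene: str
    ratio: float  # inf when group2 mean is 0 and group1 mean > 0; nan when both 0
    t_stat: float
    df: float
    p_raw: float
    p_adj: float


def collapse_replicates(df: pd.DataFrame, replicate_map: Mapping[str, str]) -> pd.DataFrame:
    """Average replicate columns onto their biological specimen.

    ``replicate_map`` maps column label -> specimen id; unmapped columns keep
    their own label as specimen.
    """
    specimens = [replicate_map.get(c, c) for c in df.columns]
    return df.T.groupby(specimens, sort=False).mean().T


def welch_de(group1: pd.DataFrame, group2: pd.DataFrame,
             correction: Literal["bonferroni"] = "bonferroni") -> list[DEResult]:
    """Welch two-sided t-test per gene between two sample matrices.

    Both inputs are genes x samples with identical gene indexes and >= 2
    samples each.  Zero variance in both groups with equal means yields
    p = 1 by convention.  Bonferroni correction spans all genes tested.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    if group1.shape[1] < 2 or group2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if list(group1.index) != list(group2.index):
        raise ValueError("gene indexes of the two groups differ")

    x1 = group1.to_numpy(dtype=float)
    x2 = group2.to_numpy(dtype=float)
    res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float, copy=True)
    p = np.array(res.pvalue, dtype=float, copy=True)
    df = np.array(res.df, dtype=float, copy=True)

    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    # degenerate genes: no variance anywhere -> t undefined from scipy (nan)
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    df[degenerate] = float(group1.shape[1] + group2.shape[1] - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m2 > 0, m1 / np.where(m2 > 0, m2, 1.0),
                         np.where(m1 > 0, np.inf, np.nan))

    p_adj = adjust_bonferroni(np.clip(p, np.nextafter(0, 1), 1.0))
    return [
        DEResult(gene=g, ratio=float(r), t_stat=float(tt), df=float(dd),
                 p_raw=float(pp), p_adj=float(pa))
        for g, r, tt, dd, pp, pa in zip(group1.index, ratio, t, df, p, p_adj)
    ]


def split_groups(matrix: ExpressionMatrix, groups: Mapping[str, str],
                 group1: str, group2: str,
                 replicate_map: Mapping[str, str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a per-sample matrix into two group DataFrames by a column->group map."""
    df = matrix.values
    if replicate_map:
        df = collapse_replicates(df, replicate_map)
        groups = {replicate_map.get(c, c): g for c, g in groups.items()}
    cols1 = [c for c in df.columns if groups.get(c) == group1]
    cols2 = [c for c in df.columns if groups.get(c) == group2]
    if not cols1 or not cols2:
        raise ValueError(f"groups {group1!r}/{group2!r} not found among columns")
    return df[cols1], df[cols2]


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "ratio": r.ratio, "t": r.t_stat, "df": r.df,
        "p_raw": r.p_raw, "p_adj": r.p_adj,
    } for r in results]).set_index("gene")
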