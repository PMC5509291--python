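"""Differential-methylation calling for promoters and gene bodies.

A feature is called differentially methylated between the trimester groups
when (1) the feature-level group-mean methylation difference is at least
10 percentage points and (2) it contains at least 2 CpGs with
Benjamini-Hochberg adjusted Mann-Whitney p < 0.05, the adjustment applied
within regions.  Gene bodies additionally require every merged fragment
containing a significant CpG to change in the same direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedInterval, cpgs_in_interval
from .methylome import FilteredCpGMatrix, Group, MergedRegion
from .stats import benjamini_hochberg, exact_mann_whitney


class Direction(str, enum.Enum):
    HYPER = "hyper"
    HYPO = "hypo"


@dataclass
class DmrResult:
    """Differential-methylation call for one feature."""

    feature: AnnotatedInterval
    n_cpgs_tested: int
    n_cpgs_significant: int
    mean_first: float
    mean_third: float
    delta: float  # third - first, percentage points
    direction: Direction
    significant: bool
    testable: bool
    fragment_directions: list[Direction] = field(default_factory=list)  # gene bodies


def cpg_pvalues(
    matrix: FilteredCpGMatrix, site_indices: Sequence[int]
) -> np.ndarray:
    """Raw two-sided exact Mann-Whitney p-value per CpG, on per-sample
    methylation percents with missing values dropped per CpG; a CpG with
    fewer than 2 values in either group gets p = 1."""
    first = matrix.site_levels(Group.FIRST)
    third = matrix.site_levels(Group.THIRD)
    ps = np.ones(len(site_indices))
    for j, i in enumerate(site_indices):
        x = first[i][~np.isnan(first[i])]
        y = third[i][~np.isnan(third[i])]
        if x.size < 2 or y.size < 2:
            continue
        ps[j] = exact_mann_whitney(x, y).p_value
    return ps


def _feature_delta(matrix: FilteredCpGMatrix, site_indices: Sequence[int]) -> tuple[float, float, float]:
    idx = np.asarray(site_indices)
    m1 = float(np.nanmean(matrix.site_group_means(Group.FIRST)[idx]))
    m3 = float(np.nanmean(matrix.site_group_means(Group.THIRD)[idx]))
    return m1, m3, m3 - m1


def call_promoter_dmr(
    matrix: FilteredCpGMatrix,
    promoter: AnnotatedInterval,
    fragments: Sequence[MergedRegion] | None = None,
    min_delta: float = 10.0,
    alpha: float = 0.05,
    min_sig_cpgs: int = 2,
    adjust_within: Literal["feature", "fragment"] = "feature",
) -> DmrResult:
    """Call a promoter DMR: delta >= ``min_delta`` percentage points in
    magnitude and >= ``min_sig_cpgs`` CpGs at FDR < ``alpha``.

    The BH family defaults to the promoter's own CpGs; ``fragment`` scopes
    the adjustment within each merged fragment instead (requires
    ``fragments``).
    """
    idx = cpgs_in_interval(matrix.sites, promoter)
    if len(idx) < min_sig_cpgs:
        m1, m3, d = _feature_delta(matrix, idx) if idx else (np.nan, np.nan, 0.0)
        return DmrResult(promoter, len(idx), 0, m1, m3, d, _direction(d), False, testable=False)
    if adjust_within == "fragment":
        if fragments is None:
            raise ValueError("fragment-scoped adjustment needs the assigned fragments")
        n_sig = _count_sig_by_fragment(matrix, promoter, fragments, alpha)[0]
    else:
        adj = benjamini_hochberg(cpg_pvalues(matrix, idx))
        n_sig = int((adj < alpha).sum())
    m1, m3, d = _feature_delta(matrix, idx)
    significant = abs(d) >= min_delta and n_sig >= min_sig_cpgs
    return DmrResult(promoter, len(idx), n_sig, m1, m3, d, _direction(d), significant, testable=True)


def _direction(delta: float) -> Direction:
    return Direction.HYPER if delta > 0 else Direction.HYPO


def _count_sig_by_fragment(
    matrix: FilteredCpGMatrix,
    feature: AnnotatedInterval,
    fragments: Sequence[MergedRegion],
    alpha: float,
) -> tuple[int, list[Direction]]:
    """BH-adjust within each fragment's CpGs (clipped to the feature);
    return the total FDR-significant CpG count and the direction of every
    fragment containing at least one significant CpG."""
    total_sig = 0
    flagged: list[Direction] = []
    for frag in fragments:
        idx = [i for i in frag.site_indices if feature.start <= matrix.sites[i][1] <= feature.end and matrix.sites[i][0] == feature.chrom]
        if not idx:
            continue
        adj = benjamini_hochberg(cpg_pvalues(matrix, idx))
        k = int((adj < alpha).sum())
        total_sig += k
        if k > 0:
            flagged.append(_direction(frag.delta))
    return total_sig, flagged


def call_gene_body_dmr(
    matrix: FilteredCpGMatrix,
    gene_body: AnnotatedInterval,
    fragments: Sequence[MergedRegion],
    min_delta: float = 10.0,
    alpha: float = 0.05,
    min_sig_cpgs: int = 2,
) -> DmrResult:
    """Call a gene-body DMR: the promoter criteria over the body's CpGs,
    with BH adjusted within each merged fragment, plus the same-direction
    requirement on every fragment containing a significant CpG."""
    idx = cpgs_in_interval(matrix.sites, gene_body)
    if len(idx) < min_sig_cpgs:
        m1, m3, d = _feature_delta(matrix, idx) if idx else (np.nan, np.nan, 0.0)
        return DmrResult(gene_body, len(idx), 0, m1, m3, d, _direction(d), False, testable=False)
    n_sig, flagged = _count_sig_by_fragment(matrix, gene_body, fragments, alpha)
    m1, m3, d = _feature_delta(matrix, idx)
    same_direction = len(set(flagged)) <= 1
    significant = abs(d) >= min_delta and n_sig >= min_sig_cpgs and same_direction
    return DmrResult(
        gene_body, len(idx), n_sig, m1, m3, d, _direction(d), significant, testable=True, fragment_directions=flagged
    )


def summarize_dmrs(results: Sequence[DmrResult]) -> dict:
    """Counts of significant features with the hyper/hypo split and a
    gene-level rollup (a gene is significant when any of its promoters is;
    its direction follows the significant promoter with the largest |delta|)."""
    summary: dict = {}
    for kind in ("promoter", "gene_body"):
        sig = [r for r in results if r.feature.feature.value == kind and r.significant]
        n_hyper = sum(r.direction == Direction.HYPER for r in sig)
        entry = {"n_significant": len(sig), "n_hyper": n_hyper, "n_hypo": len(sig) - n_hyper}
        if sig:
            entry["pct_hyper"] = 100.0 * n_hyper / len(sig)
        summary[kind] = entry

    by_gene: dict[str, DmrResult] = {}
    for r in results:
        if r.feature.feature.value == "promoter" and r.significant:
            cur = by_gene.get(r.feature.gene_id)
            if cur is None or abs(r.delta) > abs(cur.delta):
                by_gene[r.feature.gene_id] = r
    n_hyper = sum(r.direction == Direction.HYPER for r in by_gene.values())
    gene_entry: dict = {"n_significant": len(by_gene), "n_hyper": n_hyper, "n_hypo": len(by_gene) - n_hyper}
    if by_gene:
        gene_entry["pct_hyper"] = 100.0 * n_hyper / len(by_gene)
    summary["gene"] = gene_entry
    return summary


def dmr_table(results: Sequence[DmrResult]) -> pd.DataFrame:
    """Per-feature table with the columns used in reported DMR lists."""
    return pd.DataFrame(
        [
            (
                r.feature.gene_id,
                r.feature.feature.value,
                r.feature.chrom,
                r.feature.start,
                r.feature.end,
                r.n_cpgs_tested,
                r.n_cpgs_significant,
                round(r.mean_first, 2),
                round(r.mean_third, 2),
                round(r.delta, 2),
                r.direction.value,
                r.significant,
            )
            for r in results
        ],
        columns=[
            "gene_id", "feature", "chrom", "start", "end", "n_cpgs", "n_sig_cpgs",
            "mean_1T", "mean_3T", "delta", "direction", "significant",
        ],
    )
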