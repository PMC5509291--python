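"""RPKM expression quantification and differential-expression calling.

RPKM = gene reads / (total aligned reads x transcript length in kb) x 1e6.
Group-average RPKM below 0.5 is floored to 0.5; genes below 0.5 in both
groups are filtered out.  A gene is differentially expressed when the
two-sided exact Mann-Whitney p-value on per-sample RPKM is < 0.05 and the
floored third/first group-average ratio is >= 2 or <= 0.5.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import Group
from .stats import exact_mann_whitney


def rpkm(n_gene_reads: float, n_total_reads: float, length_kb: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if n_total_reads <= 0:
        raise ValueError("total aligned reads must be positive")
    if length_kb <= 0:
        raise ValueError("transcript length must be positive")
    return n_gene_reads / (n_total_reads * length_kb) * 1e6


def floor_group_average(avg: float, floor: float = 0.5) -> float:
    """Floor a group-average RPKM at ``floor`` (0.5 by default)."""
    if avg < 0:
        raise ValueError("RPKM cannot be negative")
    return max(avg, floor)


class DeDirection(str, enum.Enum):
    UP = "up"
    DOWN = "down"


@dataclass
class ExpressionTable:
    """Per-gene per-sample RPKM with group structure.

    ``rpkm`` is genes x samples; ``groups`` maps each sample column to its
    trimester group.  Group averages are computed pre-floor; the floor is
    applied only where ratios are formed.
    """

    rpkm: pd.DataFrame
    groups: Mapping[str, Group]
    floor: float = 0.5

    def __post_init__(self) -> None:
        missing = set(self.rpkm.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("negative RPKM")

    def samples_in(self, group: Group) -> list[str]:
        return [s for s in self.rpkm.columns if self.groups[s] == group]

    def group_average(self, group: Group, floored: bool = False) -> pd.Series:
        avg = self.rpkm[self.samples_in(group)].mean(axis=1)
        return avg.clip(lower=self.floor) if floored else avg

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths_kb: pd.Series,
        groups: Mapping[str, Group],
        total_reads: pd.Series | None = None,
        floor: float = 0.5,
    ) -> "ExpressionTable":
        """Build per-sample RPKM from a gene x sample counts matrix.

        ``total_reads`` defaults to each sample's column sum (all aligned
        reads assigned to genes).
        """
        lengths_kb = lengths_kb.reindex(counts.index)
        if lengths_kb.isna().any():
            raise ValueError("genes missing a transcript length")
        if (lengths_kb <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if total_reads is None:
            total_reads = counts.sum(axis=0)
        vals = counts.to_numpy(dtype=float) / np.outer(lengths_kb.to_numpy(), total_reads.reindex(counts.columns).to_numpy()) * 1e6
        return cls(pd.DataFrame(vals, index=counts.index, columns=counts.columns), dict(groups), floor)


def filter_low_expression(table: ExpressionTable) -> pd.Index:
    """Genes retained for DE analysis: pre-floor group-average RPKM >= the
    floor in at least one group."""
    a1 = table.group_average(Group.FIRST)
    a3 = table.group_average(Group.THIRD)
    keep = (a1 >= table.floor) | (a3 >= table.floor)
    return table.rpkm.index[keep]


@dataclass
class DeResult:
    gene_id: str
    avg_first: float  # floored group averages
    avg_third: float
    log2_ratio: float
    p_value: float
    significant: bool
    direction: DeDirection


def call_de(
    table: ExpressionTable,
    gene_id: str,
    p_threshold: float = 0.05,
    fold: float = 2.0,
) -> DeResult:
    """Differential-expression call for one gene: exact Mann-Whitney on the
    per-sample RPKM values, fold-change rule on the floored group averages."""
    x = table.rpkm.loc[gene_id, table.samples_in(Group.FIRST)].to_numpy(dtype=float)
    y = table.rpkm.loc[gene_id, table.samples_in(Group.THIRD)].to_numpy(dtype=float)
    p = exact_mann_whitney(x, y).p_value
    a1 = floor_group_average(float(x.mean()), table.floor)
    a3 = floor_group_average(float(y.mean()), table.floor)
    ratio = a3 / a1
    significant = p < p_threshold and (ratio >= fold or ratio <= 1.0 / fold)
    return DeResult(
        gene_id=gene_id,
        avg_first=a1,
        avg_third=a3,
        log2_ratio=float(np.log2(ratio)),
        p_value=p,
        significant=significant,
        direction=DeDirection.UP if ratio > 1 else DeDirection.DOWN,
    )


def call_de_all(table: ExpressionTable, p_threshold: float = 0.05, fold: float = 2.0) -> list[DeResult]:
    """DE call for every gene passing the low-expression filter."""
    return [call_de(table, g, p_threshold, fold) for g in filter_low_expression(table)]


def summarize_de(results: Sequence[DeResult], bin_width: float = 0.25) -> dict:
    """Up/down counts and percentages among significant genes, plus the
    log2 fold-change histogram over the significant set."""
    sig = [r for r in results if r.significant]
    n_down = sum(r.direction == DeDirection.DOWN for r in sig)
    summary: dict = {
        "n_tested": len(results),
        "n_significant": len(sig),
        "n_down": n_down,
        "n_up": len(sig) - n_down,
    }
    if sig:
        summary["pct_down"] = 100.0 * n_down / len(sig)
        summary["pct_up"] = 100.0 * (len(sig) - n_down) / len(sig)
        ratios = np.array([r.log2_ratio for r in sig])
        lo = np.floor(ratios.min() / bin_width) * bin_width
        hi = np.ceil(ratios.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, _ = np.histogram(ratios, bins=edges)
        summary["log2_histogram"] = (edges, counts)
    return summary


def imprinted_overlay(results: Sequence[DeResult], imprint_lookup: Mapping[str, str]) -> pd.DataFrame:
    """Significant DE genes that are imprinted, with direction and parental
    status, sorted by log2 ratio ascending."""
    rows = [
        (r.gene_id, round(r.avg_first, 2), round(r.avg_third, 2), round(r.log2_ratio, 2), r.direction.value, imprint_lookup[r.gene_id])
        for r in results
        if r.significant and r.gene_id in imprint_lookup
    ]
    df = pd.DataFrame(
        rows, columns=["gene_id", "avg_first", "avg_third", "log2_ratio", "direction", "imprint_status"]
    )
    return df.sort_values("log2_ratio", ignore_index=True)


def de_table(results: Sequence[DeResult]) -> pd.DataFrame:
    """Per-gene DE table with reported-list-style columns."""
    return pd.DataFrame(
        [
            (r.gene_id, round(r.avg_first, 2), round(r.avg_third, 2), round(r.log2_ratio, 2), r.p_value, r.significant, r.direction.value)
            for r in results
        ],
        columns=["gene_id", "avg_first", "avg_third", "log2_ratio", "p", "significant", "direction"],
    )
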