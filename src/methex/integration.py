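"""Methylation-expression integration.

Three analyses tie the methylome to the transcriptome: (1) 50-bin curves of
feature methylation against ranked gene expression, stratified by genomic
context (promoter / gene body / exon / intron x CGI / non-CGI); (2)
sign-concordance of genes significant in both the DMR and DE analyses, with
an exact two-sided binomial test against a 50:50 split; (3) a rank test
comparing baseline expression between the anti- and positively-correlated
classes.  The dual-luciferase normalization used to validate promoter
methylation effects is included for completeness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import DmrResult
from .expression import DeResult
from .stats import TestResult, exact_binomial_two_sided, exact_mann_whitney


def bin_genes_by_expression(expression: Mapping[str, float] | pd.Series, n_bins: int = 50) -> pd.Series:
    """Partition genes into ``n_bins`` contiguous rank-slices of increasing
    expression (group-average RPKM).

    Bin sizes differ by at most one gene; ties are broken by gene_id so the
    assignment is deterministic.  Returns a gene_id -> bin index Series
    (bins numbered from 0, expression increasing with bin index).
    """
    expr = pd.Series(expression, dtype=float)
    if n_bins > len(expr):
        raise ValueError(f"n_bins={n_bins} exceeds the {len(expr)} genes available")
    order = sorted(expr.index, key=lambda g: (expr[g], g))
    n = len(order)
    assignment = {}
    for rank, gene in enumerate(order):
        assignment[gene] = rank * n_bins // n
    return pd.Series(assignment, name="bin").sort_values(kind="stable")


@dataclass
class BinCurve:
    """Mean feature methylation per expression bin for one context/group."""

    context: str  # e.g. "promoter/CGI"
    group: str
    bin_mean_expression: np.ndarray  # RPKM, for plotting
    bin_mean_methylation: np.ndarray  # percent; NaN where no gene has data
    bin_n_genes: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean_methylation)


def bin_methylation_curve(
    bins: pd.Series,
    expression: Mapping[str, float] | pd.Series,
    feature_methylation: Mapping[str, float] | pd.Series,
    context: str = "",
    group: str = "",
) -> BinCurve:
    """Average feature methylation within each expression bin.

    Genes lacking a covered feature in the context (absent from
    ``feature_methylation`` or NaN) are excluded from their bin's mean, not
    imputed; a bin with no covered gene yields a NaN point.
    """
    expr = pd.Series(expression, dtype=float)
    meth = pd.Series(feature_methylation, dtype=float)
    n_bins = int(bins.max()) + 1
    mean_expr = np.full(n_bins, np.nan)
    mean_meth = np.full(n_bins, np.nan)
    n_genes = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        genes = bins.index[bins == b]
        mean_expr[b] = expr.reindex(genes).mean()
        covered = meth.reindex(genes).dropna()
        n_genes[b] = len(covered)
        if len(covered):
            mean_meth[b] = covered.mean()
    return BinCurve(context, group, mean_expr, mean_meth, n_genes)


def curves_to_table(curves: Sequence[BinCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for b in range(c.n_bins):
            rows.append((c.context, c.group, b, c.bin_mean_expression[b], c.bin_mean_methylation[b], c.bin_n_genes[b]))
    return pd.DataFrame(rows, columns=["context", "group", "bin", "mean_rpkm", "mean_meth", "n_genes"])


class Concordance(str, enum.Enum):
    ANTI = "anti"
    POSITIVE = "positive"


@dataclass(frozen=True)
class ConcordanceRecord:
    """One gene significant in both analyses: its methylation change (3T-1T,
    percentage points), expression log2(3T/1T), and sign-concordance class."""

    gene_id: str
    feature: str  # promoter | gene_body
    meth_delta: float
    expr_log2: float

    @property
    def concordance(self) -> Concordance:
        return Concordance.ANTI if np.sign(self.meth_delta) != np.sign(self.expr_log2) else Concordance.POSITIVE


def classify_pairs(pairs: Sequence[tuple[str, float, float]], feature: str = "promoter") -> list[ConcordanceRecord]:
    """Build concordance records from (gene_id, meth_delta, expr_log2)
    triples, excluding pairs with either component exactly zero."""
    return [
        ConcordanceRecord(g, feature, d, e)
        for g, d, e in pairs
        if d != 0.0 and e != 0.0
    ]


def concordance_table(
    dmr_results: Sequence[DmrResult],
    de_results: Sequence[DeResult],
    feature: str = "promoter",
) -> list[ConcordanceRecord]:
    """Genes significant in BOTH the DMR analysis (for ``feature``) and the
    DE analysis.  A gene with several significant features of that kind uses
    the one with the largest |delta|."""
    best: dict[str, DmrResult] = {}
    for r in dmr_results:
        if r.feature.feature.value == feature and r.significant:
            cur = best.get(r.feature.gene_id)
            if cur is None or abs(r.delta) > abs(cur.delta):
                best[r.feature.gene_id] = r
    de_by_gene = {r.gene_id: r for r in de_results if r.significant}
    pairs = [
        (g, best[g].delta, de_by_gene[g].log2_ratio)
        for g in sorted(best.keys() & de_by_gene.keys())
    ]
    return classify_pairs(pairs, feature)


def concordance_test(records: Sequence[ConcordanceRecord]) -> TestResult:
    """Exact two-sided binomial test of the anti-correlated count against a
    50:50 null."""
    if not records:
        raise ValueError("no concordance records")
    n_anti = sum(r.concordance == Concordance.ANTI for r in records)
    return exact_binomial_two_sided(n_anti, len(records), 0.5)


def compare_baseline_expression(
    records: Sequence[ConcordanceRecord],
    baseline_rpkm: Mapping[str, float] | pd.Series,
) -> tuple[TestResult, pd.DataFrame]:
    """Two-sided Mann-Whitney between the anti- and positively-correlated
    classes on log-scale first-trimester average RPKM, with per-class
    median and quartiles."""
    baseline = pd.Series(baseline_rpkm, dtype=float)
    by_class = {
        cls: np.log10(baseline.reindex([r.gene_id for r in records if r.concordance == cls]).dropna())
        for cls in (Concordance.ANTI, Concordance.POSITIVE)
    }
    for cls, vals in by_class.items():
        if len(vals) < 2:
            raise ValueError(f"class {cls.value} has fewer than 2 members")
    result = exact_mann_whitney(by_class[Concordance.ANTI], by_class[Concordance.POSITIVE])
    summary = pd.DataFrame(
        {
            cls.value: vals.quantile([0.25, 0.5, 0.75]).to_numpy()
            for cls, vals in by_class.items()
        },
        index=["q25", "median", "q75"],
    )
    return result, summary


def records_to_table(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.feature, r.meth_delta, r.expr_log2, r.concordance.value) for r in records],
        columns=["gene_id", "feature", "meth_delta", "expr_log2", "class"],
    )


def normalize_luciferase(
    firefly: float, renilla: float, firefly_empty: float, renilla_empty: float
) -> float:
    """Dual-luciferase normalization: firefly/Renilla of the promoter
    construct minus firefly/Renilla of the empty-vector control."""
    if renilla <= 0 or renilla_empty <= 0:
        raise ValueError("Renilla activity must be positive")
    return firefly / renilla - firefly_empty / renilla_empty
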