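"""Stage orchestration: thresholds, file round-trips, and the end-to-end run.

Stages communicate only through declared TSV files under one run directory;
a manifest records every output with its row count and checksum so reruns
can be verified byte-for-byte.  All thresholds default to the study's
stated values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, dmr, expression, integration, methylome
from .methylome import FilteredCpGMatrix, Group


@dataclass
class RunConfig:
    """Every numeric threshold of the analysis, at its stated default."""

    min_depth: int = 10
    min_samples: int = 3
    merge_gap: int = 500
    min_delta: float = 10.0
    alpha: float = 0.05
    min_sig_cpgs: int = 2
    rpkm_floor: float = 0.5
    de_p: float = 0.05
    fold: float = 2.0
    n_bins: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_depth", "min_samples", "merge_gap", "min_delta", "alpha",
                     "min_sig_cpgs", "rpkm_floor", "de_p", "fold", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_samples(sheet_path) -> list[methylome.MethylationCallSet]:
    """Read a sample sheet (sample_id, group, path) and each coverage file."""
    sheet = pd.read_csv(sheet_path, sep=None, engine="python")
    base = Path(sheet_path).parent
    out = []
    for _, row in sheet.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"coverage file missing: {p}")
        out.append(methylome.read_coverage_file(p, str(row["sample_id"]), Group(row["group"])))
    return out


def matrix_to_table(matrix: FilteredCpGMatrix) -> pd.DataFrame:
    df = pd.DataFrame(matrix.levels, columns=matrix.sample_ids)
    df.insert(0, "chrom", [c for c, _ in matrix.sites])
    df.insert(1, "pos", [p for _, p in matrix.sites])
    return df


def matrix_from_table(df: pd.DataFrame, groups: dict[str, Group]) -> FilteredCpGMatrix:
    sample_ids = [c for c in df.columns if c not in ("chrom", "pos")]
    sites = list(zip(df["chrom"], df["pos"].astype(int)))
    return FilteredCpGMatrix(
        sites, df[sample_ids].to_numpy(dtype=float), sample_ids, [groups[s] for s in sample_ids]
    )


def run_methylome_stage(samples, config: RunConfig):
    matrix = methylome.filter_sites(samples, config.min_depth, config.min_samples)
    regions = methylome.merge_regions(matrix, config.merge_gap)
    return matrix, regions


def run_dmr_stage(matrix, regions, genes, config: RunConfig) -> list[dmr.DmrResult]:
    """Promoter and gene-body DMR calls for every gene."""
    results = []
    for gene in genes:
        prom = annotation.promoter_interval(gene)
        results.append(
            dmr.call_promoter_dmr(
                matrix, prom, min_delta=config.min_delta, alpha=config.alpha, min_sig_cpgs=config.min_sig_cpgs
            )
        )
        body = annotation.gene_body_interval(gene)
        if body is not None:
            frags = annotation.assign_to_feature(regions, [body])[body]
            results.append(
                dmr.call_gene_body_dmr(
                    matrix, body, frags, min_delta=config.min_delta, alpha=config.alpha, min_sig_cpgs=config.min_sig_cpgs
                )
            )
    return results


def run_expression_stage(counts, lengths_kb, groups, totals, config: RunConfig):
    table = expression.ExpressionTable.from_counts(counts, lengths_kb, groups, totals, config.rpkm_floor)
    results = expression.call_de_all(table, config.de_p, config.fold)
    return table, results


def run_integration_stage(matrix, regions, genes, cgi_track, table, dmr_results, de_results, config: RunConfig):
    """Bin curves per context/group plus concordance analyses."""
    curves = []
    feature_meth: dict[tuple[str, str], dict[str, float]] = {}
    for gene in genes:
        for kind, iv in (("promoter", annotation.promoter_interval(gene)), ("gene_body", annotation.gene_body_interval(gene))):
            if iv is None:
                continue
            ctx = annotation.cgi_flag(iv, cgi_track).value
            idx = annotation.cpgs_in_interval(matrix.sites, iv)
            if not idx:
                continue
            for group in (Group.FIRST, Group.THIRD):
                m = float(np.nanmean(matrix.site_group_means(group)[np.asarray(idx)]))
                feature_meth.setdefault((f"{kind}/{ctx}", group.value), {})[gene.gene_id] = m

    retained = expression.filter_low_expression(table)
    for group in (Group.FIRST, Group.THIRD):
        expr = table.group_average(group, floored=True).reindex(retained)
        n_bins = min(config.n_bins, len(expr))
        bins = integration.bin_genes_by_expression(expr, n_bins)
        for (context, grp), meth in sorted(feature_meth.items()):
            if grp != group.value:
                continue
            curves.append(integration.bin_methylation_curve(bins, expr, meth, context, grp))

    out = {"curves": curves, "concordance": {}, "tests": {}}
    for feature in ("promoter", "gene_body"):
        records = integration.concordance_table(dmr_results, de_results, feature)
        out["concordance"][feature] = records
        if records:
            out["tests"][feature] = integration.concordance_test(records)
    gb_records = out["concordance"]["gene_body"]
    classes = {r.concordance for r in gb_records}
    if len(classes) == 2 and all(sum(r.concordance == c for r in gb_records) >= 2 for c in classes):
        baseline = table.group_average(Group.FIRST, floored=True)
        out["tests"]["baseline_expression"], _ = integration.compare_baseline_expression(gb_records, baseline)
    return out


def write_manifest(out_dir, files: dict[str, Path], thresholds: RunConfig) -> Path:
    manifest = {"thresholds": dataclasses.asdict(thresholds), "files": {}}
    for name, path in sorted(files.items()):
        path = Path(path)
        data = path.read_bytes()
        n_rows = data.count(b"\n")
        manifest["files"][name] = {
            "path": path.name,
            "rows": n_rows,
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
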