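"""Synthetic RRBS + RNA-seq data with known planted structure.

The generator emulates the study regime end-to-end: a small genome of
non-overlapping genes with CGI and non-CGI promoters, CpGs placed densely
inside CpG islands and sparsely elsewhere (so that region merging produces
both multi-CpG fragments and singletons), beta-binomial methylation reads
(beta-distributed per-sample levels around a bimodal context baseline,
binomial reads at RRBS-like depth), and negative-binomial RNA-seq counts.

Planted effects — group-wise methylation shifts on a subset of promoters
and gene bodies, fold changes on a subset of genes, and a sign coupling
between the two on "coupled" genes — are recorded in a truth table so
sensitivity and specificity of every pipeline stage can be measured.

Defaults mirror the study conditions: 6 vs 5 methylation samples, 5 vs 4
expression samples, depth-30 RRBS coverage, hypermethylation dominance and
a down-regulation-dominant transcriptome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, promoter_interval
from .methylome import CpGCall, Group, MethylationCallSet


@dataclass
class SimConfig:
    """Everything the generator needs; one seed drives all randomness."""

    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 2
    # sample sizes (methylation / expression)
    n_first_meth: int = 6
    n_third_meth: int = 5
    n_first_expr: int = 5
    n_third_expr: int = 4
    # genome geometry
    cgi_fraction: float = 0.6  # fraction of promoters with a CpG island
    # methylation model
    depth_mean: float = 30.0
    beta_precision: float = 100.0  # between-sample beta concentration
    cgi_beta: tuple[float, float] = (0.6, 6.0)  # low-methylation mode
    noncgi_beta: tuple[float, float] = (6.0, 0.6)  # high-methylation mode
    # planted methylation effects
    frac_dm_promoters: float = 0.10
    frac_dm_bodies: float = 0.10
    dm_delta: float = 20.0  # percentage points
    frac_hyper: float = 0.97
    # expression model
    rpkm_log_mean: float = np.log(5.0)
    rpkm_log_sd: float = 1.6
    nb_dispersion: float = 0.1
    total_reads: float = 2.0e6
    # planted expression effects
    frac_de: float = 0.15
    fold_change: float = 4.0
    frac_down: float = 0.772
    # genes planted with BOTH a promoter DMR and DE, sign-coupled
    frac_coupled: float = 0.0
    anti_fraction: float = 0.75

    def validate(self) -> None:
        for name in ("cgi_fraction", "frac_dm_promoters", "frac_dm_bodies", "frac_hyper",
                     "frac_de", "frac_down", "frac_coupled", "anti_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dm_delta < 0 or self.dm_delta > 100:
            raise ValueError("dm_delta must be in [0, 100] percentage points")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")


@dataclass
class PlantedEffects:
    """Per-gene planted truth: signed deltas (pp) and log2 fold changes;
    zero means no planted effect."""

    promoter_delta: dict[str, float] = field(default_factory=dict)
    body_delta: dict[str, float] = field(default_factory=dict)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    coupled: set[str] = field(default_factory=set)


@dataclass
class SimGenome:
    genes: list[GeneModel]
    cgi_track: list[tuple[str, int, int]]
    cpg_sites: list[tuple[str, int]]
    planted: PlantedEffects
    baseline_rpkm: pd.Series = None
    lengths_kb: pd.Series = None


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _place_cluster(rng, lo: int, hi: int, n: int, max_gap: int = 450) -> list[int]:
    """n CpG positions in [lo, hi] with every consecutive gap < max_gap."""
    if n == 1:
        return [int(rng.integers(lo, hi + 1))]
    base = np.linspace(lo, hi, n)
    jitter = rng.integers(-20, 21, size=n)
    pos = np.unique(np.clip((base + jitter).astype(int), lo, hi))
    while len(pos) < n:  # collision after jitter: refill deterministically
        pos = np.unique(np.concatenate([pos, [int(rng.integers(lo, hi + 1))]]))
    return sorted(int(p) for p in pos[:n])


def simulate_genome(config: SimConfig) -> SimGenome:
    """Lay out non-overlapping genes with promoters, bodies, exons, CGIs
    and CpG positions; decide the planted effects."""
    config.validate()
    rng = _rng(config, 1)
    if config.n_genes < 1 or config.n_chroms < 1:
        raise ValueError("infeasible geometry: need >= 1 gene and >= 1 chromosome")

    genes: list[GeneModel] = []
    cgi_track: list[tuple[str, int, int]] = []
    cpgs: list[tuple[str, int]] = []
    cursors = {f"chr{i + 1}": 5000 for i in range(config.n_chroms)}

    for g in range(config.n_genes):
        chrom = f"chr{(g % config.n_chroms) + 1}"
        cursor = cursors[chrom]
        gene_id = f"G{g:04d}"
        span = int(rng.integers(4000, 8001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = cursor + 1500
            tts = tss + span
            lo, hi = tss, tts
        else:
            tts = cursor + 1500
            tss = tts + span
            lo, hi = tts, tss
        # 2-4 exons tiling alternate slices of the gene span
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(lo + 200, hi - 200, 100), size=2 * n_ex - 1, replace=False))
        bounds = [lo, *map(int, cuts), hi]
        exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex)]
        gene = GeneModel(gene_id, chrom, strand, tss, tts, exons)
        genes.append(gene)

        prom = promoter_interval(gene)
        has_cgi = rng.random() < config.cgi_fraction
        if has_cgi:
            cgi_track.append((chrom, max(1, tss - 500), tss + 300))
            n_prom_cpgs = int(rng.integers(8, 13))
        else:
            n_prom_cpgs = int(rng.integers(6, 9))
        cpgs.extend((chrom, p) for p in _place_cluster(rng, prom.start + 20, prom.end - 20, n_prom_cpgs))

        # gene body: two clusters >= 700 bp apart, plus an occasional singleton
        body_lo, body_hi = min(tss, tts) + 1100, max(tss, tts) - 50
        mid = (body_lo + body_hi) // 2
        cpgs.extend((chrom, p) for p in _place_cluster(rng, body_lo, mid - 400, int(rng.integers(3, 6))))
        cpgs.extend((chrom, p) for p in _place_cluster(rng, mid + 400, body_hi - 600, int(rng.integers(3, 6))))
        if rng.random() < 0.5:
            cpgs.append((chrom, body_hi - 20))  # singleton, >= 500 bp from the last cluster
        cursors[chrom] = max(lo, hi) + 1500 + int(rng.integers(0, 1500))

    cpgs = sorted(set(cpgs))
    planted = _plant_effects(config, genes, _rng(config, 2))
    baseline = pd.Series(
        np.exp(rng.normal(config.rpkm_log_mean, config.rpkm_log_sd, size=config.n_genes)),
        index=[g.gene_id for g in genes],
        name="baseline_rpkm",
    )
    lengths = pd.Series(
        rng.uniform(0.5, 5.0, size=config.n_genes), index=baseline.index, name="length_kb"
    )
    # planted-DE genes must be expressed to be recoverable after the
    # low-expression filter: lift their baseline above the filter regime
    # sorted: set iteration order is hash-randomized per process, and rng
    # draws must map to genes deterministically
    for gid in sorted(set(planted.de_log2fc) | planted.coupled):
        if baseline[gid] < 2.0:
            baseline[gid] = float(rng.uniform(4.0, 40.0))
    return SimGenome(genes, cgi_track, cpgs, planted, baseline, lengths)


def _plant_effects(config: SimConfig, genes: list[GeneModel], rng) -> PlantedEffects:
    ids = [g.gene_id for g in genes]
    n = len(ids)
    planted = PlantedEffects()
    shuffled = list(rng.permutation(ids))

    n_coupled = round(config.frac_coupled * n)
    coupled = shuffled[:n_coupled]
    rest = shuffled[n_coupled:]
    planted.coupled = set(coupled)
    for gid in coupled:
        sign = 1.0 if rng.random() < config.frac_hyper else -1.0
        planted.promoter_delta[gid] = sign * config.dm_delta
        planted.body_delta[gid] = sign * config.dm_delta
        # anti: expression moves opposite to methylation
        anti = rng.random() < config.anti_fraction
        expr_sign = -sign if anti else sign
        planted.de_log2fc[gid] = expr_sign * np.log2(config.fold_change)

    n_dm_p = round(config.frac_dm_promoters * n)
    n_dm_b = round(config.frac_dm_bodies * n)
    n_de = round(config.frac_de * n)
    for gid in rest[:n_dm_p]:
        sign = 1.0 if rng.random() < config.frac_hyper else -1.0
        planted.promoter_delta[gid] = sign * config.dm_delta
    for gid in rest[:n_dm_b]:  # bodies planted on the same genes as promoters
        sign = 1.0 if gid in planted.promoter_delta else (1.0 if rng.random() < config.frac_hyper else -1.0)
        if gid in planted.promoter_delta:
            sign = np.sign(planted.promoter_delta[gid])
        planted.body_delta[gid] = sign * config.dm_delta
    de_pool = rest[n_dm_p:][:n_de] if n_de <= len(rest) - n_dm_p else rest[:n_de]
    for gid in de_pool:
        sign = -1.0 if rng.random() < config.frac_down else 1.0
        planted.de_log2fc[gid] = sign * np.log2(config.fold_change)
    return planted


def simulate_methylome(config: SimConfig, genome: SimGenome) -> list[MethylationCallSet]:
    """Draw per-sample CpG calls: beta-binomial reads around a bimodal
    context baseline, with the planted group shifts applied to the third
    trimester at CpGs inside planted features."""
    rng = _rng(config, 3)
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in genome.cgi_track:
        cgi_by_chrom.setdefault(c, []).append((s, e))

    def in_cgi(chrom: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in cgi_by_chrom.get(chrom, ()))

    # per-CpG baseline and planted shift
    from .annotation import gene_body_interval  # local import to avoid cycle at module load

    shift: dict[tuple[str, int], float] = {}
    for gene in genome.genes:
        d_prom = genome.planted.promoter_delta.get(gene.gene_id, 0.0)
        d_body = genome.planted.body_delta.get(gene.gene_id, 0.0)
        if d_prom:
            prom = promoter_interval(gene)
            for chrom, pos in genome.cpg_sites:
                if chrom == prom.chrom and prom.start <= pos <= prom.end:
                    shift[(chrom, pos)] = d_prom / 100.0
        if d_body:
            body = gene_body_interval(gene)
            if body is not None:
                for chrom, pos in genome.cpg_sites:
                    if chrom == body.chrom and body.start <= pos <= body.end:
                        shift[(chrom, pos)] = d_body / 100.0

    base: dict[tuple[str, int], float] = {}
    for site in genome.cpg_sites:
        d = shift.get(site, 0.0)
        if d > 0:  # leave headroom so the planted mean stays inside [0, 1]
            base[site] = float(rng.uniform(0.25, 0.60))
        elif d < 0:
            base[site] = float(rng.uniform(0.40, 0.75))
        elif in_cgi(*site):
            base[site] = float(rng.beta(*config.cgi_beta))
        else:
            base[site] = float(rng.beta(*config.noncgi_beta))

    callsets = []
    labels = [(f"F{i + 1}", Group.FIRST) for i in range(config.n_first_meth)] + [
        (f"T{i + 1}", Group.THIRD) for i in range(config.n_third_meth)
    ]
    rho = config.beta_precision
    for sample_id, group in labels:
        cs = MethylationCallSet(sample_id, group)
        for chrom, pos in genome.cpg_sites:
            m = base[(chrom, pos)]
            if group is Group.THIRD:
                m = min(0.99, max(0.01, m + shift.get((chrom, pos), 0.0)))
            m = min(0.995, max(0.005, m))
            p_sample = rng.beta(m * rho, (1 - m) * rho)
            depth = int(rng.poisson(config.depth_mean))
            n_meth = int(rng.binomial(depth, p_sample)) if depth else 0
            cs.add(CpGCall(chrom, pos, n_meth, depth - n_meth))
        callsets.append(cs)
    return callsets


def simulate_counts(config: SimConfig, genome: SimGenome) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts around planted group-mean RPKM.

    Returns (counts genes x samples, lengths_kb, total_reads per sample);
    sample columns are named E_F* / E_T* with first/third membership encoded
    in the prefix.
    """
    rng = _rng(config, 4)
    labels = [(f"E_F{i + 1}", Group.FIRST) for i in range(config.n_first_expr)] + [
        (f"E_T{i + 1}", Group.THIRD) for i in range(config.n_third_expr)
    ]
    totals = pd.Series(
        {sid: float(rng.uniform(0.9, 1.1) * config.total_reads) for sid, _ in labels}, name="total_reads"
    )
    alpha = config.nb_dispersion
    counts = {}
    for sid, group in labels:
        mu_rpkm = genome.baseline_rpkm.copy()
        if group is Group.THIRD:
            for gid, lfc in genome.planted.de_log2fc.items():
                mu_rpkm[gid] = mu_rpkm[gid] * 2.0**lfc
        mu = mu_rpkm * genome.lengths_kb * totals[sid] / 1e6
        lam = rng.gamma(1.0 / alpha, alpha * mu.to_numpy())  # gamma-poisson = NB
        counts[sid] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genome.baseline_rpkm.index)
    return df, genome.lengths_kb, totals


def expression_groups(counts: pd.DataFrame) -> dict[str, Group]:
    """Group assignment encoded in the simulated sample names."""
    return {c: (Group.FIRST if c.startswith("E_F") else Group.THIRD) for c in counts.columns}


def truth_table(genome: SimGenome) -> pd.DataFrame:
    """Machine-readable planted truth, one row per gene."""
    p = genome.planted
    rows = []
    for gene in genome.genes:
        gid = gene.gene_id
        rows.append(
            (
                gid,
                p.promoter_delta.get(gid, 0.0),
                p.body_delta.get(gid, 0.0),
                p.de_log2fc.get(gid, 0.0),
                gid in p.coupled,
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "promoter_delta", "body_delta", "de_log2fc", "coupled"])


# ---------------------------------------------------------------------------
# on-disk round trip (the same formats the pipeline reads)


def write_dataset(config: SimConfig, genome: SimGenome, out_dir) -> dict[str, Path]:
    """Write a complete simulated dataset in pipeline input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    callsets = simulate_methylome(config, genome)
    sheet_rows = []
    for cs in callsets:
        p = out / f"{cs.sample_id}.cov.tsv"
        with open(p, "w") as fh:
            for call in sorted(cs.calls.values(), key=lambda c: (c.chrom, c.pos)):
                pct = f"{call.level:.4f}" if call.depth else "0.0"
                fh.write(f"{call.chrom}\t{call.pos}\t{call.pos}\t{pct}\t{call.n_meth}\t{call.n_unmeth}\n")
        sheet_rows.append((cs.sample_id, cs.group.value, p.name))
        paths[f"coverage/{cs.sample_id}"] = p
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "group", "path"])
    paths["sample_sheet"] = out / "sample_sheet.tsv"
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    genes_df = pd.DataFrame(
        [
            (
                g.gene_id,
                g.chrom,
                g.strand,
                g.tss,
                g.tts,
                ",".join(str(s) for s, _ in g.exons),
                ",".join(str(e) for _, e in g.exons),
            )
            for g in genome.genes
        ],
        columns=["gene_id", "chrom", "strand", "tss", "tts", "exon_starts", "exon_ends"],
    )
    paths["genes"] = out / "genes.tsv"
    genes_df.to_csv(paths["genes"], sep="\t", index=False)

    paths["cgi"] = out / "cgi.bed"
    with open(paths["cgi"], "w") as fh:
        for chrom, s, e in sorted(genome.cgi_track):
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")  # 1-based closed -> BED

    counts, lengths, totals = simulate_counts(config, genome)
    paths["counts"] = out / "counts.tsv"
    counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    paths["lengths"] = out / "gene_lengths.tsv"
    lengths.rename("length_kb").rename_axis("gene_id").to_csv(paths["lengths"], sep="\t")
    paths["totals"] = out / "total_reads.tsv"
    totals.rename_axis("sample_id").to_csv(paths["totals"], sep="\t")
    expr_sheet = pd.DataFrame(
        [(sid, g.value) for sid, g in expression_groups(counts).items()], columns=["sample_id", "group"]
    )
    paths["expr_sheet"] = out / "expression_samples.tsv"
    expr_sheet.to_csv(paths["expr_sheet"], sep="\t", index=False)

    paths["truth"] = out / "truth.tsv"
    truth_table(genome).to_csv(paths["truth"], sep="\t", index=False)

    cfg = dataclasses.asdict(config)
    paths["config"] = out / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k}: {list(v) if isinstance(v, tuple) else v}\n")
    return paths
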