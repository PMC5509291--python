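"""Per-CpG methylation calls: reading, filtering, regionalization, summaries.

RRBS reports each CpG as a pair of read counts (methylated, unmethylated)
per sample; the methylation level is the percentage of methylated reads.
Sites passing the depth/coverage filter are merged into regions wherever
consecutive CpGs are closer than 500 bp, the regional unit used for
differential-methylation calling.

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on read.  CpGs are identified by the forward-strand C position;
dyads are assumed pre-collapsed.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, exact_mann_whitney

#: default human assembly: autosomes only, natural order
DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


class Group(str, enum.Enum):
    FIRST = "first_trimester"
    THIRD = "third_trimester"


class CpGCall(NamedTuple):
    """One CpG in one sample: genomic position plus read counts."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        """Methylation percent; NaN at zero depth."""
        if self.depth == 0:
            return float("nan")
        return 100.0 * self.n_meth / self.depth


@dataclass
class MethylationCallSet:
    """All CpG calls for one sample, keyed by (chrom, pos)."""

    sample_id: str
    group: Group
    calls: dict[tuple[str, int], CpGCall] = field(default_factory=dict)

    def add(self, call: CpGCall) -> None:
        key = (call.chrom, call.pos)
        if key in self.calls:
            raise ValueError(f"duplicate CpG at {call.chrom}:{call.pos}")
        self.calls[key] = call

    def __len__(self) -> int:
        return len(self.calls)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+|[A-Za-z]+)$", chrom)
    if m and m.group(1).isdigit():
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def read_coverage_file(path, sample_id: str, group: Group) -> MethylationCallSet:
    """Read per-CpG calls from a coverage-style TSV.

    Two dialects are auto-detected by column count: the 6-column Bismark
    coverage format (chrom, start, end, percent, n_meth, n_unmeth) and a
    4-column format (chrom, pos, n_meth, n_unmeth).  The percent column,
    when present, is ignored and recomputed from the counts.
    """
    callset = MethylationCallSet(sample_id=sample_id, group=Group(group))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 6:
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields
                    pos = int(start)
                elif len(fields) == 4:
                    chrom, pos_s, n_meth, n_unmeth = fields
                    pos = int(pos_s)
                else:
                    raise ValueError(f"{len(fields)} columns (expected 4 or 6)")
                call = CpGCall(chrom, pos, int(n_meth), int(n_unmeth))
                if call.n_meth < 0 or call.n_unmeth < 0:
                    raise ValueError("negative read count")
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            try:
                callset.add(call)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return callset


@dataclass
class FilteredCpGMatrix:
    """Retained CpG sites x samples matrix of methylation percents.

    ``levels`` holds NaN wherever a sample's depth at a site is below the
    filter's ``min_depth``; every retained site has at least
    ``min_samples_per_group`` non-missing values in each group.
    """

    sites: list[tuple[str, int]]
    levels: np.ndarray  # (n_sites, n_samples), percent, NaN = missing
    sample_ids: list[str]
    groups: list[Group]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.sites), len(self.sample_ids)):
            raise ValueError("levels shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    @property
    def group_sizes(self) -> dict[Group, int]:
        return {g: int(self.group_mask(g).sum()) for g in (Group.FIRST, Group.THIRD)}

    def site_levels(self, group: Group) -> np.ndarray:
        """(n_sites, n_group_samples) slice of ``levels``."""
        return self.levels[:, self.group_mask(group)]

    def site_group_means(self, group: Group) -> np.ndarray:
        """Per-site mean percent over the group's covered samples."""
        sub = self.site_levels(group)
        with np.errstate(invalid="ignore"):
            return np.nanmean(sub, axis=1)


def site_group_mean(matrix: FilteredCpGMatrix, site: tuple[str, int], group: Group) -> float:
    """Mean methylation percent of one site over the group's covered samples
    (missing samples excluded); NaN when no sample covers the site."""
    i = matrix.sites.index(tuple(site))
    vals = matrix.site_levels(group)[i]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def filter_sites(
    samples: Sequence[MethylationCallSet],
    min_depth: int = 10,
    min_samples_per_group: int = 3,
    autosomes_only: bool = True,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
) -> FilteredCpGMatrix:
    """Apply the site filter: depth >= min_depth in >= min_samples_per_group
    samples of EACH group, autosomes only.

    Levels are stored only where depth >= min_depth; shallower observations
    are treated as missing rather than imputed.
    """
    for g in (Group.FIRST, Group.THIRD):
        if not any(s.group == g for s in samples):
            raise ValueError(f"no samples in group {g.value}")

    frames = []
    for s in samples:
        if not s.calls:
            continue
        df = pd.DataFrame(
            [(c.chrom, c.pos, c.level if c.depth >= min_depth else np.nan) for c in s.calls.values()],
            columns=["chrom", "pos", s.sample_id],
        ).set_index(["chrom", "pos"])
        frames.append(df)
    wide = pd.concat(frames, axis=1) if frames else pd.DataFrame()
    if wide.empty:
        return FilteredCpGMatrix([], np.empty((0, len(samples))), [s.sample_id for s in samples], [s.group for s in samples])
    # sample columns in input order
    wide = wide.reindex(columns=[s.sample_id for s in samples])

    groups = [s.group for s in samples]
    keep = pd.Series(True, index=wide.index)
    if autosomes_only:
        allowed = set(autosomes)
        keep &= wide.index.get_level_values("chrom").isin(allowed)
    for g in (Group.FIRST, Group.THIRD):
        cols = [s.sample_id for s in samples if s.group == g]
        keep &= wide[cols].notna().sum(axis=1) >= min_samples_per_group
    wide = wide[keep]

    order = sorted(range(len(wide)), key=lambda i: (chrom_sort_key(wide.index[i][0]), wide.index[i][1]))
    wide = wide.iloc[order]
    sites = [(c, int(p)) for c, p in wide.index]
    return FilteredCpGMatrix(sites, wide.to_numpy(dtype=float), [s.sample_id for s in samples], groups)


@dataclass
class MergedRegion:
    """A maximal run of retained CpGs with consecutive gaps < merge_gap.

    ``group_means`` is the unweighted mean over member CpGs of the per-CpG
    group means; ``delta`` is third minus first, in percentage points.
    """

    chrom: str
    start_pos: int
    end_pos: int
    member_sites: list[int]  # CpG positions
    site_indices: list[int]  # rows of the source matrix
    group_means: dict[Group, float]
    delta: float

    @property
    def n_cpgs(self) -> int:
        return len(self.member_sites)


def merge_regions(matrix: FilteredCpGMatrix, merge_gap: int = 500) -> list[MergedRegion]:
    """Merge retained CpGs into regions: a new region starts whenever the gap
    to the previous CpG is >= merge_gap ("less than 500 bp" merges, taken
    strictly) or the chromosome changes."""
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    mean_first = matrix.site_group_means(Group.FIRST)
    mean_third = matrix.site_group_means(Group.THIRD)

    regions: list[MergedRegion] = []
    run: list[int] = []

    def close_run() -> None:
        idx = np.array(run)
        m1 = float(np.nanmean(mean_first[idx]))
        m3 = float(np.nanmean(mean_third[idx]))
        positions = [matrix.sites[i][1] for i in run]
        regions.append(
            MergedRegion(
                chrom=matrix.sites[run[0]][0],
                start_pos=positions[0],
                end_pos=positions[-1],
                member_sites=positions,
                site_indices=list(run),
                group_means={Group.FIRST: m1, Group.THIRD: m3},
                delta=m3 - m1,
            )
        )

    for i, (chrom, pos) in enumerate(matrix.sites):
        if run:
            prev_chrom, prev_pos = matrix.sites[run[-1]]
            if chrom != prev_chrom or pos - prev_pos >= merge_gap:
                close_run()
                run = []
        run.append(i)
    close_run()
    return regions


def regions_to_table(regions: Iterable[MergedRegion]) -> pd.DataFrame:
    """Tabulate regions: chrom, start, end, n_cpgs, mean_first, mean_third, delta."""
    return pd.DataFrame(
        [
            (r.chrom, r.start_pos, r.end_pos, r.n_cpgs, r.group_means[Group.FIRST], r.group_means[Group.THIRD], r.delta)
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_cpgs", "mean_first", "mean_third", "delta"],
    )


# ---------------------------------------------------------------------------
# group-level summaries: histograms and per-sample means


def _positions_in_intervals(chrom_pos: Sequence[tuple[str, int]], intervals: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Boolean mask: which (chrom, pos) points fall inside any interval
    (1-based closed intervals)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _, _ in intervals}:
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        by_chrom[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    mask = np.zeros(len(chrom_pos), dtype=bool)
    for i, (chrom, pos) in enumerate(chrom_pos):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        j = np.searchsorted(starts, pos, side="right") - 1
        mask[i] = j >= 0 and pos <= ends[j]
    return mask


def _interval_overlaps(regions: Sequence[MergedRegion], intervals: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Boolean mask: which regions overlap any interval by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c in by_chrom:
        by_chrom[c].sort()
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        for s, e in by_chrom.get(r.chrom, ()):
            if s > r.end_pos:
                break
            if e >= r.start_pos:
                mask[i] = True
                break
    return mask


@dataclass
class MethylationHistograms:
    """Group-mean methylation histograms stratified by unit and CGI context,
    plus third-minus-first difference histograms per unit."""

    bin_edges: np.ndarray  # level histogram edges over [0, 100]
    diff_edges: np.ndarray  # difference histogram edges over [-100, 100]
    level_counts: dict[tuple[str, str, Group], np.ndarray]  # (unit, context, group)
    diff_counts: dict[str, np.ndarray]  # unit -> counts

    def level_table(self) -> pd.DataFrame:
        rows = []
        for (unit, context, group), counts in self.level_counts.items():
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], counts):
                rows.append((unit, context, group.value, lo, hi, int(c)))
        return pd.DataFrame(rows, columns=["unit", "context", "group", "bin_low", "bin_high", "count"])


def methylation_histograms(
    matrix: FilteredCpGMatrix,
    regions: Sequence[MergedRegion],
    cgi_track: Sequence[tuple[str, int, int]],
    bin_width: float = 5.0,
) -> MethylationHistograms:
    """Histograms of group-mean methylation for single CpGs and merged
    regions, split by CGI membership, plus the per-unit third-minus-first
    difference histograms.

    A single CpG is in CGI context when its position lies inside a CGI
    interval; a region when it overlaps one by >= 1 bp.
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    diff_edges = np.arange(-100.0, 100.0 + bin_width, bin_width)

    site_means = {g: matrix.site_group_means(g) for g in (Group.FIRST, Group.THIRD)}
    region_means = {g: np.array([r.group_means[g] for r in regions]) for g in (Group.FIRST, Group.THIRD)}
    site_cgi = _positions_in_intervals(matrix.sites, cgi_track)
    region_cgi = _interval_overlaps(regions, cgi_track)

    level_counts: dict[tuple[str, str, Group], np.ndarray] = {}
    for unit, means, cgi_mask in (("single", site_means, site_cgi), ("region", region_means, region_cgi)):
        for context, mask in (("CGI", cgi_mask), ("non_CGI", ~cgi_mask)):
            for g in (Group.FIRST, Group.THIRD):
                vals = means[g][mask]
                vals = vals[~np.isnan(vals)]
                level_counts[(unit, context, g)], _ = np.histogram(np.clip(vals, 0, 100 - 1e-9), bins=edges)

    diff_counts = {}
    for unit, means in (("single", site_means), ("region", region_means)):
        d = means[Group.THIRD] - means[Group.FIRST]
        d = d[~np.isnan(d)]
        diff_counts[unit], _ = np.histogram(np.clip(d, -100, 100 - 1e-9), bins=diff_edges)

    return MethylationHistograms(edges, diff_edges, level_counts, diff_counts)


def sample_mean_methylation(
    samples: Sequence[MethylationCallSet], min_depth: int = 10
) -> tuple[pd.Series, TestResult]:
    """Per-sample mean methylation over the CpGs covered (depth >= min_depth)
    in ALL samples, with an exact two-sided Mann-Whitney U test between the
    trimester groups on those per-sample means."""
    for g in (Group.FIRST, Group.THIRD):
        if sum(s.group == g for s in samples) < 2:
            raise ValueError("need at least 2 samples per group")
    common: set[tuple[str, int]] | None = None
    for s in samples:
        covered = {k for k, c in s.calls.items() if c.depth >= min_depth}
        common = covered if common is None else common & covered
    common = common or set()
    if not common:
        raise ValueError("no CpGs covered in all samples")
    means = pd.Series(
        {s.sample_id: float(np.mean([s.calls[k].level for k in common])) for s in samples},
        name="mean_methylation",
    )
    x = [means[s.sample_id] for s in samples if s.group == Group.FIRST]
    y = [means[s.sample_id] for s in samples if s.group == Group.THIRD]
    return means, exact_mann_whitney(x, y)
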