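"""Coverage parsing, site filtering, region merging and group summaries."""

import numpy as np
import pytest

from methex.methylome import (
    CpGCall,
    Group,
    MethylationCallSet,
    filter_sites,
    merge_regions,
    methylation_histograms,
    read_coverage_file,
    sample_mean_methylation,
    site_group_mean,
)
from methex.simulate import SimConfig, simulate_genome, simulate_methylome

from conftest import make_matrix


def write_cov(tmp_path, name, rows):
    p = tmp_path / name
    p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return p


class TestReadCoverageFile:
    def test_bismark_dialect_recomputes_level_from_counts(self, tmp_path):
        p = write_cov(tmp_path, "a.cov", [("chr1", 100, 100, 70.0, 7, 3)])
        cs = read_coverage_file(p, "s1", Group.FIRST)
        call = cs.calls[("chr1", 100)]
        assert call == CpGCall("chr1", 100, 7, 3)
        assert call.level == pytest.approx(70.0)

    def test_four_column_dialect(self, tmp_path):
        p = write_cov(tmp_path, "b.tsv", [("chr2", 500, 4, 6)])
        cs = read_coverage_file(p, "s1", Group.THIRD)
        assert cs.calls[("chr2", 500)].level == pytest.approx(40.0)

    def test_zero_depth_call_retained_with_undefined_level(self, tmp_path):
        p = write_cov(tmp_path, "c.cov", [("chr1", 100, 100, 0.0, 0, 0)])
        call = read_coverage_file(p, "s1", Group.FIRST).calls[("chr1", 100)]
        assert call.depth == 0 and np.isnan(call.level)

    def test_duplicate_position_errors(self, tmp_path):
        p = write_cov(tmp_path, "d.tsv", [("chr1", 100, 1, 1), ("chr1", 100, 2, 2)])
        with pytest.raises(ValueError, match="line 2"):
            read_coverage_file(p, "s1", Group.FIRST)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = write_cov(tmp_path, "e.tsv", [("chr1", 100, 1, 1), ("chr1", "x", 1)])
        with pytest.raises(ValueError, match="line 2"):
            read_coverage_file(p, "s1", Group.FIRST)


def callsets_from_depths(spec):
    """spec: {sample_id: (group, {(chrom, pos): (n_meth, n_unmeth)})}"""
    out = []
    for sid, (group, calls) in spec.items():
        cs = MethylationCallSet(sid, group)
        for (chrom, pos), (m, u) in calls.items():
            cs.add(CpGCall(chrom, pos, m, u))
        out.append(cs)
    return out


class TestFilterSites:
    def _samples(self, depth, chrom="chr1", n_first=6, n_third=5, n_cov_first=6, n_cov_third=5):
        spec = {}
        for i in range(n_first):
            calls = {(chrom, 100): (depth // 2, depth - depth // 2)} if i < n_cov_first else {}
            spec[f"F{i}"] = (Group.FIRST, calls)
        for i in range(n_third):
            calls = {(chrom, 100): (depth // 2, depth - depth // 2)} if i < n_cov_third else {}
            spec[f"T{i}"] = (Group.THIRD, calls)
        return callsets_from_depths(spec)

    def test_boundary_inclusion_depth_10_in_3_per_group(self):
        m = filter_sites(self._samples(10, n_cov_first=3, n_cov_third=3))
        assert m.sites == [("chr1", 100)]

    def test_depth_below_cutoff_dropped(self):
        m = filter_sites(self._samples(9))
        assert m.n_sites == 0

    def test_sex_chromosome_dropped(self):
        m = filter_sites(self._samples(30, chrom="chrX"))
        assert m.n_sites == 0

    def test_coverage_below_min_samples_in_one_group_dropped(self):
        m = filter_sites(self._samples(30, n_cov_third=2))
        assert m.n_sites == 0

    def test_empty_group_errors(self):
        samples = [s for s in self._samples(30) if s.group == Group.FIRST]
        with pytest.raises(ValueError, match="third"):
            filter_sites(samples)

    def test_filter_monotone_in_thresholds(self, sim_small):
        _, _, callsets = sim_small
        n = [filter_sites(callsets, min_depth=d).n_sites for d in (5, 10, 20, 40)]
        assert n == sorted(n, reverse=True)
        k = [filter_sites(callsets, min_samples_per_group=s).n_sites for s in (1, 3, 5)]
        assert k == sorted(k, reverse=True)

    def test_levels_bounded_and_sites_genomically_sorted(self, sim_small):
        _, _, callsets = sim_small
        m = filter_sites(callsets)
        vals = m.levels[~np.isnan(m.levels)]
        assert vals.min() >= 0.0 and vals.max() <= 100.0
        assert m.sites == sorted(m.sites, key=lambda s: (int(s[0][3:]), s[1]))


def merge_oracle(positions, gap=500):
    """Brute-force transitive clustering by pairwise distance < gap."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i != j and abs(positions[i] - positions[j]) < gap:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(c) for c in clusters.values())


class TestMergeRegions:
    @pytest.mark.parametrize(
        "positions, expected_members",
        [
            ([100, 549], [[100, 549]]),  # gap 449 < 500 merges
            ([100, 600], [[100], [600]]),  # gap 500: strict, splits
            ([100, 400, 1000, 1200], [[100, 400], [1000, 1200]]),
        ],
    )
    def test_merge_rule_examples(self, positions, expected_members):
        m = make_matrix(
            np.full((len(positions), 3), 50.0), np.full((len(positions), 3), 50.0), positions
        )
        regions = merge_regions(m)
        assert [r.member_sites for r in regions] == expected_members

    def test_agrees_with_pairwise_clustering_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(1, 200))
            positions = sorted(set(rng.integers(1, 50_000, size=n).tolist()))
            m = make_matrix(
                np.full((len(positions), 3), 10.0), np.full((len(positions), 3), 20.0), positions
            )
            got = [r.member_sites for r in merge_regions(m)]
            assert got == merge_oracle(positions)

    def test_partition_and_idempotence(self, sim_small):
        _, _, callsets = sim_small
        matrix = filter_sites(callsets)
        regions = merge_regions(matrix)
        assert sum(r.n_cpgs for r in regions) == matrix.n_sites
        for r in regions:
            assert len({matrix.sites[i][0] for i in r.site_indices}) == 1  # one chromosome
            # re-merging a region's own CpGs yields the region unchanged
            sub = make_matrix(
                np.full((r.n_cpgs, 3), 1.0), np.full((r.n_cpgs, 3), 2.0), r.member_sites, chrom=r.chrom
            )
            again = merge_regions(sub)
            assert len(again) == 1 and again[0].member_sites == r.member_sites

    def test_region_delta_is_third_minus_first(self):
        m = make_matrix([[40, 40, 40]], [[60, 60, 60]], [100])
        (r,) = merge_regions(m)
        assert r.delta == pytest.approx(20.0)
        assert r.group_means[Group.FIRST] == pytest.approx(40.0)


class TestSiteGroupMean:
    def test_missing_excluded_from_mean(self):
        m = make_matrix([[70, 80, np.nan]], [[0, 0, 0]], [100])
        assert site_group_mean(m, ("chr1", 100), Group.FIRST) == pytest.approx(75.0)
        assert site_group_mean(m, ("chr1", 100), Group.THIRD) == pytest.approx(0.0)

    def test_single_observation(self):
        m = make_matrix([[100.0, np.nan, np.nan]], [[50, 50, 50]], [100])
        assert site_group_mean(m, ("chr1", 100), Group.FIRST) == pytest.approx(100.0)

    def test_no_observation_gives_nan(self):
        m = make_matrix([[np.nan, np.nan, np.nan]], [[50, 50, 50]], [100])
        assert np.isnan(site_group_mean(m, ("chr1", 100), Group.FIRST))


class TestHistograms:
    def test_all_zero_sites_mass_in_first_bin(self):
        m = make_matrix(np.zeros((4, 3)), np.zeros((4, 3)), [100, 200, 1000, 5000])
        regions = merge_regions(m)
        h = methylation_histograms(m, regions, cgi_track=[])
        single = h.level_counts[("single", "non_CGI", Group.FIRST)]
        assert single[0] == 4 and single[1:].sum() == 0
        zero_bin = np.searchsorted(h.diff_edges, 0.0, side="right") - 1
        assert h.diff_counts["single"][zero_bin] == 4

    def test_single_site_difference_entry(self):
        m = make_matrix([[40, 40, 40]], [[60, 60, 60]], [100])
        h = methylation_histograms(m, merge_regions(m), cgi_track=[])
        bin_idx = np.searchsorted(h.diff_edges, 20.0, side="right") - 1
        assert h.diff_counts["single"][bin_idx] == 1

    def test_planted_shift_moves_difference_mode(self):
        rng = np.random.default_rng(8)
        n = 300
        base = rng.uniform(20, 60, size=n)
        first = base[:, None] + rng.normal(0, 2, size=(n, 6))
        third = base[:, None] + 10 + rng.normal(0, 2, size=(n, 5))
        m = make_matrix(np.clip(first, 0, 100), np.clip(third, 0, 100), positions=np.arange(n) * 1000 + 100)
        h = methylation_histograms(m, merge_regions(m), cgi_track=[])
        mode_bin = np.argmax(h.diff_counts["single"])
        mode_center = (h.diff_edges[mode_bin] + h.diff_edges[mode_bin + 1]) / 2
        assert abs(mode_center - 10.0) <= 5.0

    def test_cgi_context_split(self):
        m = make_matrix(np.full((2, 3), 50.0), np.full((2, 3), 50.0), [100, 5000])
        h = methylation_histograms(m, merge_regions(m), cgi_track=[("chr1", 50, 150)])
        assert h.level_counts[("single", "CGI", Group.FIRST)].sum() == 1
        assert h.level_counts[("single", "non_CGI", Group.FIRST)].sum() == 1


class TestSampleMeanMethylation:
    def _callsets(self, first_means, third_means, n_sites=20, depth=20):
        spec = {}
        for i, mu in enumerate(first_means):
            calls = {("chr1", 100 + j): (int(depth * mu / 100), depth - int(depth * mu / 100)) for j in range(n_sites)}
            spec[f"F{i}"] = (Group.FIRST, calls)
        for i, mu in enumerate(third_means):
            calls = {("chr1", 100 + j): (int(depth * mu / 100), depth - int(depth * mu / 100)) for j in range(n_sites)}
            spec[f"T{i}"] = (Group.THIRD, calls)
        return callsets_from_depths(spec)

    def test_separated_groups_give_exact_extreme_p(self):
        cs = self._callsets([10, 20, 30], [70, 80, 90])
        means, res = sample_mean_methylation(cs)
        assert res.p_value == pytest.approx(0.1)  # extreme 3v3 arrangement
        assert means["T2"] > means["F0"]

    def test_identical_samples_give_p_one(self):
        cs = self._callsets([50, 50, 50], [50, 50, 50])
        _, res = sample_mean_methylation(cs)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_global_hypermethylation_detected(self, sim_small):
        cfg, genome, _ = sim_small
        # re-simulate with a global shift: every promoter and body planted hyper
        import dataclasses

        shifted = dataclasses.replace(
            cfg, frac_dm_promoters=1.0, frac_dm_bodies=1.0, frac_hyper=1.0, frac_coupled=0.0, dm_delta=15.0
        )
        g2 = simulate_genome(shifted)
        calls = simulate_methylome(shifted, g2)
        _, res = sample_mean_methylation(calls)
        assert res.p_value <= 0.05

    def test_fewer_than_two_per_group_errors(self):
        cs = self._callsets([10, 20], [70])
        with pytest.raises(ValueError):
            sample_mean_methylation(cs)
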