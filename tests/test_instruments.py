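"""Instrument selection mechanics: thresholding, windows, clumping, Steiger."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lipidmr.errors import ConfigurationError, MissingVariantError
from lipidmr.instruments import (
    GeneRegion,
    exclude_mhc,
    exclude_region,
    extract_cis_window,
    ld_clump,
    per_snp_strength,
    read_gene_regions,
    steiger_filter,
    threshold_by_pvalue,
)
from lipidmr.simulate import SimulationConfig, simulate_study
from lipidmr.sumstats import LDMatrix

from conftest import make_dataset, make_harmonized, random_psd_correlation


class TestThreshold:
    def test_strictly_below_alpha(self):
        ds = make_dataset(pvalues=[1e-9, 5e-8, 1e-7])
        kept = threshold_by_pvalue(ds, 5e-8)
        assert kept.variant_ids == ["rs1"]

    def test_alpha_one_keeps_everything_below_one(self):
        ds = make_dataset(pvalues=[0.9, 0.5, 0.0001])
        assert len(threshold_by_pvalue(ds, 1.0)) == 3

    def test_empty_dataset_passes_through(self):
        ds = make_dataset(pvalues=[0.5]).subset([False])
        assert len(threshold_by_pvalue(ds, 5e-8)) == 0


class TestRegions:
    region = GeneRegion("GENE", "1", 10_000, 20_000, "pathway")

    @pytest.mark.parametrize(
        "pos,retained",
        [(25_000, True), (24_999, True), (25_001, False), (5_000, True), (4_999, False)],
    )
    def test_cis_window_boundaries_inclusive(self, pos, retained):
        ds = make_dataset(positions=[pos], pvalues=[1e-10])
        out = extract_cis_window(ds, self.region, flank_bp=5000)
        assert (len(out) == 1) is retained

    def test_spec_worked_boundary(self):
        # region [1000, 2000], 5 kb flank: 2000+5000 = 7000 inclusive
        reg = GeneRegion("G", "1", 1000, 2000)
        for pos, keep in [(6_999, True), (7_000, True), (7_001, False)]:
            ds = make_dataset(positions=[pos])
            assert (len(extract_cis_window(ds, reg, 5000)) == 1) is keep

    def test_other_chromosome_excluded(self):
        ds = make_dataset(positions=[15_000], chroms=["2"])
        assert len(extract_cis_window(ds, self.region, 5000)) == 0

    def test_zero_flank_start_boundary(self):
        ds = make_dataset(positions=[10_000])
        assert len(extract_cis_window(ds, self.region, 0)) == 1

    @pytest.mark.parametrize(
        "chrom,pos,removed",
        [
            ("6", 30_000_000, True),
            ("6", 24_000_000, True),
            ("6", 35_000_000, True),
            ("6", 23_999_999, False),
            ("6", 35_000_001, False),
            ("5", 30_000_000, False),
        ],
    )
    def test_mhc_exclusion_window(self, chrom, pos, removed):
        ds = make_dataset(positions=[pos], chroms=[chrom])
        assert (len(exclude_mhc(ds)) == 0) is removed

    def test_selection_operations_commute(self, rng):
        J = 60
        ds = make_dataset(
            pvalues=10.0 ** -rng.uniform(0, 12, J),
            positions=rng.integers(1, 50_000_000, J).astype(float),
            chroms=rng.choice(["1", "6"], J).tolist(),
        )
        reg = GeneRegion("G", "6", 20_000_000, 40_000_000)

        a = threshold_by_pvalue(extract_cis_window(ds, reg, 5000), 1e-5)
        b = extract_cis_window(threshold_by_pvalue(ds, 1e-5), reg, 5000)
        assert a.variant_ids == b.variant_ids

        c = exclude_region(threshold_by_pvalue(ds, 1e-5), "6", 24e6, 35e6)
        d = threshold_by_pvalue(exclude_region(ds, "6", 24e6, 35e6), 1e-5)
        assert c.variant_ids == d.variant_ids

        # idempotence
        assert threshold_by_pvalue(a, 1e-5).variant_ids == a.variant_ids
        assert extract_cis_window(a, reg, 5000).variant_ids == a.variant_ids


def ld_from_r2(ids, r2_pairs):
    """Build an LDMatrix from a dict {(i,j): r2} (indices into ids)."""
    J = len(ids)
    r = np.eye(J)
    for (i, j), r2 in r2_pairs.items():
        r[i, j] = r[j, i] = np.sqrt(r2)
    return LDMatrix(ids, r)


def greedy_clump_oracle(ids, pvalues, r2, threshold):
    """Independent brute-force greedy clumping (list-based walkthrough)."""
    order = sorted(range(len(ids)), key=lambda i: (pvalues[i], ids[i]))
    remaining = list(order)
    picked = []
    while remaining:
        idx = remaining.pop(0)
        picked.append(ids[idx])
        remaining = [j for j in remaining if r2[idx][j] <= threshold]
    return picked


class TestClump:
    def test_three_snp_walkthrough(self):
        ds = make_dataset(pvalues=[1e-10, 1e-9, 1e-8])
        ld = ld_from_r2(ds.variant_ids, {(0, 1): 0.8})
        out = ld_clump(ds, ld, 0.01)
        assert out.variant_ids == ["rs1", "rs3"]

    def test_uncorrelated_all_retained(self):
        ds = make_dataset(pvalues=[1e-10, 1e-9, 1e-8])
        out = ld_clump(ds, ld_from_r2(ds.variant_ids, {}), 0.01)
        assert set(out.variant_ids) == {"rs1", "rs2", "rs3"}

    def test_single_block_keeps_top_snp_only(self):
        ds = make_dataset(pvalues=[1e-8, 1e-12, 1e-9, 1e-10, 1e-11])
        pairs = {(i, j): 0.9 for i in range(5) for j in range(i + 1, 5)}
        out = ld_clump(ds, ld_from_r2(ds.variant_ids, pairs), 0.4)
        assert out.variant_ids == ["rs2"]

    def test_missing_variant_is_named(self):
        ds = make_dataset(pvalues=[1e-10, 1e-9])
        ld = LDMatrix(["rs1"], np.eye(1))
        with pytest.raises(MissingVariantError, match="rs2"):
            ld_clump(ds, ld, 0.01)

    def test_equal_pvalues_break_ties_deterministically(self):
        ds = make_dataset(
            pvalues=[1e-8, 1e-8],
            chroms=["2", "1"],
            positions=[100, 200],
        )
        pairs = {(0, 1): 0.9}
        out = ld_clump(ds, ld_from_r2(ds.variant_ids, pairs), 0.01)
        assert out.variant_ids == ["rs2"]  # chr1 beats chr2 at equal p

    @given(st.integers(0, 400))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(2, 13))
        r = random_psd_correlation(rng, J)
        ids = [f"rs{i + 1}" for i in range(J)]
        pvals = 10.0 ** -rng.uniform(0, 12, J)
        ds = make_dataset(pvalues=pvals, ids=ids, positions=np.arange(J) * 10.0 + 1)
        threshold = float(rng.uniform(0.05, 0.8))
        out = ld_clump(ds, LDMatrix(ids, r), threshold)
        expected = greedy_clump_oracle(ids, pvals, r**2, threshold)
        assert out.variant_ids == expected
        # post-hoc invariant: selected set pairwise r2 <= threshold
        sel = [ids.index(v) for v in out.variant_ids]
        sub = (r**2)[np.ix_(sel, sel)]
        np.fill_diagonal(sub, 0.0)
        assert np.all(sub <= threshold + 1e-12)


class TestStrength:
    def test_f_statistic_arithmetic(self):
        h = make_harmonized([0.1], [0.02], [0.0], [1.0])
        s = per_snp_strength(h, n_x=1002)
        assert s.per_snp_F[0] == pytest.approx(25.0)
        assert s.per_snp_r2_x[0] == pytest.approx(25 / 1025)
        assert s.mean_F == pytest.approx(25.0)

    def test_freq_beta_variance_explained(self):
        h = make_harmonized([0.1], [0.02], [0.0], [1.0])
        h.eaf_x = np.array([0.5])
        s = per_snp_strength(h, n_x=1000, method="freq_beta")
        assert s.per_snp_r2_x[0] == pytest.approx(0.005)

    def test_freq_beta_requires_eaf(self):
        h = make_harmonized([0.1], [0.02], [0.0], [1.0])
        h.eaf_x = np.array([np.nan])
        with pytest.raises(ConfigurationError, match="freq"):
            per_snp_strength(h, n_x=1000, method="freq_beta")

    def test_total_r2_is_sum(self):
        h = make_harmonized([0.1, 0.2], [0.02, 0.02], [0, 0], [1, 1])
        s = per_snp_strength(h, n_x=1000)
        assert s.total_r2_x == pytest.approx(s.per_snp_r2_x.sum())


class TestSteiger:
    def test_direction_rules(self):
        # per-variant (r2_x, r2_y) engineered via beta/se at n=1002
        h = make_harmonized(
            bx=[0.2, 0.1, 0.1],
            sx=[0.02, 0.02, 0.02],
            by=[0.05, 0.3, 0.1],
            sy=[0.02, 0.02, 0.02],
        )
        kept, dropped = steiger_filter(h, n_x=1002, n_y=1002)
        # v1: r2_y < r2_x retained; v2: r2_y > r2_x dropped; v3: equal retained
        assert kept.variant_ids == ["rs1", "rs3"]
        assert dropped == ["rs2"]

    def test_forward_simulation_rarely_filtered(self):
        # pure exposure->outcome causation at large n: high retention
        removed = total = 0
        for k in range(25):
            s = simulate_study(
                SimulationConfig(J=40, theta=0.2, n_x=1e5, n_y=1e5, seed=500 + k)
            )
            kept, dropped = steiger_filter(s.to_harmonized(), 1e5, 1e5)
            removed += len(dropped)
            total += 40
        assert removed / total <= 0.01

    def test_z_test_mode_is_more_conservative(self, rng):
        h = make_harmonized(
            bx=rng.normal(0, 0.05, 50),
            sx=np.full(50, 0.03),
            by=rng.normal(0, 0.05, 50),
            sy=np.full(50, 0.03),
        )
        _, plain = steiger_filter(h, 5000, 5000)
        _, ztest = steiger_filter(h, 5000, 5000, use_z_test=True)
        assert set(ztest) <= set(plain)


def test_bed_regions_converted_to_one_based(tmp_path):
    p = tmp_path / "panel.bed"
    p.write_text("chr22\t37621310\t37640305\tRAC2\trho_gtpase\n")
    regions = read_gene_regions(p)
    assert regions[0].start == 37621311  # BED 0-based start + 1
    assert regions[0].end == 37640305
    assert regions[0].pathway_label == "rho_gtpase"
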