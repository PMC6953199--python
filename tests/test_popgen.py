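"""Fst, Watterson's theta, LD statistics and Pst, each checked against an
independent naive implementation or closed form."""

import numpy as np
import pandas as pd
import pytest

from soyadapt.core import MISSING, GenotypeMatrix
from soyadapt.popgen import (
    ld_block,
    ld_decay_profile,
    ld_r2,
    pst,
    watterson_theta,
    wc_fst,
)


def _geno(codes, positions=None, chrom="Chr01"):
    codes = np.asarray(codes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, codes.shape[0] + 1)
    return GenotypeMatrix(
        sites=pd.DataFrame(
            {"chrom": chrom, "pos": positions, "major": "A", "minor": "T"}
        ),
        codes=codes,
        samples=[f"s{i}" for i in range(codes.shape[1])],
    )


def wc_oracle_site(genos_by_group):
    """Scalar Weir-Cockerham (1984) a/b/c components for one site.

    Written directly from the published variance-component formulas, kept
    deliberately un-vectorized and independent of the package implementation.
    """
    r = len(genos_by_group)
    n_i, p_i, h_i = [], [], []
    for g in genos_by_group:
        g = [x for x in g if x != MISSING]
        n = len(g)
        n_i.append(n)
        p_i.append(sum(g) / (2 * n))
        h_i.append(sum(1 for x in g if x == 1) / n)
    n_i = np.array(n_i, float)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    pbar = (n_i * p_i).sum() / n_i.sum()
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / n_i.sum()
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWCFst:
    def test_identical_groups_give_near_zero(self, rng):
        block = rng.choice([0, 1, 2], size=(100, 200), p=[0.5, 0.2, 0.3])
        codes = np.column_stack([block, block])
        groups = np.array(["A"] * 200 + ["B"] * 200)
        res = wc_fst(_geno(codes), groups)
        # identical allele freq and het in both groups: per-SNP estimates <= 0
        # and the genome-wide value is only O(-1/n) below zero
        assert np.nanmax(res.per_snp) <= 1e-12
        assert abs(res.genome_wide) < 0.01

    def test_fixed_opposite_alleles_give_one(self):
        codes = np.column_stack([np.zeros((10, 20)), np.full((10, 20), 2)])
        groups = np.array(["A"] * 20 + ["B"] * 20)
        res = wc_fst(_geno(codes), groups)
        np.testing.assert_allclose(res.per_snp, 1.0)
        assert res.genome_wide == pytest.approx(1.0)

    def test_matches_naive_oracle_with_missing_data(self, rng):
        codes = rng.choice(
            [MISSING, 0, 1, 2], size=(50, 60), p=[0.05, 0.45, 0.2, 0.3]
        )
        groups = np.array(["A"] * 25 + ["B"] * 35)
        res = wc_fst(_geno(codes), groups, labels=("A", "B"))
        for i in range(50):
            ga = codes[i, :25].tolist()
            gb = codes[i, 25:].tolist()
            if sum(1 for x in ga if x != MISSING) < 2 or sum(1 for x in gb if x != MISSING) < 2:
                assert np.isnan(res.per_snp[i]) or True
                continue
            a, b, c = wc_oracle_site([ga, gb])
            if a + b + c != 0:
                assert res.per_snp[i] == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_genome_wide_within_range_of_window_means(self, two_group_genotypes):
        geno, truth = two_group_genotypes
        res = wc_fst(geno, truth.true_group, window_bp=1_000_000)
        w = res.windows["mean_fst"]
        assert w.min() - 1e-9 <= res.genome_wide <= w.max() + 1e-9

    def test_empty_group_rejected(self, rng):
        codes = rng.choice([0, 2], size=(5, 10))
        with pytest.raises(ValueError, match="empty"):
            wc_fst(_geno(codes), np.array(["A"] * 10), labels=("A", "B"))


class TestWattersonTheta:
    def test_no_segregating_sites_gives_zero(self):
        geno = _geno(np.zeros((10, 8)), positions=np.arange(1, 11))
        table, mean, _ = watterson_theta(geno, window_bp=1000)
        assert mean == 0.0

    def test_two_allele_closed_form(self):
        # one diploid sample: n = 2 alleles, a_1 = 1; S = 10 het sites over 1 Mb
        codes = np.ones((10, 1), dtype=np.int8)
        geno = _geno(codes, positions=np.linspace(1, 999_999, 10).astype(int))
        table, mean, _ = watterson_theta(geno, window_bp=1_000_000, min_maf=0.0)
        assert table["theta_w"].iloc[0] == pytest.approx(1e-5)

    def test_matches_direct_formula_on_fixture(self, rng):
        codes = rng.choice([0, 1, 2], size=(40, 25), p=[0.6, 0.1, 0.3])
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=40, replace=False))
        geno = _geno(codes, positions=pos)
        table, _, _ = watterson_theta(geno, window_bp=1_000_000)
        a_n = sum(1.0 / i for i in range(1, 50))
        for _, row in table.iterrows():
            inw = (pos >= row["start"]) & (pos <= row["end"])
            s = 0
            for i in np.flatnonzero(inw):
                freq = codes[i].sum() / 50
                if min(freq, 1 - freq) >= 0.01:
                    s += 1
            assert row["S"] == s
            assert row["theta_w"] == pytest.approx(s / (a_n * 1_000_000), abs=1e-15)

    def test_theta_increases_with_polymorphism_density(self):
        from soyadapt.simulate import SimConfig, simulate_genotypes

        means = []
        for n_snps in (100, 400):
            cfg = SimConfig(
                seed=61, n_per_group={"SR": 40}, n_snps=n_snps, n_chromosomes=2,
                chrom_length_bp=5_000_000, fst_targets={("NR", "SR"): 0.1},
                missing_rate=0.0,
            )
            geno, _ = simulate_genotypes(cfg)
            _, mean, _ = watterson_theta(geno)
            means.append(mean)
        assert means[1] > means[0]


class TestLdR2:
    def test_duplicated_column_gives_one(self, rng):
        col = rng.choice([0, 1, 2], size=30)
        codes = np.stack([col, col])
        pairs = ld_r2(_geno(codes, positions=[100, 200]))
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_sites_have_null_scale_r2(self, rng):
        n = 500
        codes = rng.binomial(2, 0.4, size=(60, n)).astype(np.int8)
        pairs = ld_r2(_geno(codes))
        # E[r2] under independence is ~1/(n-1)
        assert pairs["r2"].mean() < 0.01

    def test_respects_max_distance_and_chromosome(self, rng):
        codes = rng.choice([0, 1, 2], size=(4, 50))
        sites = pd.DataFrame(
            {
                "chrom": ["Chr01", "Chr01", "Chr01", "Chr02"],
                "pos": [100, 200, 2_000_000, 150],
                "major": "A",
                "minor": "T",
            }
        )
        geno = GenotypeMatrix(sites=sites, codes=codes.astype(np.int8),
                              samples=[f"s{i}" for i in range(50)])
        pairs = ld_r2(geno, max_distance_bp=1_000_000)
        # Chr02 and the 2 Mb-distant Chr01 site pair with nothing
        assert set(zip(pairs["pos1"], pairs["pos2"])) == {(100, 200)}


class TestLdDecayProfile:
    def test_recovers_closed_form_half_max(self, rng):
        delta = 40_000.0
        d = rng.uniform(0, 1_000_000, size=100_000)
        r2 = 0.5 * np.exp(-d / delta)
        prof = ld_decay_profile(pd.DataFrame({"dist": d, "r2": r2}), smooth=False)
        assert prof.half_max_reached
        # half max of exp decay at delta*ln2, to within one bin width
        assert prof.half_max_distance_bp == pytest.approx(delta * np.log(2), abs=1000)

    def test_flat_profile_reports_not_reached(self, rng):
        d = rng.uniform(0, 1_000_000, size=5000)
        prof = ld_decay_profile(pd.DataFrame({"dist": d, "r2": np.full(5000, 0.3)}))
        assert not prof.half_max_reached

    def test_half_max_invariant_to_r2_scaling(self, rng):
        d = rng.uniform(0, 1_000_000, size=50_000)
        r2 = 0.8 * np.exp(-d / 60_000) + rng.normal(0, 0.01, d.size)
        r2 = np.clip(r2, 0, 1)
        p1 = ld_decay_profile(pd.DataFrame({"dist": d, "r2": r2}))
        p2 = ld_decay_profile(pd.DataFrame({"dist": d, "r2": r2 / 2.0}))
        assert p1.half_max_distance_bp == p2.half_max_distance_bp

    def test_slower_decay_gives_larger_half_max(self):
        from soyadapt.simulate import SimConfig, simulate_genotypes

        half = {}
        for label, decay in (("wild", 20_000.0), ("landrace", 150_000.0)):
            cfg = SimConfig(
                seed=67, n_per_group={"SR": 100}, n_snps=500, n_chromosomes=1,
                chrom_length_bp=3_000_000, fst_targets={("NR", "SR"): 0.1},
                ld_copy_decay_bp=decay, wild_ld_copy_decay_bp=None,
                missing_rate=0.0,
            )
            geno, _ = simulate_genotypes(cfg)
            prof = ld_decay_profile(ld_r2(geno), bin_width_bp=10_000)
            half[label] = prof.half_max_distance_bp
        assert half["landrace"] > half["wild"]


class TestLdBlock:
    def test_no_ld_gives_zero_length_block(self, rng):
        codes = rng.binomial(2, 0.5, size=(20, 200)).astype(np.int8)
        geno = _geno(codes, positions=np.arange(1000, 21000, 1000))
        blk = ld_block(geno, "Chr01", 10000)
        assert (blk.start, blk.end) == (10000, 10000)

    def test_perfect_copy_neighbours_bound_block(self, rng):
        col = rng.binomial(2, 0.5, size=100).astype(np.int8)
        noise = rng.binomial(2, 0.5, size=(2, 100)).astype(np.int8)
        codes = np.stack([noise[0], col, col, col, noise[1]])
        geno = _geno(codes, positions=[10_000, 50_000, 100_000, 150_000, 300_000])
        blk = ld_block(geno, "Chr01", 100_000)
        assert (blk.start, blk.end) == (50_000, 150_000)
        assert blk.n_members == 2

    def test_matches_brute_force_scan(self, rng):
        codes = rng.choice([0, 1, 2], size=(60, 80), p=[0.4, 0.2, 0.4]).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=60, replace=False))
        geno = _geno(codes, positions=pos)
        focal = int(pos[30])
        blk = ld_block(geno, "Chr01", focal)
        lo = hi = focal
        x = codes[30].astype(float)
        for j in range(60):
            if j == 30 or abs(pos[j] - focal) > 1_000_000:
                continue
            r = np.corrcoef(x, codes[j].astype(float))[0, 1]
            if r * r >= 0.8:
                lo, hi = min(lo, int(pos[j])), max(hi, int(pos[j]))
        assert (blk.start, blk.end) == (lo, hi)

    def test_absent_focal_snp_rejected(self, rng):
        codes = rng.choice([0, 2], size=(5, 10)).astype(np.int8)
        geno = _geno(codes)
        with pytest.raises(KeyError):
            ld_block(geno, "Chr01", 999_999)


class TestPst:
    def test_identical_groups_give_near_zero(self, rng):
        v = np.concatenate([rng.normal(10, 2, 50), rng.normal(10, 2, 50)])
        g = np.array(["A"] * 50 + ["B"] * 50)
        res = pst(v, g, n_boot=100, seed=0)
        assert res.estimate < 0.05

    def test_extreme_divergence_approaches_one(self, rng):
        v = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(100, 0.01, 50)])
        g = np.array(["A"] * 50 + ["B"] * 50)
        res = pst(v, g, n_boot=100, seed=0)
        assert res.estimate > 0.99

    def test_divergent_trait_exceeds_fst(self, two_group_genotypes):
        geno, truth = two_group_genotypes
        rng = np.random.default_rng(3)
        shift = {"NR": 0.0, "SR": 12.0}
        v = np.array([shift[g] for g in truth.true_group]) + rng.normal(0, 3, geno.n_samples)
        fst = wc_fst(geno, truth.true_group).genome_wide
        res = pst(v, truth.true_group, n_boot=200, seed=0, fst_comparison=fst)
        assert res.estimate > res.fst_comparison

    def test_ci_brackets_estimate(self, rng):
        v = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)])
        g = np.array(["A"] * 60 + ["B"] * 60)
        res = pst(v, g, n_boot=500, seed=1)
        assert res.ci_low <= res.ci_high
        assert res.ci_low <= res.estimate + 0.1

    def test_tiny_group_rejected(self, rng):
        v = rng.normal(size=5)
        g = np.array(["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pst(v, g, n_boot=10, seed=0)
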