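"""Genotype-caller rule tests, including a brute-force truth-table oracle,
and the filtering cascade with oracle recomputations and idempotence."""

import numpy as np
import pandas as pd
import pytest

from soyadapt.calling import (
    call_genotype,
    call_matrix,
    discover_sites,
    filter_samples,
    filter_sites_post,
    filter_sites_pre,
    impute,
)
from soyadapt.core import MISSING, AlleleDepthMatrix, GenotypeMatrix
from soyadapt.simulate import SimConfig, simulate_genotypes, simulate_read_depths


def rule_oracle(major: int, minor: int, other: int) -> int:
    """Independent, clause-by-clause restatement of the calling rules."""
    from fractions import Fraction

    total = major + minor + other
    if total == 0:
        return MISSING
    # homozygous: the strictly-more-reads allele has >=2 reads and >=90%
    if major > minor and major >= 2 and Fraction(major, total) >= Fraction(9, 10):
        return 0
    if minor > major and minor >= 2 and Fraction(minor, total) >= Fraction(9, 10):
        return 2
    # heterozygous: both >=1, each >=20%, sum >=5 reads and >=90%
    if (
        major >= 1
        and minor >= 1
        and Fraction(major, total) >= Fraction(1, 5)
        and Fraction(minor, total) >= Fraction(1, 5)
        and major + minor >= 5
        and Fraction(major + minor, total) >= Fraction(9, 10)
    ):
        return 1
    return MISSING


class TestCallGenotype:
    @pytest.mark.parametrize(
        "reads,expected",
        [
            ((9, 1, 0), 0),    # 9 >= 2 and 90% of 10
            ((3, 2, 0), 1),    # both >= 20%, sum 5 >= 5 reads and 100%
            ((1, 0, 0), MISSING),  # major has < 2 reads
            ((0, 0, 0), MISSING),
            ((1, 9, 0), 2),    # homozygous rule applies to the minor allele
            ((2, 2, 0), MISSING),  # tie: het rule only, sum 4 < 5
            ((3, 3, 0), 1),    # tie with sum >= 5
        ],
    )
    def test_stated_rule_examples(self, reads, expected):
        assert call_genotype(*reads) == expected

    def test_exhaustive_truth_table_vs_oracle(self):
        for major in range(21):
            for minor in range(21):
                for other in range(21):
                    got = call_genotype(major, minor, other)
                    want = rule_oracle(major, minor, other)
                    assert got == want, (major, minor, other)

    def test_hom_and_het_rules_never_both_match(self):
        # with totals >= 2 the two clauses are mutually exclusive: 90% + 20%
        # for the other allele exceeds 100%
        for major in range(1, 41):
            for minor in range(1, 41):
                total = major + minor
                hom = max(major, minor) >= 2 and 10 * max(major, minor) >= 9 * total
                het = 5 * major >= total and 5 * minor >= total and total >= 5
                assert not (hom and het and major != minor)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(-1, 2, 0)

    def test_vectorized_caller_matches_scalar(self, rng):
        maj = rng.integers(0, 30, size=(40, 25))
        mnr = rng.integers(0, 30, size=(40, 25))
        oth = rng.integers(0, 5, size=(40, 25))
        depths = AlleleDepthMatrix(
            sites=pd.DataFrame(
                {"chrom": "Chr01", "pos": np.arange(1, 41), "major": "A", "minor": "T"}
            ),
            major=maj,
            minor=mnr,
            other=oth,
            samples=[f"s{i}" for i in range(25)],
        )
        called = call_matrix(depths)
        for i in range(40):
            for s in range(25):
                assert called.codes[i, s] == call_genotype(
                    int(maj[i, s]), int(mnr[i, s]), int(oth[i, s])
                )

    def test_calling_is_per_cell_independent(self, rng):
        maj = rng.integers(0, 20, size=(10, 12))
        mnr = rng.integers(0, 20, size=(10, 12))
        sites = pd.DataFrame(
            {"chrom": "Chr01", "pos": np.arange(1, 11), "major": "A", "minor": "T"}
        )
        base = AlleleDepthMatrix(
            sites=sites, major=maj, minor=mnr, other=np.zeros_like(maj),
            samples=[f"s{i}" for i in range(12)],
        )
        perm = rng.permutation(12)
        permuted = AlleleDepthMatrix(
            sites=sites, major=maj[:, perm], minor=mnr[:, perm],
            other=np.zeros_like(maj), samples=[f"s{i}" for i in perm],
        )
        assert np.array_equal(call_matrix(base).codes[:, perm], call_matrix(permuted).codes)


class TestDiscoverSites:
    def _depths(self, major, minor, other):
        m = np.asarray(major)[:, None] * np.ones((1, 4), dtype=int)
        n = np.asarray(minor)[:, None] * np.ones((1, 4), dtype=int)
        o = np.asarray(other)[:, None] * np.ones((1, 4), dtype=int)
        return AlleleDepthMatrix(
            sites=pd.DataFrame(
                {"chrom": "Chr01", "pos": np.arange(1, len(major) + 1),
                 "major": "A", "minor": "T"}
            ),
            major=m, minor=n, other=o, samples=list("abcd"),
        )

    def test_clean_biallelic_site_retained(self):
        depths = self._depths([10], [5], [0])
        assert discover_sites(depths)[0]

    def test_site_below_80pct_biallelic_dropped(self):
        depths = self._depths([5], [2], [3])  # 7/10 = 70%
        assert not discover_sites(depths)[0]

    def test_mask_matches_direct_recomputation(self, rng):
        m = rng.integers(0, 15, size=(50, 8))
        n = rng.integers(0, 15, size=(50, 8))
        o = rng.integers(0, 6, size=(50, 8))
        depths = AlleleDepthMatrix(
            sites=pd.DataFrame(
                {"chrom": "Chr01", "pos": np.arange(1, 51), "major": "A", "minor": "T"}
            ),
            major=m, minor=n, other=o, samples=[f"s{i}" for i in range(8)],
        )
        mask = discover_sites(depths)
        for i in range(50):
            bi = tot = 0
            for s in range(8):
                t = m[i, s] + n[i, s] + o[i, s]
                if t >= 5:
                    bi += m[i, s] + n[i, s]
                    tot += t
            want = tot > 0 and bi / tot >= 0.80
            assert mask[i] == want


def _geno(codes):
    codes = np.asarray(codes, dtype=np.int8)
    return GenotypeMatrix(
        sites=pd.DataFrame(
            {"chrom": "Chr01", "pos": np.arange(1, codes.shape[0] + 1),
             "major": "A", "minor": "T"}
        ),
        codes=codes,
        samples=[f"s{i}" for i in range(codes.shape[1])],
    )


class TestSiteFilters:
    def test_monomorphic_site_dropped(self):
        geno = _geno(np.zeros((1, 50)))
        assert filter_sites_pre(geno).n_sites == 0

    def test_high_het_site_dropped(self):
        row = np.array([1] * 13 + [0] * 37)  # 26% heterozygous
        geno = _geno(row[None, :])
        assert filter_sites_pre(geno).n_sites == 0

    def test_pre_filter_matches_brute_force(self, rng):
        codes = rng.choice([MISSING, 0, 1, 2], size=(80, 40), p=[0.2, 0.5, 0.1, 0.2])
        geno = _geno(codes)
        kept = filter_sites_pre(geno)
        expected = []
        for i in range(80):
            row = codes[i][codes[i] != MISSING]
            if row.size == 0:
                continue
            freq = row.sum() / (2 * row.size)
            maf = min(freq, 1 - freq)
            het = (row == 1).mean()
            miss = (codes[i] == MISSING).mean()
            if maf >= 0.01 and het <= 0.20 and miss <= 0.70:
                expected.append(i + 1)
        assert kept.sites["pos"].tolist() == expected

    def test_pre_filter_idempotent(self, rng):
        codes = rng.choice([MISSING, 0, 1, 2], size=(60, 30), p=[0.2, 0.5, 0.1, 0.2])
        once = filter_sites_pre(_geno(codes))
        twice = filter_sites_pre(once)
        assert np.array_equal(once.codes, twice.codes)

    def test_post_filter_homozygous_minor_boundary(self):
        base = np.array([0] * 60 + [2] * 19 + [1] * 2)
        geno = _geno(base[None, :])
        assert filter_sites_post(geno).n_sites == 0  # 19 < 20
        base20 = np.array([0] * 59 + [2] * 20 + [1] * 2)
        assert filter_sites_post(_geno(base20[None, :])).n_sites == 1

    def test_post_filter_matches_recount(self, rng):
        codes = rng.choice([0, 1, 2], size=(60, 120), p=[0.55, 0.1, 0.35])
        kept = filter_sites_post(_geno(codes))
        expected = []
        for i in range(60):
            hom2 = (codes[i] == 2).sum()
            freq = codes[i].sum() / (2 * 120)
            maf = min(freq, 1 - freq)
            het = (codes[i] == 1).mean()
            if hom2 >= 20 and maf >= 0.01 and het <= 0.20:
                expected.append(i + 1)
        assert kept.sites["pos"].tolist() == expected


class TestFilterSamples:
    def test_high_missing_sample_removed(self):
        codes = np.zeros((20, 3), dtype=np.int8)
        codes[:17, 1] = MISSING  # 85% missing
        kept = filter_samples(_geno(codes))
        assert kept.samples == ["s0", "s2"]

    def test_fully_called_matrix_unchanged(self, rng):
        codes = rng.choice([0, 1, 2], size=(15, 6))
        geno = _geno(codes)
        kept = filter_samples(geno)
        assert kept.samples == geno.samples

    def test_survivor_count_matches_direct_count(self, rng):
        codes = rng.choice([MISSING, 0, 2], size=(40, 25), p=[0.5, 0.3, 0.2])
        geno = _geno(codes)
        expect = int(((codes == MISSING).mean(axis=0) < 0.80).sum())
        if expect == 0:
            with pytest.raises(ValueError):
                filter_samples(geno)
        else:
            assert filter_samples(geno).n_samples == expect

    def test_all_removed_raises(self):
        codes = np.full((10, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="all samples removed"):
            filter_samples(_geno(codes))


class TestImpute:
    def test_mode_fill(self):
        codes = np.array([[0] * 90 + [2] * 10 + [MISSING]], dtype=np.int8)
        filled = impute(_geno(codes), method="mode")
        assert filled.codes[0, -1] == 0
        assert (filled.codes != MISSING).all()

    def test_no_missing_is_identity(self, rng):
        codes = rng.choice([0, 1, 2], size=(20, 10))
        geno = _geno(codes)
        filled = impute(geno, method="mode")
        assert np.array_equal(filled.codes, geno.codes)

    def test_nonmissing_entries_never_change(self, rng):
        codes = rng.choice([MISSING, 0, 1, 2], size=(30, 20), p=[0.1, 0.5, 0.1, 0.3])
        geno = _geno(codes)
        for method in ("mode", "knn-haplotype"):
            filled = impute(geno, method=method)
            keep = codes != MISSING
            assert np.array_equal(filled.codes[keep], codes[keep])
            assert (filled.codes != MISSING).all()

    def test_zero_call_site_raises(self):
        codes = np.full((3, 5), MISSING, dtype=np.int8)
        codes[0] = 0
        codes[2] = 2
        with pytest.raises(ValueError, match="zero calls"):
            impute(_geno(codes), method="mode")

    def test_knn_beats_mode_under_high_ld(self):
        cfg = SimConfig(
            seed=3, n_per_group={"NR": 60, "SR": 60}, n_snps=300,
            n_chromosomes=1, chrom_length_bp=2_000_000,
            ld_copy_decay_bp=500_000.0, wild_ld_copy_decay_bp=None,
            missing_rate=0.0,
        )
        geno, _ = simulate_genotypes(cfg)
        rng = np.random.default_rng(5)
        mask = rng.uniform(size=geno.codes.shape) < 0.05
        hidden = geno.codes.copy()
        masked = geno.codes.copy()
        masked[mask] = MISSING
        masked_geno = _geno_like(geno, masked)
        conc = {}
        for method in ("mode", "knn-haplotype"):
            filled = impute(masked_geno, method=method)
            conc[method] = (filled.codes[mask] == hidden[mask]).mean()
        assert conc["knn-haplotype"] > conc["mode"]


def _geno_like(geno, codes):
    return GenotypeMatrix(sites=geno.sites.copy(), codes=codes, samples=list(geno.samples))
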