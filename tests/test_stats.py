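"""Constituent statistics against brute-force oracles."""

import math

import numpy as np
import pytest

from csskit import daf, delta_daf, fst_per_snp, ehh, ihh, xpehh, compute_constituents
from csskit.stats import (
    StatsError,
    EhhCurve,
    standardize,
    _pop_ihh_chrom,
    _pop_ihh_chrom_python,
)

from conftest import make_panel


class TestDaf:
    def test_all_ancestral_zero(self):
        panel = make_panel(np.zeros((8, 3), dtype=np.int8), breeds=["B"] * 4)
        assert daf(panel, panel.sample_ids).tolist() == [0, 0, 0]

    def test_three_of_twenty(self):
        haps = np.zeros((20, 1), dtype=np.int8)
        haps[:3, 0] = 1
        panel = make_panel(haps, breeds=["B"] * 10)
        assert daf(panel, panel.sample_ids)[0] == pytest.approx(0.15)

    def test_matches_exhaustive_count(self, toy_panel):
        f = daf(toy_panel, toy_panel.sample_ids)
        H = toy_panel.haplotypes
        for j in range(toy_panel.n_snps):
            assert f[j] == pytest.approx(sum(H[:, j]) / H.shape[0])


class TestDeltaDaf:
    def test_duplicated_cohort_content_zero(self, toy_panel):
        # two breeds with identical haplotypes -> ddaf 0 everywhere
        haps = np.tile(toy_panel.haplotypes[:4], (2, 1))
        panel = make_panel(haps, breeds=["A", "A", "B", "B"])
        d = delta_daf(panel, ["s1", "s2"], ["s3", "s4"])
        np.testing.assert_allclose(d, 0)

    def test_fixed_difference_is_one(self):
        haps = np.vstack([np.ones((4, 2)), np.zeros((4, 2))]).astype(np.int8)
        panel = make_panel(haps, breeds=["A", "A", "B", "B"])
        d = delta_daf(panel, ["s1", "s2"], ["s3", "s4"])
        np.testing.assert_allclose(d, 1)

    def test_orientation_antisymmetry(self, toy_panel):
        a = delta_daf(toy_panel, ["s1", "s2"], ["s3", "s4"])
        b = delta_daf(toy_panel, ["s3", "s4"], ["s1", "s2"])
        np.testing.assert_array_equal(a, -b)

    def test_overlapping_cohorts_rejected(self, toy_panel):
        with pytest.raises(StatsError):
            delta_daf(toy_panel, ["s1", "s2"], ["s2", "s3"])


def _wc_theta_literal(p1, p2, n1, n2):
    """Literal transcription of the haploid ANOVA mean squares."""
    N = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / N
    ssb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msb = ssb / (2 - 1)
    ssw = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
    msw = ssw / (N - 2)
    nc = (N - (n1 ** 2 + n2 ** 2) / N) / (2 - 1)
    denom = msb + (nc - 1) * msw
    return 0.0 if denom <= 0 else (msb - msw) / denom


class TestFst:
    def _panel_with_freqs(self, k1, n1, k2, n2):
        """One SNP; k derived of n haplotypes per cohort."""
        col = np.zeros((n1 + n2, 1), dtype=np.int8)
        col[:k1] = 1
        col[n1:n1 + k2] = 1
        breeds = ["A"] * (n1 // 2) + ["B"] * (n2 // 2)
        panel = make_panel(col, breeds=breeds)
        a = [s for s, b in zip(panel.sample_ids, breeds) if b == "A"]
        b = [s for s, b in zip(panel.sample_ids, breeds) if b == "B"]
        return panel, a, b

    def test_fixed_difference_theta_one(self):
        panel, a, b = self._panel_with_freqs(10, 10, 0, 10)
        assert fst_per_snp(panel, a, b)[0] == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        panel, a, b = self._panel_with_freqs(5, 10, 5, 10)
        assert fst_per_snp(panel, a, b)[0] <= 0

    def test_random_tables_match_literal_oracle(self):
        """20 random 2x2 allele-count tables vs the mean-square formulas."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n1, n2 = 2 * rng.integers(3, 12, 2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            if k1 == 0 and k2 == 0 or k1 == n1 and k2 == n2:
                continue
            panel, a, b = self._panel_with_freqs(k1, int(n1), k2, int(n2))
            got = fst_per_snp(panel, a, b)[0]
            want = _wc_theta_literal(k1 / n1, k2 / n2, n1, n2)
            assert got == pytest.approx(want, abs=1e-12)

    def test_orientation_symmetric(self, toy_panel):
        a = fst_per_snp(toy_panel, ["s1", "s2"], ["s3", "s4"])
        b = fst_per_snp(toy_panel, ["s3", "s4"], ["s1", "s2"])
        np.testing.assert_array_equal(a, b)

    def test_monomorphic_site_zero(self):
        panel, a, b = self._panel_with_freqs(0, 10, 0, 10)
        assert fst_per_snp(panel, a, b)[0] == 0.0

    def test_hudson_fixed_difference_one(self):
        panel, a, b = self._panel_with_freqs(10, 10, 0, 10)
        assert fst_per_snp(panel, a, b, estimator="hudson")[0] == pytest.approx(1.0)


class TestEhh:
    def test_core_value_is_one(self, toy_panel):
        c = ehh(toy_panel, 1, 1, toy_panel.sample_ids, "downstream")
        assert c.values[0] == 1.0
        assert c.distances_bp[0] == 0.0

    def test_four_carriers_split_two_two(self):
        """EHH after the first flank = (C(2,2)+C(2,2))/C(4,2) = 1/3."""
        haps = np.array([
            [1, 0],
            [1, 0],
            [1, 1],
            [1, 1],
        ], dtype=np.int8)
        panel = make_panel(haps, breeds=["B", "B"])
        c = ehh(panel, 0, 1, panel.sample_ids, "downstream", ehh_cutoff=0.0)
        assert c.values.tolist() == [1.0, pytest.approx(1 / 3)]

    def test_identical_carriers_stay_one(self):
        haps = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.int8), (6, 1))
        panel = make_panel(haps, breeds=["B"] * 3)
        c = ehh(panel, 2, 1, panel.sample_ids, "upstream")
        assert np.all(c.values == 1.0)
        assert len(c.values) == 3  # core + 2 upstream SNPs

    def test_curves_non_increasing(self, small_sim):
        _, panel, _, _ = small_sim
        ids = panel.sample_ids[:20]
        for core in (5, 40, 100):
            allele = 1 if panel.haplotypes_of(ids)[:, core].sum() >= 2 else 0
            for side in ("upstream", "downstream"):
                c = ehh(panel, core, allele, ids, side, ehh_cutoff=0.0,
                        max_extend_bp=2_000_000)
                assert np.all(np.diff(c.values) <= 1e-12)

    def test_single_carrier_errors(self):
        haps = np.zeros((6, 3), dtype=np.int8)
        haps[0, 1] = 1
        panel = make_panel(haps, breeds=["B"] * 3)
        with pytest.raises(StatsError):
            ehh(panel, 1, 1, panel.sample_ids, "downstream")


class TestIhh:
    def test_constant_one_rectangle(self):
        c = EhhCurve(0, "downstream", np.array([0.0, 10_000.0]),
                     np.array([1.0, 1.0]))
        assert ihh(c) == pytest.approx(10_000)

    def test_linear_decay_trapezoid(self):
        c = EhhCurve(0, "downstream", np.array([0.0, 5_000.0, 10_000.0]),
                     np.array([1.0, 0.5, 0.0]))
        assert ihh(c) == pytest.approx(5_000)

    def test_empty_beyond_core_zero(self):
        c = EhhCurve(0, "downstream", np.array([0.0]), np.array([1.0]))
        assert ihh(c) == 0.0

    def test_ihh_monotone_in_cutoff(self, small_sim):
        """Lowering the EHH cutoff can only extend the integral."""
        _, panel, _, _ = small_sim
        ids = panel.sample_ids[:20]
        allele = 1 if panel.haplotypes_of(ids)[:, 50].sum() >= 2 else 0
        vals = []
        for cutoff in (0.5, 0.2, 0.05, 0.0):
            c = ehh(panel, 50, allele, ids, "downstream", ehh_cutoff=cutoff)
            vals.append(ihh(c))
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


class TestXpehh:
    def test_same_haplotype_content_zero(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 2, (8, 30)).astype(np.int8)
        haps = np.vstack([block, block])
        panel = make_panel(haps, breeds=["A"] * 4 + ["B"] * 4)
        ids = panel.sample_ids
        res = xpehh(panel, ids[:4], ids[4:])
        np.testing.assert_allclose(res.raw[~res.excluded], 0, atol=1e-12)

    def test_long_fixed_block_positive_inside(self):
        """A cohort fixed for one long haplotype vs a diverse reference."""
        rng = np.random.default_rng(8)
        fixed = np.tile(rng.integers(0, 2, 12).astype(np.int8), (8, 1))
        diverse = rng.integers(0, 2, (8, 12)).astype(np.int8)
        haps = np.vstack([fixed, diverse])
        panel = make_panel(haps, positions=np.arange(1, 13) * 20_000,
                           breeds=["A"] * 4 + ["B"] * 4)
        ids = panel.sample_ids
        res = xpehh(panel, ids[:4], ids[4:])
        mid = slice(3, 9)
        assert np.all(res.raw[mid][~res.excluded[mid]] > 0)

    def test_standardized_mean_zero_sd_one(self, small_sim):
        _, panel, _, _ = small_sim
        ids = panel.sample_ids
        res = xpehh(panel, ids[:20], ids[20:40])
        ok = ~res.excluded
        assert res.std[ok].mean() == pytest.approx(0, abs=1e-9)
        assert res.std[ok].std() == pytest.approx(1, abs=1e-9)

    def test_compiled_kernel_matches_reference(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, (30, 80)).astype(np.int8)
        pos = np.sort(rng.choice(4_000_000, 80, replace=False)).astype(np.int64)
        fast = _pop_ihh_chrom(H, pos, 0.05, 200_000, 1_000_000, "auto")
        ref = _pop_ihh_chrom_python(H, pos, 0.05, 200_000, 1_000_000)
        np.testing.assert_allclose(fast, ref, rtol=1e-9, atol=1e-9)


class TestConstituents:
    def test_reversed_orientation_identities(self, small_sim):
        _, panel, _, _ = small_sim
        ids = panel.sample_ids
        c = compute_constituents(panel, ids[:15], ids[15:30])
        r = c.reversed()
        np.testing.assert_array_equal(c.fst, r.fst)
        ok = ~c.excluded
        np.testing.assert_allclose(c.ddaf, -r.ddaf)
        np.testing.assert_allclose(c.xpehh_raw[ok], -r.xpehh_raw[ok])
        assert r.candidate_id == c.reference_id
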