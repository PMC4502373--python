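"""Panel I/O, polarization and QC behaviour."""

import numpy as np
import pandas as pd
import pytest

from csskit import (
    read_panel,
    write_vcf,
    write_hap_tsv,
    write_map,
    write_ancestral,
    write_samples,
    qc_filter,
    ibs_matrix,
    ibs_dedupe,
    subsample_per_breed,
)
from csskit.panel import PanelError

from conftest import make_panel


def _write_min_vcf(path, rows, samples=("sA", "sB")):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in rows:
            fh.write(r + "\n")


def _write_aux(tmp_path, snp_ids, ancestral, positions=None):
    positions = positions or list(range(100, 100 + 100 * len(snp_ids), 100))
    m = tmp_path / "map.tsv"
    pd.DataFrame({"chrom": 1, "pos": positions, "snp_id": snp_ids}).to_csv(
        m, sep="\t", index=False)
    a = tmp_path / "anc.tsv"
    pd.DataFrame({"snp_id": snp_ids, "ancestral": ancestral}).to_csv(
        a, sep="\t", index=False)
    return m, a


class TestVcfPolarization:
    def test_ancestral_alt_flips_codes(self, tmp_path):
        """Carriers of the ancestral ALT allele must be coded 0."""
        vcf = tmp_path / "x.vcf"
        _write_min_vcf(vcf, ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1"])
        m, a = _write_aux(tmp_path, ["rs1"], ["G"])
        panel, rep = read_panel(vcf, m, a)
        # REF=A is derived here: A carriers get 1, G carriers get 0
        assert panel.haplotypes[:, 0].tolist() == [1, 0, 0, 0]
        assert panel.snp_map.loc[0, "ancestral"] == "G"
        assert panel.snp_map.loc[0, "derived"] == "A"

    def test_unpolarizable_site_dropped_and_counted(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_min_vcf(vcf, [
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1",
        ])
        m, a = _write_aux(tmp_path, ["rs1", "rs2"], ["A", "T"],
                          positions=[100, 200])
        panel, rep = read_panel(vcf, m, a)
        assert panel.n_snps == 1
        assert rep.n_dropped_unpolarized == 1
        assert rep.n_input_snps == rep.n_retained_snps + 1

    def test_unphased_het_is_hard_error_naming_site(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_min_vcf(vcf, ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1"])
        m, a = _write_aux(tmp_path, ["rs1"], ["A"])
        with pytest.raises(PanelError, match="rs1"):
            read_panel(vcf, m, a)

    def test_unmapped_site_dropped(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        _write_min_vcf(vcf, [
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1",
            "1\t200\tzzz\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1",
        ])
        m, a = _write_aux(tmp_path, ["rs1"], ["A"])
        panel, rep = read_panel(vcf, m, a)
        assert rep.n_dropped_unmapped == 1
        assert panel.n_snps == 1


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_write_read_fixpoint(self, tmp_path, toy_panel, fmt):
        """read(write(panel)) reproduces codes, map and samples exactly."""
        m = tmp_path / "map.tsv"
        a = tmp_path / "anc.tsv"
        s = tmp_path / "samples.tsv"
        write_map(toy_panel, m)
        write_ancestral(toy_panel, a)
        write_samples(toy_panel, s)
        if fmt == "vcf":
            g = tmp_path / "p.vcf"
            write_vcf(toy_panel, g)
        else:
            g = tmp_path / "p.tsv"
            write_hap_tsv(toy_panel, g)
        back, rep = read_panel(g, m, a, s)
        np.testing.assert_array_equal(back.haplotypes, toy_panel.haplotypes)
        assert back.snp_map["snp_id"].tolist() == toy_panel.snp_map["snp_id"].tolist()
        assert back.samples["breed"].tolist() == toy_panel.samples["breed"].tolist()
        # second round trip is a fixpoint too
        if fmt == "vcf":
            g2 = tmp_path / "p2.vcf"
            write_vcf(back, g2)
            again, _ = read_panel(g2, m, a, s)
            np.testing.assert_array_equal(again.haplotypes, back.haplotypes)


class TestQcFilter:
    def test_maf_filter_matches_hand_counts(self):
        """Derived counts {0,1,5,10,20} of 200 haplotypes at MAF>=0.01."""
        counts = [0, 1, 5, 10, 20]
        haps = np.zeros((200, 5), dtype=np.int8)
        for j, c in enumerate(counts):
            haps[:c, j] = 1
        panel = make_panel(haps, breeds=["B"] * 100)
        out, rep = qc_filter(panel, maf_min=0.01)
        assert out.n_snps == 3
        assert rep.n_dropped_maf == 2
        assert rep.n_input_snps == 5
        kept = set(out.snp_map["pos"])
        assert kept == {30_000, 40_000, 50_000}

    def test_maf_zero_drops_only_monomorphic(self):
        haps = np.zeros((20, 3), dtype=np.int8)
        haps[0, 1] = 1
        haps[:10, 2] = 1
        panel = make_panel(haps, breeds=["B"] * 10)
        out, rep = qc_filter(panel, maf_min=0.0)
        assert out.n_snps == 2

    def test_half_frequency_all_retained(self):
        haps = np.zeros((20, 4), dtype=np.int8)
        haps[:10] = 1
        panel = make_panel(haps, breeds=["B"] * 10)
        out, rep = qc_filter(panel, maf_min=0.01)
        assert out.n_snps == 4
        assert rep.n_dropped_maf == 0

    def test_idempotent(self, small_sim):
        _, panel, _, _ = small_sim
        once, _ = qc_filter(panel, 0.01)
        twice, rep = qc_filter(once, 0.01)
        assert twice.n_snps == once.n_snps
        assert rep.n_dropped_maf == 0

    def test_empty_scope_errors(self, toy_panel):
        with pytest.raises(PanelError):
            qc_filter(toy_panel, 0.01, scope_samples=[])


class TestIbs:
    def test_identical_samples_removed(self):
        haps = np.array([[0, 1, 1], [1, 0, 1]] * 3, dtype=np.int8)
        panel = make_panel(haps, breeds=["B"] * 3)
        out, rep = ibs_dedupe(panel, 0.95)
        assert out.n_samples == 1
        assert len(rep.duplicate_pairs) == 2

    def test_opposite_dosage_kept(self):
        haps = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]], dtype=np.int8)
        panel = make_panel(haps, breeds=["B", "B"])
        assert ibs_matrix(panel)[0, 1] == 0.0
        out, _ = ibs_dedupe(panel, 0.95)
        assert out.n_samples == 2

    def test_matrix_matches_pairwise_hand_computation(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, (6, 4)).astype(np.int8)
        panel = make_panel(haps, breeds=["B"] * 3)
        D = haps[0::2] + haps[1::2]
        expected = np.ones((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    expected[i, j] = np.mean((2 - np.abs(D[i] - D[j])) / 2)
        np.testing.assert_allclose(ibs_matrix(panel), expected, atol=1e-12)

    def test_no_pair_above_threshold_after_dedupe(self, small_sim):
        _, panel, _, _ = small_sim
        sub = panel.subset_samples(panel.sample_ids[:20])
        out, _ = ibs_dedupe(sub, 0.9)
        m = ibs_matrix(out)
        np.fill_diagonal(m, 0)
        assert m.max() < 0.9


class TestSubsample:
    def test_cap_above_breed_size_is_identity(self, toy_panel):
        out = subsample_per_breed(toy_panel, 10, seed=1)
        assert out.sample_ids == toy_panel.sample_ids

    def test_cap_is_deterministic_and_exact(self, small_sim):
        _, panel, _, _ = small_sim
        a = subsample_per_breed(panel, 3, seed=5)
        b = subsample_per_breed(panel, 3, seed=5)
        assert a.sample_ids == b.sample_ids
        assert (a.samples.groupby("breed").size() == 3).all()

    def test_different_seeds_same_counts_different_subsets(self, small_sim):
        _, panel, _, _ = small_sim
        picks = [tuple(subsample_per_breed(panel, 3, seed=s).sample_ids)
                 for s in range(5)]
        for p in picks:
            assert len(p) == 3 * panel.samples["breed"].nunique()
        assert len(set(picks)) > 1
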