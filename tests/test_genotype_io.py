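import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxeset import (
    GenotypeMatrix,
    hwe_test,
    map_gene_windows,
    mean_impute,
    pi_hat,
    qc_filter,
    read_gene_table,
    read_matrix_tsv,
    read_plink_raw,
    relatedness_filter,
)


class TestHWE:
    @pytest.mark.parametrize("counts,expected", [
        ((25, 50, 25), 1.0),            # exact HWE proportions
        ((100, 0, 0), 1.0),             # monomorphic convention
        ((0, 0, 100), 1.0),
    ])
    def test_exact_fit_and_monomorphic(self, counts, expected):
        assert hwe_test(*counts) == pytest.approx(expected)

    def test_all_heterozygote_excess(self):
        # at f = 0.5 the expected counts are 25/50/25, so (0,100,0) gives
        # chi-square 25+50+25 = 100
        from scipy.stats import chi2
        p = hwe_test(0, 100, 0)
        assert p == pytest.approx(chi2.sf(100, 1), rel=1e-12)
        assert p == pytest.approx(1.54e-23, rel=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    @given(naa=st.integers(0, 200), nab=st.integers(0, 200), nbb=st.integers(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_reflection_invariance(self, naa, nab, nbb):
        """Swapping the allele labels cannot change the HWE p-value."""
        if naa + nab + nbb == 0:
            return
        assert hwe_test(naa, nab, nbb) == pytest.approx(hwe_test(nbb, nab, naa), rel=1e-9)


class TestGenotypeMatrix:
    def test_sorted_and_maf(self, small_gm):
        assert list(small_gm.snps["pos"]) == [100, 300, 150]
        assert list(small_gm.snps["chrom"]) == ["1", "1", "2"]
        assert np.all(small_gm.maf <= 0.5)

    def test_major_minor_flip(self):
        snps = pd.DataFrame({"id": ["a"], "chrom": ["1"], "pos": [1],
                             "minor_allele": ["A"], "major_allele": ["G"]})
        gm = GenotypeMatrix(["s1", "s2"], snps, np.array([[2.0], [1.0]]))
        # raw frequency 0.75 > 0.5 -> counts reflected, labels swapped
        assert gm.counts[:, 0].tolist() == [0.0, 1.0]
        assert gm.snps.loc[0, "minor_allele"] == "G"
        assert gm.maf[0] == pytest.approx(0.25)

    def test_rejects_bad_entries(self):
        snps = pd.DataFrame({"id": ["a"], "chrom": ["1"], "pos": [1],
                             "minor_allele": ["A"], "major_allele": ["G"]})
        with pytest.raises(ValueError):
            GenotypeMatrix(["s1"], snps, np.array([[3.0]]))

    def test_mean_impute(self, small_gm):
        filled = mean_impute(small_gm.counts)
        assert not np.isnan(filled).any()
        col = small_gm.counts[:, 2]
        assert filled[np.isnan(col), 2] == pytest.approx(np.nanmean(col))


class TestQCFilter:
    def _gm(self, counts):
        L = counts.shape[1]
        snps = pd.DataFrame({"id": [f"v{i}" for i in range(L)], "chrom": "1",
                             "pos": np.arange(1, L + 1), "minor_allele": "A",
                             "major_allele": "B"})
        return GenotypeMatrix([f"s{i}" for i in range(len(counts))], snps, counts)

    def test_callrate_boundary(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(100, 2)).astype(float)
        counts[:6, 0] = np.nan   # 94% call rate -> removed
        counts[:5, 1] = np.nan   # exactly 95% -> retained
        gm = self._gm(counts)
        out, rep = qc_filter(gm)
        assert rep.n_removed_callrate == 1
        assert "v1" in set(out.snps["id"])
        assert "v0" not in set(out.snps["id"])

    def test_hwe_removal(self):
        rng = np.random.default_rng(1)
        good = rng.integers(0, 3, size=(100, 1)).astype(float)
        bad = np.ones((100, 1))  # all heterozygous: p ~ 1.5e-23
        gm = self._gm(np.hstack([good, bad]))
        out, rep = qc_filter(gm)
        assert rep.n_removed_hwe == 1
        assert out.n_snps == 1

    def test_monomorphic_removal_and_identity(self):
        rng = np.random.default_rng(2)
        counts = np.hstack([rng.integers(0, 3, size=(50, 2)).astype(float),
                            np.zeros((50, 1))])
        out, rep = qc_filter(self._gm(counts))
        assert rep.n_removed_monomorphic == 1
        # clean matrix passes unchanged
        out2, rep2 = qc_filter(out)
        assert rep2.n_removed_callrate == rep2.n_removed_hwe == rep2.n_removed_monomorphic == 0
        np.testing.assert_array_equal(out2.counts, out.counts)

    def test_idempotent(self, sim_gm):
        once, _ = qc_filter(sim_gm)
        twice, rep = qc_filter(once)
        assert rep.n_retained == once.n_snps
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestRelatedness:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0, 0, 0.0), (0, 1, 1.0), (0.5, 0.25, 0.5), (1.0, 0.0, 0.5),
    ])
    def test_pi_hat(self, p1, p2, expected):
        assert pi_hat(p1, p2) == pytest.approx(expected)

    def test_pi_hat_validates_simplex(self):
        with pytest.raises(ValueError):
            pi_hat(0.8, 0.5)
        with pytest.raises(ValueError):
            pi_hat(-0.1, 0.2)

    def test_filter_single_pair_and_boundary(self):
        assert relatedness_filter([("A", "B", 0.5)]) == {"B"}
        assert relatedness_filter([("A", "B", 0.1)]) == set()  # strictly >

    def test_filter_shared_member(self):
        # removing B resolves both flagged pairs (minimal vertex cover)
        assert relatedness_filter([("A", "B", 0.3), ("B", "C", 0.3)]) == {"B"}

    def test_filter_clears_all_pairs(self):
        rng = np.random.default_rng(3)
        names = [f"s{i}" for i in range(12)]
        pairs = [(a, b, rng.uniform(0, 0.4)) for i, a in enumerate(names)
                 for b in names[i + 1:]]
        removed = relatedness_filter(pairs, threshold=0.1)
        for a, b, s in pairs:
            if s > 0.1:
                assert a in removed or b in removed


class TestGeneWindows:
    def test_published_window_example(self):
        """A 4-SNP pseudogene region: 50 kb flanks and inclusive assignment."""
        snps = pd.DataFrame({
            "id": ["rs74249839", "rs7183805", "rs16973457", "rs4238534", "far"],
            "chrom": ["15"] * 4 + ["15"],
            "pos": [82537997, 82539431, 82563991, 82564555, 90000000],
            "minor_allele": ["G", "A", "T", "T", "A"],
            "major_allele": ["T", "G", "C", "C", "B"],
        })
        counts = np.tile([0.0, 1.0, 2.0, 1.0], (5, 1)).T
        gm = GenotypeMatrix([f"s{i}" for i in range(4)], snps, counts)
        genes = pd.DataFrame({"gene_id": ["ADAMTS7P1"], "chrom": ["15"],
                              "start": [82585621], "end": [82626915]})
        win = map_gene_windows(genes, gm, flank=50_000)[0]
        assert (win.window_start, win.window_end) == (82535621, 82676915)
        assert win.n_snps == 4

    def test_clamp_and_inclusive_bounds(self, small_gm):
        genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["1"],
                              "start": [10_000], "end": [20_000]})
        win = map_gene_windows(genes, small_gm, flank=50_000)[0]
        assert win.window_start == 1
        # SNP exactly at window_end is assigned
        genes2 = pd.DataFrame({"gene_id": ["g2"], "chrom": ["1"],
                               "start": [50], "end": [90]})
        win2 = map_gene_windows(genes2, small_gm, flank=10)[0]
        assert 0 in win2.snp_indices  # pos 100 == window_end

    def test_flank_zero_exact(self, small_gm):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1"],
                              "start": [100], "end": [299]})
        win = map_gene_windows(genes, small_gm, flank=0)[0]
        assert list(win.snp_indices) == [0]

    def test_empty_window_and_malformed_row(self, small_gm):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["9"],
                              "start": [1], "end": [100]})
        assert map_gene_windows(genes, small_gm)[0].n_snps == 0
        bad = pd.DataFrame({"gene_id": ["g"], "chrom": ["1"],
                            "start": [500], "end": [100]})
        with pytest.raises(ValueError, match="row 1"):
            map_gene_windows(bad, small_gm)


class TestReaders:
    def test_matrix_tsv_roundtrip(self, tmp_path, sim_gm):
        path = tmp_path / "g.tsv"
        df = pd.DataFrame(sim_gm.counts, columns=sim_gm.snps["id"])
        df.insert(0, "IID", sim_gm.samples)
        df.to_csv(path, sep="\t", index=False)
        info = sim_gm.snps[["id", "chrom", "pos", "minor_allele", "major_allele"]]
        back = read_matrix_tsv(path, info)
        np.testing.assert_allclose(back.counts, sim_gm.counts)
        assert back.samples == sim_gm.samples

    def test_plink_raw(self, tmp_path):
        raw = tmp_path / "g.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C\n"
            "f1 s1 0 0 1 -9 0 2\n"
            "f2 s2 0 0 2 -9 1 NA\n"
            "f3 s3 0 0 1 -9 2 0\n")
        gm = read_plink_raw(raw)
        assert gm.samples == ["s1", "s2", "s3"]
        assert gm.n_snps == 2
        assert np.isnan(gm.counts).sum() == 1
        assert set(gm.snps["id"]) == {"rs1", "rs2"}

    def test_gene_table_bed_conversion(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        tsv.write_text("gene_id\tchrom\tstart\tend\nG1\t1\t1000\t2000\n")
        g = read_gene_table(tsv)
        assert g.loc[0, "start"] == 1000
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999\t2000\tG1\n")
        gb = read_gene_table(bed, bed=True)
        # BED 0-based half-open -> identical 1-based inclusive interval
        pd.testing.assert_frame_equal(g, gb)

    def test_vcf_reader(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n")
        from gxeset import read_matrix_tsv  # noqa: F401  (import check only)
        from gxeset.genotype_io import read_vcf
        gm = read_vcf(vcf)
        assert gm.n_snps == 2 and gm.n_samples == 3
        assert np.isnan(gm.counts).sum() == 1
        np.testing.assert_allclose(gm.counts[:, 0], [0, 1, 2])
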