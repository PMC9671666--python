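"""Core data model: VCF I/O, polarization, frequencies, windows, jackknife, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apomixkit import core
from apomixkit.core import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
    bh_fdr,
    block_jackknife,
    make_windows,
    polarize_by_outgroup,
    ratio_jackknife,
)
from apomixkit.vcfio import read_vcf

VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=SIFT,Number=1,Type=Float,Description="x">
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\tSIFT=0.4\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
chr1\t300\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-500\tGT\t0/1\t0/0\t1/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadVcf:
    def test_gt_dosage_mapping(self, tiny_vcf):
        vt, gm = read_vcf(tiny_vcf)
        assert gm.samples == ["s1", "s2", "s3"]
        assert list(gm.dosage[:, 0]) == [0, 1, 2]

    def test_missing_gt_is_missing_dosage(self, tiny_vcf):
        _, gm = read_vcf(tiny_vcf)
        assert gm.dosage[0, 1] == MISSING

    def test_del_svlen_sign_normalized(self, tiny_vcf):
        vt, _ = read_vcf(tiny_vcf)
        row = vt.df.iloc[2]
        assert row.vtype == "DEL" and row.svlen == 500

    def test_positions_zero_based(self, tiny_vcf):
        vt, _ = read_vcf(tiny_vcf)
        assert list(vt.pos) == [99, 199, 299]

    def test_unknown_svtype_skipped_with_warning(self, tmp_path):
        text = VCF_TEXT.replace("SVTYPE=DEL", "SVTYPE=WEIRD")
        p = tmp_path / "bad.vcf"
        p.write_text(text)
        with pytest.warns(UserWarning, match="unknown SVTYPE"):
            vt, _ = read_vcf(p)
        assert len(vt) == 2


def _gm(dosage, samples=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(samples, dosage)


def _vt(n, vtype="SNP"):
    return VariantTable(pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n) * 100, "ref": "A", "alt": "G",
        "vtype": vtype, "svlen": np.nan, "sift_score": np.nan,
        "lof_flag": False, "ancestral": "unknown"}))


class TestPolarize:
    def pm(self):
        return PopulationMap({"s0": "in", "s1": "in", "s2": "og", "s3": "og"},
                             {"outgroup": "og"})

    @pytest.mark.parametrize("og_dosages,expected", [
        ((0, 0), "ref"),    # outgroup fixed ancestral
        ((2, 2), "alt"),    # outgroup fixed for ALT: ancestral is the ALT
    ])
    def test_fixed_outgroup(self, og_dosages, expected):
        gm = _gm([[1], [1], [og_dosages[0]], [og_dosages[1]]])
        out = polarize_by_outgroup(_vt(1), gm, self.pm())
        assert out.df["ancestral"].iloc[0] == expected

    def test_polymorphic_outgroup_marked_unknown(self):
        # outgroup freq(alt) = 0.4 > max_og_minor = 0.1 -> excluded
        gm = _gm([[0], [0], [1], [1]])
        gm.dosage[2, 0], gm.dosage[3, 0] = 1, 1  # og freq 0.5... use 0.4 via 5 alleles
        gm = GenotypeMatrix(["s0", "s1", "s2", "s3", "s4"],
                            np.array([[0], [0], [1], [1], [0]], dtype=np.int8))
        pm = PopulationMap({"s0": "in", "s1": "in", "s2": "og", "s3": "og", "s4": "og"},
                           {"outgroup": "og"})
        out = polarize_by_outgroup(_vt(1), gm, pm, max_og_minor=0.1)
        assert out.df["ancestral"].iloc[0] == "unknown"

    def test_all_missing_outgroup_unknown(self):
        gm = _gm([[1], [2], [MISSING], [MISSING]])
        out = polarize_by_outgroup(_vt(1), gm, self.pm())
        assert out.df["ancestral"].iloc[0] == "unknown"

    def test_idempotent(self, small_cohort):
        cfg, vt, gm, pm, _ = small_cohort
        again = polarize_by_outgroup(vt, gm, pm)
        assert (again.df["ancestral"] == vt.df["ancestral"]).all()

    def test_no_outgroup_role_errors(self):
        gm = _gm([[0], [1]])
        pm = PopulationMap({"s0": "a", "s1": "a"})
        with pytest.raises(core.ConfigurationError):
            polarize_by_outgroup(_vt(1), gm, pm)


class TestDerivedFreqs:
    def setup_method(self):
        self.pm = PopulationMap(
            {"a1": "A", "a2": "A", "og": "og"}, {"outgroup": "og"})

    def freqs(self, dosages, min_n=2):
        gm = GenotypeMatrix(["a1", "a2", "og"], np.asarray(dosages, dtype=np.int8))
        vt = _vt(len(dosages[0])).with_ancestral(np.array(["ref"] * len(dosages[0])))
        return core.derived_freqs(gm, vt, self.pm, ["A"], min_n=min_n)

    def test_simple_frequency(self):
        aft = self.freqs([[1], [2], [0]])
        assert aft.p("A")[0] == pytest.approx(3 / 4)

    def test_missing_excluded_from_denominator(self):
        aft = self.freqs([[MISSING], [2], [0]])
        assert aft.p("A")[0] == 1.0
        assert aft.n_alleles["A"].iloc[0] == 2

    def test_min_n_masks(self):
        aft = self.freqs([[MISSING], [2], [0]], min_n=4)
        assert np.isnan(aft.p("A")[0])

    def test_alt_ancestral_flips_scale(self):
        gm = GenotypeMatrix(["a1", "a2", "og"], np.array([[2], [2], [0]], np.int8))
        vt = _vt(1).with_ancestral(np.array(["alt"]))
        aft = core.derived_freqs(gm, vt, self.pm, ["A"])
        assert aft.p("A")[0] == 0.0  # hom-ALT is ancestral here

    def test_frequencies_bounded(self, small_freqs):
        vals = small_freqs.freq.to_numpy()
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 1)).all()


class TestWindows:
    @pytest.mark.parametrize("length,size,step,expected", [
        (100_000, 25_000, 25_000, 4),
        (60_000, 50_000, 50_000, 2),
        (50_000, 25_000, 12_500, 4),
    ])
    def test_window_counts(self, length, size, step, expected):
        w = make_windows({"c": length}, size, step)
        assert len(w) == expected

    def test_partial_final_window_retained(self):
        w = make_windows({"c": 60_000}, 50_000, 50_000)
        assert (w.iloc[-1].start, w.iloc[-1].end) == (50_000, 60_000)

    def test_overlapping_starts(self):
        w = make_windows({"c": 50_000}, 25_000, 12_500)
        assert list(w.start) == [0, 12_500, 25_000, 37_500]


def brute_force_delete1_se(values):
    """Classic unweighted delete-1 jackknife SE of leave-one-out estimates."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    return np.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2))


class TestBlockJackknife:
    def test_matches_classic_delete1(self):
        res = block_jackknife([1.0, 2.0, 3.0])
        assert res.se == pytest.approx(brute_force_delete1_se([1, 2, 3]), rel=1e-12)

    def test_weight_scale_invariance(self):
        loo = [0.2, 0.5, 0.1, 0.4]
        w = np.array([1.0, 2.0, 3.0, 4.0])
        a = block_jackknife(loo, w, estimate=0.3)
        b = block_jackknife(loo, 10 * w, estimate=0.3)
        assert (a.estimate, a.se) == (b.estimate, b.se)

    def test_degenerate_identical_loo(self):
        res = block_jackknife([0.5, 0.5, 0.5], estimate=0.5)
        assert res.degenerate and res.se == 0.0 and res.p == 0.0
        res0 = block_jackknife([0.0, 0.0, 0.0], estimate=0.0)
        assert res0.degenerate and res0.p == 1.0

    def test_ratio_jackknife_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.integers(3, 11)
            num = rng.random(n)
            den = rng.random(n) + 0.5
            res = ratio_jackknife(num, den)
            # independent recomputation: delete each block by hand
            loo = np.array([(num.sum() - num[j]) / (den.sum() - den[j])
                            for j in range(n)])
            est = num.sum() / den.sum()
            w = den
            W = w.sum()
            h = W / w
            tau = h * est - (h - 1) * loo
            theta_j = n * est - np.sum((1 - w / W) * loo)
            se = np.sqrt(np.sum((tau - theta_j) ** 2 / (h - 1)) / n)
            assert res.estimate == pytest.approx(est, rel=1e-12)
            assert res.se == pytest.approx(se, rel=1e-12)

    def test_z_is_estimate_over_se(self):
        res = block_jackknife([1.0, 2.0, 4.0], estimate=2.0)
        assert res.z == pytest.approx(res.estimate / res.se, rel=1e-12)


def brute_force_bh(pvals):
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        q[idx] = prev = min(prev, p[idx] * n / rank)
    return q


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_ties(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_nan_propagates(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = bh_fdr(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_brute_force_oracle(self, pvals):
        assert bh_fdr(pvals) == pytest.approx(brute_force_bh(pvals), abs=1e-12)

    def test_oracle_on_permutations(self):
        base = [0.001, 0.04, 0.2, 0.2, 0.9]
        for perm in itertools.permutations(base):
            assert bh_fdr(list(perm)) == pytest.approx(brute_force_bh(perm))


class TestTabularIO:
    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({"chrom": ["c1", "c2"], "start": [0, 5], "x": [0.25, 1.5]})
        p = tmp_path / "t.tsv"
        core.write_tsv(df, p)
        back = core.read_tsv(p)
        pd.testing.assert_frame_equal(df, back)

    def test_bed5(self, tmp_path):
        df = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100], "D": [0.5]})
        p = tmp_path / "w.bed"
        core.write_bed(df, p, score="D")
        line = p.read_text().strip().split("\t")
        assert line == ["c1", "0", "100", ".", "0.5"]

    def test_empty_table_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["chrom", "start", "end"])
        p = tmp_path / "e.tsv"
        core.write_tsv(df, p)
        assert p.read_text().strip() == "chrom\tstart\tend"
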