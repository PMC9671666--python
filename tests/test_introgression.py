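"""D / f_d / f4 / f-branch / D_xy and ancestry profiling."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from apomixkit import core, synth
from apomixkit.core import GenotypeMatrix, VariantTable
from apomixkit.introgression import (
    TrioSpec,
    ancestry_profile,
    d_xy,
    diagnostic_markers,
    f4,
    f4_ratio,
    f_branch,
    f_d,
    patterson_d,
    site_patterns,
)
from conftest import freq_table


class TestSitePatterns:
    def test_fixed_abba_site(self, trio):
        aft = freq_table([0], [1], [1], [0])
        abba, baba = site_patterns(aft, trio)
        assert (abba[0], baba[0]) == (1.0, 0.0)

    def test_p1_equals_p2_symmetric(self, trio):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        aft = freq_table(p, p, rng.random(50), rng.random(50) * 0.1)
        abba, baba = site_patterns(aft, trio)
        assert abba.sum() == pytest.approx(baba.sum(), rel=1e-12)

    def test_hand_computed_sums(self, trio):
        aft = freq_table([0.2, 0.1], [0.8, 0.1], [0.6, 0.9], [0.0, 0.0])
        abba, baba = site_patterns(aft, trio)
        assert abba.sum() == pytest.approx(0.465, abs=1e-12)
        assert baba.sum() == pytest.approx(0.105, abs=1e-12)


class TestPattersonD:
    def test_hand_computed_d(self, trio):
        aft = freq_table([0.2, 0.1], [0.8, 0.1], [0.6, 0.9], [0.0, 0.0])
        res, _ = patterson_d(aft, trio, n_blocks=2)
        assert res.d == pytest.approx(0.36 / 0.57, abs=1e-9)

    def test_antisymmetry_under_p1_p2_swap(self, small_freqs, trio):
        res, _ = patterson_d(small_freqs, trio)
        swapped = TrioSpec(trio.p2, trio.p1, trio.p3, trio.outgroup)
        res2, _ = patterson_d(small_freqs, swapped)
        assert res2.d == pytest.approx(-res.d, rel=1e-12)

    def test_duplication_invariance(self, trio):
        rng = np.random.default_rng(1)
        p = [rng.random(40) for _ in range(3)] + [rng.random(40) * 0.05]
        aft1 = freq_table(*p)
        aft2 = freq_table(*[np.concatenate([x, x]) for x in p])
        d1, _ = patterson_d(aft1, trio, n_blocks=2)
        d2, _ = patterson_d(aft2, trio, n_blocks=2)
        assert d2.d == pytest.approx(d1.d, rel=1e-12)

    def test_all_masked_flagged_undefined(self, trio):
        aft = freq_table([np.nan], [np.nan], [np.nan], [np.nan])
        res, _ = patterson_d(aft, trio)
        assert res.undefined and np.isnan(res.d)

    def test_null_calibration(self, trio):
        """No planted flow: |Z| < 3 in nearly all replicates."""
        ok = 0
        for seed in range(10):
            cfg = synth.SynthConfig(seed=300 + seed, n_pops=3, samples_per_pop=12,
                                    n_variants=6000)
            vt, gm, truth = synth.simulate_structured_genotypes(cfg)
            pm = synth.population_map(truth, roles={"outgroup": "outgroup"})
            vt = core.polarize_by_outgroup(vt, gm, pm)
            aft = core.derived_freqs(gm, vt, pm, trio.labels)
            res, _ = patterson_d(aft, trio)
            ok += abs(res.jackknife.z) < 3
        assert ok >= 9


class TestFd:
    def win(self, n, spacing=1000):
        return core.make_windows({"chr1": n * spacing}, n * spacing)

    def test_single_site_hand_value(self, trio):
        aft = freq_table([0.0], [0.5], [1.0], [0.0])
        out = f_d(aft, trio, self.win(1), min_sites=1)
        assert out.f_d.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_complete_sharing_gives_one(self, trio):
        rng = np.random.default_rng(2)
        p2 = rng.random(30)
        aft = freq_table(np.zeros(30), p2, p2, np.zeros(30))
        out = f_d(aft, trio, self.win(30), min_sites=1)
        assert out.f_d.iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_negative_d_window_is_nan(self, trio):
        aft = freq_table([0.8], [0.0], [0.9], [0.0])  # BABA-dominated
        out = f_d(aft, trio, self.win(1), min_sites=1)
        assert np.isnan(out.f_d.iloc[0])

    def test_windows_bounded_01(self, small_freqs, trio):
        wins = core.make_windows({"chr1": 10_000_000, "chr2": 10_000_000}, 1_000_000)
        out = f_d(small_freqs, trio, wins)
        vals = out.f_d.dropna()
        assert ((vals >= -1e-9)).all()


class TestF4:
    def test_hand_value(self):
        aft = freq_table([0.8, 0.3], [0.2, 0.5], [0.9, 0.2], [0.1, 0.6])
        assert f4(aft, "pop1", "pop2", "pop3", "outgroup") == pytest.approx(0.28)

    def test_ratio_controls(self):
        cfg = synth.SynthConfig(seed=11, n_pops=4, samples_per_pop=16,
                                n_variants=12000, fst=0.15)
        vt, gm, truth = synth.simulate_structured_genotypes(cfg)
        pm = synth.population_map(truth, roles={"outgroup": "outgroup"})
        vt = core.polarize_by_outgroup(vt, gm, pm)
        aft = core.derived_freqs(gm, vt, pm,
                                 ["pop1", "pop2", "pop3", "pop4", "outgroup"])
        r1 = f4_ratio(aft, a="pop1", b="pop2", c="pop3", x="pop2",
                      outgroup="outgroup")
        r0 = f4_ratio(aft, a="pop1", b="pop2", c="pop3", x="pop3",
                      outgroup="outgroup")
        assert r1.alpha == pytest.approx(1.0, abs=1e-9)  # X = B exactly
        assert abs(r0.alpha) < 0.05                       # X = C: 0 + noise


class TestFbranch:
    def run_fb(self, m, seed, newick="(((pop1,pop2),pop3),outgroup);"):
        cfg = synth.SynthConfig(seed=seed, n_pops=3, samples_per_pop=12,
                                n_variants=6000)
        vt, gm, truth = synth.simulate_structured_genotypes(cfg)
        if m > 0:
            recips = [s for s, p in truth.population_labels.items() if p == "pop2"]
            plan = synth.IntrogressionPlan("pop3", recips, m=m, tract_len=1e6)
            gm, truth = synth.plant_introgression_tracts(
                gm, vt, truth, plan, cfg.contig_lengths, seed=seed + 999)
        pm = synth.population_map(truth, roles={"outgroup": "outgroup"})
        vt = core.polarize_by_outgroup(vt, gm, pm)
        aft = core.derived_freqs(gm, vt, pm, ["pop1", "pop2", "pop3", "outgroup"])
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return f_branch(tree, aft, "outgroup")

    def test_three_leaf_tree_empty(self):
        cfg = synth.SynthConfig(seed=7, n_pops=2, samples_per_pop=8, n_variants=2000)
        vt, gm, truth = synth.simulate_structured_genotypes(cfg)
        pm = synth.population_map(truth, roles={"outgroup": "outgroup"})
        vt = core.polarize_by_outgroup(vt, gm, pm)
        aft = core.derived_freqs(gm, vt, pm, ["pop1", "pop2", "outgroup"])
        tree = dendropy.Tree.get(data="((pop1,pop2),outgroup);", schema="newick")
        res = f_branch(tree, aft, "outgroup")
        assert res.fb.isna().all().all()

    def test_positive_control_planted_flow(self):
        res = self.run_fb(0.15, seed=88)
        assert res.significant.loc["pop2", "pop3"]
        assert res.fb.loc["pop2", "pop3"] > 0

    def test_null_no_significance(self):
        hits = 0
        for seed in range(5):
            res = self.run_fb(0.0, seed=500 + seed)
            z = res.z.to_numpy()
            hits += np.nanmax(np.abs(z)) < 3 if not np.isnan(z).all() else 1
        assert hits >= 4

    def test_polytomy_rejected(self, small_freqs):
        tree = dendropy.Tree.get(data="((pop1,pop2,pop3),outgroup);",
                                 schema="newick")
        with pytest.raises(ValueError, match="bifurcating"):
            f_branch(tree, small_freqs, "outgroup")


class TestDxy:
    def test_single_site_over_accessible(self):
        aft = freq_table([1.0], [0.0], [0.5], [0.0])
        wins = core.make_windows({"chr1": 1000}, 1000)
        out = d_xy(aft, "pop1", "pop2", wins, accessible_sites=[10])
        assert out.d_xy.iloc[0] == pytest.approx(0.1)

    def test_identical_fixed_zero(self):
        aft = freq_table([1.0, 0.0], [1.0, 0.0], [0.5, 0.5], [0.0, 0.0])
        wins = core.make_windows({"chr1": 2000}, 2000)
        out = d_xy(aft, "pop1", "pop2", wins, accessible_sites=[2])
        assert out.d_xy.iloc[0] == 0.0

    def test_half_half_gives_half(self):
        n = 20
        aft = freq_table([0.5] * n, [0.5] * n, [0.5] * n, [0.0] * n)
        wins = core.make_windows({"chr1": n * 1000}, n * 1000)
        out = d_xy(aft, "pop1", "pop2", wins, accessible_sites=[n])
        assert out.d_xy.iloc[0] == pytest.approx(0.5)

    def test_default_denominator_is_window_bp(self):
        aft = freq_table([1.0], [0.0], [0.5], [0.0])
        wins = core.make_windows({"chr1": 1000}, 1000)
        out = d_xy(aft, "pop1", "pop2", wins)
        assert out.d_xy.iloc[0] == pytest.approx(1 / 1000)
        assert out.attrs["denominator"] == "window_bp"


class TestAncestry:
    def build(self, dosages, donor_is_derived=None):
        n = dosages.shape[1]
        vt = VariantTable(pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(n) * 1000, "ref": "A", "alt": "G",
            "vtype": "SNP", "svlen": np.nan, "sift_score": np.nan,
            "lof_flag": False, "ancestral": "ref"}))
        gm = GenotypeMatrix([f"s{i}" for i in range(dosages.shape[0])],
                            dosages.astype(np.int8))
        markers = pd.DataFrame({
            "site_index": np.arange(n), "chrom": "chr1",
            "pos": np.arange(n) * 1000,
            "donor_is_derived": donor_is_derived if donor_is_derived is not None
            else np.ones(n, bool)})
        wins = core.make_windows({"chr1": n * 1000}, n * 1000)
        return gm, vt, markers, wins

    def test_hom_donor_everywhere(self):
        gm, vt, mk, w = self.build(np.full((1, 8), 2))
        prof = ancestry_profile(gm, vt, mk, w)
        assert prof.total.iloc[0] == 1.0

    def test_no_donor_alleles(self):
        gm, vt, mk, w = self.build(np.zeros((1, 8)))
        prof = ancestry_profile(gm, vt, mk, w)
        assert prof.total.iloc[0] == 0.0

    def test_mixed_dosage_arithmetic(self):
        d = np.array([[1] * 5 + [0] * 5])
        d[0, 5:] = 2  # het-donor at 5, hom-OTHER at 5 (donor allele = ref there)
        flip = np.array([True] * 5 + [False] * 5)
        gm, vt, mk, w = self.build(d, donor_is_derived=flip)
        prof = ancestry_profile(gm, vt, mk, w)
        # 5 het (dosage 1) + 5 hom-other (donor dosage 2-2=0) = 5/(2*10)
        assert prof.total.iloc[0] == pytest.approx(0.25)

    def test_no_markers_raises(self, small_freqs):
        with pytest.raises(ValueError, match="min_delta"):
            diagnostic_markers(small_freqs, "pop1", "pop2", min_delta=1.0)

    @pytest.mark.parametrize("m", [0.0, 0.1])
    def test_planted_m_recovery(self, m):
        cfg = synth.SynthConfig(seed=61, n_pops=3, samples_per_pop=24,
                                n_variants=10000, fst=(0.1, 0.1, 0.3),
                                private_fixed={"pop3": 300})
        vt, gm, truth = synth.simulate_structured_genotypes(cfg)
        pop2 = [s for s, p in truth.population_labels.items() if p == "pop2"]
        recips, panel = pop2[:12], pop2[12:]
        plan = synth.IntrogressionPlan("pop3", recips, m=m, tract_len=1e6)
        gm, truth = synth.plant_introgression_tracts(gm, vt, truth, plan,
                                                     cfg.contig_lengths, seed=62)
        labels = truth.population_labels
        pm = core.PopulationMap(
            {**{s: "donor" for s, p in labels.items() if p == "pop3"},
             **{s: "bg" for s in panel},
             **{s: "outgroup" for s, p in labels.items() if p == "outgroup"}},
            {"outgroup": "outgroup"})
        vt = core.polarize_by_outgroup(vt, gm, pm)
        aft = core.derived_freqs(gm, vt, pm, ["donor", "bg"])
        mk = diagnostic_markers(aft, "donor", "bg", min_delta=1.0)
        wins = core.make_windows(cfg.contig_lengths, 500_000)
        prof = ancestry_profile(gm, vt, mk, wins)
        assert prof.total[recips].mean() == pytest.approx(m, abs=0.02)

    def test_fragments_live_in_introgressed_windows(self):
        # one sample hom-donor in one window only
        d = np.zeros((1, 20), dtype=int)
        d[0, :5] = 2
        vt = VariantTable(pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(20) * 1000, "ref": "A", "alt": "G",
            "vtype": "SNP", "svlen": np.nan, "sift_score": np.nan,
            "lof_flag": False, "ancestral": "ref"}))
        gm = GenotypeMatrix(["s0"], d.astype(np.int8))
        mk = pd.DataFrame({"site_index": np.arange(20), "chrom": "chr1",
                           "pos": np.arange(20) * 1000,
                           "donor_is_derived": True})
        wins = core.make_windows({"chr1": 20_000}, 5_000)
        prof = ancestry_profile(gm, vt, mk, wins)
        assert len(prof.fragments) == 1
        frag = prof.fragments.iloc[0]
        assert (frag.start, frag.end) == (0, 5_000)
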