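"""varLD scoring, sliding scans, permutation p-values and I/O round trips."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from transrep.ld_divergence import (
    HaplotypePanel,
    cumulative_envelope,
    group_window_comparison,
    maf_matched_background,
    permutation_pvalue,
    read_vcf,
    signed_r2_matrix,
    sliding_window_scan,
    varld_raw_score,
    write_populations,
    write_vcf,
)
from transrep.synthetic_data import HapSimConfig, gen_two_pop_haplotypes


def make_panel(alleles, population="P", start=100):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_ind = alleles.shape[0] // 2
    return HaplotypePanel(
        sample_ids=[f"{population}{i}" for i in range(n_ind)],
        population=population,
        alleles=alleles,
        snp_ids=[f"s{j}" for j in range(alleles.shape[1])],
        chrom="1",
        pos_bp=np.arange(start, start + alleles.shape[1] * 10, 10),
    )


class TestSignedR2:
    def test_perfectly_coupled_pair(self):
        haps = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        matrix, mono = signed_r2_matrix(haps)
        assert matrix[0, 1] == pytest.approx(1.0)
        assert mono == []

    def test_repulsion_pair_is_minus_one(self):
        haps = np.array([[0, 1], [0, 1], [1, 0], [1, 0]])
        matrix, _ = signed_r2_matrix(haps)
        assert matrix[0, 1] == pytest.approx(-1.0)

    def test_equifrequent_four_gamete_set_is_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        matrix, _ = signed_r2_matrix(haps)
        assert matrix[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_independent_snps_near_zero_at_large_n(self):
        rng = np.random.default_rng(2)
        haps = (rng.random((1000, 2)) < 0.4).astype(np.int8)
        matrix, _ = signed_r2_matrix(haps)
        assert abs(matrix[0, 1]) < 0.05

    def test_monomorphic_snp_zeroed_and_flagged(self):
        haps = np.array([[0, 1], [0, 0], [0, 1], [0, 0]])
        matrix, mono = signed_r2_matrix(haps)
        assert matrix[0, 1] == 0.0
        assert matrix[0, 0] == 1.0
        assert mono == ["0"]

    def test_sign_convention_is_r_times_abs_r(self):
        rng = np.random.default_rng(8)
        haps = (rng.random((200, 5)) < 0.5).astype(np.int8)
        matrix, _ = signed_r2_matrix(haps)
        r = np.corrcoef(haps.astype(float), rowvar=False)
        np.testing.assert_allclose(matrix, np.sign(r) * r * r, atol=1e-12)


class TestVarldScore:
    def test_identical_matrices_score_zero(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert varld_raw_score(m, m) == 0.0

    def test_two_by_two_closed_form(self):
        # eigenvalues of [[1, rho], [rho, 1]] are 1 +/- rho
        m1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        m2 = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert varld_raw_score(m1, m2) == pytest.approx(0.8)

    def test_matches_independent_eigen_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a = rng.normal(size=(50, 200))
            b = rng.normal(size=(50, 200))
            m1 = np.corrcoef(a)
            m2 = np.corrcoef(b)
            ev1 = sorted(scipy.linalg.eigvalsh(m1), reverse=True)
            ev2 = sorted(scipy.linalg.eigvalsh(m2), reverse=True)
            oracle = float(np.sum(np.abs(np.array(ev1) - np.array(ev2))))
            assert varld_raw_score(m1, m2) == pytest.approx(oracle, abs=1e-8)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(14)
        m1 = np.corrcoef(rng.normal(size=(10, 50)))
        m2 = np.corrcoef(rng.normal(size=(10, 50)))
        assert varld_raw_score(m1, m2) >= 0
        assert varld_raw_score(m1, m2) == pytest.approx(
            varld_raw_score(m2, m1))
        perm = rng.permutation(10)
        assert varld_raw_score(m1[np.ix_(perm, perm)],
                               m2[np.ix_(perm, perm)]) == pytest.approx(
            varld_raw_score(m1, m2), abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            varld_raw_score(np.eye(3), np.eye(4))


class TestSlidingScan:
    def test_full_region_yields_121_windows(self, drifted_panels):
        scan = sliding_window_scan(drifted_panels.panel1,
                                   drifted_panels.panel2, 325)
        assert len(scan) == 121
        assert scan["offset"].min() == -300
        assert scan["offset"].max() == 300
        assert (scan["window_snps"] == 50).all()

    def test_self_comparison_scores_zero(self, drifted_panels):
        scan = sliding_window_scan(drifted_panels.panel1,
                                   drifted_panels.panel1, 325)
        assert np.allclose(scan["varld_raw"], 0.0)
        assert np.allclose(scan["het_diff"], 0.0)

    def test_trace_conservation_per_window(self, drifted_panels):
        # sum of eigenvalues of a correlation-type matrix = window size
        m, _ = signed_r2_matrix(drifted_panels.panel1, slice(300, 350))
        assert np.trace(m) == pytest.approx(50.0)
        assert np.linalg.eigvalsh(m).sum() == pytest.approx(50.0)

    def test_het_diff_antisymmetric_varld_symmetric(self, drifted_panels):
        fwd = sliding_window_scan(drifted_panels.panel1,
                                  drifted_panels.panel2, 325)
        rev = sliding_window_scan(drifted_panels.panel2,
                                  drifted_panels.panel1, 325)
        np.testing.assert_allclose(fwd["het_diff"], -rev["het_diff"],
                                   atol=1e-12)
        np.testing.assert_allclose(fwd["varld_raw"], rev["varld_raw"],
                                   atol=1e-9)

    def test_truncated_scan_warns(self, exchangeable_panels):
        with pytest.warns(UserWarning, match="truncated"):
            scan = sliding_window_scan(exchangeable_panels.panel1,
                                       exchangeable_panels.panel2, 60)
        assert len(scan) < 121

    def test_drifted_scores_exceed_exchangeable_scores(self):
        drifted, null = [], []
        for s in range(8):
            base = dict(n_snps=60, n_hap_pool=500, n_per_pop=40,
                        pop_size=200)
            r_d = gen_two_pop_haplotypes(HapSimConfig(
                seed=4000 + s, drift_generations=200, **base))
            r_0 = gen_two_pop_haplotypes(HapSimConfig(
                seed=4100 + s, drift_generations=0, **base))
            for panels, bucket in ((r_d, drifted), (r_0, null)):
                m1, _ = signed_r2_matrix(panels.panel1.alleles[:, 5:55])
                m2, _ = signed_r2_matrix(panels.panel2.alleles[:, 5:55])
                bucket.append(varld_raw_score(m1, m2))
        assert np.median(drifted) > np.median(null)


class TestPermutation:
    def test_pvalue_within_valid_bounds(self, exchangeable_panels):
        p = permutation_pvalue(exchangeable_panels.panel1,
                               exchangeable_panels.panel2,
                               slice(30, 80), n_perm=99, seed=1)
        assert 1 / 100 <= p <= 1.0

    def test_strong_drift_gives_minimal_pvalue(self):
        """Heavily diverged panels hit the smallest achievable p in most
        regions.  Drift is kept short of fixation (whole-haplotype
        Wright-Fisher resampling fixes windows at extreme g, which
        destroys the polymorphism the test statistic needs)."""
        pvals = []
        for seed in range(40):
            result = gen_two_pop_haplotypes(HapSimConfig(
                seed=9900 + seed, n_snps=60, drift_generations=300,
                pop_size=500, n_hap_pool=1000, n_per_pop=100))
            pvals.append(permutation_pvalue(result.panel1, result.panel2,
                                            slice(5, 55), n_perm=99,
                                            seed=seed))
        assert np.mean(np.asarray(pvals) == 1 / 100) >= 0.8

    def test_too_few_individuals_raise(self, exchangeable_panels):
        single = make_panel(np.zeros((2, 60), dtype=np.int8))
        with pytest.raises(ValueError):
            permutation_pvalue(single, single, slice(0, 50))


class TestBackground:
    def test_exact_pool_is_deterministic(self):
        focal = [0.1, 0.2, 0.3]
        panel = [0.11, 0.19, 0.31]
        groups = maf_matched_background(focal, panel, n_groups=5,
                                        group_size=3, seed=5)
        for group in groups:
            assert sorted(group) == [0, 1, 2]

    def test_groups_match_focal_maf_distribution(self):
        rng = np.random.default_rng(19)
        focal = rng.uniform(0.05, 0.5, 47)
        panel = rng.uniform(0.01, 0.5, 5000)
        groups = maf_matched_background(focal, panel, n_groups=40,
                                        group_size=47, seed=7)
        from scipy.stats import mannwhitneyu
        ok = sum(
            mannwhitneyu(focal, panel[g], alternative="two-sided").pvalue
            > 0.05
            for g in groups
        )
        assert ok >= 0.95 * len(groups)

    def test_total_slots(self):
        rng = np.random.default_rng(23)
        focal = rng.uniform(0.1, 0.4, 47)
        panel = rng.uniform(0.01, 0.5, 4000)
        groups = maf_matched_background(focal, panel, n_groups=100,
                                        group_size=47, seed=11)
        assert sum(len(g) for g in groups) == 4700

    def test_no_candidate_raises_after_widening(self):
        with pytest.warns(UserWarning, match="widening"):
            with pytest.raises(ValueError, match="no MAF-matched"):
                maf_matched_background([0.5], [0.05], n_groups=1,
                                       group_size=1, seed=1)

    def test_envelope_brackets_median(self):
        rng = np.random.default_rng(29)
        pvals = [rng.uniform(size=50) for _ in range(30)]
        env = cumulative_envelope(pvals)
        assert ((env["lo"] <= env["median"])
                & (env["median"] <= env["hi"])).all()


class TestGroupComparison:
    def test_identical_groups_nonsignificant(self):
        scores = pd.DataFrame({
            "offset": np.repeat([-5, 0, 5], 10),
            "varld_raw": np.tile(np.linspace(1, 10, 10), 3),
        })
        out = group_window_comparison(scores, scores.copy())
        assert (~out["significant"]).all()
        assert (out["p_value"] > 0.9).all()

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(31)
        base = pd.DataFrame({
            "offset": np.repeat([0], 30),
            "varld_raw": rng.normal(10, 1, 30),
        })
        high = base.assign(varld_raw=base["varld_raw"] + 5)
        out = group_window_comparison(high, base)
        assert out["significant"].all()

    def test_empty_group_raises(self):
        frame = pd.DataFrame({"offset": [0], "varld_raw": [1.0]})
        with pytest.raises(ValueError):
            group_window_comparison(frame, frame.iloc[0:0])


class TestVcfRoundTrip:
    def test_write_read_preserves_panels(self, exchangeable_panels, tmp_path):
        panels = [exchangeable_panels.panel1, exchangeable_panels.panel2]
        vcf_path = tmp_path / "panel.vcf"
        pops_path = tmp_path / "pops.tsv"
        write_vcf(panels, vcf_path)
        write_populations(panels, pops_path)
        loaded = read_vcf(vcf_path, pops_path)
        assert set(loaded) == {"EUR", "EAS"}
        for original in panels:
            recovered = loaded[original.population]
            np.testing.assert_array_equal(recovered.alleles,
                                          original.alleles)
            assert recovered.sample_ids == original.sample_ids
            np.testing.assert_array_equal(recovered.pos_bp, original.pos_bp)
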