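"""Group statistics, permutation inference and report-level summaries."""
import numpy as np
import pytest
from scipy import stats

from conftest import square_montage
from pwpe_eeg._exceptions import DesignError
from pwpe_eeg.containers import EpochSet
from pwpe_eeg.glm import BetaMap
from pwpe_eeg.inference import (StatMap, ancova, classic_mmn,
                                cluster_inference, cohen_f2,
                                group_difference, max_intensity_projection,
                                one_sample_F, quantile_split_erp)
from pwpe_eeg.validation import make_null_grid


def make_betas(data, grid=None):
    """Wrap an (n_subjects, nx, ny, nt) array as a list of BetaMaps."""
    grid = grid or make_null_grid(data.shape[1:])
    return [BetaMap(beta=d, intercept=np.zeros_like(d),
                    resvar=np.ones_like(d), df=100, xtx_inv_slope=1.0,
                    grid=grid, regressor="epsilon2", subject=f"s{i}")
            for i, d in enumerate(data)]


class TestOneSampleF:
    def test_zero_betas_give_zero_F(self):
        smap = one_sample_F(make_betas(np.zeros((5, 4, 4, 3))))
        assert np.all(smap.values == 0.0)
        assert smap.df == (1, 4)

    def test_equals_squared_scipy_t(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0.3, 1.0, (12, 4, 4, 6))
        smap = one_sample_F(make_betas(data))
        t_ref = stats.ttest_1samp(data, 0.0, axis=0).statistic
        assert np.allclose(smap.values, t_ref ** 2, atol=1e-10)

    def test_null_F_distribution_ks(self):
        """n=23 i.i.d. normal betas: voxelwise F follows F(1, 22)."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((23, 25, 20, 20))  # 10^4 voxels
        smap = one_sample_F(make_betas(data))
        ks = stats.kstest(smap.values.ravel(), stats.f(1, 22).cdf)
        assert ks.pvalue > 0.01


class TestGroupDifference:
    def test_identical_groups_zero_t(self):
        data = np.random.default_rng(2).normal(0, 1, (6, 3, 3, 2))
        smap = group_difference(make_betas(data), make_betas(data.copy()))
        assert np.allclose(smap.values, 0.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = make_betas(rng.normal(0.5, 1, (8, 3, 3, 2)))
        b = make_betas(rng.normal(0.0, 1, (11, 3, 3, 2)))
        ab = group_difference(a, b)
        ba = group_difference(b, a)
        assert np.allclose(ab.values, -ba.values, atol=1e-12)
        assert "paired" in ab.provenance  # wording discrepancy recorded

    def test_power_matches_noncentral_t_oracle(self):
        """Empirical rejection rate of the two-sample t at alpha=0.001 for a
        planted shift matches the closed-form noncentral-t power."""
        na, nb, delta, alpha = 23, 31, 1.0, 0.001
        df = na + nb - 2
        ncp = delta / np.sqrt(1 / na + 1 / nb)
        tcrit = stats.t.isf(alpha / 2, df)
        power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        rng = np.random.default_rng(4)
        n_rep, n_vox = 80, 25  # 2000 independent voxel-tests
        hits = 0
        for _ in range(n_rep):
            a = make_betas(rng.normal(delta, 1, (na, 5, 5, 1)))
            b = make_betas(rng.normal(0.0, 1, (nb, 5, 5, 1)))
            t = group_difference(a, b).values
            hits += int((np.abs(t) > tcrit).sum())
        n_tests = n_rep * n_vox
        lo, hi = stats.binom.interval(0.999, n_tests, power)
        assert lo <= hits <= hi


class TestAncova:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 20
        cov = rng.normal(10, 3, n)
        data = 0.4 * cov[:, None, None, None] + rng.normal(0, 1, (n, 3, 3, 2))
        smap = ancova(make_betas(data), cov)
        y = data[:, 1, 2, 0]
        X = sm.add_constant(cov)
        res = sm.OLS(y, X).fit()
        assert smap.values[1, 2, 0] == pytest.approx(res.tvalues[1] ** 2,
                                                     rel=1e-10)
        assert smap.slope[1, 2, 0] == pytest.approx(res.params[1], rel=1e-10)
        assert smap.df == (1, n - 2)

    def test_nuisance_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 25
        cov = rng.normal(0, 1, n)
        age = rng.normal(20, 3, n)
        data = 0.5 * cov[:, None, None, None] + \
            0.2 * age[:, None, None, None] + rng.normal(0, 1, (n, 2, 2, 2))
        smap = ancova(make_betas(data), cov, nuisance=age)
        y = data[:, 0, 0, 0]
        res = sm.OLS(y, sm.add_constant(np.column_stack([age, cov]))).fit()
        assert smap.values[0, 0, 0] == pytest.approx(res.tvalues[2] ** 2,
                                                     rel=1e-8)

    def test_collinear_covariate_raises(self):
        data = np.random.default_rng(7).normal(0, 1, (10, 2, 2, 2))
        with pytest.raises(DesignError):
            ancova(make_betas(data), np.ones(10))

    def test_type_i_error_calibrated_at_voxel_level(self):
        """Null covariate: uncorrected voxelwise rejections at p<0.01 stay
        within the binomial envelope."""
        rng = np.random.default_rng(8)
        hits, n_tests = 0, 0
        for _ in range(60):
            data = rng.standard_normal((15, 4, 4, 4))
            cov = rng.normal(10, 3, 15)
            smap = ancova(make_betas(data), cov)
            p = stats.f.sf(smap.values, *smap.df)
            hits += int((p < 0.01).sum())
            n_tests += p.size
        lo, hi = stats.binom.interval(0.999, n_tests, 0.01)
        assert lo <= hits <= hi


class TestClusterInference:
    def test_all_zero_map_gives_empty_list(self):
        _, clusters = cluster_inference(make_betas(np.zeros((6, 4, 4, 5))),
                                        n_perm=100)
        assert clusters == []

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        data = rng.normal(1.0, 1.0, (10, 6, 6, 8))
        betas = make_betas(data)
        _, c1 = cluster_inference(betas, n_perm=200, seed=5)
        _, c2 = cluster_inference(betas, n_perm=200, seed=5)
        assert [c.p_cluster_fwe for c in c1] == [c.p_cluster_fwe for c in c2]
        assert [c.extent for c in c1] == [c.extent for c in c2]

    def test_planted_cluster_found_with_correct_window(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((12, 8, 8, 30))
        data[:, 2:5, 2:5, 10:20] += 2.0
        grid = make_null_grid((8, 8, 30))
        smap, clusters = cluster_inference(make_betas(data, grid),
                                           n_perm=300, seed=2)
        assert clusters
        top = clusters[0]
        assert top.p_cluster_fwe < 0.05
        # planted window: time indices 10..19 -> 120..138 ms on this grid
        t_lo, t_hi = grid.times[10], grid.times[19]
        assert top.time_window[0] <= t_hi and top.time_window[1] >= t_lo

    def test_cluster_p_monotone_in_extent(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((12, 8, 8, 30))
        data[:, 1:3, 1:3, 2:25] += 2.0     # large cluster
        data[:, 6:8, 6:8, 27:29] += 1.6    # small cluster
        smap, clusters = cluster_inference(make_betas(data), n_perm=200,
                                           seed=3)
        if len(clusters) >= 2:
            assert clusters[0].extent >= clusters[1].extent
            assert clusters[0].p_cluster_fwe <= clusters[1].p_cluster_fwe


def test_cohen_f2_arithmetic():
    assert cohen_f2(0.0, 1, 29) == 0.0
    assert cohen_f2(29.0, 1, 29) == pytest.approx(1.0, abs=1e-12)
    vals = [cohen_f2(F, 1, 29) for F in (1.0, 5.0, 10.0, 29.0, 100.0)]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    with pytest.raises(DesignError):
        cohen_f2(1.0, 1, 0)


def test_rft_peak_approximation_behaves():
    """The labelled Gaussian-field approximation: p in [0,1], decreasing
    in F, and conservative-to-liberal ordering preserved."""
    from pwpe_eeg.inference import rft_peak_p

    grid = make_null_grid((6, 6, 10))
    values = np.linspace(0.0, 60.0, 360).reshape(6, 6, 10)
    smap = StatMap(values=values, kind="F", df=(1, 20), grid=grid)
    p = rft_peak_p(smap, fwhm_vox=(4.0, 4.0, 1.0))
    assert np.all((p >= 0) & (p <= 1))
    flat_F = values.ravel()
    flat_p = p.ravel()
    big = flat_F > 20
    assert np.all(np.diff(flat_p[big]) <= 0)  # larger F -> smaller peak p


def test_statmap_nifti_export(tmp_path):
    import nibabel as nib

    from pwpe_eeg.glm import volume_to_nifti

    grid = make_null_grid((4, 5, 6))
    values = np.random.default_rng(13).random((4, 5, 6))
    path = tmp_path / "map.nii.gz"
    volume_to_nifti(values, grid, path)
    img = nib.load(path)
    assert img.shape == (4, 5, 6)
    assert np.allclose(img.header.get_zooms(), grid.voxel)
    assert np.allclose(np.asarray(img.dataobj), values, atol=1e-6)


class TestERPSummaries:
    def make_epochs(self, n_trials=40, seed=0):
        ch = square_montage(3, with_eog=False)
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, (n_trials, ch.n, 20))
        tones = (rng.random(n_trials) < 0.3).astype(int)
        return EpochSet(data=data, times=np.arange(20) * 2.0, srate=500.0,
                        tones=tones, channels=ch)

    def test_quantile_counts_and_partition(self):
        ep = self.make_epochs(n_trials=1000, seed=1)
        reg = np.random.default_rng(2).normal(0, 1, 1000)
        high, low, times = quantile_split_erp(ep, reg, q=0.15)
        assert times.size == 20
        # q = 0.5 partitions all trials: mean of the two halves = grand mean
        h2, l2, _ = quantile_split_erp(ep, reg, q=0.5)
        assert np.allclose((h2 + l2) / 2.0, ep.data.mean(axis=0), atol=1e-12)

    def test_quantile_split_sees_planted_coupling(self):
        ep = self.make_epochs(n_trials=400, seed=3)
        reg = np.random.default_rng(4).normal(0, 1, 400)
        ep.data[:, 2, 5:10] += 3.0 * reg[:, None]  # positive coupling
        high, low, _ = quantile_split_erp(ep, reg, q=0.15,
                                          electrodes=["ch02"])
        diff = high[0] - low[0]
        assert diff[5:10].min() > 0
        assert np.abs(diff[:5]).max() < diff[5:10].min()

    def test_classic_mmn_null_and_planted(self):
        ep = self.make_epochs(n_trials=600, seed=5)
        base = classic_mmn(ep)
        assert np.abs(base).max() < 1.0  # pure noise difference
        # deviant-locked negativity at channel 4, samples 8..12
        ep.data[ep.tones == 1, 4, 8:12] -= 5.0
        diff = classic_mmn(ep)
        assert diff[4, 8:12].min() > 2.0  # standard minus deviant is positive
        lin = ep.data[ep.tones == 0].mean(0) - ep.data[ep.tones == 1].mean(0)
        assert np.allclose(diff, lin, atol=1e-12)

    def test_classic_mmn_requires_both_classes(self):
        ep = self.make_epochs()
        ep.tones[:] = 0
        with pytest.raises(DesignError):
            classic_mmn(ep)


class TestMIP:
    def test_single_voxel_projects_to_single_pixel(self):
        grid = make_null_grid((5, 6, 7))
        values = np.zeros((5, 6, 7))
        values[2, 3, 4] = 9.0
        smap = StatMap(values=values, kind="F", df=(1, 10), grid=grid)
        mip = max_intensity_projection(smap, axis=0)
        assert mip.shape == (6, 7)
        assert mip[3, 4] == 9.0 and mip.sum() == 9.0

    def test_matches_brute_force_and_monotone(self):
        rng = np.random.default_rng(12)
        values = rng.random((5, 6, 7)) * 10
        grid = make_null_grid((5, 6, 7))
        smap = StatMap(values=values, kind="F", df=(1, 10), grid=grid)
        mip = max_intensity_projection(smap, axis=0)
        brute = np.array([[values[:, j, t].max() for t in range(7)]
                          for j in range(6)])
        assert np.array_equal(mip, brute)
        thresh = StatMap(values=np.where(values > 5, values, 0.0), kind="F",
                         df=(1, 10), grid=grid)
        assert np.all(max_intensity_projection(thresh, axis=0) <= mip)
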