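"""Projection, smoothing and first-level GLM tests with algebraic oracles."""
import numpy as np
import pytest

from conftest import square_montage
from pwpe_eeg._exceptions import DesignError, ProjectionError
from pwpe_eeg.containers import EpochSet
from pwpe_eeg.glm import (build_design, first_level_fit, make_grid,
                          project_epochs, smooth_volumes)
from pwpe_eeg.hgf import filter_sequence
from pwpe_eeg.simulate import (EffectSpec, NoiseSpec, ParadigmSpec,
                               gen_subject_eeg, gen_tone_sequence)


def square_epochs(data, spacing=20.0, n_side=5):
    ch = square_montage(n_side, spacing=spacing)
    n_trials, n_ch, n_s = data.shape
    assert n_ch == ch.n
    times = 100.0 + 2.0 * np.arange(n_s)
    return EpochSet(data=data, times=times, srate=500.0,
                    tones=np.zeros(n_trials, int), channels=ch)


class TestProjection:
    def test_constant_field_everywhere(self):
        ep = square_epochs(np.full((2, 25, 10), 3.25), spacing=20.0)
        grid = make_grid(ep, voxel=(5.0, 5.0), window=(100.0, 120.0))
        vols = project_epochs(ep, grid)
        assert np.allclose(vols[:, grid.mask, :], 3.25, atol=1e-10)

    def test_linear_field_reproduced_exactly(self):
        """Barycentric interpolation has linear precision: a planar field
        is reproduced at every in-hull voxel."""
        ch = square_montage(5, spacing=20.0)
        a, b, c = 1.5, 0.12, -0.07
        field = a + b * ch.pos[:, 0] + c * ch.pos[:, 1]
        ep = square_epochs(np.tile(field[None, :, None], (1, 1, 4)))
        grid = make_grid(ep, voxel=(4.25, 5.38), window=(100.0, 106.0))
        vols = project_epochs(ep, grid)
        gx, gy = np.meshgrid(grid.x, grid.y, indexing="ij")
        expected = a + b * gx + c * gy
        got = vols[0, :, :, 0]
        assert np.allclose(got[grid.mask], expected[grid.mask], atol=1e-9)

    def test_node_values_match_channels(self):
        # lattice aligned with the montage so electrodes sit on voxels
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 5, 25)
        ep = square_epochs(np.tile(vals[None, :, None], (1, 1, 4)))
        grid = make_grid(ep, voxel=(10.0, 10.0), window=(100.0, 106.0),
                         margin=0.0)
        vols = project_epochs(ep, grid)
        for k, (x, y) in enumerate(ep.channels.pos):
            i = np.argmin(np.abs(grid.x - x))
            j = np.argmin(np.abs(grid.y - y))
            assert abs(grid.x[i] - x) < 1e-9 and abs(grid.y[j] - y) < 1e-9
            assert vols[0, i, j, 0] == pytest.approx(vals[k], abs=1e-6)

    def test_single_channel_locality(self):
        vals = np.zeros(25)
        vals[12] = 10.0  # center electrode
        ep = square_epochs(np.tile(vals[None, :, None], (1, 1, 4)))
        grid = make_grid(ep, voxel=(5.0, 5.0), window=(100.0, 106.0))
        vol = project_epochs(ep, grid)[0, :, :, 0]
        i, j = np.unravel_index(np.argmax(vol), vol.shape)
        x0, y0 = ep.channels.pos[12]
        assert abs(grid.x[i] - x0) <= 5.0 and abs(grid.y[j] - y0) <= 5.0

    def test_collinear_montage_raises(self):
        from pwpe_eeg.containers import ChannelInfo

        ch = ChannelInfo([f"c{i}" for i in range(5)],
                         np.column_stack([np.arange(5.0),
                                          np.zeros(5)]),
                         np.asarray(["scalp"] * 5, object), np.zeros(5, bool))
        ep = EpochSet(data=np.zeros((1, 5, 4)),
                      times=100.0 + 2.0 * np.arange(4), srate=500.0,
                      tones=np.zeros(1, int), channels=ch)
        with pytest.raises(ProjectionError):
            make_grid(ep)

    def test_analysis_window_restriction(self, small_subject):
        _, _, epochs = small_subject
        grid = make_grid(epochs)
        assert grid.times[0] >= 100.0 and grid.times[-1] <= 400.0
        assert grid.voxel[2] == pytest.approx(2.0)


@pytest.fixture(scope="module")
def fine_grid_setup():
    ep = square_epochs(np.zeros((1, 25, 4)), spacing=30.0)
    return make_grid(ep, voxel=(2.0, 2.0), window=(100.0, 106.0))


class TestSmoothing:
    def test_constant_unchanged(self, fine_grid_setup):
        grid = fine_grid_setup
        vol = np.where(grid.mask[:, :, None], 7.5, 0.0) * \
            np.ones((1, 1, grid.times.size))
        sm = smooth_volumes(vol, grid)
        assert np.allclose(sm[grid.mask], 7.5, atol=1e-12)

    def test_impulse_fwhm_within_5pct(self, fine_grid_setup):
        grid = fine_grid_setup
        nx, ny, nt = grid.shape
        vol = np.zeros((nx, ny, nt))
        ci, cj = nx // 2, ny // 2
        vol[ci, cj, 0] = 1.0
        sm = smooth_volumes(vol, grid, fwhm=(16.0, 16.0))[:, :, 0]
        sm = sm - np.median(sm[grid.mask])  # remove the tiny mean-shift offset
        half = sm[ci, cj] / 2.0
        for axis_vals, coord in ((sm[:, cj], grid.x), (sm[ci, :], grid.y)):
            above = np.flatnonzero(axis_vals >= half)
            # linear interpolation of the half-max crossings
            lo, hi = above[0], above[-1]
            f = lambda i0, i1: coord[i0] + (half - axis_vals[i0]) * \
                (coord[i1] - coord[i0]) / (axis_vals[i1] - axis_vals[i0])
            width = f(hi, hi + 1) - f(lo, lo - 1)
            assert abs(width - 16.0) < 0.8

    def test_masked_mean_preserved(self, small_subject):
        _, _, epochs = small_subject
        grid = make_grid(epochs, voxel=(8.5, 10.76), time_step=4.0)
        vols = project_epochs(epochs, grid)[:5]
        sm = smooth_volumes(vols, grid)
        for v, s in zip(vols, sm):
            before = v[grid.mask].mean()
            after = s[grid.mask].mean()
            assert abs(after - before) <= 1e-6 * max(abs(before), 1e-9)

    def test_linearity_mean_commutes(self, small_subject):
        _, _, epochs = small_subject
        grid = make_grid(epochs, voxel=(8.5, 10.76), time_step=4.0)
        vols = project_epochs(epochs, grid)[:10]
        sm_then_mean = smooth_volumes(vols, grid).mean(axis=0)
        mean_then_sm = smooth_volumes(vols.mean(axis=0), grid)
        assert np.allclose(sm_then_mean, mean_then_sm, atol=1e-8)


@pytest.fixture(scope="module")
def fitted_subject(small_subject):
    seq, traj, epochs = small_subject
    from pwpe_eeg.preprocess import preprocess_epochs

    clean = preprocess_epochs(epochs)
    grid = make_grid(clean, voxel=(8.5, 10.76), time_step=4.0)
    vols = smooth_volumes(project_epochs(clean, grid), grid)
    design = build_design(traj, clean, "epsilon2")
    return clean, grid, vols, design


class TestFirstLevel:
    def test_normal_equations_oracle(self, fitted_subject):
        clean, grid, vols, design = fitted_subject
        bm = first_level_fit(vols, design, grid)
        X = design.X
        Y = vols.reshape(X.shape[0], -1)
        coef = np.linalg.inv(X.T @ X) @ X.T @ Y
        assert np.allclose(bm.beta.ravel(), coef[1], atol=1e-8)
        assert np.allclose(bm.intercept.ravel(), coef[0], atol=1e-8)
        resid = Y - X @ coef
        assert np.allclose(bm.resvar.ravel(),
                           (resid ** 2).sum(0) / bm.df, atol=1e-8)
        assert bm.df == X.shape[0] - 2

    def test_statsmodels_cross_check(self, fitted_subject):
        import statsmodels.api as sm

        clean, grid, vols, design = fitted_subject
        bm = first_level_fit(vols, design, grid)
        ii, jj = np.argwhere(grid.mask)[10]
        y = vols[:, ii, jj, 5]
        res = sm.OLS(y, design.X).fit()
        assert bm.beta[ii, jj, 5] == pytest.approx(res.params[1], abs=1e-10)
        assert bm.resvar[ii, jj, 5] == pytest.approx(res.mse_resid, rel=1e-10)

    def test_affine_equivariance(self, fitted_subject):
        clean, grid, vols, design = fitted_subject
        base = first_level_fit(vols, design, grid)
        scaled = first_level_fit(3.0 * vols, design, grid)
        assert np.allclose(scaled.beta, 3.0 * base.beta, atol=1e-10)
        shifted = first_level_fit(vols + 11.0, design, grid)
        assert np.allclose(shifted.beta, base.beta, atol=1e-9)
        assert np.allclose(shifted.intercept, base.intercept + 11.0,
                           atol=1e-9)

    def test_rejected_trials_never_influence_fit(self, small_subject):
        seq, traj, epochs = small_subject
        from pwpe_eeg.preprocess import preprocess_epochs

        clean = preprocess_epochs(epochs)
        assert not clean.kept.all()  # some trials were rejected
        grid = make_grid(clean, voxel=(12.0, 12.0), time_step=8.0)
        vols = project_epochs(clean, grid)
        design = build_design(traj, clean, "epsilon2")
        bm_masked = first_level_fit(vols, design, grid)
        # physically delete the rejected trials and refit
        pruned = EpochSet(data=clean.data[clean.kept],
                          times=clean.times, srate=clean.srate,
                          tones=clean.tones[clean.kept],
                          channels=clean.channels)
        traj_pruned_x = traj.regressor("epsilon2")[clean.kept]
        x = (traj_pruned_x - traj_pruned_x.mean()) / traj_pruned_x.std()
        from pwpe_eeg.glm import DesignMatrix

        design2 = DesignMatrix(X=np.column_stack([np.ones(x.size), x]),
                               regressor="epsilon2",
                               trial_index=np.arange(x.size))
        bm_pruned = first_level_fit(project_epochs(pruned, grid), design2,
                                    grid)
        assert np.array_equal(bm_masked.beta, bm_pruned.beta)

    def test_zero_variance_regressor_rejected(self, small_subject):
        seq, traj, epochs = small_subject
        all_standard = filter_sequence(np.zeros(epochs.n_trials, int))
        with pytest.raises(DesignError):
            build_design(all_standard, epochs, "tone")

    def test_chunked_fit_matches_in_memory(self, fitted_subject):
        from pwpe_eeg.glm import first_level_fit_multi

        clean, grid, vols, design = fitted_subject
        bm = first_level_fit(vols, design, grid)
        chunked = first_level_fit_multi(clean, {"epsilon2": design}, grid,
                                        chunk_size=37)["epsilon2"]
        assert np.allclose(chunked.beta, bm.beta, atol=1e-9)
        assert np.allclose(chunked.intercept, bm.intercept, atol=1e-9)
        assert np.allclose(chunked.resvar, bm.resvar, atol=1e-8)
        assert chunked.df == bm.df

    def test_planted_slope_recovered(self):
        """5 uV planted slope recovered within 3 SE from 1000 trials."""
        paradigm = ParadigmSpec(n_trials=1000)
        seq = gen_tone_sequence(paradigm, seed=90)
        traj = filter_sequence(seq)
        eff = EffectSpec(amplitude=5.0)
        ep = gen_subject_eeg(seq, traj, [eff],
                             NoiseSpec(trial_sd=10.0, blink_rate=0.0),
                             seed=91, paradigm=paradigm)
        grid = make_grid(ep, voxel=(8.5, 10.76))
        vols = project_epochs(ep, grid)  # unsmoothed: slope exact at nodes
        design = build_design(traj, ep, "epsilon2")
        bm = first_level_fit(vols, design, grid)
        x0, y0 = ep.channels.pos[ep.channels.index("Fz")]
        i = np.argmin(np.abs(grid.x - x0))
        j = np.argmin(np.abs(grid.y - y0))
        t = np.argmin(np.abs(grid.times - 160.0))
        se = bm.slope_se()[i, j, t]
        assert abs(bm.beta[i, j, t] - 5.0) < 3 * se
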