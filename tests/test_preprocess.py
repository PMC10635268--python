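"""Time-series cleaning: drops, joint projection, global/selective split."""

import numpy as np
import pytest

from cuesync.preprocess import (
    GlobalComponent,
    VoxelSeries,
    clean_series,
    cosine_drift_basis,
    drop_initial_trs,
    extract_global_component,
    selective_component,
)


def _series(values, **kw):
    return VoxelSeries(values=np.atleast_2d(values), **kw)


class TestDropInitialTrs:
    def test_movie_scale_drop(self):
        x = _series(np.random.default_rng(0).standard_normal((2, 1033)))
        out = drop_initial_trs(x, 10)
        assert out.n_trs == 1023
        assert out.tr_offset == 10

    def test_zero_drop_is_identity(self):
        x = _series(np.arange(20.0))
        out = drop_initial_trs(x, 0)
        assert np.array_equal(out.values, x.values)
        assert out.tr_offset == 0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            drop_initial_trs(_series(np.arange(5.0)), 10)


class TestCleanSeries:
    def test_confound_column_annihilated(self, rng):
        conf = rng.standard_normal((200, 3))
        x = _series(conf[:, 1])
        out = clean_series(x, confounds=conf)
        assert np.allclose(out.values, 0.0)

    def test_linear_ramp_removed(self):
        out = clean_series(_series(np.linspace(0, 5, 300)))
        assert np.allclose(out.values, 0.0, atol=1e-8)

    def test_residual_orthogonal_to_design(self, rng):
        conf = rng.standard_normal((250, 4))
        x = _series(rng.standard_normal((3, 250)))
        out = clean_series(x, confounds=conf)
        for col in conf.T:
            r = np.abs(out.values @ col) / (np.linalg.norm(col) * np.linalg.norm(out.values, axis=1))
            assert np.all(r < 1e-8)
        # z-scored rows
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.values.std(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize(
        "period,retained",
        [(20.0, True), (400.0, False)],
    )
    def test_highpass_transfer_function(self, period, retained):
        t = np.arange(1023)
        x = np.sin(2 * np.pi * t / period)
        design = np.column_stack(
            [np.ones(t.size), np.linspace(-1, 1, t.size), cosine_drift_basis(t.size, 1.0, 140.0)]
        )
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        ratio = np.std(x - design @ beta) / np.std(x)
        if retained:
            assert ratio > 0.95
        else:
            assert ratio < 0.1

    def test_nonfinite_confounds_rejected(self, rng):
        conf = rng.standard_normal((50, 2))
        conf[3, 0] = np.nan
        with pytest.raises(ValueError):
            clean_series(_series(rng.standard_normal(50)), confounds=conf)


class TestGlobalComponent:
    def test_single_voxel_is_zscored_copy(self, rng):
        v = rng.standard_normal(100)
        g = extract_global_component(_series(v))
        assert np.allclose(g.values, (v - v.mean()) / v.std())

    def test_opposite_voxels_give_zeros_with_warning(self, rng):
        v = rng.standard_normal(80)
        x = _series(np.vstack([v, -v]))
        with pytest.warns(RuntimeWarning):
            g = extract_global_component(x)
        assert np.allclose(g.values, 0.0)

    def test_planted_global_signal_recovered(self, rng):
        t = 400
        g_true = np.cumsum(rng.standard_normal(t))
        g_true = (g_true - g_true.mean()) / g_true.std()
        voxels = g_true[None, :] + rng.standard_normal((30, t))
        g_est = extract_global_component(_series(voxels))
        assert np.corrcoef(g_est.values, g_true)[0, 1] > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_global_component([])


class TestSelectiveComponent:
    def test_series_equal_to_global_becomes_zero(self, rng):
        v = rng.standard_normal(120)
        g = GlobalComponent(values=(v - v.mean()) / v.std())
        out = selective_component(_series(v), g)
        assert np.allclose(out.values, 0.0)

    def test_orthogonal_series_unchanged_up_to_zscore(self, rng):
        t = np.arange(200)
        g_vals = np.sin(2 * np.pi * t / 20)
        x_vals = np.cos(2 * np.pi * t / 20)  # orthogonal over full periods
        g = GlobalComponent(values=(g_vals - g_vals.mean()) / g_vals.std())
        out = selective_component(_series(x_vals), g)
        z = (x_vals - x_vals.mean()) / x_vals.std()
        assert np.allclose(out.values[0], z, atol=1e-8)

    def test_residual_tracks_independent_part(self, rng):
        g_vals = rng.standard_normal(500)
        e = rng.standard_normal(500)
        g = GlobalComponent(values=(g_vals - g_vals.mean()) / g_vals.std())
        out = selective_component(_series(0.7 * g.values + e), g)
        assert np.corrcoef(out.values[0], e)[0, 1] > 0.99
        assert abs(np.corrcoef(out.values[0], g.values)[0, 1]) < 1e-10

    def test_idempotent(self, rng):
        g_vals = rng.standard_normal(150)
        g = GlobalComponent(values=(g_vals - g_vals.mean()) / g_vals.std())
        x = _series(rng.standard_normal((4, 150)))
        once = selective_component(x, g)
        twice = selective_component(once, g)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        g = GlobalComponent(values=rng.standard_normal(99))
        with pytest.raises(ValueError):
            selective_component(_series(rng.standard_normal(100)), g)
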