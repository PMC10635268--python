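"""Synthetic-data generator: label tracks, HRF, study structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuesync.labels import LabelTrack, median_split_track
from cuesync.simulate import (
    SimConfig,
    generate_label_track,
    hrf_kernel,
    simulate_study,
)


class TestLabelTrack:
    def test_exact_drug_count_at_movie_scale(self):
        track = generate_label_track(1023, 464 / 1023, seed=0)
        assert track.n_bins == 1023
        assert int(track.labels.sum()) == 464
        assert track.fraction == pytest.approx(0.454, abs=0.001)

    @pytest.mark.parametrize("fraction,value", [(0.0, 0), (1.0, 1)])
    def test_degenerate_fractions(self, fraction, value):
        track = generate_label_track(50, fraction, seed=1)
        assert np.all(track.labels == value)

    def test_deterministic_given_seed(self):
        a = generate_label_track(500, 0.4, seed=9)
        b = generate_label_track(500, 0.4, seed=9)
        assert np.array_equal(a.labels, b.labels)
        c = generate_label_track(500, 0.4, seed=10)
        assert not np.array_equal(a.labels, c.labels)

    @given(
        n_bins=st.integers(min_value=1, max_value=400),
        fraction=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_always_exact(self, n_bins, fraction, seed):
        track = generate_label_track(n_bins, fraction, seed=seed)
        assert int(track.labels.sum()) == int(round(fraction * n_bins))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_label_track(0, 0.5)
        with pytest.raises(ValueError):
            generate_label_track(10, 1.5)
        with pytest.raises(ValueError):
            LabelTrack(labels=np.array([0, 2, 1]))

    def test_median_split_control_track(self):
        values = np.array([0.1, 5.0, 2.0, 9.0, 3.0, 3.0])
        track = median_split_track(values, "loudness_high")
        # median is 3; ties at the median fall in the low class
        assert track.labels.tolist() == [0, 1, 0, 1, 0, 0]


class TestHrfKernel:
    def test_peak_near_five_seconds(self):
        k = hrf_kernel(tr_seconds=1.0)
        assert k.max() == pytest.approx(1.0)
        assert 4 <= np.argmax(k) <= 6

    def test_convolution_with_impulse_is_identity(self):
        k = hrf_kernel()
        impulse = np.zeros(40)
        impulse[0] = 1.0
        out = np.convolve(impulse, k)[: k.size]
        assert np.allclose(out, k)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel(duration=0.0)
        with pytest.raises(ValueError):
            hrf_kernel(tr_seconds=-1.0)


class TestSimulateStudy:
    def test_shapes_consistent(self, small_study):
        cfg = small_study.config
        for gi, g in enumerate(small_study.voxel_data):
            for s in small_study.voxel_data[g]:
                n = cfg.n_subjects_per_group[gi]
                assert small_study.confounds[g][s].shape == (n, cfg.n_trs, cfg.n_confounds)
                for r, arr in small_study.voxel_data[g][s].items():
                    assert arr.shape == (n, cfg.voxels_per_roi, cfg.n_trs)
                assert small_study.unassigned_voxels[g][s].shape == (
                    n,
                    cfg.n_unassigned_voxels,
                    cfg.n_trs,
                )
        assert small_study.label_track.n_bins == cfg.n_analyzed_trs
        assert len(small_study.behavior) == 2 * sum(cfg.n_subjects_per_group)

    def test_truth_records_planted_parameters(self, small_study):
        truth = small_study.truth
        assert truth["drug_locked_rois"] == (0, 1)
        assert truth["ofc_rois"] == (2, 3)
        assert "planted_delta_correlation" in truth
        assert len(truth["coupling"]["HUD"]) == 6

    def test_byte_identical_given_seed(self):
        cfg = SimConfig(
            n_subjects_per_group=(3, 3),
            n_rois=3,
            voxels_per_roi=4,
            n_unassigned_voxels=10,
            n_trs=60,
            drug_locked_rois=(0,),
            ofc_rois=(1,),
            seed=42,
        )
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        for g in a.voxel_data:
            for s in a.voxel_data[g]:
                for r in a.voxel_data[g][s]:
                    assert np.array_equal(a.voxel_data[g][s][r], b.voxel_data[g][s][r])
        assert a.behavior.equals(b.behavior)

    def test_single_subject_groups_have_valid_shapes(self):
        cfg = SimConfig(
            n_subjects_per_group=(1, 1),
            n_rois=2,
            voxels_per_roi=3,
            n_unassigned_voxels=5,
            n_trs=50,
            drug_locked_rois=(0,),
            ofc_rois=(1,),
            seed=0,
        )
        study = simulate_study(cfg)
        assert study.voxel_data["HUD"]["baseline"][0].shape == (1, 3, 50)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_subjects_per_group=(0, 5))
        with pytest.raises(ValueError):
            SimConfig(drug_fraction=1.2)
        with pytest.raises(ValueError):
            SimConfig(drug_locked_rois=(99,))
        with pytest.raises(ValueError):
            SimConfig(drug_locked_rois=(0,), ofc_rois=(0,))
        with pytest.raises(ValueError):
            SimConfig(drug_amplitude=((1.0, 1.0),))
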