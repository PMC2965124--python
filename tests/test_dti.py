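"""Tensor estimation, FA, FACT tractography, tract selection and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motornet import dti, synth


def _uniform_field(shape, direction, fa=0.7, voxel=2.0):
    tens = np.tile(synth.tensor_from_fa(direction, fa), shape + (1, 1))
    field = dti.TensorField(tens, np.diag([voxel] * 3 + [1.0]),
                            np.ones(shape, bool))
    return field, dti.fa_map(field)


class TestTensorFit:
    def test_round_trip_recovers_generating_tensor(self):
        scheme = synth.default_gradient_scheme()
        D = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
        signal = synth.simulate_dwi_signal(D, scheme, 1000.0)
        dwi = synth.DWIDataset(np.broadcast_to(signal, (2, 2, 2, len(scheme))).copy(),
                               scheme, np.eye(4))
        fitted = dti.fit_tensor_loglinear(dwi).data[0, 0, 0]
        assert np.abs(fitted - D).max() / np.abs(D).max() < 1e-6

    def test_constant_signal_gives_zero_tensor(self):
        scheme = synth.default_gradient_scheme()
        dwi = synth.DWIDataset(np.full((1, 1, 1, len(scheme)), 800.0), scheme,
                               np.eye(4))
        assert np.abs(dti.fit_tensor_loglinear(dwi).data).max() < 1e-12

    def test_isotropic_signal_gives_equal_eigenvalues(self):
        scheme = synth.default_gradient_scheme()
        signal = synth.simulate_dwi_signal(np.diag([1e-3] * 3), scheme, 1000.0)
        dwi = synth.DWIDataset(signal.reshape(1, 1, 1, -1), scheme, np.eye(4))
        evals = np.linalg.eigvalsh(dti.fit_tensor_loglinear(dwi).data[0, 0, 0])
        assert evals.max() - evals.min() < 1e-9

    def test_nonpositive_b0_masks_voxel_invalid(self):
        scheme = synth.default_gradient_scheme()
        data = np.full((1, 1, 2, len(scheme)), 500.0)
        data[0, 0, 1, ~scheme.weighted] = 0.0
        field = dti.fit_tensor_loglinear(synth.DWIDataset(data, scheme, np.eye(4)))
        assert field.mask[0, 0, 0] and not field.mask[0, 0, 1]

    def test_degenerate_scheme_rejected_naming_rank(self):
        dirs = np.vstack([np.zeros((1, 3)), np.tile([1.0, 0, 0], (6, 1))])
        bvals = np.array([0.0] + [1000.0] * 6)
        scheme = synth.GradientScheme(dirs, bvals)
        dwi = synth.DWIDataset(np.full((1, 1, 1, 7), 100.0), scheme, np.eye(4))
        with pytest.raises(ValueError, match="rank 1"):
            dti.fit_tensor_loglinear(dwi)

    def test_noisy_round_trip_within_tolerance_at_snr_20(self):
        # SNR 20: sigma = S0/20; planted FA recovered within 0.05 on average
        scheme = synth.default_gradient_scheme()
        D = synth.tensor_from_fa([0, 0, 1.0], 0.6)
        rng = np.random.default_rng(42)
        signal = synth.simulate_dwi_signal(
            np.broadcast_to(D, (400, 3, 3)), scheme, 1000.0, 50.0, rng)
        dwi = synth.DWIDataset(signal.reshape(20, 20, 1, -1), scheme, np.eye(4))
        famap = dti.fa_map(dti.fit_tensor_loglinear(dwi))
        assert abs(famap.data.mean() - 0.6) < 0.05


class TestFractionalAnisotropy:
    @pytest.mark.parametrize("evals, expected", [
        ((1.0, 0.0, 0.0), 1.0),
        ((0.7, 0.7, 0.7), 0.0),
        ((2.0, 1.0, 1.0), 1.0 / np.sqrt(6.0)),
        ((0.0, 0.0, 0.0), 0.0),  # degenerate tensor defined as isotropic
    ])
    def test_closed_form_values(self, evals, expected):
        assert dti.fractional_anisotropy(evals) == pytest.approx(expected, abs=1e-12)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dti.fractional_anisotropy((1.0, 0.5, -0.1))

    @given(st.lists(st.floats(1e-5, 3e-3), min_size=3, max_size=3),
           st.floats(0, 2 * np.pi), st.floats(0, np.pi))
    @settings(max_examples=200, deadline=None)
    def test_eigenvalue_and_invariant_forms_agree(self, lams, phi, theta):
        # random PSD tensor from random eigenvalues and a random rotation
        axis = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                         np.cos(theta)])
        b = np.eye(3) - 2 * np.outer(axis, axis) / max(axis @ axis, 1e-12)
        D = b @ np.diag(lams) @ b.T
        fa_eig = dti.fractional_anisotropy(np.linalg.eigvalsh(D))
        fa_inv = dti.fa_from_tensor_invariants(D)
        assert abs(fa_eig - fa_inv) < 1e-10

    def test_phantom_fa_recovery_noise_free(self, flat_phantom):
        ph = flat_phantom.phantom
        err = np.abs(flat_phantom.famap.data - ph.true_fa)
        assert err.max() < 0.01


class TestFactTracking:
    def test_uniform_field_spans_grid_along_principal_axis(self):
        field, famap = _uniform_field((20, 8, 8), [1.0, 0, 0])
        sls = dti.fact_track(field, famap, seeds=np.array([[10, 4, 4]]))
        assert len(sls) == 1
        extent = 20 * 2.0
        assert abs(sls[0].length() - extent) <= 2.0  # within one voxel
        assert np.ptp(sls[0].points[:, 1]) < 1e-6  # no lateral drift

    def test_isotropic_low_fa_field_yields_no_streamlines(self):
        field, famap = _uniform_field((8, 8, 8), [1.0, 0, 0], fa=0.05)
        with pytest.warns(UserWarning, match="seed"):
            sls = dti.fact_track(field, famap)
        assert sls == []

    def test_right_angle_bend_terminates_at_max_angle(self):
        shape = (20, 20, 3)
        tens = np.empty(shape + (3, 3))
        tens[:10] = synth.tensor_from_fa([1.0, 0, 0], 0.7)
        tens[10:] = synth.tensor_from_fa([0, 1.0, 0], 0.7)
        field = dti.TensorField(tens, np.diag([2.0] * 3 + [1.0]),
                                np.ones(shape, bool))
        famap = dti.fa_map(field)
        params = dti.TrackingParams(max_angle_deg=45.0, min_length_mm=4.0)
        sls = dti.fact_track(field, famap, params,
                             seeds=np.argwhere(np.ones(shape, bool)))
        # no streamline may cross the bend plane between x-voxels 9 and 10
        for sl in sls:
            x = sl.points[:, 0] / 2.0
            assert x.max() <= 10.0 + 0.51 or x.min() >= 9.49

    def test_deterministic_given_identical_inputs(self, flat_phantom):
        again = dti.fact_track(flat_phantom.tensors, flat_phantom.famap,
                               dti.TrackingParams())
        assert len(again) == len(flat_phantom.streamlines)
        for a, b in zip(again, flat_phantom.streamlines):
            assert np.array_equal(a.points, b.points)

    def test_min_length_filters_short_streamlines(self):
        field, famap = _uniform_field((3, 3, 3), [1.0, 0, 0])
        sls = dti.fact_track(field, famap,
                             dti.TrackingParams(min_length_mm=50.0))
        assert sls == []


class TestTractSelection:
    def test_phantom_recovery_retains_most_in_tube_seeds(self, flat_phantom):
        ph = flat_phantom.phantom
        in_tube = set(map(tuple, np.argwhere(ph.tube_mask)))
        retained = {s.seed for s in flat_phantom.tract.streamlines}
        assert len(retained & in_tube) / len(in_tube) >= 0.9

    def test_full_grid_rois_retain_everything(self, flat_phantom):
        full = np.ones(flat_phantom.famap.data.shape, dtype=np.uint8)
        tract = dti.select_tract_by_rois(flat_phantom.streamlines, full, full,
                                         flat_phantom.famap.affine)
        assert len(tract) == len(flat_phantom.streamlines)

    def test_unreachable_roi_gives_empty_tract(self, flat_phantom):
        ph = flat_phantom.phantom
        corner = np.zeros_like(ph.masks["cortex"])
        corner[0, 0, 0] = 1  # background corner the tube never visits
        tract = dti.select_tract_by_rois(flat_phantom.streamlines,
                                         ph.masks["cortex"], corner,
                                         flat_phantom.famap.affine)
        assert len(tract) == 0

    def test_empty_mask_rejected(self, flat_phantom):
        empty = np.zeros_like(flat_phantom.phantom.masks["cortex"])
        with pytest.raises(ValueError, match="non-empty"):
            dti.select_tract_by_rois(flat_phantom.streamlines, empty, empty,
                                     flat_phantom.famap.affine)

    def test_selection_idempotent_and_order_independent(self, flat_phantom):
        ph = flat_phantom.phantom
        args = (ph.masks["cortex"], ph.masks["brainstem"], flat_phantom.famap.affine)
        once = dti.select_tract_by_rois(flat_phantom.streamlines, *args)
        twice = dti.select_tract_by_rois(list(once.streamlines), *args)
        assert [s.seed for s in twice.streamlines] == [s.seed for s in once.streamlines]
        shuffled = list(flat_phantom.streamlines)[::-1]
        re = dti.select_tract_by_rois(shuffled, *args)
        assert {s.seed for s in re.streamlines} == {s.seed for s in once.streamlines}


class TestFAProfiles:
    def test_constant_tube_profile_flat(self, flat_phantom):
        prof = flat_phantom.profile
        assert np.abs(prof.mean_fa - 0.7).max() < 0.02
        assert np.all(np.diff(prof.positions) > 0)
        assert np.all(prof.n_streamlines == len(flat_phantom.tract))

    def test_planted_gradient_profile_monotone_with_correct_endpoints(self, ramp_phantom):
        prof = ramp_phantom.profile
        assert abs(prof.mean_fa[0] - 0.5) < 0.03
        assert abs(prof.mean_fa[-1] - 0.7) < 0.03
        # smoothed monotone rise: no decrease beyond interpolation jitter
        assert np.all(np.diff(prof.mean_fa) > -0.005)

    def test_single_streamline_over_linear_ramp(self):
        shape = (30, 5, 5)
        tens = np.tile(synth.tensor_from_fa([1.0, 0, 0], 0.7), shape + (1, 1))
        field = dti.TensorField(tens, np.diag([2.0] * 3 + [1.0]),
                                np.ones(shape, bool))
        ramp = np.broadcast_to(np.linspace(0.3, 0.8, 30)[:, None, None],
                               shape).copy()
        famap = dti.FAMap(ramp, field.affine)
        sl = dti.Streamline(np.array([[0.0, 4.0, 4.0], [58.0, 4.0, 4.0]]),
                            (0, 2, 2))
        tract = dti.Tract("ramp", (sl,), roi_a_centroid=np.zeros(3))
        prof = dti.tract_fa_profile(tract, famap, 30)
        expected = np.interp(np.linspace(0, 29, 30), np.arange(30), ramp[:, 2, 2])
        assert np.abs(prof.mean_fa - expected).max() < 0.02

    def test_orientation_flip_puts_roi_a_end_first(self, ramp_phantom):
        # selecting with the ROIs swapped must mirror the profile
        ph = ramp_phantom.phantom
        swapped = dti.select_tract_by_rois(ramp_phantom.streamlines,
                                           ph.masks["brainstem"],
                                           ph.masks["cortex"],
                                           ramp_phantom.famap.affine)
        prof = dti.tract_fa_profile(swapped, ramp_phantom.famap, 100)
        assert abs(prof.mean_fa[0] - 0.7) < 0.03
        assert abs(prof.mean_fa[-1] - 0.5) < 0.03

    def test_profile_rejects_degenerate_inputs(self, flat_phantom):
        with pytest.raises(ValueError, match="n_points"):
            dti.tract_fa_profile(flat_phantom.tract, flat_phantom.famap, 1)
        empty = dti.Tract("empty", (), roi_a_centroid=np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            dti.tract_fa_profile(empty, flat_phantom.famap, 10)


class TestSegmentMeans:
    def _flat_profile(self, value=0.7, n=100):
        return dti.FAProfile(np.linspace(0, 1, n), np.full(n, value),
                             np.full(n, 5))

    def test_flat_profile_every_segment_equal(self):
        prof = self._flat_profile()
        for seg in ("rostral", "middle", "caudal"):
            assert dti.segment_fa(prof, seg) == pytest.approx(0.7)

    def test_linear_ramp_thirds(self):
        n = 100
        prof = dti.FAProfile(np.linspace(0, 1, n),
                             0.5 + 0.2 * np.linspace(0, 1, n), np.full(n, 5))
        assert dti.segment_fa(prof, "rostral") == pytest.approx(0.533, abs=0.01)
        assert dti.segment_fa(prof, "caudal") == pytest.approx(0.667, abs=0.01)

    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError, match="unknown segment"):
            dti.segment_fa(self._flat_profile(), "distal")

    def test_planted_rostral_deficit_pattern(self, flat_phantom, ramp_phantom):
        # patient (ramp) vs control (flat): the rostral difference exceeds the
        # caudal difference, the along-tract signature of the planted deficit
        rost_diff = (dti.segment_fa(flat_phantom.profile, "rostral")
                     - dti.segment_fa(ramp_phantom.profile, "rostral"))
        caud_diff = (dti.segment_fa(flat_phantom.profile, "caudal")
                     - dti.segment_fa(ramp_phantom.profile, "caudal"))
        assert rost_diff > caud_diff + 0.05

    def test_mean_tract_fa_matches_profile_mean(self, flat_phantom):
        mean = dti.mean_tract_fa(flat_phantom.tract, flat_phantom.famap)
        assert mean == pytest.approx(flat_phantom.profile.mean_fa.mean(), abs=1e-12)


class TestIO:
    def test_dwi_nifti_bvec_bval_round_trip(self, tmp_path):
        spec = synth.PhantomSpec(grid_shape=(6, 6, 10), seed=5)
        ph = synth.make_tract_phantom(spec)
        prefix = str(tmp_path / "dwi")
        synth.save_dwi(ph.dwi, prefix)
        loaded = dti.load_dwi(prefix + ".nii.gz", prefix + ".bvec", prefix + ".bval")
        assert np.allclose(loaded.data, ph.dwi.data, atol=1e-3)
        assert np.allclose(loaded.scheme.bvalues, ph.dwi.scheme.bvalues)
        assert np.allclose(loaded.affine, ph.dwi.affine)

    def test_trk_round_trip_preserves_geometry(self, tmp_path, flat_phantom):
        import nibabel as nib

        path = str(tmp_path / "tract.trk")
        dti.save_streamlines_trk(flat_phantom.tract, flat_phantom.famap, path)
        loaded = nib.streamlines.load(path)
        orig = flat_phantom.tract.streamlines
        assert len(loaded.streamlines) == len(orig)
        assert np.allclose(loaded.streamlines[0], orig[0].points, atol=1e-3)

    def test_profile_csv_round_trip(self, tmp_path, flat_phantom):
        import pandas as pd

        path = str(tmp_path / "profile.csv")
        dti.save_profile_csv(flat_phantom.profile, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "mean_fa", "n_streamlines"]
        assert np.allclose(df["mean_fa"], flat_phantom.profile.mean_fa)
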