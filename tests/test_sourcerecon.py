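"""LCMV beamformer, pseudo-T contrast, minimum norm, virtual electrodes."""

import numpy as np
import pytest

from megfingerprint.geometry import SourceSpace, compute_leadfield
from megfingerprint.paradigm import generate_schedule
from megfingerprint.preprocess import Epochs, bandpass, epoch_and_reject
from megfingerprint.simulate import sample_cohort_params, simulate_sources, project_and_noise
from megfingerprint.sourcerecon import (
    lcmv_weights,
    mne_evoked,
    pseudo_t_image,
    virtual_electrode,
)


def _beta_epochs(rec, band=(13.0, 30.0)):
    stim = rec.events[rec.events.trial_type.str.startswith("stim")].reset_index(drop=True)
    data = bandpass(rec.data.astype(float), rec.sampling_rate_hz, *band)
    return epoch_and_reject(data, stim, rec.sampling_rate_hz, (0.0, 1.2), reject=False, band="beta")


@pytest.fixture(scope="module")
def planted(fine_space, opm_array, fine_leadfield_opm):
    """Single-subject OPM session with a known bilateral source pair."""
    params = sample_cohort_params(1, seed=6)[0]
    params.extent_sigma_m = 0.0  # point sources for localisation accuracy
    # snap the dipoles onto grid points so "within one voxel" is well defined
    params.pos_left = fine_space.positions[fine_space.nearest_voxel(params.pos_left)]
    params.pos_right = fine_space.positions[fine_space.nearest_voxel(params.pos_right)]
    sched = generate_schedule(6, seed=0)
    src = simulate_sources(params, sched, 375.0, seed=1)
    rec = project_and_noise(src, fine_leadfield_opm, opm_array, seed=2)
    return params, src, rec


class TestLCMV:
    def test_unit_gain_at_own_voxel(self, planted, fine_leadfield_opm):
        _, _, rec = planted
        ep = _beta_epochs(rec)
        bw = lcmv_weights(ep, fine_leadfield_opm.gains)
        l = np.einsum("vac,va->vc", fine_leadfield_opm.gains, bw.orientations)
        g = np.einsum("vc,vc->v", bw.weights, l)
        live = np.linalg.norm(bw.weights, axis=1) > 0
        assert np.allclose(g[live], 1.0, atol=1e-6)

    def test_planted_dipole_localised_within_5mm(self, planted, fine_space, fine_leadfield_opm):
        params, _, rec = planted
        ep = _beta_epochs(rec)
        bw = lcmv_weights(ep, fine_leadfield_opm.gains)
        img = pseudo_t_image(bw, ep)
        for side, true_pos in (("left", params.pos_left), ("right", params.pos_right)):
            peak = img.peak_voxel(fine_space.hemisphere_mask(side))
            err = np.linalg.norm(fine_space.positions[peak] - true_pos)
            assert err <= 0.005 + 1e-12

    def test_amplitude_scaling_leaves_weight_pattern_unchanged(self, planted, fine_leadfield_opm):
        _, _, rec = planted
        ep = _beta_epochs(rec)
        bw1 = lcmv_weights(ep, fine_leadfield_opm.gains)
        ep2 = Epochs(ep.data * 2.0, ep.t_start, ep.sampling_rate_hz, ep.retained, ep.events, ep.band)
        bw2 = lcmv_weights(ep2, fine_leadfield_opm.gains)
        live = np.linalg.norm(bw1.weights, axis=1) > 0
        ratio = bw2.weights[live] / bw1.weights[live]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-4)


class TestPseudoT:
    def test_equal_windows_give_zero_image(self, fine_leadfield_opm, rng):
        gains = fine_leadfield_opm.gains[::200]
        n_ch = gains.shape[2]
        data = rng.standard_normal((8, n_ch, 451))
        ep = Epochs(data, 0.0, 375.0, np.arange(8), events=None, band="beta")
        bw = lcmv_weights(ep, gains)
        # symmetric windows on stationary noise: contrast fluctuates around 0
        img = pseudo_t_image(bw, ep, early=(0.2, 0.5), late=(0.2, 0.5))
        assert np.allclose(img.values, 0.0, atol=1e-12)

    def test_values_bounded(self, planted, fine_leadfield_opm):
        _, _, rec = planted
        ep = _beta_epochs(rec)
        bw = lcmv_weights(ep, fine_leadfield_opm.gains)
        img = pseudo_t_image(bw, ep)
        assert (img.values >= -1.0).all() and (img.values <= 1.0).all()

    def test_positive_at_sensory_sources(self, planted, fine_space, fine_leadfield_opm):
        params, _, rec = planted
        ep = _beta_epochs(rec)
        bw = lcmv_weights(ep, fine_leadfield_opm.gains)
        img = pseudo_t_image(bw, ep)
        v = fine_space.nearest_voxel(params.pos_left)
        assert img.values[v] > 0  # rebound window power exceeds the ERD window


class TestMNE:
    def test_noise_free_dipole_recovered_within_two_voxels(self, fine_space, opm_array, fine_leadfield_opm):
        params = sample_cohort_params(1, seed=8)[0]
        params.extent_sigma_m = 0.0
        params.beta_amp_nAm = 0.0  # evoked-only source
        sched = generate_schedule(2, seed=0)
        src = simulate_sources(params, sched, 375.0, seed=0)
        rec = project_and_noise(src, fine_leadfield_opm, opm_array, seed=0, noise_floor=np.zeros(192))
        ep = _beta_epochs(rec, band=(5.0, 40.0))
        power, image, peak, peak_t = mne_evoked(ep, fine_leadfield_opm.gains)
        err_l = np.linalg.norm(fine_space.positions[peak] - params.pos_left)
        err_r = np.linalg.norm(fine_space.positions[peak] - params.pos_right)
        assert min(err_l, err_r) <= 0.010 + 1e-12  # within 2 voxels (5 mm grid)
        assert (power >= 0).all()

    def test_zero_input_zero_power(self, fine_leadfield_opm):
        gains = fine_leadfield_opm.gains[::300]
        ep = Epochs(np.zeros((2, gains.shape[2], 100)), 0.0, 375.0, np.arange(2), None, "evoked")
        power, image, *_ = mne_evoked(ep, gains)
        assert np.allclose(power, 0.0) and np.allclose(image, 0.0)

    def test_quadrature_power_invariant_under_orientation_rotation(self, fine_leadfield_opm, rng):
        from scipy.spatial.transform import Rotation

        gains = fine_leadfield_opm.gains[::300].copy()
        n_ch = gains.shape[2]
        data = rng.standard_normal((3, n_ch, 120))
        ep = Epochs(data, 0.0, 375.0, np.arange(3), None, "evoked")
        p0, *_ = mne_evoked(ep, gains)
        R = Rotation.from_euler("xyz", [10, 40, -25], degrees=True).as_matrix()
        rotated = np.einsum("ab,vbc->vac", R, gains)
        p1, *_ = mne_evoked(ep, rotated)
        assert np.allclose(p0, p1, rtol=1e-8, atol=1e-12)


class TestVirtualElectrode:
    def test_recovers_planted_moment(self, planted, fine_space, fine_leadfield_opm):
        params, src, rec = planted
        data = bandpass(rec.data.astype(float), 375.0, 1.0, 100.0)
        cov = np.cov(data)
        bw = lcmv_weights(None, fine_leadfield_opm.gains, covariance=cov)
        v = fine_space.nearest_voxel(params.pos_left)
        ve = virtual_electrode(bw, data, v)
        truth = bandpass(src.moments_nAm[0][None, :], 375.0, 1.0, 100.0)[0]
        r = np.corrcoef(ve, truth)[0, 1]
        assert abs(r) > 0.9

    def test_zero_data_zero_output(self, fine_leadfield_opm, rng):
        gains = fine_leadfield_opm.gains[::300]
        cov = np.eye(gains.shape[2])
        bw = lcmv_weights(None, gains, covariance=cov)
        assert np.allclose(virtual_electrode(bw, np.zeros((gains.shape[2], 50)), 1), 0.0)

    def test_linearity_in_data(self, fine_leadfield_opm, rng):
        gains = fine_leadfield_opm.gains[::300]
        cov = np.eye(gains.shape[2])
        bw = lcmv_weights(None, gains, covariance=cov)
        a = rng.standard_normal((gains.shape[2], 200))
        b = rng.standard_normal((gains.shape[2], 200))
        assert np.allclose(
            virtual_electrode(bw, a + b, 2),
            virtual_electrode(bw, a, 2) + virtual_electrode(bw, b, 2),
        )


class TestCorrelatedSources:
    def test_beamformer_suppresses_correlated_bilateral_sources_mne_does_not(
        self, fine_space, opm_array, fine_leadfield_opm
    ):
        """Perfectly correlated bilateral evoked responses collapse the
        beamformer's virtual-electrode amplitude but barely dent the
        minimum-norm peak power — the reason evoked imaging uses MNE."""
        rng = np.random.default_rng(4)
        pos_l, pos_r = np.array([-0.042, 0.01, 0.06]), np.array([0.042, 0.01, 0.06])
        space_pair = SourceSpace(np.vstack([pos_l, pos_r]), 0.005, 0.08)
        lf_pair = compute_leadfield(space_pair, opm_array)
        dirs = []
        for pos in (pos_l, pos_r):
            radial = pos / np.linalg.norm(pos)
            t1 = np.cross([0, 0, 1.0], radial)
            dirs.append(t1 / np.linalg.norm(t1))
        gains = [np.einsum("ac,a->c", lf_pair.gains[i], d) for i, d in enumerate(dirs)]

        fs, n_tr, n_s = 375.0, 40, 451
        t = np.arange(n_s) / fs

        def pulse(latency):
            return 15.0 * np.exp(-0.5 * ((t - latency) / 0.012) ** 2)

        def session(correlated):
            # correlated: identical waveform both hemispheres;
            # uncorrelated: temporally disjoint pulses (zero sample correlation)
            eps = np.zeros((n_tr, 192, n_s))
            for k in range(n_tr):
                a, b = rng.normal(1.0, 0.1, 2)
                m_l = pulse(0.05) * a
                m_r = pulse(0.05 if correlated else 0.30) * (a if correlated else b)
                eps[k] = np.outer(gains[0], m_l) + np.outer(gains[1], m_r)
                eps[k] += 50.0 * rng.standard_normal((192, n_s))
            return Epochs(eps, 0.0, fs, np.arange(n_tr), None, "evoked")

        vox = fine_space.nearest_voxel(pos_l)
        amp, mne_peak = {}, {}
        for label, corr in (("corr", True), ("uncorr", False)):
            ep = session(corr)
            cov = np.cov(ep.data.transpose(1, 0, 2).reshape(192, -1))
            bw = lcmv_weights(None, fine_leadfield_opm.gains, covariance=cov)
            ve = virtual_electrode(bw, ep.data, vox)
            # amplitude of the left response in the virtual electrode
            win = (t >= 0.02) & (t <= 0.08)
            amp[label] = np.sqrt(np.mean(ve.mean(axis=0)[win] ** 2))
            power, *_ = mne_evoked(ep, fine_leadfield_opm.gains)
            mne_peak[label] = power.max()

        assert amp["corr"] < 0.5 * amp["uncorr"]
        assert mne_peak["corr"] > 0.8 * mne_peak["uncorr"]


class TestWeightsErrors:
    def test_epochs_or_covariance_required(self, fine_leadfield_opm):
        with pytest.raises(ValueError):
            lcmv_weights(None, fine_leadfield_opm.gains)
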