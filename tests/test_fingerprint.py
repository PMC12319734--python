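"""Similarity matrices, identification, permutation nulls, chance model."""

import numpy as np
import pytest
from scipy import stats

from megfingerprint.fingerprint import (
    DatasetFeatures,
    FingerprintMatrix,
    attentional_contrast,
    build_matrix,
    chance_identifiability,
    dataset_similarity,
    diagonal_permutation_test,
    group_timecourse_null,
    identify,
)


def _feat(rng, d_img=40, d_tfs=(10, 6)):
    return DatasetFeatures(image=rng.standard_normal(d_img), tfs=rng.standard_normal(d_tfs))


def _cohort_features(rng, n, noise=0.1):
    """Four sessions per subject sharing a subject-specific template."""
    out = {}
    for i in range(n):
        img = rng.standard_normal(40)
        tfs = rng.standard_normal((10, 6))
        for platform in ("opm", "squid"):
            for run in (1, 2):
                out[(f"sub-{i + 1:02d}", platform, run)] = DatasetFeatures(
                    image=img + noise * rng.standard_normal(40),
                    tfs=tfs + noise * rng.standard_normal((10, 6)),
                )
    return out


class TestDatasetSimilarity:
    def test_self_similarity_is_one(self, rng):
        f = _feat(rng)
        assert dataset_similarity(f, f) == pytest.approx(1.0)

    def test_mean_of_two_correlations(self, rng):
        a = _feat(rng)
        b = DatasetFeatures(image=a.image.copy(), tfs=-a.tfs)
        # image r = 1, tfs r = -1 -> mean 0
        assert dataset_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_features(self, rng):
        a = _feat(rng)
        b = DatasetFeatures(image=-a.image, tfs=-a.tfs)
        assert dataset_similarity(a, b) == pytest.approx(-1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            dataset_similarity(_feat(rng, d_img=40), _feat(rng, d_img=41))

    def test_evoked_feature_set(self, rng):
        a = _feat(rng)
        a.evoked_image = rng.standard_normal(40)
        a.evoked_timecourse = rng.standard_normal(100)
        assert dataset_similarity(a, a, feature_set="evoked") == pytest.approx(1.0)
        with pytest.raises(ValueError, match="evoked"):
            dataset_similarity(_feat(rng), _feat(rng), feature_set="evoked")


class TestBuildMatrix:
    def test_two_subject_structure(self, rng):
        feats = _cohort_features(rng, 2)
        within = build_matrix(feats, "within_opm")
        assert within.values.shape == (2, 2)
        # each cell is a single run1-vs-run2 comparison
        for i, si in enumerate(within.subjects):
            for j, sj in enumerate(within.subjects):
                direct = dataset_similarity(feats[(si, "opm", 1)], feats[(sj, "opm", 2)])
                assert within.values[i, j] == pytest.approx(direct, abs=1e-9)

        cross = build_matrix(feats, "cross_platform")
        for i, si in enumerate(cross.subjects):
            for j, sj in enumerate(cross.subjects):
                vals = [
                    dataset_similarity(feats[(si, "opm", a)], feats[(sj, "squid", b)])
                    for a in (1, 2)
                    for b in (1, 2)
                ]
                assert cross.values[i, j] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_identical_runs_orthogonal_subjects(self):
        rng = np.random.default_rng(0)
        feats = _cohort_features(rng, 4, noise=0.0)
        M = build_matrix(feats, "within_squid")
        assert np.allclose(np.diag(M.values), 1.0)
        assert np.abs(M.values - np.eye(4)).max() < 0.6  # off-diagonals near 0

    def test_missing_dataset_named_in_error(self, rng):
        feats = _cohort_features(rng, 2)
        del feats[("sub-02", "squid", 2)]
        with pytest.raises(ValueError, match="sub-02.*squid.*2"):
            build_matrix(feats, "cross_platform")

    def test_subject_relabelling_equivariance(self, rng):
        feats = _cohort_features(rng, 5)
        subjects = sorted({k[0] for k in feats})
        M = build_matrix(feats, "within_opm", subjects)
        perm = [3, 0, 4, 1, 2]
        M_perm = build_matrix(feats, "within_opm", [subjects[i] for i in perm])
        assert np.allclose(M_perm.values, M.values[np.ix_(perm, perm)])
        assert identify(M_perm)[1] == identify(M)[1]


class TestIdentify:
    def test_identity_dominant_matrix(self):
        M = np.full((6, 6), 0.5) + 0.4 * np.eye(6)
        hits, n = identify(M)
        assert n == 6 and hits.all()

    def test_swapped_pair_loses_two(self):
        M = (0.9 * np.eye(8) + 0.05)[:, :]
        M[[0, 1]] = M[[1, 0]]  # swap rows: subjects 0 and 1 point at each other
        _, n = identify(M)
        assert n == 6

    def test_single_subject_always_identified(self):
        assert identify(np.array([[0.2]]))[1] == 1

    def test_ties_count_as_misses(self):
        M = np.ones((3, 3))
        assert identify(M)[1] == 0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            identify(np.zeros((2, 3)))


class TestDiagonalPermutationTest:
    def test_constant_matrix_stat_zero_p_near_one(self):
        nd = diagonal_permutation_test(np.full((6, 6), 0.3), n_perm=999, seed=0)
        assert nd.observed == pytest.approx(0.0)
        assert nd.p_value > 0.99

    def test_strongly_diagonal_matrix_attains_minimum_p(self):
        M = np.eye(10)
        nd = diagonal_permutation_test(M, n_perm=999, seed=1)
        assert nd.p_value == pytest.approx(1.0 / 1000.0)
        assert nd.n_permutations == 999 and len(nd.samples) == 999

    def test_p_uniform_under_random_matrices(self):
        """Calibration: the empirical p is uniform for information-free matrices."""
        rng = np.random.default_rng(7)
        ps = [
            diagonal_permutation_test(rng.standard_normal((15, 15)), n_perm=999, seed=rng).p_value
            for _ in range(200)
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            diagonal_permutation_test(np.eye(2), n_perm=10, seed=0)


class TestChanceIdentifiability:
    def test_matches_binomial_law(self):
        pmf, binom = chance_identifiability(15, n_sim=20000, seed=3)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.abs(pmf - binom).max() < 0.015

    def test_single_subject_always_identified(self):
        pmf, binom = chance_identifiability(1, n_sim=500, seed=0)
        assert pmf[1] == pytest.approx(1.0)
        assert binom[1] == pytest.approx(1.0)


class TestGroupTimecourseNull:
    def test_degenerate_identical_groups(self, rng):
        # identical groups: observed correlation is exactly 1
        A = rng.standard_normal((6, 50))
        nd = group_timecourse_null(A, A.copy(), n_perm=200, seed=0)
        assert nd.observed == pytest.approx(1.0)
        # fully degenerate pool (every trace equal): every sham split gives 1
        x = rng.standard_normal(50)
        B = np.tile(x, (6, 1))
        nd2 = group_timecourse_null(B, B.copy(), n_perm=200, seed=0)
        assert np.allclose(nd2.samples, 1.0)

    def test_exchangeable_groups_fall_inside_null(self, rng):
        pool = rng.standard_normal((12, 300)) + np.sin(np.linspace(0, 6, 300))
        nd = group_timecourse_null(pool[:6], pool[6:], n_perm=2000, seed=1)
        lo, hi = np.percentile(nd.samples, [2.5, 97.5])
        assert lo <= nd.observed <= hi

    def test_sign_flip_lands_in_lower_tail(self, rng):
        base = np.sin(np.linspace(0, 12, 400))
        A = base + 0.1 * rng.standard_normal((8, 400))
        B = -base + 0.1 * rng.standard_normal((8, 400))
        nd = group_timecourse_null(A, B, n_perm=2000, seed=2)
        assert nd.observed < np.percentile(nd.samples, 2.5)
        assert nd.p_value < 0.05

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            group_timecourse_null(rng.standard_normal((4, 10)), rng.standard_normal((5, 10)))


def _null_envelopes(rng, n_subjects, times, effect=0.0):
    """Envelope-level cohort: per-subject baseline + condition noise.

    ``effect`` is the fractional contralateral beta drop (attend right
    suppresses the left hemisphere and vice versa).
    """
    win = (times >= -0.8) & (times <= 1.0)
    envs = {h: {c: [] for c in ("attend_left", "attend_right")} for h in ("left", "right")}
    for _ in range(n_subjects):
        base = 1.0 + 0.3 * rng.random()
        for hemi in ("left", "right"):
            for cond in ("attend_left", "attend_right"):
                e = base * np.ones_like(times) + 0.05 * rng.standard_normal(len(times))
                contralateral = (hemi == "left") == (cond == "attend_right")
                if contralateral and effect > 0:
                    e[win] *= 1.0 - effect
                envs[hemi][cond].append(e)
    return envs


class TestAttentionalContrast:
    def test_planted_contralateral_drop_detected(self):
        rng = np.random.default_rng(0)
        times = np.linspace(-1.0, 2.0, 301)
        envs = _null_envelopes(rng, 15, times, effect=0.2)
        res = attentional_contrast(envs, times)
        assert (res["delta_left"] > 0).mean() > 0.5
        assert (res["delta_right"] < 0).mean() > 0.5
        assert res["p_value"] < 0.05

    def test_swapping_conditions_negates_deltas(self):
        rng = np.random.default_rng(1)
        times = np.linspace(-1.0, 2.0, 301)
        envs = _null_envelopes(rng, 8, times, effect=0.15)
        res = attentional_contrast(envs, times)
        swapped = {
            h: {"attend_left": envs[h]["attend_right"], "attend_right": envs[h]["attend_left"]}
            for h in envs
        }
        res2 = attentional_contrast(swapped, times)
        assert np.allclose(res2["delta_left"], -res["delta_left"])
        assert np.allclose(res2["delta_right"], -res["delta_right"])

    def test_missing_condition_rejected(self):
        times = np.linspace(-1, 2, 10)
        with pytest.raises(ValueError, match="attend_right"):
            attentional_contrast(
                {"left": {"attend_left": [times]}, "right": {"attend_left": [times]}}, times
            )
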