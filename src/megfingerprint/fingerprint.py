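"""Neural fingerprinting statistics: similarity matrices, identification,
permutation nulls, the chance-identifiability model, the group-level
cross-platform timecourse null, and the attentional beta contrast.

A dataset's fingerprint is the pair (pseudo-T beta image, TFS at the
sensory-cortex peak); similarity between two datasets is the mean of the
two Pearson correlations. Three N x N matrices are built: within-OPM and
within-SQUID (run 1 of subject i vs run 2 of subject j — a single
comparison per cell, keeping within- and between-subject cells
statistically equivalent) and cross-platform (mean of the four OPM-run x
SQUID-run comparisons). Subject i is "identified" when row i's maximum
falls on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DatasetFeatures",
    "FingerprintMatrix",
    "NullDistribution",
    "dataset_similarity",
    "build_matrix",
    "identify",
    "diagonal_permutation_test",
    "chance_identifiability",
    "group_timecourse_null",
    "attentional_contrast",
]

SCHEMES = ("within_opm", "within_squid", "cross_platform")


@dataclass
class DatasetFeatures:
    """Fingerprint features of one session on cohort-shared grids."""

    image: np.ndarray  # (n_voxels,) pseudo-T values
    tfs: np.ndarray  # (n_times, n_freqs) R matrix on the shared 1 ms grid
    evoked_image: np.ndarray | None = None
    evoked_timecourse: np.ndarray | None = None


@dataclass
class FingerprintMatrix:
    values: np.ndarray  # (N, N)
    scheme: str  # within_opm | within_squid | cross_platform
    feature_set: str = "beta"  # beta | evoked
    subjects: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NullDistribution:
    observed: float
    samples: np.ndarray
    n_permutations: int
    p_value: float
    tail: str  # "greater" | "two-sided"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"feature shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def dataset_similarity(
    a: DatasetFeatures, b: DatasetFeatures, feature_set: str = "beta"
) -> float:
    """Mean of the image correlation and the (flattened) TFS correlation.

    With ``feature_set="evoked"`` the evoked-power image and evoked
    timecourse are used instead.
    """
    if feature_set == "beta":
        return 0.5 * (_pearson(a.image, b.image) + _pearson(a.tfs, b.tfs))
    if feature_set == "evoked":
        if a.evoked_image is None or b.evoked_image is None:
            raise ValueError("evoked features not available")
        return 0.5 * (
            _pearson(a.evoked_image, b.evoked_image)
            + _pearson(a.evoked_timecourse, b.evoked_timecourse)
        )
    raise ValueError(f"unknown feature set {feature_set!r}")


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def _pairwise_sim(
    features: dict, keys_a: list, keys_b: list, feature_set: str
) -> np.ndarray:
    """Vectorised similarity between two lists of dataset keys."""
    attrs = ("image", "tfs") if feature_set == "beta" else ("evoked_image", "evoked_timecourse")
    S = np.zeros((len(keys_a), len(keys_b)))
    for attr in attrs:
        if any(getattr(features[k], attr) is None for k in (*keys_a, *keys_b)):
            raise ValueError(f"feature {attr!r} not available for all datasets")
        A = _zscore_rows(np.stack([np.ravel(getattr(features[k], attr)).astype(float) for k in keys_a]))
        B = _zscore_rows(np.stack([np.ravel(getattr(features[k], attr)).astype(float) for k in keys_b]))
        S += A @ B.T
    return S / len(attrs)


def build_matrix(
    features: dict[tuple[str, str, int], DatasetFeatures],
    scheme: str,
    subjects: list[str] | None = None,
    feature_set: str = "beta",
) -> FingerprintMatrix:
    """Assemble one fingerprint matrix.

    ``features`` is keyed by ``(subject, platform, run)`` with platform in
    {"opm", "squid"} and run in {1, 2}. Within-platform matrices compare
    run 1 of the row subject with run 2 of the column subject (one
    comparison per cell); the cross-platform matrix averages the four
    OPM-run x SQUID-run comparisons.
    """
    if subjects is None:
        subjects = sorted({k[0] for k in features})
    if scheme in ("within_opm", "within_squid"):
        platform = "opm" if scheme == "within_opm" else "squid"
        _require(features, subjects, [platform], [1, 2])
        rows = [(s, platform, 1) for s in subjects]
        cols = [(s, platform, 2) for s in subjects]
        vals = _pairwise_sim(features, rows, cols, feature_set)
    elif scheme == "cross_platform":
        _require(features, subjects, ["opm", "squid"], [1, 2])
        vals = np.zeros((len(subjects), len(subjects)))
        for a in (1, 2):
            for b in (1, 2):
                rows = [(s, "opm", a) for s in subjects]
                cols = [(s, "squid", b) for s in subjects]
                vals += _pairwise_sim(features, rows, cols, feature_set)
        vals /= 4.0
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FingerprintMatrix(values=vals, scheme=scheme, feature_set=feature_set, subjects=list(subjects))


def _require(features, subjects, platforms, runs):
    for s in subjects:
        for p in platforms:
            for r in runs:
                if (s, p, r) not in features:
                    raise ValueError(f"missing dataset: subject={s} platform={p} run={r}")


def identify(matrix: FingerprintMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    """Row-maximum identification.

    Row i scores a hit iff its unique maximum lies on the diagonal; ties
    count as misses (conservative, deterministic).
    """
    M = matrix.values if isinstance(matrix, FingerprintMatrix) else np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 1:
        raise ValueError("matrix must be square and non-empty")
    row_max = M.max(axis=1)
    hits = (np.abs(np.diag(M) - row_max) == 0) & ((M == row_max[:, None]).sum(axis=1) == 1)
    return hits, int(hits.sum())


def _diag_stat(M: np.ndarray) -> float:
    n = M.shape[0]
    d = np.trace(M) / n
    off = (M.sum() - np.trace(M)) / (n * n - n)
    return float(d - off)


def diagonal_permutation_test(
    matrix: FingerprintMatrix | np.ndarray,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Permutation test of mean(diagonal) - mean(off-diagonal).

    The null relabels the column-axis subject identities (the second
    experiment / second platform), recomputes the statistic, and repeats
    ``n_perm`` times. The empirical one-tailed p-value uses the +1
    correction, so p >= 1/(n_perm + 1).
    """
    M = matrix.values if isinstance(matrix, FingerprintMatrix) else np.asarray(matrix, float)
    n = M.shape[0]
    if n < 3:
        raise ValueError("need N >= 3 for a meaningful permutation test")
    rng = np.random.default_rng(seed)
    observed = _diag_stat(M)

    total = M.sum()
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    diag_sums = M[np.arange(n)[None, :], perms].sum(axis=1)
    null = diag_sums / n - (total - diag_sums) / (n * n - n)
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return NullDistribution(observed, null, n_perm, float(p), "greater")


def chance_identifiability(
    n_subjects: int = 15,
    n_sim: int = 100_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 5000,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of identification counts for information-free matrices.

    Simulates matrices with i.i.d. standard-normal entries and counts rows
    whose maximum falls on the diagonal. Because row maxima are independent
    across rows with hit probability 1/N, the exact law is
    Binomial(N, 1/N); the analytic pmf is returned alongside the empirical
    one as a cross-check.

    Returns
    -------
    pmf : empirical P(k identified), k = 0..N
    binom_pmf : Binomial(N, 1/N) reference
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_subjects + 1, dtype=np.int64)
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        X = rng.standard_normal((m, n_subjects, n_subjects))
        hits = (X.argmax(axis=2) == np.arange(n_subjects)[None, :]).sum(axis=1)
        counts += np.bincount(hits, minlength=n_subjects + 1)
        done += m
    pmf = counts / n_sim
    binom_pmf = stats.binom.pmf(np.arange(n_subjects + 1), n_subjects, 1.0 / n_subjects)
    return pmf, binom_pmf


def group_timecourse_null(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 500,
) -> NullDistribution:
    """Sham-mixing null for the between-platform group-average correlation.

    The observed statistic is the Pearson correlation between the two
    group-average timecourses (one subject-average timecourse per row).
    The null pools all 2N timecourses, randomly splits them into two sham
    groups of N (platform labels discarded; a subject's two traces may land
    in the same group), and re-derives the correlation. The p-value is the
    two-tailed percentile position of the observed value.
    """
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.shape != B.shape:
        raise ValueError("groups must have identical (n_subjects, n_times) shapes")
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    observed = _pearson(A.mean(axis=0), B.mean(axis=0))

    pool = np.vstack([A, B])  # (2n, T)
    total = pool.sum(axis=0)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        ind = np.zeros((m, 2 * n))
        for i in range(m):
            ind[i, rng.choice(2 * n, size=n, replace=False)] = 1.0
        S1 = ind @ pool
        S2 = total[None, :] - S1
        S1 -= S1.mean(axis=1, keepdims=True)
        S2 -= S2.mean(axis=1, keepdims=True)
        num = np.einsum("it,it->i", S1, S2)
        den = np.sqrt(np.einsum("it,it->i", S1, S1) * np.einsum("it,it->i", S2, S2))
        null[done : done + m] = num / den
        done += m
    lo = (1.0 + np.count_nonzero(null <= observed)) / (n_perm + 1.0)
    hi = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    p = min(1.0, 2.0 * min(lo, hi))
    return NullDistribution(observed, null, n_perm, float(p), "two-sided")


def attentional_contrast(
    envelopes: dict[str, dict[str, list[np.ndarray]]],
    times: np.ndarray,
    window_s: tuple[float, float] = (-0.8, 1.0),
) -> dict:
    """Attentional beta modulation contrast between hemispheres.

    Parameters
    ----------
    envelopes:
        ``envelopes[hemisphere][condition][subject]`` with hemisphere in
        {"left", "right"} and condition in {"attend_left", "attend_right"},
        each a per-subject trial-averaged beta envelope on ``times``.
    window_s:
        Averaging window relative to the cue end.

    Per subject and hemisphere the contrast is
    delta = mean envelope (attend left) - mean envelope (attend right) over
    the window; attending away from a hemisphere suppresses its beta, so
    delta is expected positive in the left hemisphere and negative in the
    right. Left- and right-hemisphere deltas are compared across subjects
    with a two-sided Wilcoxon signed-rank test.
    """
    sel = (times >= window_s[0] - 1e-9) & (times <= window_s[1] + 1e-9)
    deltas = {}
    for hemi in ("left", "right"):
        conds = envelopes[hemi]
        for c in ("attend_left", "attend_right"):
            if c not in conds:
                raise ValueError(f"missing condition {c!r} for hemisphere {hemi!r}")
        al = np.stack([np.asarray(e, float)[sel].mean() for e in conds["attend_left"]])
        ar = np.stack([np.asarray(e, float)[sel].mean() for e in conds["attend_right"]])
        deltas[hemi] = al - ar
    res = stats.wilcoxon(deltas["left"], deltas["right"], alternative="two-sided")
    return {
        "delta_left": deltas["left"],
        "delta_right": deltas["right"],
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "window_s": window_s,
    }
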