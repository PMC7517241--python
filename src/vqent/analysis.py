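"""Discrimination and interpretation analyses of entropy ERD/S courses.

Covers the downstream workflow around the entropy time-courses: building
single-trial feature vectors, 10-fold LDA accuracy, exhaustive
(tau, M, rho) grid tuning, trial-similarity matrices between estimators,
per-channel relevance (distance between class-mean courses), incremental
channel-subset accuracy, and a cluster-based spatio-temporal permutation
test between classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core_io import Montage, TrialSet
from .embedding_entropy import EntropyParams
from .erds import entropy_erds, plan_windows
from .vq_entropy import vq_model

logger = logging.getLogger(__name__)

__all__ = [
    "TuningResult",
    "RelevanceMap",
    "SimilarityMatrix",
    "ClusterResult",
    "features_from_courses",
    "lda_cv_accuracy",
    "tune_grid",
    "trial_similarity",
    "channel_relevance",
    "incremental_channel_accuracy",
    "cluster_permutation_test",
    "DEFAULT_TAUS",
    "DEFAULT_MS",
    "DEFAULT_RHOS",
]

DEFAULT_TAUS: tuple[float, ...] = (1.0, 1.5, 2.0)
DEFAULT_MS: tuple[int, ...] = (1, 2, 3)
DEFAULT_RHOS: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_OVERLAP = 0.9


@dataclass(frozen=True)
class TuningResult:
    """Exhaustive grid evaluation: one accuracy (mean, sd in %) per
    (tau, M, rho) triple; ``best`` attains the maximum mean accuracy."""

    grid: tuple[tuple[float, int, float], ...]
    accuracy_mean: np.ndarray
    accuracy_sd: np.ndarray
    best: tuple[float, int, float]
    estimator: str
    q_prime_median: float | None = None

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy_mean.max())


@dataclass(frozen=True)
class RelevanceMap:
    """Per-channel discriminability weights and the induced ranking."""

    channel_names: tuple[str, ...]
    weights: np.ndarray
    ranking: tuple[int, ...]  # channel indices, decreasing weight

    def ranked_names(self) -> tuple[str, ...]:
        return tuple(self.channel_names[i] for i in self.ranking)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Trial-by-trial similarity between two estimators' courses.

    Entries lie in (0, 1]; the upper triangle compares right-label
    trials, the lower triangle left-label trials, and the diagonal is 1.
    """

    values: np.ndarray
    sigma2_X: float
    methods: tuple[str, str]


@dataclass(frozen=True)
class ClusterResult:
    """Spatio-temporal clusters of class difference with permutation p."""

    t_obs: np.ndarray  # channels x windows
    clusters: tuple[dict, ...]  # channel/window index sets, mass, p_value
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> tuple[dict, ...]:
        return tuple(c for c in self.clusters if c["p_value"] < alpha)


def features_from_courses(
    per_trial_courses: np.ndarray,
    channels: Sequence[int] | None = None,
    time_axis: np.ndarray | None = None,
    window_interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Flatten per-trial courses (N x channels x windows) to N x F.

    ``channels`` selects channel indices (all by default);
    ``window_interval`` (with ``time_axis``) restricts the windows. NaN
    cells are imputed with the per-feature median.
    """
    x = np.asarray(per_trial_courses, dtype=float)
    if x.ndim != 3:
        raise ValueError("per_trial_courses must be N x channels x windows")
    if channels is not None:
        if len(channels) == 0:
            raise ValueError("empty channel subset")
        x = x[:, list(channels), :]
    if window_interval is not None:
        if time_axis is None:
            raise ValueError("window_interval requires time_axis")
        t0, t1 = window_interval
        keep = (time_axis >= t0) & (time_axis < t1)
        if not keep.any():
            raise ValueError("no windows inside the requested interval")
        x = x[:, :, keep]
    feats = x.reshape(x.shape[0], -1)
    if np.isnan(feats).any():
        med = np.nanmedian(feats, axis=0)
        med = np.where(np.isnan(med), 0.0, med)  # all-NaN feature
        idx = np.where(np.isnan(feats))
        feats = feats.copy()
        feats[idx] = med[idx[1]]
    return feats


def lda_cv_accuracy(
    features: np.ndarray,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold LDA accuracy, mean and sd on the 0-100 scale.

    Returns ``(mean, sd, fold_accuracies)``; deterministic for a seed.
    """
    y = np.asarray(labels)
    x = np.asarray(features, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need two classes for discrimination")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} trials for {folds}-fold CV")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(x, y):
        clf = LinearDiscriminantAnalysis()
        clf.fit(x[train], y[train])
        accs.append(float(np.mean(clf.predict(x[test]) == y[test])))
    accs = np.asarray(accs) * 100.0
    return float(accs.mean()), float(accs.std()), accs


def _median_q_prime(
    trials: TrialSet, plan, params: EntropyParams, max_trials: int = 3
) -> float:
    """Median codebook size over a subsample of windows (diagnostic)."""
    sizes = []
    for ti in range(min(max_trials, trials.n_trials)):
        for ci in range(trials.n_channels):
            sig = trials.trials[ti, ci, :]
            tol = params.rho * float(sig.std())
            if tol == 0:
                continue
            for s in plan.starts:
                w = sig[s : s + plan.n_tau]
                sizes.append(vq_model(w, params, rho_abs=tol).n_codes)
    return float(np.median(sizes)) if sizes else float("nan")


def tune_grid(
    trials: TrialSet,
    taus: Sequence[float] = DEFAULT_TAUS,
    Ms: Sequence[int] = DEFAULT_MS,
    rhos: Sequence[float] = DEFAULT_RHOS,
    estimator: str = "vqent",
    seed: int = 0,
    folds: int = 10,
    overlap: float = DEFAULT_OVERLAP,
) -> TuningResult:
    """Exhaustively evaluate the (tau, M, rho) grid by cross-validated
    LDA on entropy time-course features.

    ``trials`` should already be cropped to the analysis (MI) interval.
    The best triple is the accuracy argmax; ties resolve to the smaller
    M, then rho, then tau (the simpler model).
    """
    grid = []
    means, sds = [], []
    plans = {tau: plan_windows(trials.duration, tau, overlap, trials.rate) for tau in taus}
    for tau, m, rho in itertools.product(taus, Ms, rhos):
        params = EntropyParams(M=m, rho=rho, estimator=estimator)
        course = entropy_erds(trials, plans[tau], params)
        feats = features_from_courses(course.per_trial)
        acc, sd, _ = lda_cv_accuracy(feats, trials.labels, folds=folds, seed=seed)
        grid.append((tau, m, rho))
        means.append(acc)
        sds.append(sd)
    means = np.asarray(means)
    sds = np.asarray(sds)
    order = sorted(
        range(len(grid)),
        key=lambda i: (-means[i], grid[i][1], grid[i][2], grid[i][0]),
    )
    best = grid[order[0]]
    q_med = None
    if estimator == "vqent":
        q_med = _median_q_prime(
            trials, plans[best[0]], EntropyParams(M=best[1], rho=best[2], estimator="vqent")
        )
    return TuningResult(
        grid=tuple(grid),
        accuracy_mean=means,
        accuracy_sd=sds,
        best=best,
        estimator=estimator,
        q_prime_median=q_med,
    )


def trial_similarity(
    courses_by_method: Mapping[str, np.ndarray],
    method_pair: tuple[str, str],
    labels: Sequence[str],
    channel: int = 0,
    label_order: tuple[str, str] = ("left", "right"),
) -> SimilarityMatrix:
    """Gaussian trial-to-trial similarity between two estimators' courses.

    ``d(n, n') = exp(-||H_n^m - H_n'^m'||^2 / sigma2_X)`` with ``sigma2_X``
    the course-vector variance pooled over both methods' trial sets. The
    matrix is K x K with K = min(#left, #right); the upper triangle holds
    right-label trial pairs, the lower triangle left-label pairs.
    """
    m, m2 = method_pair
    y = np.asarray(labels)
    a = np.asarray(courses_by_method[m], dtype=float)[:, channel, :]
    b = np.asarray(courses_by_method[m2], dtype=float)[:, channel, :]
    if a.shape != b.shape:
        raise ValueError("methods must share the trial set and window plan")
    pooled = np.vstack([a, b])
    sigma2 = float(np.mean(np.sum((pooled - pooled.mean(axis=0)) ** 2, axis=1)))
    if sigma2 == 0.0:
        raise ValueError("zero course variance; similarity undefined")
    left_idx = np.where(y == label_order[0])[0]
    right_idx = np.where(y == label_order[1])[0]
    k = min(len(left_idx), len(right_idx))
    if k == 0:
        raise ValueError("both classes must be present")
    vals = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            idx = right_idx if i < j else left_idx
            diff = a[idx[i]] - b[idx[j]]
            vals[i, j] = np.exp(-np.dot(diff, diff) / sigma2)
    return SimilarityMatrix(values=vals, sigma2_X=sigma2, methods=(m, m2))


def channel_relevance(
    per_trial_courses: np.ndarray,
    labels: Sequence[str],
    channel_names: Sequence[str] | None = None,
) -> RelevanceMap:
    """Per-channel relevance: Euclidean distance between the class-mean
    entropy time-courses."""
    x = np.asarray(per_trial_courses, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(x[y == classes[0]], axis=0)
        mean_b = np.nanmean(x[y == classes[1]], axis=0)
    diff = np.nan_to_num(mean_a - mean_b)
    weights = np.sqrt((diff**2).sum(axis=-1))
    ranking = tuple(int(i) for i in np.argsort(-weights, kind="stable"))
    if channel_names is None:
        channel_names = tuple(str(i) for i in range(x.shape[1]))
    return RelevanceMap(
        channel_names=tuple(channel_names), weights=weights, ranking=ranking
    )


def incremental_channel_accuracy(
    per_trial_courses: np.ndarray,
    labels: Sequence[str],
    relevance: RelevanceMap,
    channels: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Accuracy curve (%) adding channels in decreasing relevance order.

    ``channels`` optionally restricts the pool (e.g. the ten sensorimotor
    channels); element k-1 of the result uses the top-k channels.
    """
    pool = list(relevance.ranking)
    if channels is not None:
        allowed = set(channels)
        pool = [c for c in pool if c in allowed]
    if not pool:
        raise ValueError("no channels to rank")
    curve = []
    for k in range(1, len(pool) + 1):
        feats = features_from_courses(per_trial_courses, channels=pool[:k])
        acc, _, _ = lda_cv_accuracy(feats, labels, folds=folds, seed=seed)
        curve.append(acc)
    return np.asarray(curve)


def cluster_permutation_test(
    per_trial_courses: np.ndarray,
    labels: Sequence[str],
    montage: Montage,
    n_permutations: int = 1000,
    alpha_cluster: float = 0.02,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based two-sample permutation test over channels x windows.

    Per cell, an independent two-sample t statistic between classes;
    cells with |t| above the two-sided ``alpha_cluster`` critical value
    are clustered over temporal adjacency (neighboring windows) and the
    montage's spatial adjacency; the cluster mass (summed t) is referred
    to a Monte-Carlo null of label permutations (maximum cluster mass per
    permutation), giving family-wise corrected p-values.
    """
    from mne.stats import spatio_temporal_cluster_test, ttest_ind_no_p
    from scipy.sparse import coo_matrix

    x = np.asarray(per_trial_courses, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    n1 = int((y == classes[0]).sum())
    n2 = int((y == classes[1]).sum())
    if min(n1, n2) < 5:
        raise ValueError("need at least 5 trials per class")
    if x.shape[1] != len(montage.channel_names):
        raise ValueError("montage does not match the course's channel axis")
    if n_permutations < 200:
        raise ValueError("need at least 200 permutations")

    # mne layout: (n_obs, n_times, n_vertices)
    xa = x[y == classes[0]].transpose(0, 2, 1)
    xb = x[y == classes[1]].transpose(0, 2, 1)
    df = n1 + n2 - 2
    threshold = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, df))
    adjacency = coo_matrix(montage.adjacency_matrix())
    t_obs, clusters, pvals, _ = spatio_temporal_cluster_test(
        [xa, xb],
        threshold=threshold,
        tail=0,
        stat_fun=ttest_ind_no_p,
        adjacency=adjacency,
        n_permutations=n_permutations,
        rng=np.random.default_rng(seed),
        out_type="mask",
        verbose="error",
    )
    # back to channels x windows
    t_map = np.asarray(t_obs).T
    records = []
    for mask, p in zip(clusters, pvals):
        mask_cw = np.asarray(mask).T
        ch_idx, w_idx = np.where(mask_cw)
        records.append(
            {
                "channels": tuple(int(i) for i in np.unique(ch_idx)),
                "windows": tuple(int(i) for i in np.unique(w_idx)),
                "mask": mask_cw,
                "mass": float(t_map[mask_cw].sum()),
                "p_value": float(p),
            }
        )
    records.sort(key=lambda r: r["p_value"])
    return ClusterResult(
        t_obs=t_map, clusters=tuple(records), n_permutations=n_permutations
    )
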