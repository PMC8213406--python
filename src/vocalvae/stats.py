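"""Statistics on syllable feature tables.

A *feature table* is a :class:`pandas.DataFrame` of syllables x named
numeric features — VAE latent means or features exported by external tools
(MUPET / DeepSqueak / SAP style CSVs).  This module implements the
downstream statistics used to compare vocal repertoires:

- **Maximum mean discrepancy (MMD)** with a spherical Gaussian kernel and
  the median-distance bandwidth heuristic, for pairwise repertoire
  difference matrices.
- A robust **variability index**: the minimum over candidate centers of
  the median squared distance to all points, plus a fast coordinate-median
  approximation.
- **Cross-prediction**: how well one feature set predicts another via
  k-nearest-neighbor regression (variance explained over shuffled folds).
- **Effective dimensionality**: cumulative PCA variance of z-scored
  features.
- **Clustering evaluation**: GMM cross-validation scored by silhouette /
  Calinski-Harabasz / Davies-Bouldin against a covariance-matched Gaussian
  null, and GMM label consistency across disjoint training halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor


def _as_array(X) -> np.ndarray:
    a = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
    if a.ndim != 2:
        a = np.atleast_2d(a)
    if not np.all(np.isfinite(a)):
        raise ValueError("feature table contains non-finite values")
    return a


# ---------------------------------------------------------------------------
# Maximum mean discrepancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMDConfig:
    """Kernel and estimator choices for MMD.

    ``bandwidth_fraction`` scales the median-distance heuristic (1.0 is the
    plain heuristic; 0.25 focuses on finer differences, as used for
    tutor/pupil comparisons).  ``bandwidth`` fixes sigma directly and
    bypasses the heuristic.  The biased V-statistic (always >= 0) is the
    default; the unbiased U-statistic may be slightly negative.
    ``matrix_bandwidth`` chooses whether pairwise matrices resolve sigma on
    each pair's union ("pair", default) or once on the pooled sample
    ("pooled").
    """

    bandwidth_fraction: float = 1.0
    bandwidth: float | None = None
    estimator: str = "biased"  # "biased" | "unbiased"
    matrix_bandwidth: str = "pair"  # "pair" | "pooled"

    def __post_init__(self):
        if not 0 < self.bandwidth_fraction <= 1:
            raise ValueError("bandwidth_fraction must be in (0, 1]")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.estimator not in ("biased", "unbiased"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.matrix_bandwidth not in ("pair", "pooled"):
            raise ValueError(f"unknown matrix_bandwidth {self.matrix_bandwidth!r}")


def median_bandwidth(Z, fraction: float = 1.0) -> float:
    """sigma = fraction x median pairwise Euclidean distance (the median heuristic)."""
    Z = _as_array(Z)
    if len(Z) < 2:
        raise ValueError("need >= 2 rows for the median heuristic")
    med = float(np.median(pdist(Z)))
    if med == 0:
        raise ValueError("all points identical: zero bandwidth")
    return fraction * med


def _gaussian_kernel(A, B, sigma):
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))


def _resolve_bandwidth(X, Y, config: MMDConfig) -> float:
    if config.bandwidth is not None:
        return config.bandwidth
    return median_bandwidth(np.vstack([X, Y]), config.bandwidth_fraction)


def mmd2(X, Y, config: MMDConfig = MMDConfig(), sigma: float | None = None) -> float:
    """Squared maximum mean discrepancy between two samples.

    Gaussian-kernel RKHS estimate; the bandwidth is resolved on the
    aggregate (union) sample unless *sigma* or ``config.bandwidth`` is
    given.  The biased estimator is a V-statistic and is nonnegative.
    """
    X, Y = _as_array(X), _as_array(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature mismatch: X has {X.shape[1]} columns, Y has {Y.shape[1]}"
        )
    if len(X) < 2 or len(Y) < 2:
        raise ValueError("need >= 2 rows per sample")
    if sigma is None:
        sigma = _resolve_bandwidth(X, Y, config)
    kxx = _gaussian_kernel(X, X, sigma)
    kyy = _gaussian_kernel(Y, Y, sigma)
    kxy = _gaussian_kernel(X, Y, sigma)
    n, m = len(X), len(Y)
    if config.estimator == "biased":
        return float(kxx.mean() + kyy.mean() - 2.0 * kxy.mean())
    sxx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    syy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    return float(sxx + syy - 2.0 * kxy.mean())


def mmd_matrix(sessions, config: MMDConfig = MMDConfig(), cluster_order: bool = False):
    """Pairwise MMD between session repertoires.

    *sessions* maps session id -> feature table (or is a list).  Bandwidths
    follow ``config.matrix_bandwidth``: per-pair union (default) or one
    sigma resolved on the pooled sample.  Returns a symmetric, zero-
    diagonal DataFrame; with ``cluster_order`` rows are reordered by
    average-linkage agglomerative clustering of the MMD distances.
    """
    if isinstance(sessions, dict):
        ids, tables = list(sessions.keys()), list(sessions.values())
    else:
        ids, tables = list(range(len(sessions))), list(sessions)
    if len(tables) < 2:
        raise ValueError("need >= 2 sessions")
    arrays = [_as_array(t) for t in tables]
    bad = [ids[i] for i, a in enumerate(arrays) if len(a) < 2]
    if bad:
        raise ValueError(f"degenerate sessions with < 2 rows: {bad}")
    sigma = None
    if config.bandwidth is not None:
        sigma = config.bandwidth
    elif config.matrix_bandwidth == "pooled":
        sigma = median_bandwidth(np.vstack(arrays), config.bandwidth_fraction)
    n = len(arrays)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = mmd2(arrays[i], arrays[j], config, sigma=sigma)
    df = pd.DataFrame(M, index=ids, columns=ids)
    if cluster_order:
        from scipy.cluster.hierarchy import leaves_list, linkage

        order = leaves_list(linkage(squareform(np.maximum(M, 0.0), checks=False),
                                    method="average"))
        df = df.iloc[order, order]
    return df


# ---------------------------------------------------------------------------
# Variability index
# ---------------------------------------------------------------------------

def _rho(Z, center):
    """Median over all points of the squared distance to *center* (self included)."""
    return float(np.median(np.sum((Z - center) ** 2, axis=1)))


def variability_index(Z) -> float:
    """Robust dispersion: V.I. = min over data points z_i of
    median_j ||z_i - z_j||^2 (the self term j = i, distance 0, included).

    Exact O(n^2) evaluation over all candidate centers.
    """
    Z = _as_array(Z)
    if len(Z) < 2:
        raise ValueError("need >= 2 rows")
    sq = squareform(pdist(Z, "sqeuclidean"))
    return float(np.min(np.median(sq, axis=1)))


def variability_index_fast(Z) -> float:
    """Approximate V.I.: rho evaluated only at the coordinate-wise median.

    O(n d) memory; suitable for per-timepoint variability traces where the
    exact index would be recomputed thousands of times.
    """
    Z = _as_array(Z)
    if len(Z) < 2:
        raise ValueError("need >= 2 rows")
    return _rho(Z, np.median(Z, axis=0))


def variability_reduction(Z_a, Z_b, fast: bool = False) -> float:
    """1 - V.I.(a) / V.I.(b): positive when condition *a* is less variable.

    Condition *a* plays the "directed" role, *b* the "undirected" baseline.
    The index is meaningful within a single syllable type: across a mixed
    repertoire it is dominated by between-type distances; see
    :func:`variability_reduction_by_type`.
    """
    vi = variability_index_fast if fast else variability_index
    vb = vi(Z_b)
    if vb == 0:
        raise ValueError("baseline variability index is zero")
    return 1.0 - vi(Z_a) / vb


def variability_reduction_by_type(Z_a, Z_b, types_a, types_b,
                                  fast: bool = False) -> float:
    """Mean per-syllable-type variability reduction of condition *a* vs *b*.

    The variability index is computed separately for each syllable type
    (condition-a vs condition-b rows of that type) and the reductions are
    averaged over the types present in both conditions.
    """
    Z_a, Z_b = _as_array(Z_a), _as_array(Z_b)
    types_a, types_b = np.asarray(types_a), np.asarray(types_b)
    shared = [t for t in np.unique(types_a) if (types_b == t).sum() >= 2
              and (types_a == t).sum() >= 2]
    if not shared:
        raise ValueError("no syllable type present in both conditions")
    reductions = [
        variability_reduction(Z_a[types_a == t], Z_b[types_b == t], fast=fast)
        for t in shared
    ]
    return float(np.mean(reductions))


# ---------------------------------------------------------------------------
# Cross-prediction and effective dimensionality
# ---------------------------------------------------------------------------

def drop_minor_pcs(Z, min_variance_fraction: float = 0.01) -> np.ndarray:
    """Project onto principal components holding >= the given variance fraction.

    Mirrors the latent-feature preprocessing in which components carrying
    less than 1% of total feature variance are removed before comparison.
    """
    Z = _as_array(Z)
    pca = PCA().fit(Z)
    keep = pca.explained_variance_ratio_ >= min_variance_fraction
    return pca.transform(Z)[:, keep]


def _variance_explained(pred, target):
    """Mean per-column squared Pearson correlation of prediction vs target.

    Chosen over the residual-based R^2 because the k-neighbor average
    carries sampling variance of order 1/k even for a perfect predictor,
    which biases residual R^2 by about -1/k on unpredictable targets; the
    squared correlation is ~0 for independent noise and ~1 for faithful
    prediction.
    """
    pred = np.atleast_2d(pred.T).T
    target = np.atleast_2d(target.T).T
    out = []
    for j in range(target.shape[1]):
        sp, st = pred[:, j].std(), target[:, j].std()
        if sp == 0 or st == 0:
            out.append(0.0)
            continue
        out.append(float(np.corrcoef(pred[:, j], target[:, j])[0, 1] ** 2))
    return float(np.mean(out))


def _knn_r2(A, B, k, folds, seed):
    """Held-out variance explained predicting B from A with k-NN regression."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    r2s = []
    for train, test in kf.split(A):
        mu_a, sd_a = A[train].mean(0), A[train].std(0)
        mu_b, sd_b = B[train].mean(0), B[train].std(0)
        sd_a[sd_a == 0] = 1.0
        sd_b[sd_b == 0] = 1.0
        a_tr, a_te = (A[train] - mu_a) / sd_a, (A[test] - mu_a) / sd_a
        b_tr, b_te = (B[train] - mu_b) / sd_b, (B[test] - mu_b) / sd_b
        pred = KNeighborsRegressor(n_neighbors=k).fit(a_tr, b_tr).predict(a_te)
        r2s.append(_variance_explained(pred, b_te))
    return float(np.mean(r2s))


def cross_predict(
    A,
    B,
    k: int = 10,
    folds: int = 5,
    seed: int = 0,
    filter_pcs: str | None = None,
):
    """Bidirectional k-NN cross-prediction between two feature tables.

    Rows must be aligned (the same syllables described by two feature
    sets).  Features are z-scored with training-fold statistics; nearest
    neighbors use Euclidean distance with k = 10 by default, and the
    reported variance explained is the mean held-out R^2 over *folds*
    shuffled folds.  ``filter_pcs`` ("a", "b" or "both") drops principal
    components holding < 1% of total variance from that table first — the
    treatment applied to latent features.

    Returns ``{"a_to_b": R2, "b_to_a": R2}``.
    """
    A, B = _as_array(A), _as_array(B)
    if len(A) != len(B):
        raise ValueError(f"misaligned rows: {len(A)} vs {len(B)}")
    if filter_pcs in ("a", "both"):
        A = drop_minor_pcs(A)
    if filter_pcs in ("b", "both"):
        B = drop_minor_pcs(B)
    return {
        "a_to_b": _knn_r2(A, B, k, folds, seed),
        "b_to_a": _knn_r2(B, A, k, folds, seed),
    }


def effective_dimensionality_curve(Z) -> np.ndarray:
    """Cumulative variance fraction per number of principal components.

    Columns are z-scored first (so eigenvalues sum to the column count and
    no feature's natural scale dominates); zero-variance columns are
    dropped with a warning.  The returned curve is nondecreasing and ends
    at 1.
    """
    import warnings

    Z = _as_array(Z)
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance columns")
        Z = Z[:, sd > 0]
        sd = sd[sd > 0]
    Zs = (Z - Z.mean(axis=0)) / sd
    var = PCA().fit(Zs).explained_variance_ratio_
    return np.cumsum(var)


def effective_dimensionality(Z, min_variance_fraction: float = 0.01) -> int:
    """Number of principal components each holding >= the given variance fraction."""
    Z = _as_array(Z)
    ratio = PCA().fit(Z).explained_variance_ratio_
    return int(np.sum(ratio >= min_variance_fraction))


def nearest_neighbors(query, Z, n: int):
    """Ids of the n Euclidean-nearest rows, ascending distance, ties by id."""
    arr = _as_array(Z)
    if n > len(arr):
        raise ValueError(f"n={n} exceeds {len(arr)} rows")
    q = np.asarray(query, dtype=float).ravel()
    if q.shape[0] != arr.shape[1]:
        raise ValueError("query dimension mismatch")
    dist = np.sqrt(np.sum((arr - q) ** 2, axis=1))
    ids = Z.index.to_numpy() if isinstance(Z, pd.DataFrame) else np.arange(len(arr))
    order = np.lexsort((ids, dist))
    return list(ids[order[:n]])


# ---------------------------------------------------------------------------
# Clustering evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClusterEvalResult:
    """Per-fold clustering metrics for data and a matched Gaussian null.

    ``differences`` holds real-minus-null values oriented so that higher
    means more clustered (Davies-Bouldin is negated).
    """

    real: pd.DataFrame
    null: pd.DataFrame
    differences: pd.DataFrame
    flags: list


_METRICS = ("silhouette", "calinski_harabasz", "davies_bouldin")


def _score_fold(train, test, k, seed, flags, tag):
    gmm = GaussianMixture(n_components=k, covariance_type="full", random_state=seed,
                          n_init=1, reg_covar=1e-6)
    labels = gmm.fit(train).predict(test)
    present = np.unique(labels)
    if len(present) < 2:
        flags.append(f"{tag}: single cluster on held-out data")
        return {m: np.nan for m in _METRICS}
    if len(present) < k:
        flags.append(f"{tag}: {k - len(present)} empty clusters on held-out data")
    return {
        "silhouette": silhouette_score(test, labels),
        "calinski_harabasz": calinski_harabasz_score(test, labels),
        "davies_bouldin": davies_bouldin_score(test, labels),
    }


def cluster_eval(Z, k: int = 6, folds: int = 10, seed: int = 0) -> ClusterEvalResult:
    """How clustered are the features, relative to matched Gaussian noise?

    For each cross-validation fold a Gaussian mixture model (k components,
    full covariance) is fit on the training split by EM and held-out points
    are assigned; the mean silhouette coefficient, Calinski-Harabasz index
    and Davies-Bouldin index are computed on the held-out split.  The same
    procedure runs on a synthetic Gaussian dataset matched for covariance,
    mean and sample count.  Reported differences are real minus null per
    fold, signs oriented so higher = more clustered.
    """
    Z = _as_array(Z)
    if len(Z) < k * folds:
        raise ValueError(f"need >= k*folds = {k * folds} rows, got {len(Z)}")
    rng = np.random.default_rng(seed)
    null = rng.multivariate_normal(Z.mean(axis=0), np.cov(Z.T), size=len(Z))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    flags, real_rows, null_rows = [], [], []
    for f, (tr, te) in enumerate(kf.split(Z)):
        real_rows.append(_score_fold(Z[tr], Z[te], k, seed, flags, f"real fold {f}"))
        null_rows.append(_score_fold(null[tr], null[te], k, seed, flags,
                                     f"null fold {f}"))
    real = pd.DataFrame(real_rows)
    null_df = pd.DataFrame(null_rows)
    diff = real - null_df
    diff["davies_bouldin"] = -diff["davies_bouldin"]  # lower DB = more clustered
    return ClusterEvalResult(real=real, null=null_df, differences=diff, flags=flags)


def gmm_label_consistency(Z, k: int, seed: int = 0) -> float:
    """Agreement of GMM labelings trained on disjoint halves of the data.

    The rows are split in half at random; a GMM(k, full covariance) is fit
    on each half and both label the full dataset.  The score is the best
    label-permutation agreement (optimal assignment on the confusion
    matrix), between 1/k (inconsistent) and 1 (identical partitions).
    """
    Z = _as_array(Z)
    if len(Z) < 2 * k:
        raise ValueError("need >= 2k rows")
    if k == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(Z))
    half = len(Z) // 2
    fits = [
        GaussianMixture(n_components=k, covariance_type="full", random_state=seed,
                        reg_covar=1e-6).fit(Z[idx])
        for idx in (perm[:half], perm[half:])
    ]
    la, lb = (f.predict(Z) for f in fits)
    confusion = np.zeros((k, k))
    np.add.at(confusion, (la, lb), 1.0)
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum() / len(Z))


# ---------------------------------------------------------------------------
# CSV I/O for feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV: first column observation id, rest numeric."""
    df = pd.read_csv(path, index_col=0)
    df = df.dropna()
    if df.columns.duplicated().any():
        raise ValueError("duplicate feature column names")
    return df.astype(float)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path)
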