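"""Multivariate morphometric statistics: log transform, standardization,
species means, PCA, one-way ANOVA, CVA with Mahalanobis distances, Goodall's
Procrustes ANOVA, OLS regression and body-size correction.

Data enter as pandas DataFrames (rows = specimens or species, columns =
traits or shape coordinates) with a parallel species/group label sequence.
Missing values (NaN) propagate through the log transform; multivariate
routines drop incomplete rows, univariate routines work per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrdinationResult",
    "CvaResult",
    "AnovaResult",
    "DistanceMatrix",
    "log_transform",
    "standardize",
    "species_means",
    "pca",
    "one_way_anova",
    "cva",
    "procrustes_anova",
    "ols_regression",
    "size_correct",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal and row labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels and matrix size mismatch")
        v = (v + v.T) / 2.0  # enforce exact symmetry against fp noise
        np.fill_diagonal(v, 0.0)
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = np.clip(v, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reindex(self, labels) -> "DistanceMatrix":
        """The same distances with rows/columns in the given label order."""
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        pos = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=labels, values=self.values[np.ix_(pos, pos)])


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # rows × components
    loadings: pd.DataFrame  # variables × components
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if not np.isclose(vf.sum(), 1.0, atol=1e-9):
            raise ValueError("variance fractions must sum to 1")
        if (np.diff(vf) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
        self.variance_fraction = vf


@dataclass
class CvaResult:
    canonical_scores: pd.DataFrame
    mahalanobis: DistanceMatrix
    axis_eigenvalues: np.ndarray


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float = np.nan
    ss_within: float = np.nan


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def log_transform(frame: pd.DataFrame) -> pd.DataFrame:
    """Natural log of every (positive) value; NaN propagates as missing."""
    num = frame.select_dtypes(include=[np.number])
    bad = (num <= 0).any()
    if bad.any():
        col = bad[bad].index[0]
        row = num.index[(num[col] <= 0).fillna(False)][0]
        raise ValueError(f"nonpositive value for trait {col!r}, specimen {row!r}")
    out = frame.copy()
    out[num.columns] = np.log(num)
    return out


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to unit sample variance."""
    if len(frame) < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = frame.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"constant column(s): {list(zero.index)}")
    return (frame - frame.mean(axis=0)) / sd


def species_means(frame: pd.DataFrame, species) -> pd.DataFrame:
    """Per-species arithmetic means over complete rows, in first-appearance
    order of the species labels."""
    species = pd.Series(list(species), index=frame.index, name="species")
    complete = frame.dropna(axis=0)
    if complete.empty:
        raise ValueError("no complete rows")
    groups = species.loc[complete.index]
    order = list(dict.fromkeys(species))
    empty = [s for s in order if s not in set(groups)]
    if empty:
        raise ValueError(f"species with no complete rows: {empty}")
    means = complete.groupby(groups, sort=False).mean()
    return means.loc[order]


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


def pca(frame: pd.DataFrame, mode: str = "covariance") -> OrdinationResult:
    """Principal component analysis of a rows × variables table.

    ``mode="covariance"`` decomposes the covariance matrix of the centered
    data; ``"correlation"`` additionally scales columns to unit variance.
    Components are ordered by decreasing eigenvalue; for reproducibility the
    largest-magnitude loading of each component is made positive.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown PCA mode {mode!r}")
    if len(frame) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    Xc = X - X.mean(axis=0)
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column in correlation-mode PCA")
        Xc = Xc / sd
    n = Xc.shape[0]
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = svals**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("data have zero total variance")
    loadings = Vt.T
    # sign convention: largest-|loading| positive, per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = Xc @ loadings
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=frame.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=frame.columns, columns=comp_names),
        variance_fraction=eig / total,
    )


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _group_sums_of_squares(values: np.ndarray, groups: np.ndarray):
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in np.unique(groups):
        v = values[groups == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    return ssb, ssw


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = len(values)
    df_b = len(uniq) - 1
    df_w = n - len(uniq)
    if df_w < 1:
        raise ValueError("zero within-group degrees of freedom (all singletons)")
    ssb, ssw = _group_sums_of_squares(values, groups)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, ssb, ssw)
        warnings.warn("zero within-group variation: F is infinite")
        return AnovaResult(np.inf, df_b, df_w, 0.0, ssb, ssw)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(ssb), float(ssw))


def procrustes_anova(
    shape_matrix,
    centroid_sizes,
    groups,
    shape_dim: int | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[AnovaResult, AnovaResult]:
    """Goodall-style shape ANOVA plus a size ANOVA.

    Shape variation (rows of ``shape_matrix``, typically tangent-space
    coordinates) is decomposed into between- and within-group sums of
    squared deviations summed over all coordinates; degrees of freedom are
    multiplied by the shape-space dimension (``2k - 4`` for k 2-D landmarks
    unless ``shape_dim`` is given). Size is a classical one-way ANOVA on log
    centroid size. With ``n_perm`` set, the shape p-value is replaced by a
    permutation p over random group relabelings.
    """
    X = np.asarray(shape_matrix, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if shape_dim is None:
        ncoord = X.shape[1]
        if ncoord % 2 == 0 and ncoord >= 6:
            shape_dim = ncoord - 4  # 2k - 4 for k 2-D landmarks
        else:
            shape_dim = ncoord
    n = X.shape[0]
    g = len(uniq)
    df_b = (g - 1) * shape_dim
    df_w = (n - g) * shape_dim
    if df_b < 1 or df_w < 1:
        raise ValueError("degenerate degrees of freedom")

    def shape_F(labels: np.ndarray) -> tuple[float, float, float]:
        grand = X.mean(axis=0)
        ssb = 0.0
        ssw = 0.0
        for lab in uniq:
            sub = X[labels == lab]
            m = sub.mean(axis=0)
            ssb += len(sub) * ((m - grand) ** 2).sum()
            ssw += ((sub - m) ** 2).sum()
        if ssw == 0:
            return (np.inf if ssb > 0 else 0.0), ssb, ssw
        return (ssb / df_b) / (ssw / df_w), ssb, ssw

    F, ssb, ssw = shape_F(groups)
    if np.isinf(F):
        warnings.warn("zero within-group shape variation: F is infinite")
        p = 0.0
    elif n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            Fp, _, _ = shape_F(perm)
            if Fp >= F:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p = float(stats.f.sf(F, df_b, df_w))
    shape_res = AnovaResult(float(F), df_b, df_w, float(p), float(ssb), float(ssw))
    size_res = one_way_anova(np.log(np.asarray(centroid_sizes, dtype=float)), groups)
    return shape_res, size_res


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------


def cva(frame: pd.DataFrame, groups, rank_tol: float = 1e-10) -> CvaResult:
    """Canonical variate analysis with pairwise Mahalanobis distances.

    The data are first reduced to the principal components of their total
    covariance whose eigenvalues exceed ``rank_tol`` times the largest
    (superimposed shape coordinates are rank-deficient by construction), then
    the canonical axes are the eigenvectors of W⁻¹B for pooled within-group
    covariance W and between-group scatter B. Mahalanobis distances use W in
    the reduced space and are invariant to invertible linear transforms of
    the input.
    """
    groups = np.asarray([str(g) for g in groups])
    X = frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("CVA input contains missing values")
    uniq = list(dict.fromkeys(groups))
    if len(uniq) < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = {g: int((groups == g).sum()) for g in uniq}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    Xc = X - X.mean(axis=0)
    n = Xc.shape[0]
    g = len(uniq)
    # rank reduction via total-covariance PCA; the pooled within-group
    # covariance has rank at most n - g, so cap the subspace there and back
    # off further if W is still numerically singular
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = svals**2
    d_max = min(int((eig > rank_tol * eig.max()).sum()), n - g)
    if d_max < 1:
        raise ValueError("no usable dimensions after rank reduction")

    from scipy.linalg import eigh

    W = B = Z = None
    for d in range(d_max, 0, -1):
        basis = Vt[:d].T
        Z = Xc @ basis
        means = np.stack([Z[groups == lab].mean(axis=0) for lab in uniq])
        W = np.zeros((d, d))
        for lab, m in zip(uniq, means):
            sub = Z[groups == lab] - m
            W += sub.T @ sub
        W /= n - g
        wev = np.linalg.eigvalsh(W)
        if wev.min() > rank_tol * max(wev.max(), 1e-300):
            break
    else:  # pragma: no cover
        raise ValueError("pooled within-group covariance is singular")
    B = np.zeros((d, d))
    for lab, m in zip(uniq, means):
        B += counts[lab] * np.outer(m, m)
    B /= g - 1
    p = d
    evals, evecs = eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    evecs = evecs[:, order][:, :n_axes]
    scores = Z @ evecs
    axis_names = [f"CV{i + 1}" for i in range(n_axes)]

    Winv = np.linalg.inv(W)
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            D[i, j] = D[j, i] = float(np.sqrt(d @ Winv @ d))
    return CvaResult(
        canonical_scores=pd.DataFrame(scores, index=frame.index, columns=axis_names),
        mahalanobis=DistanceMatrix(labels=tuple(uniq), values=D),
        axis_eigenvalues=evals,
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass
class OlsResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    stderr: float


def ols_regression(y, x) -> OlsResult:
    """Simple least-squares regression with a two-sided t test on the slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("regression needs at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(y) == 0:
        # a flat response is a legal degenerate fit, not an error
        return OlsResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                         p=1.0, stderr=0.0)
    res = stats.linregress(x, y)
    return OlsResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        stderr=float(res.stderr),
    )


def size_correct(trait_frame: pd.DataFrame, log_weight) -> pd.DataFrame:
    """Residuals of each (log) trait regressed on log body weight — the
    conventional size-corrected traits."""
    w = np.asarray(log_weight, dtype=float)
    if len(w) != len(trait_frame):
        raise ValueError("weight vector length mismatch")
    if not np.isfinite(w).all():
        raise ValueError("log weight must be present for every row")
    out = {}
    for col in trait_frame.columns:
        y = trait_frame[col].to_numpy(dtype=float)
        fit = ols_regression(y, w)
        out[col] = y - (fit.intercept + fit.slope * w)
    return pd.DataFrame(out, index=trait_frame.index)
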