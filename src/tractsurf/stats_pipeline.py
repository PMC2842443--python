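"""Group statistics on per-vertex surface maps.

Five stages, mirroring a classical morphometry battery:

1. vertex-wise ordinary least squares with diagnosis as the main factor
   (and optionally intracranial volume as a nuisance covariate);
2. an omnibus permutation test on the suprathreshold vertex count —
   diagnosis labels are permuted, covariates stay with their subjects, and
   the overall p is the fraction of permutations whose count of p < alpha
   vertices reaches the observed count;
3. PCA of the stacked maps, followed by a pooled-variance two-sample t-test
   per component to select the components that separate the groups;
4. two-class LDA on the selected components with leave-one-out cross
   validation, summarized by accuracy, sensitivity (AD detection rate),
   specificity (control detection rate), and the F-score of the
   control-positive class;
5. a canonical analysis: the leading eigenvector of E^-1 H (H the
   between-group SSCP of the fitted group contrast, E the residual SSCP)
   weights the selected components into one canonical score per subject,
   which is then correlated with the MMSE cognitive score.

By default ("paper" mode) PCA and component selection are computed once on
the full sample and only the LDA fit is cross-validated; a leakage-free
"nested" mode refits both inside every fold and is the statistically
preferred option when the goal is an unbiased accuracy estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


# ---------------------------------------------------------------------------
# Design and vertex-wise GLM
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Intercept + diagnosis indicator (CON=0, AD=1) + optional covariates."""

    diagnosis: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.diagnosis = np.asarray(self.diagnosis, dtype=np.float64).ravel()
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != len(self.diagnosis):
                self.covariates = self.covariates.T
        X = self.matrix()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient")

    def matrix(self, diagnosis: np.ndarray | None = None) -> np.ndarray:
        d = self.diagnosis if diagnosis is None else np.asarray(diagnosis, dtype=np.float64)
        cols = [np.ones(len(d)), d]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        return np.column_stack(cols)

    @property
    def n_subjects(self) -> int:
        return len(self.diagnosis)


@dataclass
class GlmVertexResult:
    coef: np.ndarray       # diagnosis effect per vertex
    t: np.ndarray
    p: np.ndarray          # two-sided
    df: int


def vertexwise_glm(maps: np.ndarray, design: DesignMatrix) -> GlmVertexResult:
    """OLS at every vertex; t and two-sided p for the diagnosis coefficient.

    ``maps`` is (n_subjects, n_vertices).  Requires at least three more
    subjects than design columns so the residual variance is estimable.
    """
    Y = np.asarray(maps, dtype=np.float64)
    X = design.matrix()
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("one row of maps per subject required")
    if n < k + 3:
        raise ValueError("need at least 3 more subjects than design columns")
    coef, t, df = _diagnosis_t(Y, X)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return GlmVertexResult(coef=coef, t=t, p=p, df=df)


def _diagnosis_t(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Diagnosis coefficient and t statistic for each column of Y."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / df
    se = np.sqrt(np.clip(sigma2 * XtX_inv[1, 1], 1e-300, None))
    return beta[1], beta[1] / se, df


# ---------------------------------------------------------------------------
# Permutation omnibus on the suprathreshold count
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    overall_p: float
    alpha: float
    n_perm: int


def permutation_omnibus(maps: np.ndarray, design: DesignMatrix,
                        alpha: float = 0.05, n_perm: int = 10000,
                        seed: int | np.random.Generator = 0,
                        add_one: bool = False) -> PermutationResult:
    """Omnibus significance of a vertex-wise statistical map.

    Each trial randomly reassigns the diagnosis labels (covariates stay with
    their subjects) and records the number of vertices with p < alpha; the
    overall p-value is the fraction of trials whose count is >= the observed
    count.  ``add_one`` switches to the (b+1)/(m+1) estimator.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse omnibus p-value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    glm = vertexwise_glm(maps, design)
    observed = int(np.sum(glm.p < alpha))
    # p < alpha is equivalent to |t| > t_crit at the same df, which avoids
    # evaluating the t survival function inside the permutation loop
    t_crit = sps.t.isf(alpha / 2.0, glm.df)
    Y = np.asarray(maps, dtype=np.float64)
    labels = design.diagnosis.copy()
    null_counts = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        d = DesignMatrix(perm, design.covariates, design.covariate_names)
        _, t_null, _ = _diagnosis_t(Y, d.matrix())
        null_counts[b] = int(np.sum(np.abs(t_null) > t_crit))
    if observed == 0:
        overall = 1.0
    elif add_one:
        overall = (np.sum(null_counts >= observed) + 1.0) / (n_perm + 1.0)
    else:
        overall = float(np.sum(null_counts >= observed)) / n_perm
    return PermutationResult(observed_count=observed, null_counts=null_counts,
                             overall_p=float(overall), alpha=alpha, n_perm=n_perm)


# ---------------------------------------------------------------------------
# PCA and component selection
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray          # (n_subjects, n_components)
    components: np.ndarray      # (n_components, n_features)
    explained_variance: np.ndarray
    mean: np.ndarray


def pca_reduce(feature_matrix: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Column-mean-centered SVD; at most n_subjects - 1 components."""
    X = np.asarray(feature_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (subjects x features) matrix with >= 2 subjects")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(len(s), bool)
    keep &= np.arange(len(s)) < X.shape[0] - 1
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    scores = U * s
    explained = s ** 2 / (X.shape[0] - 1)
    return PcaResult(scores=scores, components=Vt, explained_variance=explained, mean=mean)


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Student t with pooled variance; returns (t, two-sided p)."""
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def select_pcs(scores: np.ndarray, labels: np.ndarray,
               alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Indices (0-based) of components whose group t-test has p < alpha.

    Returns ``(selected_indices, p_values)``.  Report component numbers as
    index + 1 when naming them ("2nd PC").
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    pvals = np.array([pooled_t_test(scores[labels == groups[0], j],
                                    scores[labels == groups[1], j])[1]
                      for j in range(scores.shape[1])])
    return np.flatnonzero(pvals < alpha), pvals


# ---------------------------------------------------------------------------
# LDA with leave-one-out cross validation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResult:
    tp: int   # controls called control (control = positive class)
    fn: int   # controls called AD
    tn: int   # AD called AD
    fp: int   # AD called control
    predictions: np.ndarray
    accuracy_pct: float = field(init=False)
    sensitivity_pct: float = field(init=False)
    specificity_pct: float = field(init=False)
    f_score: float = field(init=False)

    def __post_init__(self) -> None:
        m = classification_metrics((self.tp, self.fn, self.tn, self.fp))
        self.accuracy_pct = m["accuracy_pct"]
        self.sensitivity_pct = m["sensitivity_pct"]
        self.specificity_pct = m["specificity_pct"]
        self.f_score = m["f_score"]


def _round_half_up(x: float, ndigits: int) -> float:
    """Round with halves away from zero (the convention of reported tables,
    where e.g. 26/32 = 81.25% is reported as 81.3%), unlike Python's
    round-half-even."""
    if not np.isfinite(x):
        return x
    scale = 10.0 ** ndigits
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x))


def classification_metrics(confusion) -> dict[str, float]:
    """Accuracy/sensitivity/specificity (%) and control-positive F-score.

    ``confusion`` is ``(tp, fn, tn, fp)`` with controls as the positive
    class: tp = controls called control, fn = controls called AD, tn = AD
    called AD, fp = AD called control.  Sensitivity is the AD detection
    rate tn / (tn + fp); specificity the control detection rate
    tp / (tp + fn).  Percentages are rounded (half up) to one decimal and
    the F-score to three decimals, the conventional reporting precision.
    """
    tp, fn, tn, fp = (int(v) for v in confusion)
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    specificity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {
        "accuracy_pct": _round_half_up(accuracy, 1),
        "sensitivity_pct": _round_half_up(sensitivity, 1),
        "specificity_pct": _round_half_up(specificity, 1),
        "f_score": _round_half_up(f, 3),
    }


def _fit_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    try:
        lda.fit(X, y)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; ridge-regularizing LDA")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
        lda.fit(X, y)
    return lda


def lda_loocv(features: np.ndarray, labels: np.ndarray) -> ClassifierResult:
    """Leave-one-out LDA: each subject predicted by a model fit on the rest.

    ``labels`` are 0 for controls, 1 for AD.  Class priors come from each
    training fold.  The aggregate confusion uses controls as the positive
    class.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] == 1 and len(np.asarray(labels)) > 1:
        X = X.T
    y = np.asarray(labels, dtype=int).ravel()
    if X.shape[1] == 0:
        raise ValueError("no features selected: classifier refuses an empty feature set")
    n = len(y)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 subjects per group")
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        lda = _fit_lda(X[mask], y[mask])
        preds[i] = int(lda.predict(X[i:i + 1])[0])
        mask[i] = True
    tp = int(np.sum((y == 0) & (preds == 0)))
    fn = int(np.sum((y == 0) & (preds == 1)))
    tn = int(np.sum((y == 1) & (preds == 1)))
    fp = int(np.sum((y == 1) & (preds == 0)))
    return ClassifierResult(tp=tp, fn=fn, tn=tn, fp=fp, predictions=preds)


def classify_maps(maps: np.ndarray, labels: np.ndarray, alpha: float = 0.05,
                  mode: str = "paper") -> tuple[ClassifierResult, np.ndarray]:
    """PCA -> t-test component selection -> LOOCV LDA on a map stack.

    ``mode="paper"``: PCA and selection on the full sample, LOOCV on the
    LDA fit only.  ``mode="nested"``: PCA and selection recomputed inside
    each training fold (no information from the held-out subject leaks into
    feature construction).  Returns the classifier result and the selected
    component indices of the full-sample analysis (for reporting).
    """
    y = np.asarray(labels, dtype=int).ravel()
    pca = pca_reduce(np.asarray(maps, dtype=np.float64))
    selected, _ = select_pcs(pca.scores, y, alpha=alpha)
    if mode == "paper":
        if selected.size == 0:
            raise ValueError("no components pass the selection threshold")
        result = lda_loocv(pca.scores[:, selected], y)
        return result, selected
    if mode != "nested":
        raise ValueError("mode must be 'paper' or 'nested'")
    X = np.asarray(maps, dtype=np.float64)
    n = len(y)
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        p = pca_reduce(X[mask])
        sel, _ = select_pcs(p.scores, y[mask], alpha=alpha)
        if sel.size == 0:
            # fall back to the most discriminative component of the fold
            _, pv = select_pcs(p.scores, y[mask], alpha=1.1)
            sel = np.array([int(np.argmin(pv))])
        lda = _fit_lda(p.scores[:, sel], y[mask])
        test_scores = ((X[i] - p.mean) @ p.components.T)[sel]
        preds[i] = int(lda.predict(test_scores[None, :])[0])
        mask[i] = True
    tp = int(np.sum((y == 0) & (preds == 0)))
    fn = int(np.sum((y == 0) & (preds == 1)))
    tn = int(np.sum((y == 1) & (preds == 1)))
    fp = int(np.sum((y == 1) & (preds == 0)))
    return ClassifierResult(tp=tp, fn=fn, tn=tn, fp=fp, predictions=preds), selected


# ---------------------------------------------------------------------------
# Canonical analysis and correlation
# ---------------------------------------------------------------------------

@dataclass
class CanonicalResult:
    weights: np.ndarray
    scores: np.ndarray
    pearson_r: float
    p: float


def canonical_scores(pc_scores: np.ndarray, labels: np.ndarray,
                     mmse: np.ndarray | None = None) -> CanonicalResult:
    """Canonical discriminant scores from selected component scores.

    Fits the multivariate linear model (components ~ group), forms H — the
    SSCP of the fitted group-contrast values — and E — the SSCP of the
    residuals — and takes the leading eigenvector of ``E^-1 H`` as the
    weight vector.  The sign is fixed so the AD group mean score exceeds
    the control group mean.  When ``mmse`` is given, the Pearson
    correlation of scores with MMSE is attached.
    """
    X = np.atleast_2d(np.asarray(pc_scores, dtype=np.float64))
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("one row of scores per subject required")
    if len(np.unique(y)) != 2:
        raise ValueError("two groups required")
    D = np.column_stack([np.ones(len(y)), y])
    beta = np.linalg.lstsq(D, X, rcond=None)[0]
    fitted = D @ beta
    resid = X - fitted
    contrast = fitted - fitted.mean(axis=0)      # group effect around the grand mean
    H = contrast.T @ contrast
    E = resid.T @ resid
    try:
        M = np.linalg.solve(E, H)
    except np.linalg.LinAlgError:
        warnings.warn("singular residual SSCP; ridge-regularizing")
        E = E + 1e-6 * np.trace(E) / max(len(E), 1) * np.eye(len(E))
        M = np.linalg.solve(E, H)
    eigvals, eigvecs = np.linalg.eig(M)
    w = np.real(eigvecs[:, np.argmax(np.real(eigvals))])
    scores = X @ w
    if scores[y == 1].mean() < scores[y == 0].mean():
        w = -w
        scores = -scores
    if mmse is not None:
        r, p = pearson_corr(scores, np.asarray(mmse, dtype=np.float64))
    else:
        r, p = float("nan"), float("nan")
    return CanonicalResult(weights=w, scores=scores, pearson_r=r, p=p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold ``alpha / n_tests`` (report at 4 decimals)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
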