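"""Evaluation machinery for the discriminant pipeline.

Covers the analysis protocol applied to the panel features:
natural-log transformation, univariate screening with
Benjamini–Hochberg FDR, Pearson correlations, ROC/AUC with operating
point metrics, Monte-Carlo cross-validation (repeated class-stratified
2/3 train / 1/3 test splits), permutation testing of the MCCV accuracy,
bootstrap AUC confidence intervals, the univariate logistic risk model,
and Ward hierarchical clustering.

AUC is computed by the midrank (Mann–Whitney) statistic, so ties are
split; curves come from a threshold sweep.  All stochastic operations
take an explicit seed and never touch global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .ratios import FeatureTable

__all__ = [
    "ROCResult", "OperatingPoint", "MCCVConfig", "MCCVResult",
    "PermutationResult", "LogisticModel", "HierarchicalClustering",
    "log_transform", "univariate_screen", "pearson_correlations",
    "roc_auc", "operating_point", "mccv_evaluate", "permutation_test",
    "bootstrap_auc_ci", "fit_univariate_logistic", "hierarchical_cluster",
    "benjamini_hochberg", "LAC_PYR_REFERENCE_MODEL",
]


# ------------------------------------------------------------- basics

def _as_matrix(features) -> pd.DataFrame:
    if isinstance(features, FeatureTable):
        return features.values
    return features


def log_transform(features):
    """Natural log, element-wise; missing entries stay missing.

    Nonpositive finite values are a contract violation (zeros must have
    been handled by the below-LOD policy upstream) and raise.
    """
    df = _as_matrix(features)
    bad = (df <= 0) & df.notna()
    if bad.any().any():
        cols = list(df.columns[bad.any()])
        raise ValueError(
            f"nonpositive values in {cols}: apply a below-LOD policy "
            "(half_min or missing) before log transformation"
        )
    out = np.log(df)
    if isinstance(features, FeatureTable):
        return FeatureTable(values=out, provenance=features.provenance)
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------- screening

def univariate_screen(
    features, labels, max_missing: float = 0.5
) -> pd.DataFrame:
    """Per-feature group comparison with BH FDR.

    Two groups: Welch's t-test; more: one-way ANOVA.  Features missing
    in more than ``max_missing`` of samples are skipped with a note;
    zero variance in every group yields p = 1 with a note.
    """
    df = _as_matrix(features)
    labels = pd.Series(np.asarray(labels), index=df.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("univariate screening needs at least two groups")

    rows = []
    for name in df.columns:
        col = df[name]
        note = ""
        stat = p = np.nan
        if col.isna().mean() > max_missing:
            note = "skipped: excessive missingness"
        else:
            parts = [col[labels == g].dropna().to_numpy() for g in groups]
            if any(len(x) < 2 for x in parts):
                note = "skipped: group with <2 observations"
            elif all(np.ptp(x) == 0 for x in parts):
                stat, p, note = 0.0, 1.0, "degenerate: zero variance"
            elif len(groups) == 2:
                stat, p = sps.ttest_ind(parts[0], parts[1], equal_var=False)
            else:
                stat, p = sps.f_oneway(*parts)
        rows.append((name, stat, p, note))

    out = pd.DataFrame(rows, columns=["feature", "statistic", "p", "note"])
    out["fdr"] = benjamini_hochberg(out["p"])
    return out.set_index("feature")


def pearson_correlations(features, target) -> pd.DataFrame:
    """Pearson r of every feature against a numeric target, with BH FDR.

    Pairwise-complete; features with fewer than 3 paired observations
    or zero variance are reported as missing with a reason.
    """
    df = _as_matrix(features)
    target = pd.Series(np.asarray(target, dtype=float), index=df.index)
    rows = []
    for name in df.columns:
        col = df[name]
        ok = col.notna() & target.notna()
        note, r, p = "", np.nan, np.nan
        if ok.sum() < 3:
            note = "skipped: fewer than 3 paired observations"
        elif np.ptp(col[ok].to_numpy()) == 0 or np.ptp(target[ok].to_numpy()) == 0:
            note = "undefined: constant vector"
        else:
            r, p = sps.pearsonr(col[ok], target[ok])
        rows.append((name, r, p, note))
    out = pd.DataFrame(rows, columns=["feature", "r", "p", "note"])
    out["fdr"] = benjamini_hochberg(out["p"])
    return out.set_index("feature")


# ---------------------------------------------------------------- ROC

@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    ci95: tuple[float, float] | None = None


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and midrank AUC.

    AUC equals the Mann–Whitney probability that a random positive
    outranks a random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def operating_point(roc: ROCResult, labels, scores) -> OperatingPoint:
    """Confusion metrics at the Youden-J-maximizing threshold.

    J = sensitivity + specificity − 1; ties are broken toward higher
    specificity.  A sample is called positive when score ≥ threshold.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmin(roc.fpr[best])]
    thr = roc.thresholds[idx]
    if not np.isfinite(thr):  # sklearn's sentinel above the max score
        thr = scores.max()
    pred = scores >= thr
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return OperatingPoint(float(thr), sens, spec, ppv, npv)


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC, resampling with
    replacement within each class (so resamples are never one-class)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([ps, ns])
        y = np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)])
        aucs[b] = roc_auc(s, y).auc
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------- MCCV

@dataclass(frozen=True)
class MCCVConfig:
    n_iterations: int = 100
    train_fraction: float = 2 / 3
    balanced: bool = True
    classifier: str = "logistic_l2"  # or "plsda"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class MCCVResult:
    per_iteration_auc: list[float]
    per_iteration_accuracy: list[float]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_iteration_auc))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_iteration_accuracy))


def _fit_score(X_tr, y_tr, X_te, classifier: str) -> np.ndarray:
    # standardization is fit on the training fold only
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z_tr = (X_tr - mu) / sd
    Z_te = (X_te - mu) / sd
    if classifier == "logistic_l2":
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(Z_tr, y_tr)
        return clf.predict_proba(Z_te)[:, 1]
    if classifier == "plsda":
        from sklearn.cross_decomposition import PLSRegression

        ncomp = min(2, Z_tr.shape[1])
        pls = PLSRegression(n_components=ncomp)
        pls.fit(Z_tr, y_tr.astype(float))
        return pls.predict(Z_te).ravel()
    raise ValueError(f"unknown classifier {classifier!r}")


def mccv_evaluate(features, labels, config: MCCVConfig) -> MCCVResult:
    """Monte-Carlo cross-validation with balanced subsampling.

    Each iteration draws, class-stratified and without replacement,
    2/3 of each class for training; the model (including its feature
    scaling) is fit on the training fold only and scored on the
    held-out third.  Fully reproducible from ``config.seed``.
    """
    X = _as_matrix(features)
    if isinstance(X, pd.DataFrame):
        if X.isna().any().any():
            raise ValueError("MCCV requires complete features; drop or "
                             "impute missing values first")
        X = X.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if len(idx_pos) < 3 or len(idx_neg) < 3:
        raise ValueError("each class needs at least 3 samples for a "
                         "stratified 2/3 split")
    n_tr_pos = max(1, int(round(config.train_fraction * len(idx_pos))))
    n_tr_neg = max(1, int(round(config.train_fraction * len(idx_neg))))
    n_tr_pos = min(n_tr_pos, len(idx_pos) - 1)
    n_tr_neg = min(n_tr_neg, len(idx_neg) - 1)

    rng = np.random.default_rng(config.seed)
    aucs, accs, pooled_s, pooled_y = [], [], [], []
    for _ in range(config.n_iterations):
        pp = rng.permutation(idx_pos)
        nn = rng.permutation(idx_neg)
        tr = np.concatenate([pp[:n_tr_pos], nn[:n_tr_neg]])
        te = np.concatenate([pp[n_tr_pos:], nn[n_tr_neg:]])
        scores = _fit_score(X[tr], y[tr], X[te], config.classifier)
        aucs.append(roc_auc(scores, y[te]).auc)
        # both classifiers score on a 0..1 scale (probability / fitted y)
        accs.append(float(((scores >= 0.5).astype(int) == y[te]).mean()))
        pooled_s.append(scores)
        pooled_y.append(y[te])
    return MCCVResult(
        per_iteration_auc=aucs,
        per_iteration_accuracy=accs,
        pooled_scores=np.concatenate(pooled_s),
        pooled_labels=np.concatenate(pooled_y),
    )


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: list[float]
    p_value: float


def permutation_test(
    features, labels, config: MCCVConfig, n_perm: int = 1000
) -> PermutationResult:
    """Permutation test of the mean MCCV accuracy.

    The null is built by re-running MCCV under random label
    permutations; p = (#{null ≥ observed} + 1) / (n_perm + 1), the
    conservative add-one convention, so p is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels).astype(int)
    observed = mccv_evaluate(features, y, config).mean_accuracy
    rng = np.random.default_rng(config.seed)
    null = []
    for i in range(n_perm):
        perm = rng.permutation(y)
        sub = MCCVConfig(
            n_iterations=config.n_iterations,
            train_fraction=config.train_fraction,
            balanced=config.balanced,
            classifier=config.classifier,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        null.append(mccv_evaluate(features, perm, sub).mean_accuracy)
    b = sum(1 for v in null if v >= observed)
    p = (b + 1) / (n_perm + 1)
    return PermutationResult(observed, null, p)


# ----------------------------------------------------------- logistic

@dataclass
class LogisticModel:
    """Univariate logistic risk model logit(P) = intercept + slope·x."""

    intercept: float
    slope: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.slope))

    def predict_proba(self, x):
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * x)))


#: The packaged reference model relating the lactate/pyruvate ratio to
#: 5-year mortality risk: logit(P) = −12.24 + 1.80·(Lac/Pyr).  Note
#: exp(1.80) = 6.05; the originally reported odds ratio of 6.08
#: corresponds to an unrounded slope of ≈1.805.
LAC_PYR_REFERENCE_MODEL = LogisticModel(intercept=-12.24, slope=1.80)


def fit_univariate_logistic(x, labels) -> LogisticModel:
    """Maximum-likelihood univariate logistic regression.

    Under perfect separation the MLE diverges; a warning is issued and
    a ridge-penalized estimate is returned instead.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=False)
        b0, b1 = fit.params
        return LogisticModel(
            float(b0), float(b1),
            diagnostics={
                "llf": float(fit.llf),
                "p_slope": float(fit.pvalues[1]),
                "se_slope": float(fit.bse[1]),
                "converged": bool(fit.mle_retvals["converged"]),
                "penalized": False,
            },
        )
    except Exception:
        warnings.warn("perfect separation or non-convergence; returning a "
                      "ridge-penalized estimate")
        z = (x - x.mean()) / (x.std() or 1.0)
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(z[:, None], y)
        slope = float(clf.coef_[0, 0] / (x.std() or 1.0))
        intercept = float(clf.intercept_[0] - slope * x.mean())
        return LogisticModel(intercept, slope,
                             diagnostics={"penalized": True})


# ----------------------------------------------------------- clusters

@dataclass
class HierarchicalClustering:
    linkage: np.ndarray
    leaf_order: list[int]
    sample_ids: list


def hierarchical_cluster(features, autoscale: bool = True) -> HierarchicalClustering:
    """Agglomerative Ward clustering on Euclidean distances of
    (optionally autoscaled) features; deterministic leaf order."""
    df = _as_matrix(features)
    if isinstance(df, pd.DataFrame):
        ids = list(df.index)
        X = df.to_numpy(dtype=float)
    else:
        X = np.asarray(df, dtype=float)
        ids = list(range(len(X)))
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("clustering requires complete features")
    if autoscale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    order = hierarchy.leaves_list(Z).tolist()
    return HierarchicalClustering(linkage=Z, leaf_order=order, sample_ids=ids)
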