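"""Segmentation-robust feature-selection cascade.

Four stages, applied to a training feature table:

1. drop features with zero variance across cases;
2. standardize the remainder to zero mean / unit SD (training parameters are
   frozen and re-applied to any test table);
3. keep features whose concordance correlation coefficient between the
   reference-mask values and *every* repeat-segmentation table exceeds a
   threshold (default 0.90) — features that survive boundary perturbation;
4. prune highly correlated pairs (|Pearson r| > 0.90), dropping from each
   pair the feature with the weaker univariable association with the class
   label, then fit an L1-penalized (LASSO) logistic model with stratified
   five-fold cross-validation over a log-spaced penalty grid.

The univariable association test is a two-sided Mann-Whitney U by default
(rank-based and scale-free); a logistic-regression Wald test is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .model import ModelSpec
from .utils import derive_seed

VARIANCE_SIG_DIGITS = 12


@dataclass
class SelectionReport:
    """Stage-by-stage accounting of the cascade."""

    n_initial: int = 0
    n_after_zero_variance: int = 0
    n_after_stability: int = 0
    n_after_correlation: int = 0
    n_after_lasso: int = 0
    ccc: dict = field(default_factory=dict)  # feature -> min CCC across repeats
    dropped: list = field(default_factory=list)  # (feature, stage, reason)
    seed: int | None = None
    lambda_best: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": {
                "initial": self.n_initial,
                "after_zero_variance": self.n_after_zero_variance,
                "after_stability": self.n_after_stability,
                "after_correlation": self.n_after_correlation,
                "after_lasso": self.n_after_lasso,
            },
            "ccc": self.ccc,
            "dropped": [list(d) for d in self.dropped],
            "seed": self.seed,
            "lambda_best": self.lambda_best,
        }


@dataclass(frozen=True)
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series


def _round_sig(x: np.ndarray, digits: int = VARIANCE_SIG_DIGITS) -> np.ndarray:
    """Round a column to ``digits`` significant digits of its largest value,
    so float round-off cannot disguise a constant feature."""
    out = np.asarray(x, dtype=float)
    scale = np.abs(out).max()
    if scale == 0:
        return out
    return np.round(out / scale, digits)


def drop_zero_variance(table: pd.DataFrame, report: SelectionReport | None = None):
    """Remove features constant across cases (after rounding to 12 significant
    digits, so storage round-off does not hide a constant)."""
    if len(table) < 2:
        raise ValueError("need at least two cases")
    report = report or SelectionReport(n_initial=table.shape[1])
    keep = []
    for col in table.columns:
        vals = _round_sig(table[col].to_numpy())
        if np.all(vals == vals[0]):
            report.dropped.append((col, "zero_variance", "constant across cases"))
        else:
            keep.append(col)
    out = table[keep]
    report.n_after_zero_variance = len(keep)
    return out, report


def fit_standardizer(table: pd.DataFrame) -> StandardizationParams:
    """Per-feature mean and (n-1 denominator) SD learned on training data."""
    sd = table.std(ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"zero-variance features must be removed first: {bad}")
    return StandardizationParams(mean=table.mean(), sd=sd)


def apply_standardizer(table: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    return (table[params.mean.index] - params.mean) / params.sd


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments):

        2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2)

    Degenerate rules: both constant with equal means -> 1; one constant (or
    unequal constant means) -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("lin_ccc needs two equal-length vectors, n >= 3")
    vx, vy = x.var(), y.var()
    dmean = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        return 1.0 if dmean == 0 else 0.0
    if vx == 0 or vy == 0:
        return 0.0
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (vx + vy + dmean**2))


def stability_filter(
    primary: pd.DataFrame,
    repeats,
    threshold: float = 0.90,
    report: SelectionReport | None = None,
):
    """Retain features whose minimum CCC against all repeat tables exceeds
    ``threshold``.

    The repeat tables hold the same features for a (sub)set of the primary
    cases, re-extracted from independent segmentations; rows are matched by
    index and must all be present in ``primary``.
    """
    report = report or SelectionReport(n_initial=primary.shape[1])
    keep = []
    for rep in repeats:
        missing = rep.index.difference(primary.index)
        if len(missing):
            raise ValueError(f"repeat table has unknown cases: {list(missing)[:5]}")
        if not set(primary.columns) <= set(rep.columns):
            raise ValueError("repeat table is missing feature columns")
    for col in primary.columns:
        cccs = [
            lin_ccc(primary.loc[rep.index, col].to_numpy(), rep[col].to_numpy())
            for rep in repeats
        ]
        worst = min(cccs) if cccs else 1.0
        report.ccc[col] = worst
        if worst > threshold:
            keep.append(col)
        else:
            report.dropped.append((col, "stability", f"min CCC {worst:.3f} <= {threshold}"))
    out = primary[keep]
    report.n_after_stability = len(keep)
    return out, report


def mann_whitney_p(x: np.ndarray, y01: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value of a feature between the two classes."""
    a, b = x[y01 == 1], x[y01 == 0]
    if len(a) == 0 or len(b) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def logistic_wald_p(x: np.ndarray, y01: np.ndarray) -> float:
    """Wald p of the slope in a univariable logistic fit (alternative test)."""
    import statsmodels.api as sm

    z = (x - x.mean()) / (x.std() or 1.0)
    try:
        fit = sm.Logit(y01, sm.add_constant(z)).fit(disp=0)
        return float(fit.pvalues[1])
    except Exception:
        return 1.0


def correlation_prune(
    table: pd.DataFrame,
    labels,
    r_threshold: float = 0.90,
    p_value=mann_whitney_p,
    report: SelectionReport | None = None,
):
    """Break up highly correlated feature pairs.

    Pairs with |Pearson r| > threshold are visited in descending |r|; for
    each pair still fully retained, the member with the larger univariable
    class-association p-value is dropped.  The result contains no retained
    pair above the threshold.
    """
    report = report or SelectionReport(n_initial=table.shape[1])
    y = np.asarray(labels).astype(int)
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    n = len(cols)
    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(corr[i, j]) > r_threshold
    ]
    pairs.sort(reverse=True)
    pcache: dict[int, float] = {}

    def pval(i: int) -> float:
        if i not in pcache:
            pcache[i] = p_value(x[:, i], y)
        return pcache[i]

    removed: set[int] = set()
    for r, i, j in pairs:
        if i in removed or j in removed:
            continue
        # drop the weaker-association member; ties favour the first column
        drop = j if pval(j) >= pval(i) else i
        removed.add(drop)
        report.dropped.append(
            (cols[drop], "correlation", f"|r|={r:.3f} with {cols[i if drop == j else j]}")
        )
    keep = [c for k, c in enumerate(cols) if k not in removed]
    out = table[keep]
    report.n_after_correlation = len(keep)
    return out, report


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_cv_fit(
    table: pd.DataFrame,
    labels,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
    one_se: bool = True,
    report: SelectionReport | None = None,
) -> ModelSpec:
    """L1-penalized logistic regression with stratified K-fold CV.

    The penalty grid is log-spaced over ``lambda_decades`` decades below
    lambda_max = max |X^T (y - ybar)| / n (the smallest penalty that zeroes
    every coefficient).  lambda* follows the one-standard-error rule: the
    largest penalty whose mean cross-validated binomial deviance lies within
    one standard error of the minimum (with ``one_se=False``, the exact
    minimizer, ties toward the larger penalty).  The model is refit on all
    data at lambda*.  Expects standardized features.
    """
    report = report or SelectionReport(n_initial=table.shape[1])
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    x = table.to_numpy(dtype=float)
    n = len(y)
    if min(np.bincount(y)) < n_folds:
        raise ValueError("need at least n_folds cases per class")

    lam_max = np.max(np.abs(x.T @ (y - y.mean()))) / n
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - lambda_decades, n_lambdas)

    def fit_at(lam: float, xi: np.ndarray, yi: np.ndarray) -> LogisticRegression:
        c = 1.0 / (len(yi) * lam)
        # large intercept_scaling keeps liblinear's intercept effectively
        # unpenalized, matching the usual LASSO convention
        clf = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", max_iter=20000, tol=1e-7,
            random_state=0, intercept_scaling=1000.0,
        )
        clf.fit(xi, yi)
        return clf

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=derive_seed(seed, "folds"))
    folds = list(skf.split(x, y))
    mean_dev = np.empty(len(lambdas))
    se_dev = np.empty(len(lambdas))
    for k, lam in enumerate(lambdas):
        devs = []
        for tr, te in folds:
            clf = fit_at(lam, x[tr], y[tr])
            p = clf.predict_proba(x[te])[:, 1]
            devs.append(_binomial_deviance(y[te], p))
        mean_dev[k] = np.mean(devs)
        se_dev[k] = np.std(devs, ddof=1) / np.sqrt(n_folds)
    # grid is ordered from the largest lambda down; argmin takes the first
    # (sparser) exact minimizer
    best = int(np.argmin(mean_dev))
    if one_se:
        # largest penalty within one SE of the minimum: sparser, more stable
        threshold = mean_dev[best] + se_dev[best]
        best = int(np.argmax(mean_dev <= threshold))
    lam_best = float(lambdas[best])

    clf = fit_at(lam_best, x, y)
    coefs = clf.coef_.ravel()
    support = np.abs(coefs) > 1e-8
    names = [c for c, s in zip(table.columns, support) if s]
    report.n_after_lasso = len(names)
    report.seed = seed
    report.lambda_best = lam_best
    for c, s in zip(table.columns, support):
        if not s:
            report.dropped.append((c, "lasso", "coefficient shrunk to zero"))
    return ModelSpec(
        feature_names=tuple(names),
        coefficients=tuple(float(b) for b in coefs[support]),
        intercept=float(clf.intercept_[0]),
        cutoff=0.0,
        standardization_mean=None,
        standardization_sd=None,
    )


def run_cascade(
    train: pd.DataFrame,
    labels,
    repeats=(),
    ccc_threshold: float = 0.90,
    r_threshold: float = 0.90,
    n_folds: int = 5,
    seed: int = 0,
):
    """The full four-stage cascade; returns (ModelSpec, StandardizationParams,
    SelectionReport).  ``repeats`` are feature tables from repeat
    segmentations of a case subset."""
    report = SelectionReport(n_initial=train.shape[1])
    t1, report = drop_zero_variance(train, report)
    params = fit_standardizer(t1)
    z = apply_standardizer(t1, params)
    if repeats:
        z_reps = [apply_standardizer(r[t1.columns], params) for r in repeats]
        z2, report = stability_filter(z, z_reps, ccc_threshold, report)
    else:
        z2 = z
        report.n_after_stability = z.shape[1]
    z3, report = correlation_prune(z2, labels, r_threshold, report=report)
    spec = lasso_cv_fit(z3, labels, n_folds=n_folds, seed=seed, report=report)
    params = StandardizationParams(
        mean=params.mean[list(spec.feature_names)], sd=params.sd[list(spec.feature_names)]
    )
    spec = spec.with_standardization(params.mean, params.sd)
    return spec, params, report
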