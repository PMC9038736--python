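"""The 12-feature radiomics malignancy signature and the diagnostic statistics
used to compare segmentations: ROC/AUC with DeLong variance, paired DeLong
test, Youden-index cutoff, Wilson confidence intervals, and the exact McNemar
test.

The shipped signature is a linear combination of standardized features
weighted by LASSO coefficients; its score is intercept + sum(beta_i * z_i)
and a case is called malignant when the score reaches the decision cutoff.
The training-cohort standardization parameters of the published signature
were never released, so the shipped spec stores them as unspecified and
``score`` requires pre-standardized inputs for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ModelSpec:
    """Ordered features, coefficients, intercept, standardization, cutoff."""

    feature_names: tuple
    coefficients: tuple
    intercept: float
    cutoff: float
    standardization_mean: pd.Series | None = None
    standardization_sd: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("coefficient count must equal feature count")

    def with_standardization(self, mean: pd.Series, sd: pd.Series) -> "ModelSpec":
        return ModelSpec(
            self.feature_names, self.coefficients, self.intercept, self.cutoff, mean, sd
        )

    def with_cutoff(self, cutoff: float) -> "ModelSpec":
        return ModelSpec(
            self.feature_names,
            self.coefficients,
            self.intercept,
            float(cutoff),
            self.standardization_mean,
            self.standardization_sd,
        )

    def to_json(self) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "standardization_mean": None
            if self.standardization_mean is None
            else self.standardization_mean.to_dict(),
            "standardization_sd": None
            if self.standardization_sd is None
            else self.standardization_sd.to_dict(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        mean = d.get("standardization_mean")
        sd = d.get("standardization_sd")
        return cls(
            tuple(d["feature_names"]),
            tuple(d["coefficients"]),
            float(d["intercept"]),
            float(d["cutoff"]),
            None if mean is None else pd.Series(mean),
            None if sd is None else pd.Series(sd),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def published_model() -> ModelSpec:
    """The shipped 12-feature signature (coefficients, intercept -0.176,
    decision cutoff 0.328), loaded from package data."""
    text = resources.files("vertomics.data").joinpath("published_model.json").read_text()
    return ModelSpec.from_json(text)


def score(model: ModelSpec, features) -> float:
    """Linear radiomics score: intercept + sum of beta_i * z_i.

    ``features`` maps feature names to standardized values (a mapping or
    pandas Series).  If the model carries standardization parameters they are
    applied first; otherwise inputs must already be standardized.
    """
    values = {}
    for name in model.feature_names:
        try:
            values[name] = float(features[name])
        except (KeyError, IndexError) as exc:
            raise KeyError(f"missing feature: {name}") from exc
    z = np.array([values[n] for n in model.feature_names])
    if model.standardization_mean is not None:
        mu = model.standardization_mean[list(model.feature_names)].to_numpy()
        sd = model.standardization_sd[list(model.feature_names)].to_numpy()
        z = (z - mu) / sd
    return float(model.intercept + np.dot(np.asarray(model.coefficients), z))


def classify(model: ModelSpec, features) -> str:
    """'malignant' iff score >= cutoff, else 'benign' (ties call malignant)."""
    return "malignant" if score(model, features) >= model.cutoff else "benign"


def score_table(model: ModelSpec, table: pd.DataFrame) -> pd.Series:
    """Score every row of a feature table."""
    return pd.Series(
        {idx: score(model, row) for idx, row in table.iterrows()}, name="score"
    )


# ---------------------------------------------------------------------------
# diagnostic statistics


def _wilson(k: int, n: int):
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def diagnostic_metrics(counts: ConfusionCounts) -> dict[str, dict]:
    """Accuracy, sensitivity, specificity, PPV, NPV with Wilson 95% CIs.

    Each entry is {"value": proportion, "ci": (lo, hi), "num": k, "den": n};
    a metric with a zero denominator is reported with value None.
    """
    c = counts
    defs = {
        "accuracy": (c.tp + c.tn, c.total),
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    out = {}
    for name, (k, n) in defs.items():
        if n == 0:
            out[name] = {"value": None, "ci": None, "num": k, "den": n}
        else:
            out[name] = {"value": k / n, "ci": _wilson(k, n), "num": k, "den": n}
    return out


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise, via midranks
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(auc), v10, v01


def roc_auc(scores, labels):
    """Empirical ROC curve and AUC (= Mann-Whitney concordance with half
    credit for ties), with a DeLong 95% CI.

    Returns a dict with keys ``auc``, ``ci``, ``curve`` (list of
    (cutoff, sensitivity, specificity) triples over all distinct cutoffs).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _delong_structural(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.96 * np.sqrt(var)
    curve = []
    for cut in np.unique(s):
        pred = s >= cut
        sens = float((pred & (y == 1)).sum() / (y == 1).sum())
        spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
        curve.append((float(cut), sens, spec))
    return {
        "auc": auc,
        "ci": (max(0.0, auc - half), min(1.0, auc + half)),
        "curve": curve,
    }


def delong_test(scores_a, scores_b, labels):
    """Two-sided DeLong test for paired AUCs.

    Returns dict with auc_a, auc_b, z, p, and a 95% CI on the AUC difference.
    Degenerate zero variance yields p = 1 (with z = 0).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores must share the cases")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10a, v01a = _delong_structural(sa, y)
    auc_b, v10b, v01b = _delong_structural(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0
        ci = (diff, diff)
    else:
        se = float(np.sqrt(var_diff))
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        ci = (diff - 1.96 * se, diff + 1.96 * se)
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": p, "diff_ci": ci}


def youden_cutoff(scores, labels):
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct scores plus
    sentinels below/above the range; on ties the lowest cutoff is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = [uniq[0] - 1.0]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [uniq[-1] + 1.0]
    best_cut, best_j = candidates[0], -np.inf
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    for cut in candidates:
        pred = s >= cut
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return float(best_cut), float(best_j)


def mcnemar_exact(correct_a, correct_b) -> float:
    """Exact two-sided McNemar p for paired correctness indicators.

    With discordant counts b (A right, B wrong) and c (A wrong, B right),
    p = min(1, 2 * P[X <= min(b, c)]), X ~ Binomial(b + c, 1/2); p = 1 when
    there are no discordant pairs.
    """
    a = np.asarray(correct_a).astype(bool)
    bvec = np.asarray(correct_b).astype(bool)
    if a.shape != bvec.shape:
        raise ValueError("paired vectors must have equal length")
    b = int((a & ~bvec).sum())
    c = int((~a & bvec).sum())
    nd = b + c
    if nd == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5)))


def confusion_from_predictions(pred_malignant, truth_malignant) -> ConfusionCounts:
    p = np.asarray(pred_malignant).astype(bool)
    t = np.asarray(truth_malignant).astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
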