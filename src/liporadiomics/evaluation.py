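"""Classification performance and comparison statistics.

Conventions: the malignant class (ALT/WDLS) is positive, so sensitivity is
the malignant detection rate.  AUC is the Mann-Whitney statistic (ties
count 1/2) with a DeLong structural-component variance and a normal 95%
CI; binary proportions get exact Clopper-Pearson intervals.  Two paired
ROC curves are compared with DeLong's test; two readers' binary calls with
Cohen's kappa (asymptotic CI, via statsmodels).  Per-feature group
differences use the two-sided Mann-Whitney U test with Bonferroni
correction; demographic covariates use chi-squared / Fisher exact
(categorical) or Welch t / Mann-Whitney (continuous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class ScoredSet:
    """Lesion ids, true labels, and continuous scores or binary calls."""

    ids: tuple[str, ...]
    labels: np.ndarray  # y in {0, 1}; 1 = malignant
    scores: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.labels) == len(self.scores)):
            raise ValueError("ids, labels, scores must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("lesion ids must be unique")

    @classmethod
    def from_arrays(cls, ids, labels, scores) -> "ScoredSet":
        y = np.asarray(labels)
        if y.dtype.kind in "USO":
            y = (y == POSITIVE_LABEL).astype(float)
        return cls(
            ids=tuple(str(i) for i in ids),
            labels=np.asarray(y, dtype=float),
            scores=np.asarray(scores, dtype=float),
        )


def _check_both_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, s: np.ndarray):
    """AUC and the DeLong structural components V10 (positives), V01."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def roc_auc(scored: ScoredSet, alpha: float = 0.05) -> dict:
    """AUC with a DeLong-variance normal CI, clipped to [0, 1]."""
    y, s = scored.labels, scored.scores
    _check_both_classes(y)
    auc, v10, v01 = _delong_components(y, s)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return {
        "auc": auc,
        "auc_ci": (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))),
        "variance": float(var),
    }


def delong_test(set_a: ScoredSet, set_b: ScoredSet) -> dict:
    """DeLong's test for two paired ROC curves (same lesions and labels).

    Returns the two AUCs, z, and the two-sided p; identical score vectors
    give z = 0, p = 1.  The test is symmetric in its arguments.
    """
    if set_a.ids != set_b.ids:
        raise ValueError("scored sets are not paired (lesion ids differ)")
    if not np.array_equal(set_a.labels, set_b.labels):
        raise ValueError("scored sets disagree on true labels")
    y = set_a.labels
    _check_both_classes(y)
    auc_a, v10_a, v01_a = _delong_components(y, set_a.scores)
    auc_b, v10_b, v01_b = _delong_components(y, set_b.scores)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": p}


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for k successes out of n."""
    if n == 0:
        return (0.0, 1.0)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def confusion_metrics(scored: ScoredSet, threshold: float = 0.5) -> dict:
    """Sensitivity/specificity/accuracy with Clopper-Pearson 95% CIs.

    Scores >= threshold call malignant; pass binary calls with
    threshold 0.5 to evaluate a reader.
    """
    y = scored.labels
    calls = (scored.scores >= threshold).astype(float)
    tp = int(((calls == 1) & (y == 1)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class is empty; sensitivity/specificity undefined")
    n = len(y)
    out = {
        "threshold": threshold,
        "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        "sensitivity": tp / (tp + fn),
        "sensitivity_ci": clopper_pearson(tp, tp + fn),
        "specificity": tn / (tn + fp),
        "specificity_ci": clopper_pearson(tn, tn + fp),
        "accuracy": (tp + tn) / n,
        "accuracy_ci": clopper_pearson(tp + tn, n),
    }
    return out


def classification_report(scored: ScoredSet, threshold: float = 0.5) -> dict:
    """Combined AUC + threshold metrics (one Table-2-style row)."""
    return {**roc_auc(scored), **confusion_metrics(scored, threshold)}


# ---------------------------------------------------------------------------
# Agreement and group tests
# ---------------------------------------------------------------------------

def cohen_kappa(calls_a, calls_b, alpha: float = 0.05) -> dict:
    """Cohen's kappa for two paired binary calls, with asymptotic 95% CI."""
    a = np.asarray(calls_a).astype(int)
    b = np.asarray(calls_b).astype(int)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    table = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            table[i, j] = int(((a == i) & (b == j)).sum())
    res = _sm_kappa(table, return_results=True)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * float(res.std_kappa)
    return {
        "kappa": float(res.kappa),
        "kappa_ci": (
            float(np.clip(res.kappa - half, -1, 1)),
            float(np.clip(res.kappa + half, -1, 1)),
        ),
    }


def group_feature_tests(
    table: pd.DataFrame, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Bonferroni-corrected Mann-Whitney U per feature, benign vs malignant.

    Uses scipy's two-sided test (exact for small untied samples, tie-
    corrected normal otherwise); adjusted p = min(1, m * p) with m the
    number of features tested.  Constant features get p = 1 with a warning.
    """
    if feature_names is None:
        feature_names = [c for c in table.columns if c != "label"]
    y = table["label"].to_numpy()
    _check_both_classes((y == POSITIVE_LABEL).astype(float))
    m = len(feature_names)
    rows = []
    for name in feature_names:
        g0 = table.loc[y != POSITIVE_LABEL, name].to_numpy(dtype=float)
        g1 = table.loc[y == POSITIVE_LABEL, name].to_numpy(dtype=float)
        pooled = np.concatenate([g0, g1])
        if np.all(pooled == pooled[0]):
            warnings.warn(f"feature {name!r} is constant; p set to 1", stacklevel=2)
            u, p = float(len(g0) * len(g1) / 2), 1.0
        else:
            res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((name, u, p, min(1.0, m * p)))
    return pd.DataFrame(
        rows, columns=["feature", "u_statistic", "p_raw", "p_bonferroni"]
    ).set_index("feature")


def demographics_tests(
    table: pd.DataFrame, covariate_types: dict[str, str]
) -> pd.DataFrame:
    """Table-1-style group comparisons of per-case covariates.

    ``covariate_types`` maps column name to 'categorical', 'continuous'
    (Welch's t-test) or 'continuous_nonnormal' (Mann-Whitney U).
    Categorical 2xK tables use Pearson chi-squared without continuity
    correction, falling back to Fisher's exact test when any expected
    count of a 2x2 table is below 5.
    """
    y = table["label"].to_numpy()
    rows = []
    for name, kind in covariate_types.items():
        if kind == "categorical":
            ct = pd.crosstab(table[name], table["label"]).to_numpy()
            expected = stats.contingency.expected_freq(ct)
            if ct.shape == (2, 2) and (expected < 5).any():
                p = float(stats.fisher_exact(ct)[1])
                test = "fisher"
            else:
                p = float(stats.chi2_contingency(ct, correction=False)[1])
                test = "chi2"
        elif kind in ("continuous", "continuous_nonnormal"):
            g0 = table.loc[y != POSITIVE_LABEL, name].astype(float)
            g1 = table.loc[y == POSITIVE_LABEL, name].astype(float)
            if kind == "continuous":
                p = float(stats.ttest_ind(g0, g1, equal_var=False).pvalue)
                test = "welch_t"
            else:
                p = float(
                    stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
                )
                test = "mannwhitney_u"
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {name!r}")
        rows.append((name, test, p))
    return pd.DataFrame(rows, columns=["covariate", "test", "p"]).set_index("covariate")
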