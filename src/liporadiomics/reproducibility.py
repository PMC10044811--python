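"""Feature reproducibility under segmentation variability.

Manual tumor segmentation varies within and between observers; a feature
is only useful if it survives that variability.  Agreement per feature is
quantified with the intraclass correlation coefficient ICC(2,1) — two-way
random-effects ANOVA, single measurement, absolute agreement — plus
Pearson r and Spearman rho as descriptive correlations.  Features are
retained only when ICC exceeds a threshold (default 0.75, strict
inequality).  When both an intra-observer and an inter-observer screen are
available, a feature must pass both, i.e. the minimum of the two ICCs must
exceed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ICC_THRESHOLD = 0.75


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects x k raters) matrix with no missing cells.
    From the two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Zero between-subject variance is not an error; the formula's value
    (possibly <= 0) is returned.  NaN is returned only when the denominator
    is 0 (all values identical).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"ratings must be at least 2x2, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class ReproducibilityRecord:
    feature_name: str
    icc: float
    pearson_r: float
    spearman_rho: float
    keep: bool
    note: str = ""


def agreement_suite(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature agreement between two feature tables of the same lesions.

    Tables must share lesion ids (index) and feature columns; non-feature
    columns (``label``) are ignored.  Returns a DataFrame indexed by
    feature name with columns icc, pearson_r, spearman_rho, keep, note.
    Constant features have undefined correlations, recorded as NaN with a
    reason; their keep flag follows the ICC rule alone.
    """
    feats = [c for c in table_a.columns if c != "label"]
    if [c for c in table_b.columns if c != "label"] != feats:
        raise ValueError("feature tables have different feature columns")
    if set(table_a.index) != set(table_b.index):
        raise ValueError("feature tables cover different lesion ids")
    b = table_b.loc[table_a.index]

    records = []
    for name in feats:
        va = table_a[name].to_numpy(dtype=float)
        vb = b[name].to_numpy(dtype=float)
        note = ""
        if np.isnan(va).any() or np.isnan(vb).any():
            records.append((name, np.nan, np.nan, np.nan, False, "missing values"))
            continue
        icc = icc_2_1(np.column_stack([va, vb]))
        if np.std(va) == 0 or np.std(vb) == 0:
            r = rho = np.nan
            note = "constant feature; correlation undefined"
        else:
            r = float(stats.pearsonr(va, vb).statistic)
            rho = float(stats.spearmanr(va, vb).statistic)
        keep = bool(np.isfinite(icc) and icc > threshold)
        records.append((name, icc, r, rho, keep, note))
    return pd.DataFrame(
        records, columns=["feature", "icc", "pearson_r", "spearman_rho", "keep", "note"]
    ).set_index("feature")


def combine_screens(
    intra: pd.DataFrame,
    inter: pd.DataFrame,
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> pd.DataFrame:
    """Combine intra- and inter-observer screens: both ICCs must pass.

    Returns a DataFrame with icc_intra, icc_inter, icc (their minimum),
    the correlations from the inter-observer screen, and the keep flag.
    """
    if list(intra.index) != list(inter.index):
        raise ValueError("screens cover different features")
    out = pd.DataFrame(
        {
            "icc_intra": intra["icc"],
            "icc_inter": inter["icc"],
            "icc": np.minimum(intra["icc"], inter["icc"]),
            "pearson_r": inter["pearson_r"],
            "spearman_rho": inter["spearman_rho"],
        }
    )
    out["keep"] = np.isfinite(out["icc"]) & (out["icc"] > threshold)
    return out


def filter_reproducible(
    report: pd.DataFrame, threshold: float = DEFAULT_ICC_THRESHOLD
) -> list[str]:
    """Feature names with ICC strictly above the threshold, in table order.

    A feature with ICC exactly at the threshold is dropped.
    """
    icc = report["icc"]
    keep = icc.notna() & (icc > threshold)
    return list(report.index[keep])
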