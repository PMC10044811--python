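"""CV-LASSO logistic classification of benign vs malignant lesions.

Workflow: a stratified 70/30 learning/testing split; tenfold
cross-validation on the learning set over a descending lambda grid, with
standardization and L1 feature selection refit inside every training fold
(no leakage); lambda chosen at the minimum mean CV misclassification error
(ties broken toward the larger, sparser lambda); a final refit of the
LASSO logistic model on the whole learning set.  The same L1 fit performs
feature selection (the nonzero support) and classification.

The penalized problem solved by :func:`fit_lasso_logistic` is

    min_{b0, b}  (1/n) sum_i [log(1 + exp(eta_i)) - y_i eta_i] + lam ||b||_1

with eta = b0 + X b, the intercept unpenalized, and X standardized
column-wise by the caller.  The solver is IRLS with cyclic coordinate
descent (the glmnet scheme) and verifies the KKT conditions at the
solution: |(1/n) x_j'(y - p)| <= lam for zero coefficients and equal to
lam (with matching sign) for active ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_ORDER = ("benign", "malignant")  # malignant encodes as y = 1


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; message carries diagnostics."""


class SplitError(ValueError):
    """The cohort cannot support the requested split/stratification."""


def encode_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    unknown = set(lab) - set(LABEL_ORDER)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    return (lab == "malignant").astype(float)


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    learning_ids: tuple[str, ...]
    testing_ids: tuple[str, ...]
    fold_assignment: dict[str, int]  # learning id -> fold 1..folds
    folds: int
    seed: int


def make_split(
    table: pd.DataFrame, ratio: float = 0.7, folds: int = 10, seed: int = 0
) -> SplitPlan:
    """Stratified learning/testing split plus fold assignment.

    The learning count is rounded per class (round-half-up of
    n_class * ratio), so a 38/30 cohort at ratio 0.7 gives 27 + 21 = 48
    learning and 20 testing lesions.  Folds are assigned round-robin
    within each shuffled class, so every fold is label-stratified.
    """
    if not 0 < ratio < 1:
        raise SplitError(f"ratio must be in (0, 1), got {ratio}")
    if folds < 2:
        raise SplitError(f"folds must be >= 2, got {folds}")
    rng = np.random.default_rng(seed)
    learning, testing, fold_of = [], [], {}
    for label in LABEL_ORDER:
        ids = np.asarray(table.index[table["label"] == label])
        if len(ids) == 0:
            raise SplitError(f"class {label!r} absent from the cohort")
        ids = ids[rng.permutation(len(ids))]
        n_learn = int(np.floor(len(ids) * ratio + 0.5))
        if n_learn == len(ids):
            raise SplitError(f"class {label!r}: testing set would be empty")
        if n_learn < folds:
            raise SplitError(
                f"class {label!r}: {n_learn} learning lesions cannot stratify "
                f"{folds} folds"
            )
        cls_learn = ids[:n_learn]
        learning.extend(cls_learn)
        testing.extend(ids[n_learn:])
        for i, cid in enumerate(cls_learn):
            fold_of[str(cid)] = i % folds + 1
    return SplitPlan(
        learning_ids=tuple(str(i) for i in learning),
        testing_ids=tuple(str(i) for i in testing),
        fold_assignment=fold_of,
        folds=folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# L1-penalized logistic regression (IRLS + cyclic coordinate descent)
# ---------------------------------------------------------------------------

def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    beta0: np.ndarray | None = None,
    intercept0: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    kkt_tol: float = 5e-7,
    best_effort: bool = False,
) -> tuple[np.ndarray, float]:
    """Minimize the L1-penalized average logistic loss.

    X must be standardized column-wise by the caller; ``lam >= 0``.
    Returns (coefficients, intercept).  Warm starts via ``beta0`` /
    ``intercept0`` speed up path computation; ``kkt_tol`` is the stationarity
    tolerance verified on the true (non-quadratic) gradient.
    ``best_effort`` caps the iteration budget and skips the final KKT
    verification — adequate for scoring held-out lesions along a CV path,
    never for a final model.

    Raises
    ------
    ConvergenceError
        If the KKT conditions are not met within ``max_iter`` rounds, e.g.
        on separable data at a vanishing penalty.
    """
    from scipy.special import expit

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    b0 = float(intercept0)
    eta = b0 + X @ beta
    n_rounds = 3 if best_effort else max_iter
    n_irls = 10 if best_effort else max_iter

    # working-set strategy: IRLS + cyclic CD restricted to candidate
    # coordinates, then a full KKT scan (one matvec) absorbs any violators
    score = X.T @ (y - expit(eta)) / n
    candidates = np.union1d(np.flatnonzero(beta), np.flatnonzero(np.abs(score) > lam))

    for _round in range(n_rounds):
        cand = candidates.astype(int)
        Xc = np.ascontiguousarray(X[:, cand])
        bc = beta[cand].copy()
        nc = len(cand)
        for _irls in range(n_irls):
            prob = expit(eta)
            w = np.clip(prob * (1.0 - prob), 1e-5, None)
            z = eta + (y - prob) / w
            w_sum = w.sum()
            WXc = w[:, None] * Xc
            wxx = (w @ (Xc * Xc)) / n  # per-coordinate curvature this round
            r = z - eta  # working residual, kept in sync with (b0, bc)
            wr = w * r

            def sweep(ks) -> float:
                nonlocal b0, r, wr
                max_delta = 0.0
                delta = float(wr.sum()) / w_sum
                if delta != 0.0:
                    b0 += delta
                    r -= delta
                    wr -= delta * w
                    max_delta = abs(delta)
                for k in ks:
                    grad = float(wr @ Xc[:, k]) / n + wxx[k] * bc[k]
                    new_bk = _soft_threshold(grad, lam) / wxx[k]
                    delta = new_bk - bc[k]
                    if delta != 0.0:
                        r -= delta * Xc[:, k]
                        wr -= delta * WXc[:, k]
                        bc[k] = new_bk
                        if abs(delta) > max_delta:
                            max_delta = abs(delta)
                return max_delta

            # full passes are expensive; iterate mostly on the active set
            for _cycle in range(5 if best_effort else 60):
                if sweep(range(nc)) < tol:
                    break
                for _s in range(30 if best_effort else 500):
                    if sweep(np.flatnonzero(bc)) < tol:
                        break
            eta = z - r
            if np.abs(bc).max(initial=0.0) > 1e4:
                raise ConvergenceError(
                    f"coefficients diverging (separable data?) at lam={lam:.3g}"
                )
            # restricted problem converged when its own true KKT holds
            prob = expit(eta)
            resid = y - prob
            if abs(resid.mean()) > kkt_tol:
                continue
            if nc == 0:
                break
            sc = Xc.T @ resid / n
            nz = bc != 0
            if np.all(np.abs(sc[~nz]) <= lam + kkt_tol) and np.all(
                np.abs(sc[nz] - lam * np.sign(bc[nz])) <= kkt_tol
            ):
                break
        else:
            if not best_effort:
                raise ConvergenceError(f"IRLS did not converge at lam={lam:.3g}")

        beta[:] = 0.0
        beta[cand] = bc
        score = X.T @ (y - prob) / n
        violators = np.flatnonzero((np.abs(score) > lam + kkt_tol) & (beta == 0))
        violators = np.setdiff1d(violators, cand)
        if len(violators) == 0 or best_effort:
            return beta, b0
        candidates = np.union1d(cand, violators)
    if best_effort:
        return beta, b0
    raise ConvergenceError(
        f"working set did not stabilize after {max_iter} rounds (lam={lam:.3g})"
    )


def lambda_grid_for(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                    eps: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to eps*lambda_max.

    lambda_max is the smallest penalty that zeroes every coefficient:
    max_j |(1/n) x_j'(y - ybar)| on standardized X.
    """
    ybar = y.mean()
    lam_max = float(np.abs(X.T @ (y - ybar)).max() / len(y))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


@dataclass(frozen=True)
class LassoPath:
    lambda_grid: np.ndarray
    cv_error_mean: np.ndarray
    cv_error_sd: np.ndarray
    chosen_lambda: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "log_lambda": np.log(self.lambda_grid),
                "cv_error_mean": self.cv_error_mean,
                "cv_error_sd": self.cv_error_sd,
            }
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def cv_select_lambda(
    table: pd.DataFrame,
    plan: SplitPlan,
    feature_names: list[str],
    lambda_grid: np.ndarray | None = None,
    threshold: float = 0.5,
) -> LassoPath:
    """Tenfold CV misclassification error along the lambda path.

    For each fold, standardization statistics and the L1 fit (selection +
    model) are recomputed on the training folds only; the held-out fold is
    scored at the given probability threshold.  The chosen lambda attains
    the minimum mean error; ties go to the larger lambda.
    """
    learn = table.loc[list(plan.learning_ids)]
    X_all = learn[feature_names].to_numpy(dtype=float)
    y_all = encode_labels(learn["label"])
    fold = np.array([plan.fold_assignment[i] for i in plan.learning_ids])

    if lambda_grid is None:
        Xs, _, _ = _standardize(X_all)
        lambda_grid = lambda_grid_for(Xs, y_all)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) >= 0) and len(lambda_grid) > 1:
        raise ValueError("lambda grid must be strictly decreasing")

    errors = np.full((plan.folds, len(lambda_grid)), np.nan)
    for f in range(1, plan.folds + 1):
        tr = fold != f
        te = fold == f
        if len(np.unique(y_all[tr])) < 2:
            raise SplitError(f"fold {f}: training folds contain one class only")
        Xtr, mu, sd = _standardize(X_all[tr])
        ytr = y_all[tr]
        Xte = (X_all[te] - mu) / sd
        beta = np.zeros(Xtr.shape[1])
        b0 = float(np.log(ytr.mean() / (1 - ytr.mean())))
        for li, lam in enumerate(lambda_grid):
            try:
                # path exploration runs at a looser stationarity tolerance;
                # the chosen lambda is refit tightly in finalize()
                beta, b0 = fit_lasso_logistic(
                    Xtr, ytr, lam, beta0=beta, intercept0=b0,
                    tol=1e-6, kkt_tol=1e-4, best_effort=True,
                )
            except ConvergenceError:
                # separable training folds can defeat tiny lambdas at the
                # path tail; such grid points are excluded from selection
                break
            prob = 1.0 / (1.0 + np.exp(-(b0 + Xte @ beta)))
            pred = (prob >= threshold).astype(float)
            errors[f - 1, li] = float((pred != y_all[te]).mean())

    valid = ~np.isnan(errors).any(axis=0)
    if not valid.any():
        raise ConvergenceError("no lambda on the grid converged in every fold")
    mean_err = np.where(valid, np.nanmean(np.where(valid, errors, np.nan), axis=0), np.inf)
    with np.errstate(invalid="ignore"):
        sd_err = np.where(
            valid,
            np.nanstd(np.where(valid, errors, np.nan), axis=0, ddof=1)
            if plan.folds > 1
            else 0.0,
            np.nan,
        )
    best = mean_err.min()
    chosen = float(lambda_grid[np.flatnonzero(mean_err == best)[0]])  # grid descends
    return LassoPath(
        lambda_grid=lambda_grid,
        cv_error_mean=mean_err,
        cv_error_sd=sd_err,
        chosen_lambda=chosen,
    )


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FinalModel:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # standardized scale, aligned with feature_names
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    chosen_lambda: float
    threshold: float = 0.5

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(
            n for n, b in zip(self.feature_names, self.coefficients) if b != 0
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": list(self.feature_names),
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "chosen_lambda": self.chosen_lambda,
                    "threshold": self.threshold,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FinalModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            chosen_lambda=float(d["chosen_lambda"]),
            threshold=float(d["threshold"]),
        )


def finalize(
    table: pd.DataFrame,
    plan: SplitPlan,
    feature_names: list[str],
    chosen_lambda: float,
    threshold: float = 0.5,
) -> FinalModel:
    """Refit the LASSO logistic model on the full learning set."""
    learn = table.loc[list(plan.learning_ids)]
    X = learn[feature_names].to_numpy(dtype=float)
    y = encode_labels(learn["label"])
    Xs, mu, sd = _standardize(X)
    b0_init = float(np.log(y.mean() / (1 - y.mean())))
    beta, b0 = fit_lasso_logistic(Xs, y, chosen_lambda, intercept0=b0_init)
    return FinalModel(
        feature_names=tuple(feature_names),
        coefficients=beta,
        intercept=b0,
        means=mu,
        sds=sd,
        chosen_lambda=chosen_lambda,
        threshold=threshold,
    )


def importance_ranking(model: FinalModel) -> list[tuple[str, float]]:
    """Selected features ranked by |standardized coefficient|, descending.

    Ties break alphabetically; an all-zero model gives an empty ranking.
    """
    pairs = [
        (n, abs(float(b)))
        for n, b in zip(model.feature_names, model.coefficients)
        if b != 0
    ]
    return sorted(pairs, key=lambda t: (-t[1], t[0]))


def predict_proba(model: FinalModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted malignancy probability for each row.

    Raises
    ------
    KeyError
        Naming the first missing feature column.
    """
    for name in model.feature_names:
        if name not in rows.columns:
            raise KeyError(f"missing feature column: {name!r}")
    X = rows[list(model.feature_names)].to_numpy(dtype=float)
    Xs = (X - model.means) / model.sds
    eta = model.intercept + Xs @ model.coefficients
    return 1.0 / (1.0 + np.exp(-eta))
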