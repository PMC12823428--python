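"""Protein selection and incident-disease prediction.

Pipeline: random 80/20 split; L1-penalized logistic regression over a
100-point penalty grid with 10-fold cross-validation and the one-standard-
error rule (lambda.1se); balanced-subsample stability selection (all cases +
an equal number of controls per iteration, selection frequency >= 0.5);
backward stepwise-AIC refits of four nested logistic models; and test-set
discrimination (ROC AUC, precision-recall AUC, paired DeLong tests).

The penalized solver is coordinate descent inside an IRLS loop (the glmnet
algorithm) with per-feature penalty factors so that demographic covariates
stay unpenalized while proteins are shrunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._glm import logistic_fit

try:  # compiled coordinate-descent kernel; falls back to pure numpy
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# penalized solver


@njit(cache=True)
def _nb_objective(X, y, b0, beta, penalty, pf):
    n = X.shape[0]
    eta = b0 + X @ beta
    nll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0:
            lse = e + np.log1p(np.exp(-e))
        else:
            lse = np.log1p(np.exp(e))
        nll -= y[i] * e - lse
    return nll / n + penalty * np.sum(pf * np.abs(beta))


@njit(cache=True)
def _nb_solve(X, y, penalty, pf, beta, b0, max_outer, tol):
    """IRLS outer loop + coordinate-descent inner loop, fully compiled."""
    n, p = X.shape
    obj_old = _nb_objective(X, y, b0, beta, penalty, pf)
    converged = False
    all_coords = np.arange(p)
    for _outer in range(max_outer):
        eta = b0 + X @ beta
        mu = np.empty(n)
        w = np.empty(n)
        z = np.empty(n)
        for i in range(n):
            e = eta[i]
            if e > 35.0:
                e = 35.0
            elif e < -35.0:
                e = -35.0
            m = 1.0 / (1.0 + np.exp(-e))
            mu[i] = m
            wi = m * (1.0 - m)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            z[i] = eta[i] + (y[i] - m) / wi
        wx2 = np.zeros(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wx2[j] = s / n
        r = z - b0 - X @ beta
        w_sum = np.sum(w)
        for _cycle in range(50):
            b0, max_delta = _cd_pass(
                X, w, r, beta, b0, wx2, pf, penalty, all_coords, n, w_sum
            )
            if max_delta < 1e-8:
                break
            active = np.nonzero(beta)[0]
            for _inner in range(200):
                b0, max_delta = _cd_pass(
                    X, w, r, beta, b0, wx2, pf, penalty, active, n, w_sum
                )
                if max_delta < 1e-8:
                    break
        obj = _nb_objective(X, y, b0, beta, penalty, pf)
        if abs(obj_old - obj) < tol * (abs(obj_old) + 1e-4):
            converged = True
            break
        obj_old = obj
    return b0, converged


@njit(cache=True)
def _cd_pass(X, w, r, beta, b0, wx2, pf, penalty, coords, n, w_sum):
    """One cyclic coordinate-descent pass over ``coords`` on the weighted LS
    problem; updates r/beta in place, returns (new_b0, max coefficient move)."""
    delta = np.sum(w * r) / w_sum
    r -= delta
    b0 = b0 + delta
    max_delta = abs(delta)
    for j in coords:
        if wx2[j] == 0.0:
            continue
        rho = 0.0
        for i in range(n):
            rho += w[i] * X[i, j] * r[i]
        rho = rho / n + wx2[j] * beta[j]
        t = penalty * pf[j]
        if rho > t:
            new = (rho - t) / wx2[j]
        elif rho < -t:
            new = (rho + t) / wx2[j]
        else:
            new = 0.0
        if new != beta[j]:
            d = new - beta[j]
            for i in range(n):
                r[i] -= X[i, j] * d
            if abs(d) > max_delta:
                max_delta = abs(d)
            beta[j] = new
    return b0, max_delta


def lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: float,
    penalty_factor: np.ndarray | None = None,
    beta_init: np.ndarray | None = None,
    intercept_init: float = 0.0,
    max_outer: int = 100,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray, bool]:
    """L1-penalized logistic regression by IRLS + coordinate descent.

    Minimizes -(1/n) loglik + penalty * sum_j pf_j |beta_j| with an
    unpenalized intercept.  Convergence is declared when the objective
    changes by less than ``tol``.  Returns (intercept, beta, converged).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    pf = (
        np.ones(p)
        if penalty_factor is None
        else np.ascontiguousarray(penalty_factor, dtype=np.float64)
    )
    beta = np.zeros(p) if beta_init is None else beta_init.astype(np.float64)
    b0 = float(intercept_init)

    b0, converged = _nb_solve(X, y, float(penalty), pf, beta, b0, max_outer, tol)
    return float(b0), beta, converged


# ---------------------------------------------------------------------------
# cross-validated penalty path


@dataclass
class PenaltyPath:
    """Penalty grid with 10-fold CV binomial deviance and the 1-SE rule."""

    grid: np.ndarray
    cv_loss: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    n_nonzero: np.ndarray
    converged: np.ndarray


def default_grid(n_points: int = 100, lo: float = 1e-6, hi: float = 0.07) -> np.ndarray:
    """Logarithmic penalty grid, descending (largest first for warm starts)."""
    return np.logspace(np.log10(hi), np.log10(lo), n_points)


def lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    penalty_factor: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> PenaltyPath:
    """Tune the L1 penalty by cross-validated binomial deviance.

    Fold labels are drawn once (seeded) and shared across the grid;
    lambda.1se is the largest penalty whose CV loss stays within one standard
    error of the minimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    grid = default_grid() if grid is None else np.sort(np.asarray(grid))[::-1]
    rng = np.random.default_rng(seed)
    fold_id = rng.integers(0, folds, size=n)
    # guard: every fold must contain both classes
    for f in range(folds):
        if len(np.unique(y[fold_id == f])) < 2:
            order = rng.permutation(n)
            fold_id = np.empty(n, dtype=int)
            fold_id[order] = np.arange(n) % folds
            break

    L = len(grid)
    losses = np.full((folds, L), np.nan)
    for f in range(folds):
        tr = fold_id != f
        te = ~tr
        beta = np.zeros(X.shape[1])
        b0 = 0.0
        for li, lam in enumerate(grid):
            b0, beta, _ = lasso_logistic(
                X[tr], y[tr], lam, penalty_factor, beta_init=beta, intercept_init=b0
            )
            losses[f, li] = _deviance(X[te], y[te], b0, beta)
    cv_loss = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(folds)
    imin = int(np.argmin(cv_loss))
    lam_min = float(grid[imin])
    admissible = cv_loss <= cv_loss[imin] + cv_se[imin]
    lam_1se = float(grid[np.nonzero(admissible)[0][0]])  # grid descends

    nnz = np.zeros(L, dtype=int)
    conv = np.zeros(L, dtype=bool)
    beta = np.zeros(X.shape[1])
    b0 = 0.0
    for li, lam in enumerate(grid):
        b0, beta, ok = lasso_logistic(
            X, y, lam, penalty_factor, beta_init=beta, intercept_init=b0
        )
        pf = np.ones(X.shape[1]) if penalty_factor is None else penalty_factor
        nnz[li] = int(np.sum((beta != 0) & (pf > 0)))
        conv[li] = ok
    return PenaltyPath(grid, cv_loss, cv_se, lam_min, lam_1se, nnz, conv)


def _deviance(X, y, b0, beta) -> float:
    eta = b0 + X @ beta
    lse = np.where(eta > 0, eta + np.log1p(np.exp(-np.abs(eta))), np.log1p(np.exp(eta)))
    return float(-2.0 * np.mean(y * eta - lse))


# ---------------------------------------------------------------------------
# split / stability selection


def split(
    data: pd.DataFrame, outcome: str, test_fraction: float = 0.20, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random (non-stratified) train/test split, seeded.

    Rejects splits that leave either partition without cases.
    """
    y = data[outcome].to_numpy()
    if int(np.sum(y == 1)) < 2:
        raise ValueError("need at least two cases to split")
    n = len(data)
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n_test >= n:
        raise ValueError("degenerate split sizes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train = data.iloc[np.sort(train_idx)].reset_index(drop=True)
    test = data.iloc[np.sort(test_idx)].reset_index(drop=True)
    if train[outcome].sum() == 0 or test[outcome].sum() == 0:
        raise ValueError("split left a partition without cases; use another seed")
    return train, test


@dataclass
class StabilityResult:
    """Per-feature selection frequency over balanced subsamples."""

    frequency: pd.Series
    selected: list[str]
    n_iter: int
    threshold: float
    penalty: float


def stability_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    penalty: float,
    penalty_factor: np.ndarray | None = None,
    n_iter: int = 100,
    threshold: float = 0.5,
    seed: int = 0,
) -> StabilityResult:
    """Balanced-subsample stability selection at a fixed penalty.

    Each iteration keeps every case and an equal-size control subsample drawn
    without replacement, refits the penalized model, and records which
    penalized features obtain nonzero coefficients.  Features selected in at
    least ``threshold`` of the iterations form the stable set.
    """
    yv = np.asarray(y, dtype=float)
    cases = np.nonzero(yv == 1)[0]
    controls = np.nonzero(yv == 0)[0]
    if len(controls) < len(cases):
        raise ValueError(
            "fewer controls than cases: balanced subsampling without "
            "replacement is impossible"
        )
    Xv = X.to_numpy(dtype=float)
    pf = np.ones(Xv.shape[1]) if penalty_factor is None else penalty_factor
    rng = np.random.default_rng(seed)
    counts = np.zeros(Xv.shape[1])
    for _ in range(n_iter):
        ctrl = rng.choice(controls, size=len(cases), replace=False)
        idx = np.concatenate([cases, ctrl])
        _, beta, _ = lasso_logistic(Xv[idx], yv[idx], penalty, pf)
        counts += (beta != 0) & (pf > 0)
    freq = pd.Series(counts / n_iter, index=X.columns)
    selected = sorted(freq.index[(freq >= threshold) & (pf > 0)])
    return StabilityResult(freq, selected, n_iter, threshold, penalty)


# ---------------------------------------------------------------------------
# stepwise refits


@dataclass
class FittedModel:
    """Plain logistic model with named predictors."""

    name: str
    predictors: list[str]
    intercept: float
    beta: np.ndarray
    aic: float
    aic_path: list[float] = field(default_factory=list)

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.predictors].to_numpy(dtype=float)
        eta = self.intercept + X @ self.beta
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _fit_named(data: pd.DataFrame, outcome: str, predictors: list[str], name: str):
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    fit = logistic_fit(X, y)
    k = len(predictors) + 1
    aic = 2 * k - 2 * fit.loglik
    return FittedModel(name, list(predictors), float(fit.beta[0]), fit.beta[1:], aic)


def stepwise_aic(
    data: pd.DataFrame,
    outcome: str,
    proteins: list[str],
    forced: list[str],
    name: str,
) -> FittedModel:
    """Backward elimination over proteins only; forced terms always stay.

    At each step the protein whose removal lowers AIC the most is dropped
    (ties broken alphabetically); elimination stops when no removal improves
    AIC.
    """
    current = sorted(proteins)
    model = _fit_named(data, outcome, forced + current, name)
    path = [model.aic]
    while current:
        best_aic, best_prot = model.aic, None
        for prot in current:  # sorted: alphabetical tie-break
            trial = [p for p in current if p != prot]
            cand = _fit_named(data, outcome, forced + trial, name)
            if cand.aic < best_aic - 1e-9:
                best_aic, best_prot = cand.aic, prot
        if best_prot is None:
            break
        current = [p for p in current if p != best_prot]
        model = _fit_named(data, outcome, forced + current, name)
        path.append(model.aic)
    model.aic_path = path
    return model


def refit_models(
    train: pd.DataFrame,
    outcome: str,
    selected: list[str],
    demographics: tuple[str, ...] = ("age", "sex", "bmi"),
    e4_col: str = "hap_count",
) -> dict[str, FittedModel]:
    """Fit the four nested prediction models on the training set.

    1 basic (demographics); 2 proteomic (stability-selected proteins);
    3 proteomic + basic; 4 risk-haplotype + proteomic + basic.  Models 2-4
    apply backward stepwise-AIC elimination over the proteins; demographics
    and the haplotype count are never eliminated.
    """
    models = {"basic": _fit_named(train, outcome, list(demographics), "basic")}
    if not selected:
        return models
    models["proteomic"] = stepwise_aic(train, outcome, selected, [], "proteomic")
    models["proteomic+basic"] = stepwise_aic(
        train, outcome, selected, list(demographics), "proteomic+basic"
    )
    models["apoe+proteomic+basic"] = stepwise_aic(
        train, outcome, selected, list(demographics) + [e4_col], "apoe+proteomic+basic"
    )
    return models


# ---------------------------------------------------------------------------
# evaluation


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the pairwise concordance rank statistic (ties count 1/2)."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    from scipy.stats import rankdata

    r = rankdata(np.concatenate([pos, neg]))
    return float(
        (r[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    )


def pr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Precision-recall AUC by step interpolation (average precision)."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    precision = tp / (tp + fp)
    recall = tp / y.sum()
    # evaluate at distinct thresholds only (last index of each tied block)
    distinct = np.nonzero(np.diff(np.append(s, -np.inf)))[0]
    precision, recall = precision[distinct], recall[distinct]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(
    y_true: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong comparison of two AUCs on the same test set.

    Returns (delta_auc, two-sided p) using the placement-value covariance
    estimator with a normal reference.  Identical score vectors give
    (0, 1) by convention.
    """
    y = np.asarray(y_true, dtype=float)
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    pos_mask, neg_mask = y == 1, y == 0
    v10a, v01a = _placements(a[pos_mask], a[neg_mask])
    v10b, v01b = _placements(b[pos_mask], b[neg_mask])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    n1, n0 = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2 * norm.sf(abs(z)))


@dataclass
class PredictionEval:
    """Discrimination metrics per model plus pairwise DeLong comparisons."""

    metrics: pd.DataFrame
    pairwise: pd.DataFrame


def evaluate(
    models: dict[str, FittedModel], test: pd.DataFrame, outcome: str
) -> PredictionEval:
    y = test[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class")
    scores = {name: m.predict_proba(test) for name, m in models.items()}
    metrics = pd.DataFrame(
        [
            {"model": name, "roc_auc": roc_auc(y, s), "pr_auc": pr_auc(y, s)}
            for name, s in scores.items()
        ]
    )
    rows = []
    for a, b in combinations(scores, 2):
        delta, p = delong_test(y, scores[a], scores[b])
        rows.append({"model_a": a, "model_b": b, "delta_auc": delta, "p": p})
    return PredictionEval(metrics, pd.DataFrame(rows))
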