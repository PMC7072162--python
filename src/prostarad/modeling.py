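"""Bootstrap forward logistic modelling with the 0.632+ AUC estimator.

From a reduced (rank-ordered) feature signature, logistic models of order
1..10 are grown by forward selection: the order-i model keeps the order-(i-1)
features and adds the candidate that maximizes the 0.632+ bootstrap AUC.
Resampling is imbalance-adjusted (IABR): each training multiset draws the
two classes in (near-)equal numbers with replacement, and evaluation uses
the out-of-bag instances — the set never drawn into that sample.  The same
pre-drawn bootstrap samples are reused for every candidate and order, so
comparisons are paired and the build is reproducible regardless of
evaluation order.

The 0.632+ estimator blends apparent and out-of-bag performance:

    R = clip((theta_app - theta_oob) / (theta_app - 0.5), 0, 1)
    w = 0.632 / (1 - 0.368 * R)
    theta_632+ = (1 - w) * theta_app + w * max(theta_oob, 0.5)

where R measures relative overfitting (R = 0: no optimism, plain 0.632 rule;
R = 1: full shrinkage to the no-information rate 0.5).  Sensitivity and
specificity at the probability threshold use the same combination.

Logistic fits are maximum likelihood with a mild ridge (lambda = 1e-6 on
standardized slopes) so separable bootstrap samples stay finite, solved by
damped Newton iterations; fits are deterministic.

:class:`ForwardBootstrapClassifier` packages the procedure as a
scikit-learn classifier (fit / predict_proba over the finalized best-order
model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling configuration for model building and finalization."""

    n_samples: int = 1000
    seed: int = 0
    balance: str = "iabr"       # "iabr" (class-balanced) or "stratified"
    threshold: float = 0.5      # probability cutoff for sensitivity/specificity
    oob: str = "pooled"         # OOB summary: "pooled" (leave-one-out) or "mean"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.balance not in ("iabr", "stratified"):
            raise ValueError("balance must be 'iabr' or 'stratified'")
        if self.oob not in ("pooled", "mean"):
            raise ValueError("oob must be 'pooled' or 'mean'")


@dataclass
class ModelResult:
    """One model order: its features, finalized coefficients, performance."""

    order: int
    features: list[str]
    intercept: float
    coefficients: dict[str, float]
    auc632: float
    sens632: float
    spec632: float
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# resampling


def iabr_samples(
    labels, cfg: BootstrapConfig, rng: np.random.Generator | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Imbalance-adjusted bootstrap samples: (train multiset, OOB test set).

    Each training multiset has size n with the positive class contributing
    ceil(n/2) draws and the negative class floor(n/2) draws from their own
    instances ("stratified" instead preserves the original class ratio).
    The test set is every instance never drawn; samples whose test set is
    empty or single-class are redrawn (bounded retries).
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 instances for IABR")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.balance == "iabr":
        n_pos, n_neg = (n + 1) // 2, n // 2
    else:
        n_pos = int(round(n * len(pos) / n))
        n_neg = n - n_pos
    out = []
    for _ in range(cfg.n_samples):
        for _retry in range(100):
            train = np.concatenate([rng.choice(pos, n_pos), rng.choice(neg, n_neg)])
            test = np.setdiff1d(np.arange(n), train)
            if len(test) > 0 and len(np.unique(y[test])) == 2:
                out.append((train, test))
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with a two-class test set")
    return out


# --------------------------------------------------------------------------
# logistic fitting


def _logistic_fit_std(X, y, l2: float, max_iter: int, tol: float, warm=None):
    """Newton logistic fit; returns raw-scale (intercept, coefs), the
    standardized-scale coefficient vector, and a convergence flag."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    A = np.column_stack([np.ones(n), Z])
    pen = np.full(p + 1, l2)
    pen[0] = 0.0  # no penalty on the intercept

    beta = np.zeros(p + 1)
    beta[0] = np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12))
    if warm is not None and len(warm) == p + 1:
        beta = np.asarray(warm, dtype=float).copy()
    converged = False

    def nll(b):
        eta = A @ b
        return float(np.logaddexp(0.0, eta).sum() - y @ eta + 0.5 * (pen * b * b).sum())

    cur = nll(beta)
    eye = np.diag(pen + 1e-12)
    for _ in range(max_iter):
        prob = expit(A @ beta)
        g = A.T @ (prob - y) + pen * beta
        w = np.clip(prob * (1 - prob), 1e-12, None)
        H = (A * w[:, None]).T @ A + eye
        step = np.linalg.solve(H, g)
        # step halving keeps the iteration monotone
        alpha = 1.0
        new = nll(beta - step)
        for _h in range(30):
            if new <= cur:
                break
            alpha *= 0.5
            new = nll(beta - alpha * step)
        beta = beta - alpha * step
        if abs(cur - new) < tol * (1 + abs(cur)):
            converged = True
            break
        cur = new

    coefs = np.zeros(p)
    coefs[ok] = beta[1:][ok] / sd[ok]
    intercept = float(beta[0] - (coefs * mu).sum())
    return intercept, coefs, beta, converged


def _logistic_fit_batch(Xb: np.ndarray, yb: np.ndarray, l2: float = 1e-6,
                        max_iter: int = 30, tol: float = 1e-8):
    """Damped Newton logistic fits run in lockstep over a batch.

    ``Xb`` is (B, n, p), ``yb`` is (B, n); returns raw-scale intercepts (B,)
    and coefficients (B, p).  Identical model to :func:`logistic_fit`
    (standardized columns, ridge l2 on slopes), vectorized over the batch
    with per-member step halving and convergence freezing.
    """
    Xb = np.asarray(Xb, dtype=float)
    yb = np.asarray(yb, dtype=float)
    B, n, p = Xb.shape
    mu = Xb.mean(axis=1)                      # (B, p)
    sd = Xb.std(axis=1)
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    Z = (Xb - mu[:, None, :]) / sd_safe[:, None, :]
    Z = np.where(ok[:, None, :], Z, 0.0)
    A = np.concatenate([np.ones((B, n, 1)), Z], axis=2)   # (B, n, p+1)
    pen = np.full(p + 1, l2)
    pen[0] = 0.0

    beta = np.zeros((B, p + 1))
    ymean = np.clip(yb.mean(axis=1), 1e-12, 1 - 1e-12)
    beta[:, 0] = np.log(ymean / (1 - ymean))

    def nll(b):
        eta = np.einsum("bnj,bj->bn", A, b)
        return (
            np.logaddexp(0.0, eta).sum(axis=1)
            - np.einsum("bn,bn->b", yb, eta)
            + 0.5 * (pen * b * b).sum(axis=1)
        )

    cur = nll(beta)
    active = np.ones(B, dtype=bool)
    eye = np.diag(pen + 1e-12)
    for _ in range(max_iter):
        prob = expit(np.einsum("bnj,bj->bn", A, beta))
        g = np.einsum("bnj,bn->bj", A, prob - yb) + pen * beta
        w = np.clip(prob * (1 - prob), 1e-12, None)
        H = np.einsum("bnj,bn,bnk->bjk", A, w, A) + eye
        step = np.linalg.solve(H, g[..., None])[..., 0]
        alpha = np.ones(B)
        new = nll(beta - step)
        for _h in range(20):
            worse = active & (new > cur)
            if not worse.any():
                break
            alpha[worse] *= 0.5
            trial = beta[worse] - alpha[worse, None] * step[worse]
            new[worse] = nll_rows(A, yb, pen, trial, worse)
        upd = beta - alpha[:, None] * step
        beta = np.where(active[:, None], upd, beta)
        done = np.abs(cur - new) < tol * (1 + np.abs(cur))
        cur = np.where(active, new, cur)
        active = active & ~done
        if not active.any():
            break

    coefs = np.where(ok, beta[:, 1:] / sd_safe, 0.0)
    intercept = beta[:, 0] - (coefs * mu).sum(axis=1)
    return intercept, coefs


def nll_rows(A, yb, pen, betas, rows) -> np.ndarray:
    """Penalized logistic NLL of ``betas`` for the selected batch rows."""
    Ar = A[rows]
    yr = yb[rows]
    eta = np.einsum("bnj,bj->bn", Ar, betas)
    return (
        np.logaddexp(0.0, eta).sum(axis=1)
        - np.einsum("bn,bn->b", yr, eta)
        + 0.5 * (pen * betas * betas).sum(axis=1)
    )


def logistic_fit(X, y, l2: float = 1e-6, max_iter: int = 40, tol: float = 1e-8):
    """Ridge-stabilized maximum-likelihood logistic regression.

    Columns are standardized internally (constant columns get coefficient 0)
    and the mild L2 penalty acts on standardized slopes only, keeping
    separable data finite; coefficients are returned on the raw scale as
    ``(intercept, coefs, converged)``.  Damped Newton iterations make the
    fit deterministic.
    """
    intercept, coefs, _, converged = _logistic_fit_std(X, y, l2, max_iter, tol)
    return intercept, coefs, converged


def predict_proba(intercept: float, coefs: np.ndarray, X) -> np.ndarray:
    eta = np.asarray(X, dtype=float) @ np.asarray(coefs, dtype=float) + intercept
    return expit(eta)


# --------------------------------------------------------------------------
# 0.632+ combination


def auc_632plus(theta_app: float, theta_oob: float) -> float:
    """The 0.632+ combination of apparent and out-of-bag performance."""
    if not (0.0 <= theta_app <= 1.0 and 0.0 <= theta_oob <= 1.0):
        raise ValueError("performance estimates must lie in [0, 1]")
    oob = max(theta_oob, 0.5)
    if theta_app <= oob:
        r = 0.0
    else:
        r = np.clip((theta_app - theta_oob) / (theta_app - 0.5), 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * theta_app + w * oob)


def _sens_spec(y, prob, threshold: float) -> tuple[float, float]:
    pred = prob >= threshold
    y = np.asarray(y).astype(bool)
    sens = float(pred[y].mean()) if y.any() else np.nan
    spec = float((~pred[~y]).mean()) if (~y).any() else np.nan
    return sens, spec


def _evaluate_combo(
    X, y, samples, threshold: float, oob_estimator: str = "pooled"
) -> dict[str, float]:
    """Apparent + OOB performance of one feature combination, 0.632+ blended.

    ``oob_estimator`` chooses how out-of-bag predictions are summarized:
    ``"pooled"`` (leave-one-out bootstrap: each instance's prediction is
    averaged over the samples in which it is out-of-bag, then one AUC is
    computed over all instances) or ``"mean"`` (AUC per bootstrap test set,
    averaged).  Also returns the per-bootstrap coefficient mean/sd (the
    IABR-finalized coefficients of this combination).
    """
    intercept, coefs, _, _ = _logistic_fit_std(X, y, 1e-6, 40, 1e-8)
    prob_app = predict_proba(intercept, coefs, X)
    auc_app = float(roc_auc_score(y, prob_app))
    sens_app, spec_app = _sens_spec(y, prob_app, threshold)

    B = len(samples)
    Xtr = np.stack([X[tr] for tr, _ in samples])
    ytr = np.stack([y[tr] for tr, _ in samples])
    ib, cb = _logistic_fit_batch(Xtr, ytr)
    boot_coefs = np.column_stack([ib, cb])
    prob_all = expit(X @ cb.T + ib)  # (n, B): every instance under every model

    if oob_estimator == "pooled":
        psum = np.zeros(len(y))
        cnt = np.zeros(len(y))
        for b, (_, test) in enumerate(samples):
            psum[test] += prob_all[test, b]
            cnt[test] += 1
        seen = cnt > 0
        pbar = psum[seen] / cnt[seen]
        auc_oob = float(roc_auc_score(y[seen], pbar))
        sens_oob, spec_oob = _sens_spec(y[seen], pbar, threshold)
    elif oob_estimator == "mean":
        aucs, senss, specs = [], [], []
        for b, (_, test) in enumerate(samples):
            prob = prob_all[test, b]
            aucs.append(roc_auc_score(y[test], prob))
            s, sp = _sens_spec(y[test], prob, threshold)
            senss.append(s)
            specs.append(sp)
        auc_oob = float(np.mean(aucs))
        sens_oob = float(np.nanmean(senss))
        spec_oob = float(np.nanmean(specs))
    else:
        raise ValueError("oob_estimator must be 'pooled' or 'mean'")
    return {
        "auc632": auc_632plus(auc_app, auc_oob),
        "sens632": auc_632plus(sens_app, sens_oob),
        "spec632": auc_632plus(spec_app, spec_oob),
        "auc_app": auc_app,
        "auc_oob": auc_oob,
        "coef_mean": boot_coefs.mean(axis=0),
        "coef_sd": boot_coefs.std(axis=0),
    }


# --------------------------------------------------------------------------
# forward model building


def forward_build_models(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    cfg: BootstrapConfig,
    max_order: int = 10,
) -> list[ModelResult]:
    """Models of order 1..max_order grown by 0.632+ AUC forward selection.

    Columns of ``X`` must be in signature rank order; ties between
    candidates go to the earlier-ranked one.  Coefficients stored per order
    are the IABR-averaged fits of that order's combination.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_feat = X.shape[1]
    if max_order > n_feat:
        warnings.warn(
            f"max_order={max_order} exceeds the {n_feat} available features", stacklevel=2
        )
        max_order = n_feat
    samples = iabr_samples(y, cfg)
    chosen: list[int] = []
    results: list[ModelResult] = []
    for order in range(1, max_order + 1):
        best = None
        for j in range(n_feat):  # rank order; strict > keeps earlier rank on ties
            if j in chosen:
                continue
            ev = _evaluate_combo(X[:, chosen + [j]], y, samples, cfg.threshold, cfg.oob)
            if best is None or ev["auc632"] > best[1]["auc632"]:
                best = (j, ev)
        j, ev = best
        chosen.append(j)
        feats = [feature_names[i] for i in chosen]
        results.append(
            ModelResult(
                order=order,
                features=feats,
                intercept=float(ev["coef_mean"][0]),
                coefficients=dict(zip(feats, ev["coef_mean"][1:].tolist())),
                auc632=ev["auc632"],
                sens632=ev["sens632"],
                spec632=ev["spec632"],
                diagnostics={
                    "auc_app": ev["auc_app"],
                    "auc_oob": ev["auc_oob"],
                    "coef_sd": ev["coef_sd"].tolist(),
                },
            )
        )
    return results


def choose_best_order(results: list[ModelResult], tol: float = 0.005) -> int:
    """Smallest order whose 0.632+ AUC is within ``tol`` of the maximum.

    ``tol = 0`` is the literal argmax rule (first maximum on ties).
    """
    if not results:
        raise ValueError("no model results")
    aucs = np.array([r.auc632 for r in results])
    target = aucs.max() - tol
    for r, a in zip(results, aucs):
        if a >= target:
            return r.order
    return results[int(np.argmax(aucs))].order  # unreachable; defensive


def finalize_model(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    cfg: BootstrapConfig,
    refit_full: bool = False,
) -> ModelResult:
    """Final coefficients for a fixed feature combination.

    Default: mean (and sd) of the per-bootstrap IABR training fits;
    ``refit_full`` instead refits once on all data.  Performance estimates
    are the 0.632+ blends over the same samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    samples = iabr_samples(y, cfg)
    ev = _evaluate_combo(X, y, samples, cfg.threshold, cfg.oob)
    if refit_full:
        intercept, coefs, _ = logistic_fit(X, y)
    else:
        intercept, coefs = float(ev["coef_mean"][0]), ev["coef_mean"][1:]
    return ModelResult(
        order=X.shape[1],
        features=list(feature_names),
        intercept=float(intercept),
        coefficients=dict(zip(feature_names, np.asarray(coefs).tolist())),
        auc632=ev["auc632"],
        sens632=ev["sens632"],
        spec632=ev["spec632"],
        diagnostics={
            "auc_app": ev["auc_app"],
            "auc_oob": ev["auc_oob"],
            "coef_sd": ev["coef_sd"].tolist(),
        },
    )


def results_table(results: list[ModelResult]) -> pd.DataFrame:
    """Order-wise performance table (the content of the order/AUC curves)."""
    return pd.DataFrame(
        {
            "order": [r.order for r in results],
            "auc632": [r.auc632 for r in results],
            "sens632": [r.sens632 for r in results],
            "spec632": [r.spec632 for r in results],
            "added_feature": [r.features[-1] for r in results],
        }
    )


# --------------------------------------------------------------------------
# sklearn estimator


class ForwardBootstrapClassifier(ClassifierMixin, BaseEstimator):
    """0.632+ bootstrap forward logistic classifier.

    Fitting grows models of order 1..max_order over the columns of X (taken
    in the given order as the signature ranking), picks the best order by
    the plateau rule, and finalizes coefficients by IABR averaging.

    Attributes (after fit): ``results_`` (per-order ModelResults),
    ``best_order_``, ``features_`` (column indices of the final model),
    ``intercept_``, ``coef_``, ``final_`` (the finalized ModelResult).
    """

    def __init__(
        self,
        max_order: int = 10,
        n_bootstrap: int = 1000,
        random_state: int = 0,
        balance: str = "iabr",
        threshold: float = 0.5,
        plateau_tol: float = 0.005,
        refit_full: bool = False,
    ):
        self.max_order = max_order
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.balance = balance
        self.threshold = threshold
        self.plateau_tol = plateau_tol
        self.refit_full = refit_full

    def fit(self, X, y):
        names = list(X.columns) if hasattr(X, "columns") else None
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary outcome required")
        yb = (y == self.classes_[1]).astype(int)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        cfg = BootstrapConfig(
            n_samples=self.n_bootstrap,
            seed=self.random_state,
            balance=self.balance,
            threshold=self.threshold,
        )
        self.results_ = forward_build_models(X, yb, names, cfg, self.max_order)
        self.best_order_ = choose_best_order(self.results_, self.plateau_tol)
        best_feats = self.results_[self.best_order_ - 1].features
        idx = [names.index(f) for f in best_feats]
        final_cfg = BootstrapConfig(
            n_samples=self.n_bootstrap,
            seed=self.random_state + 1,
            balance=self.balance,
            threshold=self.threshold,
        )
        self.final_ = finalize_model(X[:, idx], yb, best_feats, final_cfg, self.refit_full)
        self.features_ = idx
        self.feature_names_selected_ = best_feats
        self.intercept_ = self.final_.intercept
        self.coef_ = np.array([self.final_.coefficients[f] for f in best_feats])
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        p1 = predict_proba(self.intercept_, self.coef_, X[:, self.features_])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]
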