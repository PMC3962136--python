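"""Maximum-likelihood multinomial-logit and ordered-logit models.

These two regression families are the workhorses of the multi-class
conditional independence test: the nominal-outcome test compares nested
multinomial-logit fits, the ordinal-outcome test compares nested
ordered-logit (proportional-odds) fits.

Multinomial logit.  With ``K`` outcome classes and regressor row ``w`` (an
intercept plus ``q`` features), class ``K`` (the last code) is the baseline
and ``ln Pr(T=k)/Pr(T=K) = beta_k . w`` for ``k = 1..K-1``; probabilities
normalise through ``Pr(T=K) = 1/(1 + sum_k exp(beta_k . w))``.  The model has
``(K-1)(q+1)`` free parameters.

Ordered logit.  The outcome is the observed discretisation of a latent
``T* = beta . w + eps`` with standard-logistic noise; strictly increasing
thresholds ``mu_1 < ... < mu_{K-1}`` cut the latent axis into the K ordered
classes, so ``Pr(T=k) = F(mu_k - beta.w) - F(mu_{k-1} - beta.w)`` with F the
logistic CDF.  Only ``q + K - 1`` parameters are needed, which is why the
ordinal model is preferred whenever class order is meaningful.

Numerical policy (shared by both families): zero-variance and linearly
dependent regressor columns are dropped before fitting (and reported), all
free parameters are box-constrained to ``[-30, 30]`` so that separated data
yield a finite, near-supremum log-likelihood instead of a divergent fit, and
ordered-logit threshold monotonicity is enforced by optimising the first
threshold plus log-increments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

from .data import LabeledDataset

__all__ = [
    "MultinomialLogit",
    "OrderedLogit",
    "MultinomialLogitResults",
    "OrderedLogitResults",
    "fit_multinomial_logit",
    "fit_ordered_logit",
    "predict_proba",
    "intercept_only_loglik",
]

COEF_BOUND = 30.0
MAX_ITER = 200
LL_RTOL = 1e-10
GRAD_TOL = 1e-6
_RANK_TOL = 1e-9


def intercept_only_loglik(counts: np.ndarray) -> float:
    """Saturated intercept-only log-likelihood: sum_k n_k ln(n_k / n)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    pos = counts > 0
    return float(np.sum(counts[pos] * np.log(counts[pos] / n)))


def _independent_columns(X: np.ndarray) -> tuple[list[int], list[int]]:
    """Greedy left-to-right selection of columns independent of the intercept
    and of previously kept columns. Returns (kept, dropped) column indices."""
    n, q = X.shape
    kept: list[int] = []
    dropped: list[int] = []
    basis = [np.full(n, 1.0 / np.sqrt(n))]
    for j in range(q):
        v = X[:, j].astype(float).copy()
        scale = np.linalg.norm(v)
        if scale <= 0:
            dropped.append(j)
            continue
        for b in basis:
            v -= (b @ v) * b
        if np.linalg.norm(v) <= _RANK_TOL * scale:
            dropped.append(j)
        else:
            kept.append(j)
            basis.append(v / np.linalg.norm(v))
    return kept, dropped


# ---------------------------------------------------------------------------
# multinomial logit
# ---------------------------------------------------------------------------


def _mnl_eta_logz(W: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = W @ B.T  # (n, K-1); baseline class has implicit eta 0
    mx = np.maximum(eta.max(axis=1), 0.0)
    logz = mx + np.log(np.exp(-mx) + np.exp(eta - mx[:, None]).sum(axis=1))
    return eta, logz


def _mnl_loglik(W: np.ndarray, B: np.ndarray, Y: np.ndarray) -> float:
    eta, logz = _mnl_eta_logz(W, B)
    return float((eta * Y).sum() - logz.sum())


def _fit_mnlogit_newton(
    W: np.ndarray, y: np.ndarray, k: int, start: np.ndarray | None = None
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton ascent of the multinomial-logit log-likelihood with
    coefficients projected into [-COEF_BOUND, COEF_BOUND]."""
    n, m = W.shape
    d = k - 1
    Y = (y[:, None] == np.arange(d)).astype(float)
    B = np.zeros((d, m)) if start is None else np.clip(start, -COEF_BOUND, COEF_BOUND)
    ll = _mnl_loglik(W, B, Y)
    converged = False
    for _ in range(MAX_ITER):
        eta, logz = _mnl_eta_logz(W, B)
        P = np.exp(eta - logz[:, None])  # (n, d)
        G = (Y - P).T @ W  # (d, m)
        if np.abs(G).max() < GRAD_TOL:
            converged = True
            break
        H = np.empty((d * m, d * m))
        for a in range(d):
            for b in range(a, d):
                wgt = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                blk = (W * wgt[:, None]).T @ W
                H[a * m : (a + 1) * m, b * m : (b + 1) * m] = blk
                H[b * m : (b + 1) * m, a * m : (a + 1) * m] = blk
        g = G.ravel()
        ridge = 0.0
        for _attempt in range(6):
            try:
                step = np.linalg.solve(-(H + ridge * np.eye(d * m)), -g)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-8)
        else:  # pragma: no cover - pathological Hessian
            step = g
        step = step.reshape(d, m)
        # halving line search; projection keeps separated fits finite
        t = 1.0
        for _half in range(40):
            Bn = np.clip(B + t * step, -COEF_BOUND, COEF_BOUND)
            lln = _mnl_loglik(W, Bn, Y)
            if lln >= ll:
                break
            t *= 0.5
        if lln < ll:
            converged = True  # cannot improve: at (projected) optimum
            break
        improved = lln - ll
        B, ll = Bn, lln
        if improved < LL_RTOL * (abs(ll) + 1.0):
            converged = True
            break
    return B, ll, converged


@dataclass
class MultinomialLogitResults:
    """Fitted multinomial-logit model.

    ``coefficients`` is a ``(K-1) x (q+1)`` matrix over the regressors passed
    to the model (column 0 = intercept); columns dropped for rank reasons
    carry zero coefficients and are listed in ``dropped_columns``.
    ``n_params`` counts only parameters actually fitted.
    """

    coefficients: np.ndarray
    baseline_class: int
    log_lik: float
    n_params: int
    converged: bool
    n_obs: int
    dropped_columns: list[int] = field(default_factory=list)

    @property
    def llf(self) -> float:
        return self.log_lik

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        q = self.coefficients.shape[1] - 1
        if features.shape[1] != q:
            raise ValueError(
                f"model has {q} regressors but features have {features.shape[1]} columns"
            )
        W = np.column_stack([np.ones(features.shape[0]), features])
        eta, logz = _mnl_eta_logz(W, self.coefficients)
        P = np.exp(eta - logz[:, None])
        return np.column_stack([P, np.exp(-logz)])

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)

    def summary(self) -> str:
        k = self.coefficients.shape[0] + 1
        lines = [
            "Multinomial logit results",
            f"  classes: {k} (baseline class code {self.baseline_class})",
            f"  observations: {self.n_obs}",
            f"  log-likelihood: {self.log_lik:.4f}",
            f"  parameters: {self.n_params}",
            f"  converged: {self.converged}",
        ]
        if self.dropped_columns:
            lines.append(f"  dropped regressor columns: {self.dropped_columns}")
        for i, row in enumerate(self.coefficients):
            lines.append(
                f"  class {i} vs baseline: "
                + " ".join(f"{c: .4f}" for c in row)
            )
        return "\n".join(lines)


class MultinomialLogit:
    """Multinomial (baseline-category) logit model, statsmodels-style.

    Parameters
    ----------
    endog : ndarray of int class codes in {0..K-1}
    exog : ndarray (n, q) of continuous regressors, or None/empty for an
        intercept-only model.  An intercept is always added.
    n_classes : optional explicit K (inferred from endog otherwise).
    """

    def __init__(self, endog, exog=None, n_classes: int | None = None):
        self.endog = np.asarray(endog, dtype=int)
        n = len(self.endog)
        if exog is None:
            exog = np.empty((n, 0))
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        self.k = int(n_classes or self.endog.max() + 1)
        if n < self.k:
            raise ValueError("need at least one sample per class")

    def fit(self, start_coefficients: np.ndarray | None = None) -> MultinomialLogitResults:
        """Fit by damped Newton; ``start_coefficients`` (full (K-1, q+1)
        layout) warm-start the optimisation, e.g. from a nested fit."""
        n, q = self.exog.shape
        kept, dropped = _independent_columns(self.exog)
        coefficients = np.zeros((self.k - 1, q + 1))
        if not kept:
            counts = np.bincount(self.endog, minlength=self.k).astype(float)
            # closed-form saturated fit: logits of class frequencies
            with np.errstate(divide="ignore"):
                logp = np.log(counts / n)
            base = logp[self.k - 1]
            coefficients[:, 0] = np.clip(
                logp[: self.k - 1] - base, -COEF_BOUND, COEF_BOUND
            )
            ll = intercept_only_loglik(counts)
            return MultinomialLogitResults(
                coefficients, self.k - 1, ll, self.k - 1, True, n, dropped
            )
        # standardize kept columns: conditioning-independent fits whose
        # coefficient bound acts on the standardized scale
        Xk = self.exog[:, kept]
        mean = Xk.mean(axis=0)
        scale = Xk.std(axis=0)
        Xs = (Xk - mean) / scale
        W = np.column_stack([np.ones(n), Xs])
        start = None
        if start_coefficients is not None:
            raw = start_coefficients[:, [j + 1 for j in kept]] * scale
            start = np.column_stack(
                [start_coefficients[:, 0] + raw @ (mean / scale), raw]
            )
        B, ll, converged = _fit_mnlogit_newton(W, self.endog, self.k, start)
        if not converged:
            warnings.warn("multinomial logit did not converge", RuntimeWarning)
        coefficients[:, 0] = B[:, 0] - (B[:, 1:] / scale) @ mean
        for pos, j in enumerate(kept):
            coefficients[:, j + 1] = B[:, pos + 1] / scale[pos]
        n_params = (self.k - 1) * (len(kept) + 1)
        return MultinomialLogitResults(
            coefficients, self.k - 1, ll, n_params, converged, n, dropped
        )


# ---------------------------------------------------------------------------
# ordered logit
# ---------------------------------------------------------------------------


def _ol_unpack(theta: np.ndarray, q: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:q]
    mu = np.empty(k - 1)
    mu[0] = theta[q]
    if k > 2:
        mu[1:] = mu[0] + np.cumsum(np.exp(theta[q + 1 :]))
    return beta, mu


def _ol_negll_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, k: int
) -> tuple[float, np.ndarray]:
    n, q = X.shape
    beta, mu = _ol_unpack(theta, q, k)
    xb = X @ beta if q else np.zeros(n)
    # upper / lower cut-points per sample; +-inf at the extremes
    up = np.where(y < k - 1, mu[np.minimum(y, k - 2)] - xb, np.inf)
    lo = np.where(y > 0, mu[np.maximum(y - 1, 0)] - xb, -np.inf)
    Fu = expit(up)
    Fl = expit(lo)
    P = np.clip(Fu - Fl, 1e-300, None)
    negll = -float(np.log(P).sum())
    fu = np.where(np.isfinite(up), Fu * (1 - Fu), 0.0)
    fl = np.where(np.isfinite(lo), Fl * (1 - Fl), 0.0)
    r = (fu - fl) / P  # d ll_i / d(-xb) wrt shift
    grad = np.zeros_like(theta)
    if q:
        # d ll/d beta = -x * (fu - fl)/P  =>  d negll/d beta = x * (fu-fl)/P
        grad[:q] = (X * r[:, None]).sum(axis=0)
    # gradient wrt thresholds mu_j: +fu/P if j is the upper cut, -fl/P if lower
    gmu = np.zeros(k - 1)
    for j in range(k - 1):
        upper_mask = y == j  # class j uses mu_{j+1-1}=mu_j as upper cut (0-based)
        lower_mask = y == j + 1
        gmu[j] = float((fu[upper_mask] / P[upper_mask]).sum()) - float(
            (fl[lower_mask] / P[lower_mask]).sum()
        )
    gmu = -gmu  # to negative log-likelihood
    # chain through reparametrisation mu_1=a0, mu_j = mu_{j-1}+exp(d_{j-1})
    grad[q] = gmu.sum()
    if k > 2:
        tail = np.cumsum(gmu[::-1])[::-1]  # sum_{j>=m} gmu[j]
        grad[q + 1 :] = np.exp(theta[q + 1 :]) * tail[1:]
    return negll, grad


@dataclass
class OrderedLogitResults:
    """Fitted ordered-logit (proportional-odds) model over q regressors."""

    slope: np.ndarray
    thresholds: np.ndarray
    log_lik: float
    n_params: int
    converged: bool
    n_obs: int
    dropped_columns: list[int] = field(default_factory=list)

    @property
    def llf(self) -> float:
        return self.log_lik

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != len(self.slope):
            raise ValueError(
                f"model has {len(self.slope)} regressors but features have "
                f"{features.shape[1]} columns"
            )
        xb = features @ self.slope
        cuts = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        cum = expit(cuts[None, :] - xb[:, None])
        return np.diff(cum, axis=1)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)

    def summary(self) -> str:
        lines = [
            "Ordered logit results",
            f"  classes: {len(self.thresholds) + 1}",
            f"  observations: {self.n_obs}",
            f"  log-likelihood: {self.log_lik:.4f}",
            f"  parameters: {self.n_params}",
            f"  converged: {self.converged}",
            "  slope: " + " ".join(f"{c: .4f}" for c in self.slope),
            "  thresholds: " + " ".join(f"{m: .4f}" for m in self.thresholds),
        ]
        if self.dropped_columns:
            lines.append(f"  dropped regressor columns: {self.dropped_columns}")
        return "\n".join(lines)


class OrderedLogit:
    """Ordered-logit model for an ordinal outcome, statsmodels-style."""

    def __init__(self, endog, exog=None, n_classes: int | None = None):
        self.endog = np.asarray(endog, dtype=int)
        n = len(self.endog)
        if exog is None:
            exog = np.empty((n, 0))
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != n:
            raise ValueError("endog and exog lengths differ")
        self.k = int(n_classes or self.endog.max() + 1)
        if n < self.k:
            raise ValueError("need at least one sample per class")

    def _empirical_thresholds(self) -> np.ndarray:
        counts = np.bincount(self.endog, minlength=self.k).astype(float)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        cum = np.clip(cum, 1e-9, 1 - 1e-9)
        return np.log(cum / (1 - cum))

    def fit(self) -> OrderedLogitResults:
        n, q = self.exog.shape
        kept, dropped = _independent_columns(self.exog)
        mu0 = self._empirical_thresholds()
        if not kept:
            counts = np.bincount(self.endog, minlength=self.k)
            ll = intercept_only_loglik(counts)
            return OrderedLogitResults(
                np.zeros(q), np.clip(mu0, -COEF_BOUND, COEF_BOUND), ll,
                self.k - 1, True, n, dropped,
            )
        Xk = self.exog[:, kept]
        mean = Xk.mean(axis=0)
        scale = Xk.std(axis=0)
        X = (Xk - mean) / scale
        qk = len(kept)
        theta0 = np.zeros(qk + self.k - 1)
        theta0[qk] = mu0[0]
        if self.k > 2:
            theta0[qk + 1 :] = np.log(np.maximum(np.diff(mu0), 1e-3))
        bounds = (
            [(-COEF_BOUND, COEF_BOUND)] * qk
            + [(-COEF_BOUND, COEF_BOUND)]
            + [(-COEF_BOUND, 5.0)] * (self.k - 2)
        )
        res = optimize.minimize(
            _ol_negll_grad,
            theta0,
            args=(X, self.endog, self.k),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": MAX_ITER, "ftol": LL_RTOL, "gtol": GRAD_TOL},
        )
        beta_k, mu = _ol_unpack(res.x, qk, self.k)
        converged = bool(res.success) or res.status == 1
        if not converged:
            warnings.warn("ordered logit did not converge", RuntimeWarning)
        mu = mu + beta_k @ (mean / scale)  # undo standardization
        slope = np.zeros(q)
        for pos, j in enumerate(kept):
            slope[j] = beta_k[pos] / scale[pos]
        return OrderedLogitResults(
            slope, mu, -float(res.fun), qk + self.k - 1, converged, n, dropped
        )


# ---------------------------------------------------------------------------
# dataset-level wrappers
# ---------------------------------------------------------------------------


def fit_multinomial_logit(
    data: LabeledDataset, regressor_indices
) -> MultinomialLogitResults:
    """Fit a multinomial logit of the outcome on the given feature columns."""
    idx = list(regressor_indices)
    return MultinomialLogit(
        data.outcome, data.features[:, idx], n_classes=data.n_classes
    ).fit()


def fit_ordered_logit(data: LabeledDataset, regressor_indices) -> OrderedLogitResults:
    """Fit an ordered logit; requires an ordinal outcome declaration."""
    if data.outcome_kind != "ordinal":
        raise ValueError("ordered logit requires an ordinal outcome")
    idx = list(regressor_indices)
    return OrderedLogit(
        data.outcome, data.features[:, idx], n_classes=data.n_classes
    ).fit()


def predict_proba(model, features: np.ndarray) -> np.ndarray:
    """Class probabilities from a fitted model; rows sum to one."""
    return model.predict_proba(features)
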