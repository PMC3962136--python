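"""Conditional independence tests behind one uniform contract.

Three tests of the null "X is independent of the class outcome Y given the
feature set Z" are provided:

* :func:`mc_cit` — the multi-class test: a log-likelihood-ratio comparison of
  nested multinomial-logit (nominal outcome) or ordered-logit (ordinal
  outcome) fits, with and without X among the regressors.
* :func:`fisher_z_cit` — the classical Fisher z-transform of the partial
  correlation between X and the integer-encoded outcome given Z; assumes
  linear-Gaussian relationships.
* :func:`g2_cit` — the asymptotic G² test on stratified contingency tables
  after three-bin discretization of the continuous features, guarded by a
  power heuristic that declines to test when the sample is too small for the
  table's degrees of freedom.

Every test is also available as a callable object (``MCCIT``, ``FisherZ``,
``G2``) satisfying ``test(data, x, cond) -> CITResult`` so that selection
algorithms are test-agnostic.  A test that cannot be assessed reports
``p_value = 1`` — independence is not refutable — which downstream selection
treats as "do not include".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .data import LabeledDataset
from .glm import MultinomialLogit, OrderedLogit

__all__ = [
    "CITResult",
    "CITConfig",
    "mc_cit",
    "fisher_z_cit",
    "g2_cit",
    "discretize_three_bins",
    "MCCIT",
    "FisherZ",
    "G2",
    "make_cit",
]


@dataclass
class CITResult:
    """Outcome of one conditional independence test.

    ``assessable=False`` means the test declined to judge (insufficient
    sample, non-convergence); by convention ``p_value`` is then 1.
    """

    p_value: float
    statistic: float
    df: int
    assessable: bool
    test_name: str
    n_used: int


@dataclass
class CITConfig:
    """Options shared across the tests.

    df_convention
        ``"param_diff"`` uses the true difference in parameter counts between
        the nested fits (K-1 for the multinomial model, 1 for the ordered
        model); ``"paper_one_df"`` always refers the statistic to chi-square
        with one degree of freedom.
    g2_hpa
        Minimum average sample count per degree of freedom required before
        the G-squared test is assessed (power heuristic).
    """

    test_kind: str = "mc_cit"
    df_convention: str = "param_diff"
    g2_hpa: int = 5

    def __post_init__(self) -> None:
        if self.df_convention not in ("param_diff", "paper_one_df"):
            raise ValueError("df_convention must be 'param_diff' or 'paper_one_df'")
        if self.g2_hpa < 1:
            raise ValueError("g2_hpa must be >= 1")


# ---------------------------------------------------------------------------
# MC-CIT: nested-model log-likelihood-ratio test
# ---------------------------------------------------------------------------


def _fit_loglik(data: LabeledDataset, regressors: tuple[int, ...], cache=None):
    """Fit the appropriate model on the given regressor columns, returning
    (log_lik, converged, x_dropped) where x_dropped indicates whether the
    LAST regressor column was discarded as rank-deficient.

    With a cache, nominal-outcome fits warm-start from the cached nested fit
    (same regressors minus the last) — the dominant cost saver in selection
    sweeps where each full model extends an already-fitted alternative."""
    key = frozenset(regressors)
    if cache is not None and key in cache:
        return cache[key]
    X = data.features[:, list(regressors)]
    if data.outcome_kind == "ordinal":
        res = OrderedLogit(data.outcome, X, n_classes=data.n_classes).fit()
    else:
        start = None
        if cache is not None and regressors:
            alt_coef = cache.get(("coef", regressors[:-1]))
            if alt_coef is not None:
                start = np.column_stack([alt_coef, np.zeros(alt_coef.shape[0])])
        res = MultinomialLogit(data.outcome, X, n_classes=data.n_classes).fit(
            start_coefficients=start
        )
        if cache is not None:
            cache[("coef", regressors)] = res.coefficients
    out = (res.log_lik, res.converged, len(regressors) - 1 in res.dropped_columns)
    if cache is not None:
        cache[key] = out
    return out


def mc_cit(
    data: LabeledDataset,
    x: int,
    cond,
    config: CITConfig | None = None,
    cache: dict | None = None,
) -> CITResult:
    """Multi-class conditional independence test of X vs the outcome given Z.

    The full model regresses the outcome on ``cond + {x}``, the alternative
    on ``cond`` alone; ``D = 2 (LogL_full - LogL_alt)`` is referred to a
    chi-square distribution whose degrees of freedom follow the configured
    convention.  A regressor ``x`` that is constant or linearly dependent on
    the conditioning set cannot change the achievable likelihood, so the
    statistic is exactly 0 and p = 1.
    """
    config = config or CITConfig()
    cond = tuple(sorted(cond))
    if x in cond:
        raise ValueError("x must not be part of the conditioning set")
    ll_alt, conv_alt, _ = _fit_loglik(data, cond, cache)
    ll_full, conv_full, x_dropped = _fit_loglik(data, cond + (x,), cache)
    if config.df_convention == "paper_one_df":
        df = 1
    else:
        df = 1 if data.outcome_kind == "ordinal" else data.n_classes - 1
    if not (conv_full or conv_alt):
        warnings.warn("mc_cit: neither nested fit converged", RuntimeWarning)
        return CITResult(1.0, 0.0, df, False, "mc_cit", data.n_samples)
    stat = 0.0 if x_dropped else max(0.0, 2.0 * (ll_full - ll_alt))
    p = float(special.chdtrc(df, stat)) if stat > 0 else 1.0
    return CITResult(p, stat, df, True, "mc_cit", data.n_samples)


# ---------------------------------------------------------------------------
# Fisher Z partial-correlation test
# ---------------------------------------------------------------------------


def _partial_corr(u: np.ndarray, v: np.ndarray, Z: np.ndarray) -> float:
    """Partial correlation of u and v given the columns of Z, via residuals
    of the two least-squares regressions on [1, Z]."""
    n = len(u)
    W = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    coef_u, *_ = np.linalg.lstsq(W, u, rcond=None)
    coef_v, *_ = np.linalg.lstsq(W, v, rcond=None)
    ru = u - W @ coef_u
    rv = v - W @ coef_v
    su = np.linalg.norm(ru)
    sv = np.linalg.norm(rv)
    if su <= 1e-300 or sv <= 1e-300:
        return 0.0
    return float(ru @ rv / (su * sv))


def fisher_z_cit(data: LabeledDataset, x: int, cond) -> CITResult:
    """Fisher z-transform test of the partial correlation between feature x
    and the integer-encoded outcome given the conditioning features.

    The outcome enters as its class codes 0..K-1 (declared order for ordinal
    outcomes; lexicographic label order for nominal ones), which imposes a
    possibly arbitrary ordering on nominal classes — the known weakness this
    package's multi-class test addresses.
    """
    cond = tuple(sorted(cond))
    if x in cond:
        raise ValueError("x must not be part of the conditioning set")
    n = data.n_samples
    dof = n - len(cond) - 3
    if dof < 1:
        return CITResult(1.0, 0.0, 1, False, "fisher_z", n)
    r = _partial_corr(
        data.features[:, x].astype(float),
        data.outcome.astype(float),
        data.features[:, list(cond)],
    )
    if abs(r) >= 1.0 - 1e-12:
        return CITResult(0.0, np.inf, 1, True, "fisher_z", n)
    z = 0.5 * np.log((1 + r) / (1 - r))
    stat = np.sqrt(dof) * abs(z)
    p = float(2.0 * special.ndtr(-stat))
    return CITResult(p, float(stat), 1, True, "fisher_z", n)


# ---------------------------------------------------------------------------
# G-squared test on discretized data
# ---------------------------------------------------------------------------


def discretize_three_bins(values) -> np.ndarray:
    """Code values as 0=low, 1=medium, 2=high relative to mean +/- one sample
    standard deviation (n-1 denominator). A constant vector is all medium."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    m = v.mean()
    s = v.std(ddof=1) if v.size > 1 else 0.0
    codes = np.ones(v.shape, dtype=int)
    codes[v < m - s] = 0
    codes[v > m + s] = 2
    return codes


def _g2_from_codes(
    xc: np.ndarray, yc: np.ndarray, zcols: np.ndarray, hpa: int
) -> CITResult:
    n = len(xc)
    lx = len(np.unique(xc))
    ly = len(np.unique(yc))
    if lx < 2 or ly < 2:
        return CITResult(1.0, 0.0, 1, False, "g2", n)
    if zcols.size:
        lz = [len(np.unique(zcols[:, j])) for j in range(zcols.shape[1])]
        n_strata = int(np.prod(lz))
        _, strat = np.unique(zcols, axis=0, return_inverse=True)
    else:
        n_strata = 1
        strat = np.zeros(n, dtype=int)
    df_nominal = (lx - 1) * (ly - 1) * n_strata
    if n < hpa * df_nominal:
        return CITResult(1.0, 0.0, max(df_nominal, 1), False, "g2", n)
    g2 = 0.0
    observed_strata = len(np.unique(strat))
    df = (lx - 1) * (ly - 1) * observed_strata  # empty strata contribute no df
    xi = np.unique(xc, return_inverse=True)[1]
    yi = np.unique(yc, return_inverse=True)[1]
    for s in np.unique(strat):
        mask = strat == s
        table = np.zeros((lx, ly))
        np.add.at(table, (xi[mask], yi[mask]), 1.0)
        tot = table.sum()
        exp_ = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
        pos = table > 0
        g2 += 2.0 * float(np.sum(table[pos] * np.log(table[pos] / exp_[pos])))
    df = max(df, 1)
    p = float(stats.chi2.sf(g2, df))
    return CITResult(p, g2, df, True, "g2", n)


def g2_cit(
    discrete_features: np.ndarray,
    outcome: np.ndarray,
    x: int,
    cond,
    config: CITConfig | None = None,
) -> CITResult:
    """Stratified G-squared test on integer-coded features.

    ``discrete_features`` holds the (already discretized) feature codes; the
    outcome uses its native class codes.  The test is assessed only when
    ``n >= g2_hpa * df`` with ``df = (L_x - 1)(K - 1) prod_z L_z`` over the
    observed level counts; otherwise power is deemed too low and p = 1 is
    returned with ``assessable=False``.
    """
    config = config or CITConfig()
    cond = tuple(sorted(cond))
    if x in cond:
        raise ValueError("x must not be part of the conditioning set")
    xc = np.asarray(discrete_features)[:, x]
    zc = np.asarray(discrete_features)[:, list(cond)]
    return _g2_from_codes(xc, np.asarray(outcome), zc, config.g2_hpa)


# ---------------------------------------------------------------------------
# uniform callable contract
# ---------------------------------------------------------------------------


class _DataBoundCache:
    """Per-dataset memo reset whenever a different dataset object arrives."""

    def __init__(self) -> None:
        self._data: LabeledDataset | None = None
        self.store: dict = {}

    def for_data(self, data: LabeledDataset) -> dict:
        if data is not self._data:
            self._data = data
            self.store = {}
        return self.store


@dataclass
class MCCIT:
    """Multi-class CIT as a reusable callable; caches nested-model
    log-likelihoods per dataset so selection sweeps never refit a model."""

    config: CITConfig = field(default_factory=CITConfig)
    _cache: _DataBoundCache = field(default_factory=_DataBoundCache, repr=False)

    name = "mc_cit"

    def __call__(self, data: LabeledDataset, x: int, cond) -> CITResult:
        return mc_cit(data, x, cond, self.config, cache=self._cache.for_data(data))


@dataclass
class FisherZ:
    """Fisher Z partial-correlation CIT under the uniform contract."""

    name = "fisher_z"

    def __call__(self, data: LabeledDataset, x: int, cond) -> CITResult:
        return fisher_z_cit(data, x, cond)


@dataclass
class G2:
    """G-squared CIT; discretizes each feature into three bins (below /
    within / above mean +/- sd) once per dataset and caches the codes."""

    config: CITConfig = field(default_factory=CITConfig)
    _cache: _DataBoundCache = field(default_factory=_DataBoundCache, repr=False)

    name = "g2"

    def _codes(self, data: LabeledDataset) -> np.ndarray:
        store = self._cache.for_data(data)
        if "codes" not in store:
            f = data.features
            m = f.mean(axis=0)
            s = f.std(axis=0, ddof=1) if f.shape[0] > 1 else np.zeros(f.shape[1])
            codes = np.ones(f.shape, dtype=int)
            codes[f < m - s] = 0
            codes[f > m + s] = 2
            store["codes"] = codes
        return store["codes"]

    def __call__(self, data: LabeledDataset, x: int, cond) -> CITResult:
        return g2_cit(self._codes(data), data.outcome, x, cond, self.config)


def make_cit(kind: str, config: CITConfig | None = None):
    """Factory for the uniform test contract; kind in {mc_cit, fisher_z, g2}."""
    config = config or CITConfig(test_kind=kind)
    if kind in ("mc_cit", "mc-cit"):
        return MCCIT(config)
    if kind in ("fisher_z", "fisher-z"):
        return FisherZ()
    if kind == "g2":
        return G2(config)
    raise ValueError(f"unknown test kind: {kind!r}")
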