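"""Seeded synthetic-data generators with known ground truth.

The generators emulate the shape of multi-class gene-expression studies —
tens to hundreds of samples, up to tens of thousands of continuous features,
3-4 outcome classes — so the whole selection pipeline is testable without
any download.  Features are i.i.d. standard normal (stand-ins for normalized
expression values); outcomes are drawn from the very mechanisms the models
assume: a multinomial-logit law for nominal classes, a latent-variable
logistic-threshold law for ordinal ones.  A Bayesian-network fixture with an
exact d-separation oracle provides error-free "tests" for validating the
selection algorithm's graph-recovery guarantees.

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .cit import CITResult
from .data import LabeledDataset

__all__ = [
    "GroundTruth",
    "gen_categorical_dataset",
    "gen_ordinal_dataset",
    "gen_null_triplet",
    "gen_bn_fixture",
    "toy_bn_fixture",
    "DSeparationOracle",
]

logger = logging.getLogger(__name__)

OUTCOME_NODE = "Y"


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    relevant_features: list[int]
    generating_params: dict = field(default_factory=dict)
    graph: Optional[nx.DiGraph] = None
    pc_set: Optional[list[int]] = None


def _softmax_rows(eta_free: np.ndarray) -> np.ndarray:
    """Class probabilities from (n, K-1) free logits with baseline-last 0."""
    eta = np.column_stack([eta_free, np.zeros(eta_free.shape[0])])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def _sample_classes(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(probs.shape[0])
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def _draw_spanning(draw, n: int, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Call ``draw(rng)`` until every class code appears, bumping a sub-seed;
    small samples may legitimately need a few attempts."""
    for attempt in range(1000):
        rng = np.random.default_rng(seed + attempt)
        X, y = draw(rng)
        if len(np.unique(y)) == k:
            if attempt:
                logger.info("regenerated with sub-seed offset %d to span all classes", attempt)
            return X, y
    raise RuntimeError("could not generate a dataset spanning all classes")


def _alternating_coefs(k: int, n_relevant: int, effect_size: float) -> np.ndarray:
    j = np.arange(n_relevant)
    kk = np.arange(k - 1)[:, None]
    return effect_size * (-1.0) ** (j[None, :] + kk)


def gen_categorical_dataset(
    n: int,
    p: int,
    k: int,
    n_relevant: int,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledDataset, GroundTruth]:
    """Nominal-outcome dataset drawn from a multinomial-logit law.

    Nonzero coefficients of magnitude ``effect_size`` (alternating sign over
    feature and class) sit only on ``n_relevant`` seed-chosen feature
    columns; all other features are pure noise.
    """
    if n_relevant > p or k < 2 or n < 1:
        raise ValueError("invalid sizes: need n_relevant <= p, K >= 2, n >= 1")
    pos_rng = np.random.default_rng(seed)
    relevant = sorted(pos_rng.choice(p, size=n_relevant, replace=False).tolist())
    coefs = _alternating_coefs(k, n_relevant, effect_size)

    def draw(rng):
        X = rng.standard_normal((n, p))
        eta = X[:, relevant] @ coefs.T if n_relevant else np.zeros((n, k - 1))
        y = _sample_classes(_softmax_rows(eta), rng)
        return X, y

    X, y = _draw_spanning(draw, n, k, seed)
    data = LabeledDataset(X, y, outcome_kind="nominal")
    truth = GroundTruth(
        relevant_features=relevant,
        generating_params={"coefficients": coefs, "effect_size": effect_size},
    )
    return data, truth


def gen_ordinal_dataset(
    n: int,
    p: int,
    k: int,
    n_relevant: int,
    effect_size: float = 1.0,
    seed: int = 0,
    thresholds: Optional[np.ndarray] = None,
) -> tuple[LabeledDataset, GroundTruth]:
    """Ordinal-outcome dataset from the latent logistic-threshold mechanism.

    The latent score is ``X_rel . beta + eps`` with standard-logistic noise;
    default thresholds sit at the logistic quantiles that give equal class
    marginals when the effect is zero.
    """
    if n_relevant > p or k < 2 or n < 1:
        raise ValueError("invalid sizes: need n_relevant <= p, K >= 2, n >= 1")
    pos_rng = np.random.default_rng(seed)
    relevant = sorted(pos_rng.choice(p, size=n_relevant, replace=False).tolist())
    beta = effect_size * (-1.0) ** np.arange(n_relevant)
    if thresholds is None:
        q = np.arange(1, k) / k
        thresholds = np.log(q / (1 - q))
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) != k - 1 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing, length K-1")

    def draw(rng):
        X = rng.standard_normal((n, p))
        latent = (X[:, relevant] @ beta if n_relevant else np.zeros(n)) + rng.logistic(size=n)
        y = np.digitize(latent, thresholds)
        return X, y

    X, y = _draw_spanning(draw, n, k, seed)
    data = LabeledDataset(X, y, outcome_kind="ordinal")
    truth = GroundTruth(
        relevant_features=relevant,
        generating_params={
            "slope": beta,
            "thresholds": thresholds,
            "effect_size": effect_size,
        },
    )
    return data, truth


def gen_null_triplet(
    n: int,
    k: int,
    z_dim: int,
    seed: int = 0,
    w: float = 0.7,
) -> tuple[LabeledDataset, GroundTruth]:
    """Calibration harness for the conditional-independence null.

    Column 0 is X, columns 1..z_dim are Z.  X loads on Z (weight ``w``) plus
    unit noise, and the outcome is multinomial-logit on Z only — so
    X is independent of Y *given* Z while marginally associated with it
    (unless ``w = 0``).
    """
    if z_dim < 1:
        raise ValueError("z_dim must be >= 1")
    # class rows alternate sign but load every Z coordinate the same way, so
    # the outcome varies along sum(Z) — the direction X itself loads on —
    # keeping the marginal X-Y association strong
    coefs = (-1.0) ** np.arange(k - 1)[:, None] * np.ones((1, z_dim))

    def draw(rng):
        Z = rng.standard_normal((n, z_dim))
        x = w * Z.sum(axis=1) / np.sqrt(z_dim) + rng.standard_normal(n)
        y = _sample_classes(_softmax_rows(Z @ coefs.T), rng)
        return np.column_stack([x, Z]), y

    X, y = _draw_spanning(draw, n, k, seed)
    names = ["x"] + [f"z{i}" for i in range(z_dim)]
    data = LabeledDataset(X, y, outcome_kind="nominal", feature_names=names)
    truth = GroundTruth(
        relevant_features=list(range(1, z_dim + 1)),
        generating_params={"w": w, "coefficients": coefs, "x_index": 0},
    )
    return data, truth


# ---------------------------------------------------------------------------
# Bayesian-network fixtures and the exact d-separation oracle
# ---------------------------------------------------------------------------


class DSeparationOracle:
    """Error-free CIT given a known DAG: p = 1 if X and Y are d-separated
    given Z, else p = 0.  Satisfies the uniform ``test(data, x, cond)``
    contract (the data argument is ignored); feature index i maps to the
    i-th non-outcome node in sorted order."""

    def __init__(self, graph: nx.DiGraph, outcome=OUTCOME_NODE):
        self.graph = graph
        self.outcome = outcome
        self.feature_nodes = sorted(v for v in graph.nodes if v != outcome)

    name = "dsep_oracle"

    @property
    def pc_set(self) -> list[int]:
        """True parents-and-children of the outcome, as feature indices."""
        nbrs = set(self.graph.predecessors(self.outcome)) | set(
            self.graph.successors(self.outcome)
        )
        return [i for i, v in enumerate(self.feature_nodes) if v in nbrs]

    def d_separated(self, x: int, cond) -> bool:
        z = {self.feature_nodes[j] for j in cond}
        return nx.is_d_separator(
            self.graph, {self.feature_nodes[x]}, {self.outcome}, z
        )

    def __call__(self, data, x: int, cond) -> CITResult:
        sep = self.d_separated(x, cond)
        return CITResult(
            p_value=1.0 if sep else 0.0,
            statistic=0.0 if sep else np.inf,
            df=1,
            assessable=True,
            test_name="dsep_oracle",
            n_used=0,
        )


def _sample_bn_data(
    graph: nx.DiGraph, n: int, k: int, rng: np.random.Generator
) -> LabeledDataset:
    """Ancestral sampling: linear-Gaussian feature nodes, multinomial-logit
    outcome on its feature parents; the outcome feeds children through its
    centered class code."""
    order = list(nx.topological_sort(graph))
    feature_nodes = sorted(v for v in graph.nodes if v != OUTCOME_NODE)
    col = {v: i for i, v in enumerate(feature_nodes)}
    weights = {
        e: rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0]) for e in graph.edges
    }
    X = np.zeros((n, len(feature_nodes)))
    y = None
    for v in order:
        parents = list(graph.predecessors(v))
        if v == OUTCOME_NODE:
            eta = np.zeros((n, k - 1))
            for u in parents:
                coef = _alternating_coefs(k, 1, weights[(u, v)])[:, 0]
                eta += X[:, col[u]][:, None] * coef[None, :]
            y = _sample_classes(_softmax_rows(eta), rng)
        else:
            val = rng.standard_normal(n)
            for u in parents:
                contrib = (
                    (y - (k - 1) / 2.0) if u == OUTCOME_NODE else X[:, col[u]]
                )
                val = val + weights[(u, v)] * contrib
            X[:, col[v]] = val
    if y is None or len(np.unique(y)) < k:  # outcome parentless or class missing
        raise RuntimeError("BN sample did not span all outcome classes")
    return LabeledDataset(X, y, outcome_kind="nominal",
                          feature_names=[str(v) for v in feature_nodes])


def _one_sided_recoverable(oracle: "DSeparationOracle", k_max: int) -> bool:
    """True iff every non-neighbor of the outcome is d-separated from it by
    some subset of the outcome's own parents-and-children with size <= k_max.

    This is the sufficient condition under which a parents-and-children
    search that conditions only on subsets of its own selection (as MMPC
    does, without the symmetry correction) recovers PC(Y) exactly."""
    from itertools import combinations

    pc = oracle.pc_set
    if not pc:
        return False
    for x in range(len(oracle.feature_nodes)):
        if x in pc:
            continue
        ok = any(
            oracle.d_separated(x, z)
            for size in range(0, min(k_max, len(pc)) + 1)
            for z in combinations(pc, size)
        )
        if not ok:
            return False
    return True


def gen_bn_fixture(
    n_nodes: int,
    seed: int = 0,
    n_samples: int = 0,
    k: int = 3,
    expected_degree: float = 2.5,
    ensure_recoverable: Optional[int] = 3,
) -> tuple[nx.DiGraph, DSeparationOracle, Optional[LabeledDataset]]:
    """Random sparse DAG with a designated outcome node and its exact
    d-separation oracle; sparsity mirrors the believed sparsity of gene
    regulatory networks (expected degree <= 3).

    The outcome is the highest-degree node with degree at most 3 (ties to
    the lowest index): its neighborhood should be small, which is exactly
    the sparse-network prior that motivates small ``k_max`` values.

    When ``ensure_recoverable`` is an integer m, graphs are resampled (with
    an incremented sub-seed) until every non-neighbor of the outcome is
    d-separable from it by a subset of PC(Y) of size <= m — the regime in
    which a one-sided parents-and-children search is provably exact, making
    the fixture a valid ground truth for recovery tests.  Pass ``None`` to
    keep arbitrary graphs (useful for studying the search outside its
    guarantee).  Optionally draws ``n_samples`` rows by ancestral sampling.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    p_edge = min(1.0, expected_degree / (n_nodes - 1))
    for attempt in range(1000):
        rng = np.random.default_rng(seed + 100_003 * attempt)
        g = nx.DiGraph()
        g.add_nodes_from(range(n_nodes))
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p_edge:
                    g.add_edge(i, j)
        degrees = dict(g.degree())
        small = [v for v, d in degrees.items() if 1 <= d <= 3]
        pool = small if small else list(degrees)
        outcome = min(pool, key=lambda v: (-degrees[v], v))
        g = nx.relabel_nodes(g, {outcome: OUTCOME_NODE})
        oracle = DSeparationOracle(g)
        if ensure_recoverable is None or _one_sided_recoverable(
            oracle, ensure_recoverable
        ):
            if attempt:
                logger.info("resampled DAG %d time(s) for recoverability", attempt)
            break
    else:
        raise RuntimeError("could not sample a recoverable DAG fixture")
    data = None
    if n_samples:
        for attempt in range(100):
            try:
                data = _sample_bn_data(
                    g, n_samples, k, np.random.default_rng(seed + 1 + attempt)
                )
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError("could not sample BN data spanning all classes")
    return g, oracle, data


def toy_bn_fixture() -> tuple[nx.DiGraph, DSeparationOracle]:
    """Hand-checkable 6-node fixture: Y <- X1, Y <- X2, Y -> X3, X4 -> X3,
    X5 isolated.  PC(Y) = {X1, X2, X3}; X4 is Y's spouse (d-connected to Y
    only when conditioning opens the collider at X3)."""
    g = nx.DiGraph()
    g.add_nodes_from(["X1", "X2", "X3", "X4", "X5", OUTCOME_NODE])
    g.add_edges_from(
        [("X1", OUTCOME_NODE), ("X2", OUTCOME_NODE), (OUTCOME_NODE, "X3"), ("X4", "X3")]
    )
    return g, DSeparationOracle(g)
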