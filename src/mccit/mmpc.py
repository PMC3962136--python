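"""Max-Min Parents-and-Children (MMPC) feature selection.

MMPC retrieves the set of features X such that the conditional independence
Ind(X, Y | Z) is rejected for every conditioning set Z drawn from the
selected features themselves (up to size ``k_max``).  Under faithfulness to a
Bayesian network and error-free tests this set is exactly the parents and
children of the outcome node — the core of its Markov blanket and a
principled minimal biomarker signature.

The algorithm is test-agnostic: any callable satisfying
``test(data, x, cond) -> CITResult`` may be plugged in, including the exact
d-separation oracle produced by :mod:`mccit.synthetic` for ground-truth
checks.

Two phases:

* **forward (max-min)** — repeatedly compute, for every remaining candidate,
  the *maximum* p-value over all conditioning subsets of the current
  selection (its weakest association); admit the candidate whose weakest
  association is *strongest* (minimum of the maxima) provided it is still
  significant at ``alpha``.  Candidates whose max-p ever exceeds ``alpha``
  are permanently discarded.
* **backward** — re-test every selected feature against all subsets of the
  other selected features and drop it if any subset renders it independent.

All decisions are recorded in a trace; results are deterministic functions
of the data and configuration (ties on p-value break toward the larger test
statistic, then the lower feature index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional

from .cit import CITConfig, CITResult, make_cit
from .data import LabeledDataset

__all__ = [
    "MMPCConfig",
    "MMPCResult",
    "AssocCache",
    "TraceRecord",
    "min_assoc",
    "mmpc_forward",
    "mmpc_backward",
    "mmpc",
    "MMPC",
]


@dataclass
class MMPCConfig:
    """MMPC tuning parameters.

    alpha
        Significance threshold for rejecting conditional independence
        (the study grid uses 0.01 and 0.05).
    k_max
        Maximal conditioning-set size (the study grid uses 3 and 4); with
        sparse regulatory networks in mind small values suffice.
    test
        A CIT callable ``test(data, x, cond) -> CITResult`` or the name of a
        built-in test ({"mc_cit", "fisher_z", "g2"}).
    max_cpc
        Optional cap on the number of selected features.
    unassessable
        How a test that declines to judge (``assessable=False``, e.g. the
        G-squared power heuristic) enters the max-min computation.
        ``"skip"`` (default): the forgone test contributes nothing — the
        max runs over assessable results only, and a candidate with *no*
        assessable test anywhere gets p_max = 1 and is excluded.  This
        reproduces the reference behaviour in which low-power conditional
        tests are simply not performed, so weakly-assessable tests prune
        less and the selection grows with the table sizes.
        ``"independent"``: a forgone test counts as p = 1, i.e. independence
        not refuted, which immediately discards the candidate.
    """

    alpha: float = 0.05
    k_max: int = 3
    test: Callable | str = "mc_cit"
    cit_config: Optional[CITConfig] = None
    max_cpc: Optional[int] = None
    unassessable: str = "skip"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.unassessable not in ("skip", "independent"):
            raise ValueError("unassessable must be 'skip' or 'independent'")
        if isinstance(self.test, str):
            self.test = make_cit(self.test, self.cit_config)


@dataclass
class TraceRecord:
    candidate: int
    cond_set: tuple[int, ...]
    p_value: float
    statistic: float
    action: str  # added | rejected | removed


@dataclass
class AssocCache:
    """Memo of CIT results keyed by (feature, frozen conditioning set)."""

    store: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, data, x: int, cond: tuple[int, ...], test) -> CITResult:
        key = (x, frozenset(cond))
        if key in self.store:
            self.hits += 1
            return self.store[key]
        self.misses += 1
        res = test(data, x, cond)
        self.store[key] = res
        return res


@dataclass
class MMPCResult:
    """Selected candidate parents-and-children set plus the decision trace."""

    selected: list[int]
    trace: list[TraceRecord]
    tests_performed: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_names(self) -> list[str]:
        if not self.feature_names:
            return [str(i) for i in self.selected]
        return [self.feature_names[i] for i in self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "selected_names": self.selected_names,
            "tests_performed": self.tests_performed,
            "trace": [
                {
                    "candidate": r.candidate,
                    "cond_set": list(r.cond_set),
                    "p_value": r.p_value,
                    "statistic": r.statistic,
                    "action": r.action,
                }
                for r in self.trace
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "MMPC selection results",
            f"  selected features ({len(self.selected)}): "
            + ", ".join(self.selected_names),
            f"  tests performed: {self.tests_performed}",
            f"  trace records: {len(self.trace)}",
        ]
        return "\n".join(lines)


def _subsets(pool, k_max: int):
    pool = sorted(pool)
    for size in range(0, min(k_max, len(pool)) + 1):
        yield from combinations(pool, size)


def min_assoc(
    data: LabeledDataset,
    x: int,
    cpc,
    config: MMPCConfig,
    cache: AssocCache,
    stop_above: float | None = None,
) -> tuple[float, tuple[int, ...], float]:
    """Weakest association of x with the outcome over conditioning subsets.

    Returns ``(p_max, witness, statistic)`` where ``p_max`` is the maximum
    p-value of ``test(x, Y | Z)`` over all ``Z`` drawn from ``cpc`` with
    ``|Z| <= k_max`` (the empty set always included) and ``witness`` attains
    it.  If ``stop_above`` is given, enumeration stops as soon as the running
    maximum exceeds it (the candidate can no longer be admitted); the partial
    maximum returned is then itself > ``stop_above``.
    """
    if x in cpc:
        raise ValueError("x must not be in the current selection")
    p_max = -1.0
    witness: tuple[int, ...] = ()
    stat_at = 0.0
    any_assessable = False
    for z in _subsets(cpc, config.k_max):
        res = cache.get(data, x, z, config.test)
        if config.unassessable == "skip" and not res.assessable:
            continue
        any_assessable = True
        if res.p_value > p_max:
            p_max, witness, stat_at = res.p_value, z, res.statistic
        if stop_above is not None and p_max > stop_above:
            break
    if not any_assessable:
        return 1.0, (), 0.0
    return p_max, witness, stat_at


def mmpc_forward(
    data: LabeledDataset,
    config: MMPCConfig,
    cache: AssocCache | None = None,
) -> tuple[list[int], list[TraceRecord]]:
    """Forward max-min inclusion phase."""
    cache = cache if cache is not None else AssocCache()
    cpc: list[int] = []
    trace: list[TraceRecord] = []
    remaining = list(range(data.n_features))
    while remaining:
        if config.max_cpc is not None and len(cpc) >= config.max_cpc:
            break
        best = None  # (p_max, -stat, index, witness)
        survivors = []
        for x in remaining:
            p_max, witness, stat = min_assoc(
                data, x, cpc, config, cache, stop_above=config.alpha
            )
            if p_max > config.alpha:
                trace.append(TraceRecord(x, witness, p_max, stat, "rejected"))
                continue
            survivors.append(x)
            key = (p_max, -stat, x)
            if best is None or key < best[0]:
                best = (key, x, witness, p_max, stat)
        remaining = survivors
        if best is None:
            break
        _, x_star, witness, p_max, stat = best
        cpc.append(x_star)
        remaining.remove(x_star)
        trace.append(TraceRecord(x_star, witness, p_max, stat, "added"))
    return cpc, trace


def mmpc_backward(
    data: LabeledDataset,
    cpc: list[int],
    config: MMPCConfig,
    cache: AssocCache | None = None,
) -> tuple[list[int], list[TraceRecord]]:
    """Backward conditioning phase: drop any selected feature rendered
    independent by some subset of the other selected features.  Removals are
    processed in reverse insertion order and immediately shrink the pool the
    remaining features are tested against."""
    cache = cache if cache is not None else AssocCache()
    kept = list(cpc)
    trace: list[TraceRecord] = []
    for x in list(reversed(cpc)):
        pool = [f for f in kept if f != x]
        any_assessable = False
        for z in _subsets(pool, config.k_max):
            res = cache.get(data, x, z, config.test)
            if config.unassessable == "skip" and not res.assessable:
                continue
            any_assessable = True
            if res.p_value > config.alpha:
                kept.remove(x)
                trace.append(
                    TraceRecord(x, z, res.p_value, res.statistic, "removed")
                )
                break
        if not any_assessable:
            kept.remove(x)
            trace.append(TraceRecord(x, (), 1.0, 0.0, "removed"))
    return kept, trace


def mmpc(
    data: LabeledDataset,
    config: MMPCConfig | None = None,
    cache: AssocCache | None = None,
) -> MMPCResult:
    """Run both MMPC phases and return the selection with its full trace."""
    config = config or MMPCConfig()
    cache = cache if cache is not None else AssocCache()
    cpc, trace_f = mmpc_forward(data, config, cache)
    kept, trace_b = mmpc_backward(data, cpc, config, cache)
    return MMPCResult(
        selected=kept,
        trace=trace_f + trace_b,
        tests_performed=cache.misses,
        feature_names=list(data.feature_names),
    )


class MMPC:
    """Object-style front end: ``MMPC(data, alpha=..., k_max=...).fit()``."""

    def __init__(self, data: LabeledDataset, config: MMPCConfig | None = None, **kwargs):
        self.data = data
        self.config = config or MMPCConfig(**kwargs)

    def fit(self) -> MMPCResult:
        return mmpc(self.data, self.config)
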