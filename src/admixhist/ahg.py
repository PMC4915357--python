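"""Admixture History Graph: ordering admixture events from Q-matrix covariance.

When an already two-way admixed population (ancestries A, B) receives a later
pulse of a new ancestry C, every individual's A and B proportions are scaled
down by the same individual-specific factor (1 - c_i).  The *ratio* of the
two older ancestries is therefore unchanged by the new pulse and independent
of C, while each of A and B separately covaries with C.  Among the three
candidate "most recent" labels of a trio, the correct one minimizes
|cov(ratio of the other two, candidate)|; the full arrival order over K >= 3
components is assembled by vote-peeling over all C(K,3) trios.

The ratio is parameterized as q_A / (q_A + q_B), which is bounded, defined
whenever A + B > 0, and carries the same independence property.  Covariances
are population (1/n) covariances; selection only compares their absolute
values, so the normalization does not affect the inferred order.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import QMatrix

__all__ = [
    "TrioStatistics",
    "CandidateStat",
    "AHGResult",
    "ancestry_ratio",
    "trio_statistics",
    "permutation_consistency",
    "infer_graph",
    "reliability_flags",
    "run_consistency",
]

MIN_PROP_DEFAULT = 0.05  # components below this mean proportion are unreliable
_EQUAL_VARIANCE_RATIO = 2.0


class TrioError(ValueError):
    """A trio cannot be evaluated (too few usable individuals, ties, ...)."""


def _pop_cov(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((x - x.mean()) * (y - y.mean())))


def ancestry_ratio(q: QMatrix, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual ratio r_i = q_ia / (q_ia + q_ib).

    Individuals with q_ia + q_ib == 0 are excluded; returns (ratio values,
    indices of the individuals used).  Errors if more than half are excluded.
    """
    if a == b:
        raise TrioError("ratio needs two distinct components")
    qa, qb = q.column(a), q.column(b)
    denom = qa + qb
    used = np.where(denom > 0)[0]
    if used.size < q.n_individuals / 2:
        raise TrioError(
            f"ratio {a}/({a}+{b}) undefined for more than half the individuals"
        )
    return qa[used] / denom[used], used


@dataclass
class CandidateStat:
    recent: str
    abs_cov: float
    correlation: float
    n_used: int
    zero_variance: bool


@dataclass
class TrioStatistics:
    trio: tuple[str, str, str]
    candidates: list[CandidateStat]
    chosen_recent: str
    margin: float  # second-smallest / smallest |cov|; larger = more decisive


def trio_statistics(
    q: QMatrix, trio: tuple[str, str, str], min_individuals: int = 4
) -> TrioStatistics:
    """Evaluate all three candidate-recent orderings of a trio and pick the
    one with the least absolute covariance.

    Candidates with zero variance (in the candidate column or the ratio) are
    flagged and excluded from selection rather than silently chosen.  At
    least ``min_individuals`` usable individuals are required per candidate.
    """
    trio = tuple(trio)
    if len(set(trio)) != 3 or any(c not in q.component_names for c in trio):
        raise TrioError(f"trio {trio} is not three distinct components of the Q matrix")
    cands: list[CandidateStat] = []
    for recent in trio:
        older = sorted(c for c in trio if c != recent)
        r, used = ancestry_ratio(q, older[0], older[1])
        if used.size < min_individuals:
            raise TrioError(
                f"trio {trio}: only {used.size} usable individuals "
                f"(need >= {min_individuals})"
            )
        x = q.column(recent)[used]
        zero_var = bool(np.var(x) == 0 or np.var(r) == 0)
        cov = _pop_cov(r, x)
        if zero_var:
            corr = np.nan
        else:
            corr = float(np.corrcoef(r, x)[0, 1])
        cands.append(CandidateStat(recent, abs(cov), corr, int(used.size), zero_var))
    valid = [c for c in cands if not c.zero_variance]
    if not valid:
        raise TrioError(f"trio {trio}: all candidate orderings have zero variance")
    ranked = sorted(valid, key=lambda c: c.abs_cov)
    chosen = ranked[0]
    if len(ranked) > 1:
        margin = ranked[1].abs_cov / ranked[0].abs_cov if ranked[0].abs_cov > 0 else np.inf
    else:
        margin = np.inf
    return TrioStatistics(trio, cands, chosen.recent, float(margin))


def permutation_consistency(
    q: QMatrix,
    trio: tuple[str, str, str],
    recent: str,
    B: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation support for an ordering: p = (1 + #{permuted |cov| <=
    observed |cov|}) / (B + 1).  Small p means the observed covariance is
    smaller than expected by chance, supporting ``recent`` as the latest
    arrival."""
    if B < 99:
        raise TrioError("need at least 99 permutations")
    if recent not in trio:
        raise TrioError(f"{recent!r} not in trio {trio}")
    older = sorted(c for c in trio if c != recent)
    r, used = ancestry_ratio(q, older[0], older[1])
    x = q.column(recent)[used]
    obs = abs(_pop_cov(r, x))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        if abs(_pop_cov(r, rng.permutation(x))) <= obs:
            count += 1
    return (1 + count) / (B + 1)


def reliability_flags(q: QMatrix) -> list[str]:
    """Warnings about Q-matrix features known to degrade the ordering test:
    components below 5% mean proportion, and near-equal component variances
    (which obscure the covariance signal)."""
    flags = []
    means = q.proportions.mean(axis=0)
    for name, mu in zip(q.component_names, means):
        if mu < MIN_PROP_DEFAULT:
            flags.append(
                f"component {name} has mean proportion {mu:.3f} (below 5%); "
                "ordering accuracy decreases for low-proportion components"
            )
    variances = q.proportions.var(axis=0)
    vmin = variances.min()
    if vmin > 0 and variances.max() / vmin < _EQUAL_VARIANCE_RATIO:
        flags.append(
            "component variances are approximately equal "
            f"(max/min = {variances.max() / vmin:.2f} < {_EQUAL_VARIANCE_RATIO}); "
            "covariance may be obscured"
        )
    return flags


@dataclass
class AHGResult:
    """Inferred arrival order: the (unordered) founding pair followed by
    later components oldest to newest."""

    arrival_order: list  # [tuple(a, b), comp3, comp4, ...]
    trio_table: list[TrioStatistics]
    warnings: list[str] = field(default_factory=list)
    consistency: float | None = None

    def order_key(self) -> tuple:
        pair = tuple(sorted(self.arrival_order[0]))
        return (pair, *self.arrival_order[1:])

    def to_dict(self) -> dict:
        return {
            "arrival_order": [list(self.arrival_order[0])] + list(self.arrival_order[1:]),
            "warnings": list(self.warnings),
            "consistency": self.consistency,
            "trios": [
                {
                    "trio": list(t.trio),
                    "chosen_recent": t.chosen_recent,
                    "margin": None if np.isinf(t.margin) else t.margin,
                    "candidates": [
                        {
                            "recent": c.recent,
                            "abs_cov": c.abs_cov,
                            "correlation": None if np.isnan(c.correlation) else c.correlation,
                            "n_used": c.n_used,
                            "zero_variance": c.zero_variance,
                        }
                        for c in t.candidates
                    ],
                }
                for t in self.trio_table
            ],
        }


def infer_graph(
    q: QMatrix, min_prop: float = MIN_PROP_DEFAULT, seed: int | None = None
) -> AHGResult:
    """Infer the full arrival order of all usable components.

    Components with mean proportion below ``min_prop`` are dropped with a
    warning.  All C(K,3) trios are evaluated; the order is peeled newest
    first: among the remaining components, the one chosen as recent by the
    most trios fully contained in the remaining set is the latest arrival
    (ties broken by larger mean margin).  Recursion ends at the founding
    pair.
    """
    warnings_ = reliability_flags(q)
    means = q.means()
    keep = [c for c in q.component_names if means[c] >= min_prop]
    dropped = [c for c in q.component_names if c not in keep]
    if dropped:
        warnings_.append(
            f"components dropped below min_prop={min_prop}: {', '.join(dropped)}"
        )
    if len(keep) < 3:
        raise TrioError(
            f"need at least 3 components with mean proportion >= {min_prop}; "
            f"have {len(keep)}"
        )
    sub = q.subset_components(keep)
    stats = {
        trio: trio_statistics(sub, trio)
        for trio in itertools.combinations(sorted(keep), 3)
    }
    remaining = sorted(keep)
    peeled: list[str] = []
    while len(remaining) > 2:
        votes: Counter[str] = Counter()
        margins: dict[str, list[float]] = {}
        for trio in itertools.combinations(remaining, 3):
            t = stats[trio]
            votes[t.chosen_recent] += 1
            margins.setdefault(t.chosen_recent, []).append(t.margin)
        top = votes.most_common()
        best, n_best = top[0]
        tied = [c for c, n in top if n == n_best]
        if len(tied) > 1:
            mean_margin = {c: float(np.mean(margins[c])) for c in tied}
            mx = max(mean_margin.values())
            tied = [c for c in tied if mean_margin[c] == mx]
            if len(tied) > 1:
                raise TrioError(
                    f"unresolved tie between candidates {tied} "
                    f"({n_best} votes each, equal mean margins)"
                )
            best = tied[0]
        peeled.append(best)
        remaining = [c for c in remaining if c != best]
    arrival = [tuple(remaining)] + list(reversed(peeled))
    return AHGResult(arrival, list(stats.values()), warnings_)


def _align_components(ref: QMatrix, other: QMatrix, min_corr: float = 0.8) -> QMatrix:
    """Match ``other``'s columns to ``ref``'s by maximum column correlation
    (label switching across independent clustering runs)."""
    if other.n_individuals != ref.n_individuals:
        raise TrioError("runs have different numbers of individuals")
    k = ref.k
    if other.k != k:
        raise TrioError("runs have different numbers of components")
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            a = ref.proportions[:, i]
            b = other.proportions[:, j]
            if a.std() == 0 or b.std() == 0:
                corr[i, j] = -1.0
            else:
                corr[i, j] = np.corrcoef(a, b)[0, 1]
    ri, ci = linear_sum_assignment(-corr)
    matched = corr[ri, ci]
    if np.any(matched < min_corr):
        worst = matched.min()
        raise TrioError(
            f"component sets not alignable: best assignment has correlation "
            f"{worst:.3f} < {min_corr}"
        )
    perm = np.empty(k, dtype=int)
    perm[ri] = ci
    return QMatrix(
        list(other.individual_ids),
        list(ref.component_names),
        other.proportions[:, perm],
        other.populations,
    )


def run_consistency(
    runs: list[QMatrix],
    min_prop: float = MIN_PROP_DEFAULT,
    seed: int | None = None,
) -> AHGResult:
    """Consensus graph over replicate clustering runs.

    Columns of every run are aligned to the first run by correlation, a graph
    is inferred per run, and the modal graph is returned with ``consistency``
    set to the fraction of runs agreeing with it.
    """
    if len(runs) < 2:
        raise TrioError("need at least 2 runs")
    aligned = [runs[0]] + [_align_components(runs[0], r) for r in runs[1:]]
    results = [infer_graph(r, min_prop=min_prop, seed=seed) for r in aligned]
    keys = [r.order_key() for r in results]
    modal_key, n_modal = Counter(keys).most_common(1)[0]
    consensus = results[keys.index(modal_key)]
    consensus.consistency = n_modal / len(runs)
    return consensus
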