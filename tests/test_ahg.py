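import itertools

import numpy as np
import pytest

from admixhist.ahg import (
    TrioError,
    ancestry_ratio,
    infer_graph,
    permutation_consistency,
    reliability_flags,
    run_consistency,
    trio_statistics,
)
from admixhist.io import QMatrix
from admixhist.simulate import AdmixtureHistorySpec, Pulse, simulate_history


def _q(props, names=None):
    props = np.asarray(props, dtype=float)
    names = names or [chr(ord("A") + i) for i in range(props.shape[1])]
    return QMatrix([f"i{j}" for j in range(props.shape[0])], names, props)


class TestAncestryRatio:
    def test_direct_arithmetic(self):
        q = _q([[0.14, 0.56, 0.30]] * 5)
        r, used = ancestry_ratio(q, "A", "B")
        assert r == pytest.approx([0.2] * 5)

    def test_zero_numerator_boundary(self):
        q = _q([[0.0, 0.7, 0.3]] * 5)
        r, _ = ancestry_ratio(q, "A", "B")
        assert (r == 0).all()

    def test_degenerate_rows_excluded(self):
        rows = [[0.2, 0.5, 0.3]] * 5 + [[0.0, 0.0, 1.0]]
        r, used = ancestry_ratio(_q(rows), "A", "B")
        assert len(r) == 5 and 5 not in used

    def test_mostly_degenerate_errors(self):
        rows = [[0.0, 0.0, 1.0]] * 6 + [[0.2, 0.5, 0.3]] * 4
        with pytest.raises(TrioError, match="half"):
            ancestry_ratio(_q(rows), "A", "B")


class TestTrioStatistics:
    def test_layered_construction_exact_zero(self, layered_q):
        """For Q built as a second pulse on a two-way mixture with the pulse
        vector orthogonal to the founding ratio, cov(A/(A+B), C) vanishes
        and C is chosen as most recent."""
        t = trio_statistics(layered_q, ("A", "B", "C"))
        by = {c.recent: c for c in t.candidates}
        assert by["C"].abs_cov <= 1e-15
        assert by["A"].abs_cov == pytest.approx(0.0106445, abs=1e-6)
        assert t.chosen_recent == "C"
        assert t.margin > 1e10

    def test_zero_variance_candidate_flagged_not_chosen(self):
        # C is constant: cov(r, C) = 0 trivially, but C must be flagged and
        # not silently chosen
        rows = np.array([[0.16, 0.64, 0.2], [0.32, 0.48, 0.2], [0.48, 0.32, 0.2],
                         [0.64, 0.16, 0.2], [0.40, 0.40, 0.2]])
        t = trio_statistics(_q(rows), ("A", "B", "C"))
        by = {c.recent: c for c in t.candidates}
        assert by["C"].zero_variance
        assert t.chosen_recent != "C"

    def test_too_few_individuals(self):
        with pytest.raises(TrioError, match="usable individuals"):
            trio_statistics(_q([[0.2, 0.5, 0.3]] * 3), ("A", "B", "C"))

    def test_individual_order_invariance(self, layered_q):
        perm = np.random.default_rng(0).permutation(4)
        shuffled = QMatrix(
            [layered_q.individual_ids[i] for i in perm],
            layered_q.component_names,
            layered_q.proportions[perm],
        )
        t1 = trio_statistics(layered_q, ("A", "B", "C"))
        t2 = trio_statistics(shuffled, ("A", "B", "C"))
        assert t1.chosen_recent == t2.chosen_recent
        for c1, c2 in zip(t1.candidates, t2.candidates):
            assert c1.abs_cov == pytest.approx(c2.abs_cov, abs=1e-15)


def _layered(n=16, seed=6):
    """Layered K=3 construction with the pulse vector exactly orthogonal to
    the founding ratio (deviations Gram-Schmidt-orthogonalized)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.2, 0.8, n)
    c = rng.uniform(0.15, 0.45, n)
    da = a - a.mean()
    dc = c - c.mean()
    dc = dc - (dc @ da) / (da @ da) * da
    c = 0.3 + dc
    q = np.column_stack([(1 - c) * a, (1 - c) * (1 - a), c])
    return _q(q)


class TestPermutationConsistency:
    def test_rank_one_bound_for_exact_zero(self):
        # observed |cov| is (numerically) zero; essentially no permutation
        # matches it, so p attains its lower bound 1/(B+1)
        q = _layered()
        p = permutation_consistency(q, ("A", "B", "C"), "C", B=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_rank_max_bound(self):
        # ratio and candidate sorted alike: no permutation exceeds the
        # observed |cov| (rearrangement bound), so p = 1
        a = np.linspace(0.2, 0.8, 10)
        c = np.linspace(0.1, 0.5, 10)
        q = _q(np.column_stack([(1 - c) * a, (1 - c) * (1 - a), c]))
        p = permutation_consistency(q, ("A", "B", "C"), "C", B=199, seed=0)
        assert p == 1.0

    def test_deterministic_given_seed(self, layered_q):
        p1 = permutation_consistency(layered_q, ("A", "B", "C"), "C", B=999, seed=42)
        p2 = permutation_consistency(layered_q, ("A", "B", "C"), "C", B=999, seed=42)
        assert p1 == p2

    def test_minimum_permutations(self, layered_q):
        with pytest.raises(TrioError):
            permutation_consistency(layered_q, ("A", "B", "C"), "C", B=10)


class TestReliabilityFlags:
    def test_low_proportion_flag(self):
        rng = np.random.default_rng(0)
        base = np.column_stack([
            rng.uniform(0.4, 0.6, 20), rng.uniform(0.35, 0.55, 20),
            rng.uniform(0.01, 0.05, 20),
        ])
        q = _q(base / base.sum(axis=1, keepdims=True))
        flags = reliability_flags(q)
        assert any("C" in f and "below 5%" in f for f in flags)

    def test_equal_variance_flag(self):
        rng = np.random.default_rng(1)
        cols = [rng.normal(0.33, 0.03, 40) for _ in range(3)]
        base = np.abs(np.column_stack(cols))
        q = _q(base / base.sum(axis=1, keepdims=True))
        v = q.proportions.var(axis=0)
        assert v.max() / v.min() < 2
        assert any("obscured" in f for f in reliability_flags(q))

    def test_distinct_variances_no_flag(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 0.20, 60)
        b = rng.normal(0.3, 0.02, 60)
        base = np.abs(np.column_stack([a, b, 1 - a - b]))
        q = _q(base / base.sum(axis=1, keepdims=True))
        assert not any("obscured" in f for f in reliability_flags(q))


def _noiseless_k4():
    """D layered on an (A,B)+C mixture with mutually orthogonal construction
    vectors (Hadamard contrasts), so every trio's covariance is exactly zero
    for the true candidate and the vote count alone fixes the order."""
    from scipy.linalg import hadamard

    H = hadamard(8)
    h1, h2, h3 = H[1], H[2], H[4]  # pairwise and triple products average to 0
    a = 0.5 + 0.2 * h1
    c = 0.25 + 0.1 * h2
    d = 0.2 + 0.08 * h3
    A = (1 - d) * (1 - c) * a
    B = (1 - d) * (1 - c) * (1 - a)
    C = (1 - d) * c
    return _q(np.column_stack([A, B, C, d]))


class TestInferGraph:
    def test_k4_vote_arithmetic(self):
        q = _noiseless_k4()
        res = infer_graph(q, min_prop=0.0)
        assert res.arrival_order[0] == ("A", "B")
        assert res.arrival_order[1:] == ["C", "D"]
        votes_d = sum(
            1 for t in res.trio_table if "D" in t.trio and t.chosen_recent == "D"
        )
        assert votes_d == 3

    def test_low_proportion_component_dropped(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.3, 0.7, 30)
        c = rng.uniform(0.2, 0.4, 30)
        e = rng.uniform(0.01, 0.03, 30)  # mean ~2%
        A = (1 - e) * (1 - c) * a
        B = (1 - e) * (1 - c) * (1 - a)
        C = (1 - e) * c
        q = _q(np.column_stack([A, B, C, e]), names=["A", "B", "C", "E"])
        res = infer_graph(q, min_prop=0.05)
        assert all("E" not in str(x) for x in res.arrival_order)
        assert any("E" in w and "min_prop" in w for w in res.warnings)

    def test_fewer_than_three_components_errors(self):
        q = _q([[0.5, 0.5]] * 10)
        with pytest.raises(TrioError, match="3 components"):
            infer_graph(q)

    def test_simulated_k3_recovery(self, genome):
        """At an adequate sample size (n=50 individuals) the covariance
        ordering recovers the simulated truth in >= 95% of replicates."""
        gmap, grid = genome
        spec = AdmixtureHistorySpec(
            60, ("A", "B"), 0.4, [Pulse(20, "C", 0.3)],
            population_size=500, sample_size=100,
        )
        ok = 0
        reps = 40
        for s in range(reps):
            sim = simulate_history(
                spec, gmap, grid, seed=7000 + s, rasterize=False, build_tracts=False
            )
            ok += infer_graph(sim.q).order_key() == (("A", "B"), "C")
        assert ok / reps >= 0.9


class TestRunConsistency:
    def test_identical_runs_agree_fully(self):
        q = _noiseless_k4()
        res = run_consistency([q] * 10, min_prop=0.0)
        assert res.consistency == 1.0
        assert res.arrival_order[0] == ("A", "B")

    def test_permuted_columns_aligned(self):
        q = _noiseless_k4()
        perm = [2, 0, 3, 1]
        q2 = QMatrix(
            list(q.individual_ids),
            [q.component_names[i] for i in perm],
            q.proportions[:, perm],
        )
        res = run_consistency([q, q2], min_prop=0.0)
        assert res.consistency == 1.0

    def test_unalignable_runs_rejected(self):
        q = _noiseless_k4()
        rng = np.random.default_rng(5)
        other = rng.dirichlet(np.ones(4), size=q.n_individuals)
        q2 = QMatrix(list(q.individual_ids), list(q.component_names), other)
        with pytest.raises(TrioError, match="alignable"):
            run_consistency([q, q2], min_prop=0.0)
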