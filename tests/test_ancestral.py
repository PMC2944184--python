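import itertools
import math

import numpy as np
import pytest

from divtempo import parse_newick
from divtempo.ancestral import (
    find_focal_root,
    fit_mk1,
    internal_node_ids,
    marginal_states,
    mk1_loglik,
    read_tip_states,
    reconstruct,
    write_tip_states,
)
from divtempo.treesim import simulate_mk1_states, simulate_yule


def enumeration_oracle(tree, states, q):
    """Exhaustive sum over all internal-state assignments: joint likelihood
    and per-node marginals, for trees small enough to enumerate."""
    nodes = list(tree.tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    marg = {i: [0.0, 0.0] for i in range(len(internals))}
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assign)}
        L = 0.5  # equal root prior
        for nd in nodes:
            if nd.parent_node is None:
                continue
            ps = amap[id(nd.parent_node)]
            s = states[nd.taxon.label] if nd.is_leaf() else amap[id(nd)]
            stay = 0.5 * (1 + math.exp(-2 * q * nd.edge.length))
            L *= stay if s == ps else 1 - stay
        total += L
        for i, s in enumerate(assign):
            marg[i][s] += L
    return math.log(total), {i: m[1] / sum(m) for i, m in marg.items()}


class TestLoglik:
    def test_two_tip_concordant_q0(self):
        t = parse_newick("(A:1,B:1);")
        assert mk1_loglik(t, {"A": 1, "B": 1}, 0.0) == pytest.approx(-math.log(2))

    def test_two_tip_discordant_q0_impossible(self):
        t = parse_newick("(A:1,B:1);")
        assert mk1_loglik(t, {"A": 1, "B": 0}, 0.0) == -math.inf

    def test_two_tip_stationary_limit(self):
        t = parse_newick("(A:1,B:1);")
        assert mk1_loglik(t, {"A": 1, "B": 1}, 100.0) == pytest.approx(
            -math.log(4), abs=1e-9
        )

    def test_missing_state_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            mk1_loglik(t, {"A": 1}, 0.1)
        with pytest.raises(ValueError):
            mk1_loglik(t, {"A": 1, "B": 0, "Z": 1}, 0.1)

    def test_pruning_equals_enumeration(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            t = simulate_yule(n, 1.0, rng)
            st = simulate_mk1_states(t, 0.5, int(rng.integers(2)), rng)
            q = float(rng.uniform(0.01, 3.0))
            expected, _ = enumeration_oracle(t, st, q)
            assert mk1_loglik(t, st, q) == pytest.approx(expected, abs=1e-9)


class TestMarginals:
    def test_q0_all_tips_one(self):
        t = simulate_yule(10, 1.0, 2)
        rec = reconstruct(t, {lab: 1 for lab in t.tip_labels})
        assert rec.q_boundary
        assert all(p == 1.0 for p in rec.node_probs.values())

    def test_symmetric_two_tip_root_is_half(self):
        t = parse_newick("(A:1,B:1);")
        for q in (0.05, 0.5, 5.0):
            rec = marginal_states(t, {"A": 1, "B": 0}, q)
            (p,) = rec.node_probs.values()
            assert p == pytest.approx(0.5, abs=1e-12)

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            t = simulate_yule(n, 1.0, rng)
            st = simulate_mk1_states(t, 0.5, 1, rng)
            q = float(rng.uniform(0.05, 2.0))
            _, expected = enumeration_oracle(t, st, q)
            rec = marginal_states(t, st, q)
            for nid, p in rec.node_probs.items():
                assert p == pytest.approx(expected[nid], abs=1e-9)

    def test_label_permutation_invariance(self):
        """Swapping two tips that carry the same state leaves every
        marginal unchanged."""
        t = simulate_yule(8, 1.0, 3)
        st = simulate_mk1_states(t, 0.4, 1, 5)
        ones = [lab for lab, s in st.items() if s == 1]
        if len(ones) >= 2:
            st2 = dict(st)
            st2[ones[0]], st2[ones[1]] = st2[ones[1]], st2[ones[0]]
            r1 = marginal_states(t, st, 0.3)
            r2 = marginal_states(t, st2, 0.3)
            for nid in r1.node_probs:
                assert r1.node_probs[nid] == pytest.approx(r2.node_probs[nid])

    def test_probabilities_in_unit_interval(self):
        t = simulate_yule(30, 1.0, 12)
        st = simulate_mk1_states(t, 0.2, 1, 0)
        if len(set(st.values())) < 2:  # ensure informative data
            st[t.tip_labels[0]] = 0
        rec = reconstruct(t, st)
        assert all(0.0 <= p <= 1.0 for p in rec.node_probs.values())
        assert rec.q_hat >= 0


class TestFitMk1:
    def test_all_identical_boundary(self):
        t = simulate_yule(12, 1.0, 6)
        fit = fit_mk1(t, {lab: 1 for lab in t.tip_labels})
        assert fit.q_boundary
        assert fit.q_hat == 0.0
        assert fit.lnL == pytest.approx(-math.log(2))

    def test_grid_search_oracle(self):
        t = simulate_yule(10, 1.0, 77)
        st = simulate_mk1_states(t, 0.8, 1, 4)
        if len(set(st.values())) < 2:
            st[t.tip_labels[0]] = 0
        fit = fit_mk1(t, st)
        qs = np.geomspace(1e-4, 10, 10_000)
        lls = [mk1_loglik(t, st, q) for q in qs]
        q_grid = qs[int(np.argmax(lls))]
        assert fit.q_hat == pytest.approx(q_grid, rel=1e-3, abs=1e-4)
        assert fit.lnL >= max(lls) - 1e-9

    def test_optimum_is_local_max(self):
        t = simulate_yule(15, 1.0, 21)
        st = simulate_mk1_states(t, 0.5, 1, 9)
        if len(set(st.values())) < 2:
            st[t.tip_labels[0]] = 0
        fit = fit_mk1(t, st)
        eps = 1e-4
        here = mk1_loglik(t, st, fit.q_hat)
        assert here >= mk1_loglik(t, st, fit.q_hat * (1 + eps)) - 1e-8
        assert here >= mk1_loglik(t, st, fit.q_hat * (1 - eps)) - 1e-8


class TestFocalRoot:
    def test_uniform_focal_state_returns_root(self):
        t = simulate_yule(10, 1.0, 1)
        rec = reconstruct(t, {lab: 1 for lab in t.tip_labels})
        res = find_focal_root(t, rec, focal_state=1, threshold=0.95)
        assert res.found
        assert res.probability == 1.0
        assert res.age == pytest.approx(t.root_age)
        assert set(res.tip_labels) == set(t.tip_labels)

    def test_subclade_ancestor_found(self):
        # two clades, left all focal, right all other; short stems keep the
        # clade ancestors confidently reconstructed
        t = parse_newick(
            "(((A:9,B:9):1,(C:9,D:9):1):1,((E:9,F:9):1,(G:9,H:9):1):1);"
        )
        st = {k: 1 for k in "ABCD"} | {k: 0 for k in "EFGH"}
        rec = reconstruct(t, st)
        res = find_focal_root(t, rec, focal_state=1, threshold=0.9)
        assert res.found
        assert set(res.tip_labels) == {"A", "B", "C", "D"}

    def test_explicit_null_with_best_candidate(self):
        t = parse_newick("(A:1,B:1);")
        rec = marginal_states(t, {"A": 1, "B": 0}, 0.5)
        res = find_focal_root(t, rec, focal_state=1, threshold=0.95)
        assert not res.found
        assert res.node_id is None
        assert res.probability == pytest.approx(0.5)

    def test_threshold_validated(self):
        t = simulate_yule(5, 1.0, 0)
        rec = reconstruct(t, {lab: 1 for lab in t.tip_labels})
        with pytest.raises(ValueError):
            find_focal_root(t, rec, threshold=1.5)


class TestStateIO:
    def test_round_trip(self, tmp_path):
        st = {"sp_a": 1, "sp_b": 0, "sp c": 1}
        text = write_tip_states(st)
        assert read_tip_states(text) == st
        p = tmp_path / "states.tsv"
        p.write_text(text)
        assert read_tip_states(p) == st

    def test_bad_header(self):
        with pytest.raises(ValueError):
            read_tip_states("species\tarea\nA\t1\n")

    def test_bad_state(self):
        with pytest.raises(ValueError):
            read_tip_states("tip\tstate\nA\t2\n")

    def test_node_ids_are_postorder(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        ids = internal_node_ids(t)
        assert set(ids[0]) == {"A", "B"}
        assert set(ids[1]) == {"A", "B", "C"}
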