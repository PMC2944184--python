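"""Synthetic chronograms: pure-birth and birth-death simulation, random
incomplete sampling, and binary-character evolution.

This is the engine behind every null distribution and recovery experiment
in the package.  Trees are grown forward in time conditioned on a fixed tip
count n:

* while i lineages exist the next speciation waits Exp(i*lambda) and a
  uniformly chosen lineage splits (which yields the Yule topology
  distribution);
* after the n-th lineage appears, the duration separating the last
  branching from the present is drawn as the Exp(n*lambda) waiting time to
  the unobserved next event.  This final-interval convention is what makes
  the gamma statistic of complete trees exactly mean-0/variance-1 under the
  null, so the analytic CR test and the simulated null agree.

Because the gamma statistic depends on the tree only through its internode
intervals, batch null generation uses a flat array representation and never
builds node objects; :func:`simulate_yule` wraps the same draws into a full
:class:`~divtempo.chronogram.Chronogram` when an actual tree is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .chronogram import BranchingTimes, Chronogram, ChronogramError

__all__ = [
    "SimulationConfig",
    "simulate_yule",
    "simulate_birth_death",
    "sample_incomplete",
    "simulate_mk1_states",
    "yule_intervals",
    "pruned_yule_branching_times",
    "yule_gamma_sample",
    "two_rate_branching_times",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for a batch of simulated chronograms.

    ``death_rate`` 0 means pure birth; for birth-death conditioning on n
    surviving tips the relative extinction mu/lambda must stay below 1.
    """

    n_tips: int
    birth_rate: float = 1.0
    death_rate: float = 0.0
    seed: int | None = None
    reps: int = 1

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not self.birth_rate > 0:
            raise ValueError("birth_rate must be > 0")
        if self.death_rate < 0 or self.death_rate >= self.birth_rate:
            if self.death_rate != 0:
                raise ValueError("need 0 <= death_rate < birth_rate")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Accept an int seed, an existing Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# pure birth
# ----------------------------------------------------------------------


def yule_intervals(n_tips: int, birth_rate: float, rng, size: int | None = None) -> np.ndarray:
    """Internode durations g_2..g_n of fixed-n pure-birth trees.

    g_k ~ Exp(k*lambda) independently, including the final interval g_n
    (see module docstring).  With ``size`` an array of shape
    (size, n_tips-1) is returned.
    """
    rng = as_rng(rng)
    k = np.arange(2, n_tips + 1, dtype=float)
    shape = (n_tips - 1,) if size is None else (size, n_tips - 1)
    return rng.exponential(1.0 / (k * birth_rate), size=shape)


def _yule_topology(n_tips: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Children arrays of a Yule topology in creation order.

    Internal nodes are numbered 0..n-2 in order of increasing branching
    depth from the root (node j has age = sum of g_{j+2}..g_n).  Child codes
    < n-1 refer to internal nodes; code n-1+t refers to tip t.
    """
    n = n_tips
    ch = np.empty((n - 1, 2), dtype=np.int64)
    # active lineage slots encoded as (parent_node, side)
    slots = [(0, 0), (0, 1)]
    for j in range(1, n - 1):
        idx = int(rng.integers(len(slots)))
        p, s = slots[idx]
        ch[p, s] = j
        slots[idx] = (j, 0)
        slots.append((j, 1))
    for t, (p, s) in enumerate(slots):
        ch[p, s] = (n - 1) + t
    return ch[:, 0], ch[:, 1]


def _ages_from_intervals(g: np.ndarray) -> np.ndarray:
    """Node ages (descending, creation order) from g_2..g_n."""
    return np.cumsum(g[::-1])[::-1]


def _chronogram_from_arrays(
    ch0: np.ndarray, ch1: np.ndarray, ages: np.ndarray, labels: list[str]
) -> Chronogram:
    n_int = len(ages)
    n_tips = n_int + 1
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node() for _ in range(n_int)]

    def attach(parent_idx: int, code: int) -> None:
        parent = nodes[parent_idx]
        if code < n_int:
            child = nodes[code]
            blen = ages[parent_idx] - ages[code]
        else:
            child = dendropy.Node(taxon=taxa[code - n_int])
            blen = ages[parent_idx]
        parent.add_child(child)
        child.edge.length = float(blen)

    # children have larger creation indices than parents, so a single
    # forward pass attaches every edge
    for j in range(n_int):
        attach(j, int(ch0[j]))
        attach(j, int(ch1[j]))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return Chronogram(tree)


def _tip_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def simulate_yule(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator | None = None
) -> Chronogram:
    """One pure-birth chronogram with exactly ``n_tips`` tips.

    Deterministic given the seed/generator.  Tip labels are t01, t02, ...
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = as_rng(seed)
    g = yule_intervals(n_tips, birth_rate, rng)
    ch0, ch1 = _yule_topology(n_tips, rng)
    return _chronogram_from_arrays(ch0, ch1, _ages_from_intervals(g), _tip_labels(n_tips))


# ----------------------------------------------------------------------
# incomplete sampling
# ----------------------------------------------------------------------


def sample_incomplete(
    tree: Chronogram, n_keep: int, seed: int | np.random.Generator | None = None
) -> Chronogram:
    """Retain a uniformly random subset of ``n_keep`` tips."""
    labels = tree.tip_labels
    if not 2 <= n_keep <= len(labels):
        raise ValueError("need 2 <= n_keep <= n_tips")
    if n_keep == len(labels):
        return tree
    rng = as_rng(seed)
    chosen = rng.choice(len(labels), size=n_keep, replace=False)
    return tree.prune({labels[i] for i in chosen})


def _pruned_times_from_arrays(
    ch0: np.ndarray, ch1: np.ndarray, ages: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Branching times of the induced subtree on the kept tips.

    An internal node survives pruning as a bifurcation exactly when both of
    its child subtrees retain at least one kept tip; its age is unchanged.
    Children always carry larger creation indices than their parents, so a
    reverse pass computes subtree kept-tip counts in one sweep.
    """
    n_int = len(ages)
    counts = np.zeros(n_int, dtype=np.int64)
    out = []
    for j in range(n_int - 1, -1, -1):
        c0, c1 = int(ch0[j]), int(ch1[j])
        k0 = counts[c0] if c0 < n_int else int(keep[c0 - n_int])
        k1 = counts[c1] if c1 < n_int else int(keep[c1 - n_int])
        counts[j] = k0 + k1
        if k0 > 0 and k1 > 0:
            out.append(ages[j])
    out.reverse()  # ages are descending in creation order
    return np.array(out)


def pruned_yule_branching_times(
    n_total: int,
    n_keep: int,
    rng,
    birth_rate: float = 1.0,
) -> np.ndarray:
    """Branching times of one Yule(n_total) tree randomly pruned to n_keep tips.

    Array fast path equivalent to ``simulate_yule`` -> ``sample_incomplete``
    -> ``branching_times`` (same distribution; no tree objects built).
    """
    if not 2 <= n_keep <= n_total:
        raise ValueError("need 2 <= n_keep <= n_total")
    rng = as_rng(rng)
    g = yule_intervals(n_total, birth_rate, rng)
    if n_keep == n_total:
        return _ages_from_intervals(g)
    ch0, ch1 = _yule_topology(n_total, rng)
    keep = np.zeros(n_total, dtype=bool)
    keep[rng.choice(n_total, size=n_keep, replace=False)] = True
    return _pruned_times_from_arrays(ch0, ch1, _ages_from_intervals(g), keep)


def yule_gamma_sample(
    n_total: int,
    n_keep: int,
    reps: int,
    rng,
    birth_rate: float = 1.0,
) -> np.ndarray:
    """``reps`` draws of gamma from simulated-then-pruned pure-birth trees.

    Complete sampling (n_keep == n_total) is vectorized over replicates;
    otherwise each replicate simulates a topology and prunes it.
    """
    from .gamma import gamma_from_intervals

    rng = as_rng(rng)
    if n_keep == n_total:
        g = yule_intervals(n_total, birth_rate, rng, size=reps)
        return gamma_from_intervals(g)
    vals = np.empty(reps)
    for r in range(reps):
        t = pruned_yule_branching_times(n_total, n_keep, rng, birth_rate)
        bt = BranchingTimes(n=n_keep, times=t)
        vals[r] = gamma_from_intervals(bt.intervals)
    return vals


# ----------------------------------------------------------------------
# birth-death
# ----------------------------------------------------------------------


def simulate_birth_death(
    n_tips: int,
    birth_rate: float,
    death_rate: float,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 100_000,
) -> Chronogram:
    """Reconstructed birth-death tree conditioned on ``n_tips`` survivors.

    The process starts from two lineages, runs forward with per-lineage
    rates (lambda, mu), and is retried from scratch whenever it goes extinct
    before the standing count first reaches ``n_tips``.  At that first
    passage the present is placed one Exp(n*(lambda+mu)) waiting time later
    (the time to the unobserved next event), mirroring the pure-birth
    final-interval convention — at mu = 0 this reduces exactly to
    :func:`simulate_yule`.  Extinct lineages are removed and the survivors'
    induced (reconstructed, ultrametric) tree is returned.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > 0 or death_rate < 0 or death_rate >= birth_rate:
        raise ValueError("need birth_rate > 0 and 0 <= death_rate < birth_rate")
    if death_rate == 0:
        return simulate_yule(n_tips, birth_rate, seed)
    rng = as_rng(seed)
    lam, mu = birth_rate, death_rate
    total = lam + mu
    p_birth = lam / total

    for _ in range(max_tries):
        # node records: children (None for pending/leaf), forward split time
        children: list[list[int] | None] = [None]
        split_time: list[float] = [np.nan]
        alive = [0]
        t = 0.0
        # root = node 0: force the initial split so the origin has 2 lineages
        first = True
        failed = False
        while True:
            i = len(alive)
            if i == 0:
                failed = True
                break
            if i >= n_tips:
                t += rng.exponential(1.0 / (n_tips * total))
                break
            if first:
                event_birth = True
                first = False
            else:
                t += rng.exponential(1.0 / (i * total))
                event_birth = rng.random() < p_birth
            idx = int(rng.integers(i))
            node = alive[idx]
            if event_birth:
                a = len(children)
                children.extend([None, None])
                split_time.extend([np.nan, np.nan])
                children[node] = [a, a + 1]
                split_time[node] = t
                alive[idx] = a
                alive.append(a + 1)
            else:
                split_time[node] = t  # death time; node stays a leaf
                alive[idx] = alive[-1]
                alive.pop()
        if failed:
            continue
        present = t
        alive_set = set(alive)
        tree = _reconstructed_survivor_tree(children, split_time, alive_set, present)
        if tree is not None:
            return tree
    raise RuntimeError("birth-death simulation failed to reach the target tip count")


def _reconstructed_survivor_tree(
    children: list[list[int] | None],
    split_time: list[float],
    alive: set[int],
    present: float,
) -> Chronogram | None:
    """Induced ultrametric tree on surviving leaves (iterative, no recursion)."""
    n_nodes = len(children)
    # reduced[v]: None (extinct), ('leaf', v) or a dendropy Node
    reduced: list[object] = [None] * n_nodes
    taxa_labels: dict[int, str] = {}
    order = range(n_nodes - 1, -1, -1)  # children indices always > parent
    age: dict[int, float] = {}
    for v in order:
        kids = children[v]
        if kids is None:
            if v in alive:
                reduced[v] = ("leaf", v)
                age[v] = 0.0
            continue
        sub = [reduced[c] for c in kids if reduced[c] is not None]
        if not sub:
            continue
        if len(sub) == 1:
            reduced[v] = sub[0]
            continue
        node_age = present - split_time[v]
        nd = dendropy.Node()
        for child in sub:
            if isinstance(child, tuple):
                _, leaf_id = child
                cn = dendropy.Node()
                cn._leaf_id = leaf_id
                blen = node_age
            else:
                cn = child
                blen = node_age - cn._age
            nd.add_child(cn)
            cn.edge.length = float(blen)
        nd._age = node_age
        reduced[v] = nd
    root = reduced[0]
    if root is None or isinstance(root, tuple):
        return None  # fewer than 2 survivors (should not happen)
    # label surviving leaves deterministically
    leaves = [nd for nd in root.leaf_iter()]
    labels = _tip_labels(len(leaves))
    taxa = dendropy.TaxonNamespace(labels)
    for lab, nd in zip(taxa, sorted(leaves, key=lambda x: x._leaf_id)):
        nd.taxon = lab
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return Chronogram(tree)


# ----------------------------------------------------------------------
# binary character evolution (Mk1)
# ----------------------------------------------------------------------


def simulate_mk1_states(
    tree: Chronogram,
    q: float,
    root_state: int,
    seed: int | np.random.Generator | None = None,
) -> dict[str, int]:
    """Evolve a binary character down the tree under a symmetric rate q.

    Along a branch of duration t the state flips with probability
    (1 - exp(-2 q t)) / 2.  Returns tip label -> state.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    rng = as_rng(seed)
    states: dict[int, int] = {}
    out: dict[str, int] = {}
    root = tree.tree.seed_node
    states[id(root)] = root_state
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * q * t))
        state = parent_state ^ int(rng.random() < p_flip)
        states[id(node)] = state
        if node.is_leaf():
            out[node.taxon.label] = state
    return out


# ----------------------------------------------------------------------
# two-rate pure birth (for model-selection power experiments)
# ----------------------------------------------------------------------


def two_rate_branching_times(
    n_tips: int,
    rate_early: float,
    rate_late: float,
    n_switch: int,
    rng,
) -> BranchingTimes:
    """Branching times of a pure-birth tree whose rate shifts once.

    The clade diversifies at ``rate_early`` until ``n_switch`` lineages
    exist, then at ``rate_late``; the model-selection power experiments use
    this as the data-generating process the Yule-2-rate model should win on.
    Only times are produced (diversification likelihoods never need the
    topology).
    """
    if not 2 <= n_switch <= n_tips:
        raise ValueError("need 2 <= n_switch <= n_tips")
    rng = as_rng(rng)
    k = np.arange(2, n_tips + 1, dtype=float)
    rates = np.where(k <= n_switch, rate_early, rate_late)
    g = rng.exponential(1.0 / (k * rates))
    return BranchingTimes(n=n_tips, times=_ages_from_intervals(g))
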