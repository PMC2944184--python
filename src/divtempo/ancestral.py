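"""Mk1 ancestral-state reconstruction for a binary biogeographic character.

The Mk1 model is the 1-parameter symmetric continuous-time Markov chain on
two states (here 1 = Central America, 0 = South America / Greater
Antilles): a single rate q governs flips in both directions, so along a
branch of duration t

    P(stay) = (1 + exp(-2 q t)) / 2,    P(flip) = (1 - exp(-2 q t)) / 2.

The tree likelihood comes from the standard post-order pruning recursion
with the root combined under the equal prior (1/2, 1/2) — which is also
the chain's stationary distribution, the only prior consistent with the
model's symmetry.  Marginal per-node state probabilities (the pie diagrams
of ancestral-area figures) come from the usual two-pass (inside/outside)
algorithm.

The focal-root search answers the biogeographic question directly: find
the most basal node confidently reconstructed in the focal area, which
then serves as the origin for downstream diversification analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .chronogram import Chronogram

__all__ = [
    "AncestralReconstruction",
    "FocalRootResult",
    "read_tip_states",
    "write_tip_states",
    "mk1_loglik",
    "fit_mk1",
    "marginal_states",
    "find_focal_root",
    "internal_node_ids",
]

#: bracket for the 1-D rate search (per unit time of the input tree)
Q_MIN, Q_MAX = 1e-8, 10.0


# ----------------------------------------------------------------------
# tip-state table I/O:  two-column TSV with header "tip<TAB>state"
# ----------------------------------------------------------------------


def read_tip_states(source) -> dict[str, int]:
    """Read a tip -> {0,1} table from a path or a string of TSV text."""
    if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:2]] != ["tip", "state"]:
        raise ValueError('expected header "tip<TAB>state"')
    out: dict[str, int] = {}
    for ln in lines[1:]:
        tip, state = ln.split("\t")[:2]
        s = int(state)
        if s not in (0, 1):
            raise ValueError(f"state for {tip!r} must be 0 or 1, got {state!r}")
        if tip in out:
            raise ValueError(f"duplicate tip {tip!r} in state table")
        out[tip] = s
    return out


def write_tip_states(states: dict[str, int]) -> str:
    lines = ["tip\tstate"] + [f"{tip}\t{s}" for tip, s in states.items()]
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class AncestralReconstruction:
    """Fitted rate, likelihood, and per-node marginals.

    ``node_probs`` maps a deterministic internal-node id (post-order index
    over internal nodes) to the marginal probability of state 1; state 0 is
    the complement.  ``node_ages`` carries the matching ages.  ``q_boundary``
    flags a degenerate data set (all tips identical) where the rate MLE sits
    at the q = 0 boundary.
    """

    q_hat: float
    lnL: float
    node_probs: dict[int, float]
    node_ages: dict[int, float]
    q_boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "q_hat": self.q_hat,
            "lnL": self.lnL,
            "q_boundary": self.q_boundary,
            "node_probs": {str(k): v for k, v in self.node_probs.items()},
            "node_ages": {str(k): v for k, v in self.node_ages.items()},
        }


@dataclass(frozen=True)
class FocalRootResult:
    """Outcome of the focal-root search (explicit null when nothing passes)."""

    found: bool
    node_id: int | None
    probability: float
    age: float
    tip_labels: tuple[str, ...]


# ----------------------------------------------------------------------
# engine: tree flattened to post-order arrays
# ----------------------------------------------------------------------


class _Mk1Engine:
    """Tree compiled to post-order arrays so each likelihood evaluation is a
    single cheap sweep."""

    def __init__(self, tree: Chronogram, states: dict[str, int]):
        labels = tree.tip_labels
        missing = [lab for lab in labels if lab not in states]
        if missing:
            raise ValueError(f"missing states for tips: {missing[:5]}")
        extra = set(states) - set(labels)
        if extra:
            raise ValueError(f"states given for unknown tips: {sorted(extra)[:5]}")

        self.nodes = list(tree.tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.is_leaf = [nd.is_leaf() for nd in self.nodes]
        self.children = [
            [(self.index[id(c)], c.edge.length or 0.0) for c in nd.child_nodes()]
            for nd in self.nodes
        ]
        self.parent = [None] * len(self.nodes)
        for i, nd in enumerate(self.nodes):
            for j, _ in self.children[i]:
                self.parent[j] = i
        self.tip_state = [
            states[nd.taxon.label] if nd.is_leaf() else -1 for nd in self.nodes
        ]
        self.age = [nd.age for nd in self.nodes]
        # internal ids: post-order over internal nodes only
        self.internal_ids = {}
        next_id = 0
        for i, leaf in enumerate(self.is_leaf):
            if not leaf:
                self.internal_ids[i] = next_id
                next_id += 1
        self.root = len(self.nodes) - 1

    @staticmethod
    def _pmatrix(q: float, t: float) -> np.ndarray:
        stay = 0.5 * (1.0 + math.exp(-2.0 * q * t))
        return np.array([[stay, 1.0 - stay], [1.0 - stay, stay]])

    def _inside(self, q: float):
        """Conditional (partial) likelihoods, log-scaled per node."""
        n = len(self.nodes)
        D = np.empty((n, 2))
        logscale = np.zeros(n)
        for i in range(n):
            if self.is_leaf[i]:
                D[i] = 0.0
                D[i, self.tip_state[i]] = 1.0
                continue
            part = np.ones(2)
            ls = 0.0
            for j, blen in self.children[i]:
                P = self._pmatrix(q, blen)
                part = part * (P @ D[j])
                ls += logscale[j]
            m = part.max()
            if m <= 0.0:
                return None, None  # impossible data at q = 0
            D[i] = part / m
            logscale[i] = ls + math.log(m)
        return D, logscale

    def loglik(self, q: float) -> float:
        D, logscale = self._inside(q)
        if D is None:
            return -np.inf
        L = 0.5 * D[self.root].sum()
        if L <= 0.0:
            return -np.inf
        return math.log(L) + logscale[self.root]

    def marginals(self, q: float) -> tuple[dict[int, float], float]:
        """Per-internal-node marginal P(state 1) and the lnL at q."""
        D, logscale = self._inside(q)
        if D is None:
            raise ValueError("likelihood is zero (q = 0 with discordant tips)")
        n = len(self.nodes)
        O = np.empty((n, 2))  # outside likelihoods, rescaled per node
        O[self.root] = [0.5, 0.5]
        # pre-order sweep (reverse post-order)
        for i in range(n - 1, -1, -1):
            if self.is_leaf[i]:
                continue
            kids = self.children[i]
            down = []  # P @ D for each child, needed for sibling products
            for j, blen in kids:
                P = self._pmatrix(q, blen)
                down.append((j, P, P @ D[j]))
            for j, P, _ in down:
                sib = np.ones(2)
                for j2, _, pd in down:
                    if j2 != j:
                        sib = sib * pd
                contrib = (O[i] * sib) @ P  # sum over parent state
                m = contrib.max()
                O[j] = contrib / m if m > 0 else contrib
        probs: dict[int, float] = {}
        for i, nid in self.internal_ids.items():
            w = O[i] * D[i]
            s = w.sum()
            probs[nid] = float(w[1] / s)
        lnL = self.loglik(q)
        return probs, lnL

    def node_ages(self) -> dict[int, float]:
        return {nid: float(self.age[i]) for i, nid in self.internal_ids.items()}


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------


def internal_node_ids(tree: Chronogram) -> dict[int, tuple[str, ...]]:
    """Deterministic internal-node labeling: post-order index -> tip labels
    of the subtended clade."""
    out: dict[int, tuple[str, ...]] = {}
    nid = 0
    clade: dict[int, tuple[str, ...]] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            clade[id(nd)] = (nd.taxon.label,)
            continue
        tips = tuple(x for c in nd.child_nodes() for x in clade[id(c)])
        clade[id(nd)] = tips
        out[nid] = tips
        nid += 1
    return out


def mk1_loglik(tree: Chronogram, states: dict[str, int], q: float) -> float:
    """Log-likelihood of the tip states under Mk1 at rate ``q``.

    Returns -inf (rather than raising) when q = 0 and the tips disagree,
    since that is the correct limit of the likelihood.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    return _Mk1Engine(tree, states).loglik(q)


def fit_mk1(tree: Chronogram, states: dict[str, int]) -> AncestralReconstruction:
    """ML estimate of the symmetric rate (reconstruction not yet populated).

    The search runs on log q over [1e-8, 10]; a data set with all tips in
    one state sits at the q = 0 boundary and is returned flagged, with
    lnL = -ln 2 (the root prior mass on the shared state).
    """
    engine = _Mk1Engine(tree, states)
    vals = set(engine.tip_state) - {-1}
    ages = engine.node_ages()
    if len(vals) == 1:
        return AncestralReconstruction(
            q_hat=0.0, lnL=-math.log(2.0), node_probs={}, node_ages=ages,
            q_boundary=True,
        )
    res = minimize_scalar(
        lambda lq: -engine.loglik(math.exp(lq)),
        bounds=(math.log(Q_MIN), math.log(Q_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q = math.exp(res.x)
    # guard the bracket ends: the optimum may sit at a boundary
    cands = [(q, -res.fun)] + [(b, engine.loglik(b)) for b in (Q_MIN, Q_MAX)]
    q_hat, lnL = max(cands, key=lambda p: p[1])
    return AncestralReconstruction(
        q_hat=float(q_hat), lnL=float(lnL), node_probs={}, node_ages=ages
    )


def marginal_states(
    tree: Chronogram, states: dict[str, int], q: float
) -> AncestralReconstruction:
    """Marginal P(state 1) for every internal node at fixed rate ``q``."""
    if q < 0:
        raise ValueError("q must be >= 0")
    engine = _Mk1Engine(tree, states)
    probs, lnL = engine.marginals(q)
    return AncestralReconstruction(
        q_hat=float(q), lnL=float(lnL), node_probs=probs,
        node_ages=engine.node_ages(),
    )


def reconstruct(tree: Chronogram, states: dict[str, int]) -> AncestralReconstruction:
    """Fit q by ML, then reconstruct marginals at the fitted rate."""
    fit = fit_mk1(tree, states)
    if fit.q_boundary:
        # all tips identical: every node is that state with certainty
        shared = next(iter({states[l] for l in tree.tip_labels}))
        probs = {nid: float(shared) for nid in fit.node_ages}
        return AncestralReconstruction(
            q_hat=0.0, lnL=fit.lnL, node_probs=probs, node_ages=fit.node_ages,
            q_boundary=True,
        )
    rec = marginal_states(tree, states, fit.q_hat)
    return rec


def find_focal_root(
    tree: Chronogram,
    recon: AncestralReconstruction,
    focal_state: int = 1,
    threshold: float = 0.95,
) -> FocalRootResult:
    """Most basal internal node reconstructed in the focal area above
    ``threshold``.

    Ties in age resolve toward the earlier post-order id.  When no node
    qualifies the result carries ``found=False`` and reports the best
    candidate (highest probability, oldest first).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if focal_state not in (0, 1):
        raise ValueError("focal_state must be 0 or 1")
    clades = internal_node_ids(tree)
    items = []
    for nid, p1 in recon.node_probs.items():
        p = p1 if focal_state == 1 else 1.0 - p1
        items.append((nid, p, recon.node_ages[nid]))
    if not items:
        raise ValueError("reconstruction carries no node probabilities")
    qualified = [it for it in items if it[1] > threshold]
    if qualified:
        nid, p, age = max(qualified, key=lambda it: (it[2], -it[0]))
        return FocalRootResult(True, nid, float(p), float(age), clades[nid])
    nid, p, age = max(items, key=lambda it: (it[1], it[2], -it[0]))
    return FocalRootResult(False, None, float(p), float(age), clades[nid])
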