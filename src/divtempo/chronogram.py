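"""Ultrametric chronograms: parsing, validation, pruning, calibration.

A chronogram is a rooted phylogeny whose branch lengths are in units of
absolute time, so that every tip is equidistant from the root (ultrametric).
Node *ages* are measured backward from the present: tips sit at age 0 and the
root at ``root_age``.  The vector of internal-node ages (the branching times)
is the sufficient statistic for every diversification computation in this
package, so this module is mostly about getting that vector right: polytomy
handling, tie-breaking, and exact conservation of ages through pruning and
rescaling.

Newick reading and writing are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "CalibrationPoint",
    "ChronogramError",
    "NewickFormatError",
    "UltrametricityError",
    "parse_newick",
    "write_newick",
    "branching_times",
    "scale_to_calibration",
    "prune_tips",
]

#: Relative tolerance (against root age) within which root-to-tip path
#: lengths must agree for a tree to count as ultrametric.  Input trees often
#: carry rounding noise from external dating programs.
ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Base class for chronogram validation problems."""


class NewickFormatError(ChronogramError):
    """Malformed Newick or missing branch lengths."""


class UltrametricityError(ChronogramError):
    """Root-to-tip path lengths disagree beyond tolerance."""


@dataclass(frozen=True)
class CalibrationPoint:
    """Fix the age of the most recent common ancestor of two tips.

    Used for linear rescaling of a relative-time chronogram onto an absolute
    time axis (e.g. anchoring a biogeographic divergence at 7.5 Ma).
    """

    tip_a: str
    tip_b: str
    age: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("calibration age must be > 0")


@dataclass(frozen=True)
class BranchingTimes:
    """Ordered internal-node ages of a chronogram.

    ``times`` holds the n-1 internal-node ages sorted descending
    (``times[0]`` is the root age).  The derived internode ``intervals``
    are the durations g_2..g_n during which exactly k reconstructed lineages
    exist: g_k = t_{k-1} - t_k with t_n := 0, so ``sum(intervals)`` equals
    the root age.

    ``from_polytomies`` flags that the source tree contained multifurcations,
    which are read as bifurcations separated by zero-length edges (hence
    zero-length intervals).
    """

    n: int
    times: np.ndarray
    from_polytomies: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.n < 2:
            raise ChronogramError("branching times require at least 2 tips")
        if t.ndim != 1 or len(t) != self.n - 1:
            raise ChronogramError(
                f"expected {self.n - 1} branching times for n={self.n}, got {len(t)}"
            )
        if np.any(np.diff(t) > 0):
            raise ChronogramError("branching times must be sorted descending")
        if len(t) and t[-1] < 0:
            raise ChronogramError("branching times must be non-negative")

    @property
    def root_age(self) -> float:
        return float(self.times[0])

    @property
    def intervals(self) -> np.ndarray:
        """Internode durations g_2..g_n (length n-1, sums to root_age)."""
        t = self.times
        return np.concatenate([-np.diff(t), [t[-1]]])


def _require_unique_labels(labels: list[str]) -> None:
    if any(lab is None or lab == "" for lab in labels):
        raise ChronogramError("every tip must carry a non-empty label")
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ChronogramError(f"duplicate tip labels: {dup}")


class Chronogram:
    """A rooted ultrametric tree with node ages in time units before present.

    Thin wrapper around a :class:`dendropy.Tree` that validates
    ultrametricity on construction and annotates every node with an ``age``
    attribute (tips exactly 0, root at :attr:`root_age`).  Polytomies are
    accepted; diversification code treats a node with c children as c-1
    coincident bifurcations.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_age()

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except ChronogramError:
            raise
        except Exception as exc:  # dendropy raises assorted error types
            raise NewickFormatError(f"could not parse Newick: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def _validate_and_age(self) -> None:
        tree = self._tree
        root = tree.seed_node
        leaves = []
        # depth-first depths from the root
        root.depth = 0.0
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            blen = node.edge.length
            if blen is None:
                raise NewickFormatError(
                    "branch length missing on an edge "
                    f"(above {'tip ' + node.taxon.label if node.is_leaf() else 'an internal node'})"
                )
            if blen < 0:
                raise ChronogramError("negative branch length")
            node.depth = node.parent_node.depth + blen
        for leaf in tree.leaf_node_iter():
            leaves.append(leaf)
        if len(leaves) < 2:
            raise ChronogramError("a chronogram needs at least 2 tips")
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
        _require_unique_labels(labels)

        depths = np.array([lf.depth for lf in leaves])
        root_age = float(depths.max())
        tol = ULTRAMETRIC_RTOL * max(root_age, 1e-300)
        worst = int(np.argmax(np.abs(depths - root_age)))
        if abs(depths[worst] - root_age) > tol:
            raise UltrametricityError(
                f"tree is not ultrametric: tip {labels[worst]!r} has root-to-tip "
                f"path {depths[worst]:.9g}, expected {root_age:.9g}"
            )
        self._root_age = root_age
        for node in tree.preorder_node_iter():
            node.age = 0.0 if node.is_leaf() else max(root_age - node.depth, 0.0)

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (nodes carry an ``age`` attribute)."""
        return self._tree

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def has_polytomies(self) -> bool:
        return any(
            len(nd.child_nodes()) > 2 for nd in self._tree.preorder_internal_node_iter()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram n_tips={self.n_tips} root_age={self.root_age:.6g}>"

    # ------------------------------------------------------------------
    # operations
    # ------------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    def branching_times(self) -> BranchingTimes:
        """Extract the descending vector of internal-node ages.

        A node with c children contributes c-1 copies of its age (the
        zero-length resolution of polytomies), so the vector always has
        length n-1.  Ties are broken by a stable preorder index, so equal
        ages keep a deterministic order.
        """
        ages = []
        poly = False
        for idx, node in enumerate(self._tree.preorder_internal_node_iter()):
            c = len(node.child_nodes())
            if c > 2:
                poly = True
            ages.extend([(node.age, idx)] * (c - 1))
        ages.sort(key=lambda pair: (-pair[0], pair[1]))
        times = np.array([a for a, _ in ages])
        return BranchingTimes(n=self.n_tips, times=times, from_polytomies=poly)

    def mrca_age(self, tip_a: str, tip_b: str) -> float:
        if tip_a == tip_b:
            raise ChronogramError("MRCA of a tip with itself has age 0")
        labels = set(self.tip_labels)
        for lab in (tip_a, tip_b):
            if lab not in labels:
                raise ChronogramError(f"unknown tip label: {lab!r}")
        mrca = self._tree.mrca(taxon_labels=[tip_a, tip_b])
        return float(mrca.age)

    def rescale(self, factor: float) -> "Chronogram":
        """Multiply all node ages by ``factor`` (topology unchanged)."""
        if not factor > 0:
            raise ChronogramError("rescale factor must be > 0")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Chronogram(clone)

    def prune(self, keep: set[str]) -> "Chronogram":
        """Induced subtree on ``keep``; retained node ages are unchanged.

        Degree-2 nodes created by the pruning are suppressed and the result
        is re-rooted at the MRCA of the kept tips, so ``root_age`` equals
        that MRCA's age.
        """
        keep = set(keep)
        labels = set(self.tip_labels)
        unknown = keep - labels
        if unknown:
            raise ChronogramError(f"unknown tip labels: {sorted(unknown)}")
        if len(keep) < 2:
            raise ChronogramError("need at least 2 tips to keep")
        if keep == labels:
            return Chronogram(self._tree.clone(depth=1))
        sub = self._tree.extract_tree_with_taxa_labels(labels=keep)
        # collapse any single-child chain above the MRCA of the kept tips
        root = sub.seed_node
        while len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        if root is not sub.seed_node:
            root.parent_node.remove_child(root)
            root.edge.length = None
            sub.seed_node = root
        return Chronogram(sub)


# ----------------------------------------------------------------------
# functional façade (mirrors the operation vocabulary used elsewhere)
# ----------------------------------------------------------------------


def parse_newick(text: str) -> Chronogram:
    """Parse a Newick string with branch lengths into a validated Chronogram."""
    return Chronogram.from_newick(text)


def write_newick(tree: Chronogram) -> str:
    """Serialize to Newick; re-parsing reproduces all node ages to ~1e-9."""
    return tree.to_newick()


def branching_times(tree: Chronogram) -> BranchingTimes:
    return tree.branching_times()


def scale_to_calibration(tree: Chronogram, cal: CalibrationPoint) -> Chronogram:
    """Linearly rescale so MRCA(tip_a, tip_b) sits at ``cal.age``.

    This is a pure change of time units (no rate smoothing); every
    scale-invariant statistic (such as gamma) is unaffected.
    """
    current = tree.mrca_age(cal.tip_a, cal.tip_b)
    if current <= 0:
        raise ChronogramError("calibration MRCA has age 0")
    return tree.rescale(cal.age / current)


def prune_tips(tree: Chronogram, keep: set[str]) -> Chronogram:
    return tree.prune(keep)
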