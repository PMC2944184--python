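"""Deterministic test fixtures with hand-checkable expected values.

Four fixture families:

(a) the 3-tip tree whose gamma is forced by direct arithmetic;
(b) ladder trees with harmonic internode intervals g_k = c/k, for which
    gamma is exactly 0 by an algebraic identity;
(c) a study-scale pair: a 122-tip pure-birth tree rescaled to root age
    16.2 plus its random 90-tip subsample;
(d) small trees with simulated binary tip states, sized for exhaustive
    enumeration of the Mk1 likelihood.

Every expected value in the table is regenerated by its stated oracle in
the test suite; the generator is seeded and byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ancestral import write_tip_states
from .chronogram import Chronogram
from .treesim import (
    sample_incomplete,
    simulate_birth_death,
    simulate_mk1_states,
    simulate_yule,
)

__all__ = ["FixtureSet", "make_fixtures", "write_fixtures"]

GAMMA3_NEWICK = "((A:1.0,B:1.0):1.0,C:2.0);\n"
#: gamma of the 3-tip tree above: (mean(S) - T/2) / (T sqrt(1/12)) with
#: T = 5, S_2 = 2, i.e. -sqrt(12)/10
GAMMA3_VALUE = -math.sqrt(12.0) / 10.0

HARMONIC_SIZES = (5, 10, 50)
STUDY_N_TOTAL = 122
STUDY_N_SAMPLED = 90
STUDY_ROOT_AGE = 16.2
MK1_SIZES = (5, 6, 8)
MK1_Q = 0.25
#: extinction-rich reconstructed tree used as the birth-death reference
#: instance (its ML fit is cross-checked against an external implementation)
BD_N, BD_LAMBDA, BD_MU, BD_SEED = 40, 1.0, 0.6, 11


@dataclass(frozen=True)
class FixtureSet:
    name: str
    newicks: dict[str, str]
    states: dict[str, dict[str, int]]
    expected: list[tuple[str, float, str]]  # (statistic, value, oracle tag)

    def expected_tsv(self) -> str:
        lines = ["statistic\tvalue\toracle"]
        lines += [f"{s}\t{v:.12g}\t{tag}" for s, v, tag in self.expected]
        return "\n".join(lines) + "\n"


def harmonic_ladder_newick(n: int, c: float = 1.0) -> str:
    """Caterpillar tree whose internode intervals are g_k = c/k, k=2..n.

    Branching times are the harmonic tail sums t_j = sum_{k=j+1..n} c/k
    (descending); a ladder topology realises any descending time vector.
    """
    g = c / np.arange(2, n + 1)
    times = np.cumsum(g[::-1])[::-1]  # t_1 .. t_{n-1}
    # build from the youngest cherry outward
    labels = [f"L{i + 1:02d}" for i in range(n)]
    sub = f"({labels[0]}:{times[-1]:.17g},{labels[1]}:{times[-1]:.17g})"
    age = times[-1]
    for j in range(n - 3, -1, -1):
        t = times[j]
        sub = f"({sub}:{t - age:.17g},{labels[n - 1 - j]}:{t:.17g})"
        age = t
    return sub + ";\n"


def make_fixtures(seed: int = 20100914) -> FixtureSet:
    """Build the full fixture set deterministically from ``seed``."""
    rng = np.random.SeedSequence(seed)
    s_tree, s_prune, s_states = [np.random.default_rng(s) for s in rng.spawn(3)]

    newicks: dict[str, str] = {"gamma3": GAMMA3_NEWICK}
    states: dict[str, dict[str, int]] = {}
    expected: list[tuple[str, float, str]] = [
        ("gamma3:gamma", GAMMA3_VALUE, "direct formula arithmetic (T=5, S_2=2)"),
    ]

    for n in HARMONIC_SIZES:
        key = f"harmonic{n}"
        newicks[key] = harmonic_ladder_newick(n)
        expected.append(
            (f"{key}:gamma", 0.0, "algebraic identity: g_k = c/k makes S_i linear")
        )

    big = simulate_yule(STUDY_N_TOTAL, birth_rate=1.0, seed=s_tree)
    big = big.rescale(STUDY_ROOT_AGE / big.root_age)
    small = sample_incomplete(big, STUDY_N_SAMPLED, seed=s_prune)
    newicks["study122"] = big.to_newick()
    newicks["study90"] = small.to_newick()
    expected += [
        ("study122:root_age", STUDY_ROOT_AGE, "rescaling target"),
        ("study90:n_branching_times", float(STUDY_N_SAMPLED - 1), "n - 1 count"),
    ]

    newicks["bd40"] = simulate_birth_death(BD_N, BD_LAMBDA, BD_MU, seed=BD_SEED).to_newick()

    for n in MK1_SIZES:
        key = f"mk1_{n}"
        tr = simulate_yule(n, birth_rate=1.0, seed=s_tree)
        newicks[key] = tr.to_newick()
        states[key] = simulate_mk1_states(tr, MK1_Q, root_state=1, seed=s_states)

    return FixtureSet(name="divtempo-fixtures", newicks=newicks, states=states,
                      expected=expected)


def write_fixtures(fs: FixtureSet, out_dir) -> list[Path]:
    """Write trees/, states/ and the expected-value table under ``out_dir``."""
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "states").mkdir(parents=True, exist_ok=True)
    written = []
    for key, nwk in sorted(fs.newicks.items()):
        p = out / "trees" / f"{key}.nwk"
        p.write_text(nwk)
        written.append(p)
    for key, st in sorted(fs.states.items()):
        p = out / "states" / f"{key}.tsv"
        p.write_text(write_tip_states(st))
        written.append(p)
    p = out / "expected.tsv"
    p.write_text(fs.expected_tsv())
    written.append(p)
    return written
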