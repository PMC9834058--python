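"""Shared fixtures and independent oracle helpers.

The oracles deliberately re-derive quantities by brute-force enumeration at
codon level so they share no code path with the array implementations they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from omegac import (
    AncestralPosteriors,
    UNIVERSAL_CODE,
    balanced_tree,
    build_tensors,
)


@pytest.fixture(scope="session")
def code():
    return UNIVERSAL_CODE


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tree4():
    """Balanced 4-tip tree: branches 1..6, tips t1..t4 = nodes 2,3,5,6."""
    return balanced_tree(4, 0.3)


def delta_posteriors(states: np.ndarray, code=UNIVERSAL_CODE) -> AncestralPosteriors:
    """Point-mass posteriors from true per-node codon states (used to turn
    a simulated truth into 'perfectly reconstructed' tensors)."""
    n, L = states.shape
    probs = np.zeros((n, L, code.n_codons))
    missing = states < 0
    idx = np.nonzero(~missing)
    probs[idx[0], idx[1], states[~missing]] = 1.0
    return AncestralPosteriors(probs, missing, code)


def tensors_from_states(tree, states, code=UNIVERSAL_CODE):
    return build_tensors(delta_posteriors(states, code), tree)


# ---------------------------------------------------------------------------
# brute-force combinatorial-substitution oracle (codon-level enumeration)


def _support(row, tol=0.0):
    return [int(i) for i in np.flatnonzero(np.asarray(row) > tol)]


def oracle_combinatorial(parent_rows, child_rows, category, view,
                         code=UNIVERSAL_CODE):
    """Exhaustive weighted enumeration of combinatorial substitutions for
    one site across K branches.

    ``parent_rows`` / ``child_rows``: per-branch 61-state marginal
    distributions.  Every assignment of (ancestral, derived) codon states
    to the K branches is enumerated; its weight is the product of the
    marginal probabilities and it counts toward the category if every
    branch satisfies the category's constraints.
    """
    aa = code.aa_of_codon
    K = len(parent_rows)
    branch_states = []
    for p, c in zip(parent_rows, child_rows):
        branch_states.append(
            [(i, j) for i in _support(p) for j in _support(c) if i != j]
        )
    total = 0.0
    for combo in itertools.product(*branch_states):
        if view == "N":
            if any(aa[i] == aa[j] for i, j in combo):
                continue
        else:
            if any(aa[i] != aa[j] for i, j in combo):
                continue
            # synonymous combinations must share one amino-acid group
            if len({int(aa[i]) for i, _ in combo}) != 1:
                continue
        if category == "any2any":
            ok = True
        elif category == "any2spe":
            if view == "N":
                ok = len({int(aa[j]) for _, j in combo}) == 1
            else:
                ok = len({j for _, j in combo}) == 1
        elif category == "spe2spe":
            if view == "N":
                ok = (
                    len({int(aa[j]) for _, j in combo}) == 1
                    and len({int(aa[i]) for i, _ in combo}) == 1
                )
            else:
                ok = (
                    len({j for _, j in combo}) == 1
                    and len({i for i, _ in combo}) == 1
                )
        elif category == "any2dif":
            return oracle_combinatorial(
                parent_rows, child_rows, "any2any", view, code
            ) - oracle_combinatorial(parent_rows, child_rows, "any2spe", view, code)
        elif category == "dif2spe":
            return oracle_combinatorial(
                parent_rows, child_rows, "any2spe", view, code
            ) - oracle_combinatorial(parent_rows, child_rows, "spe2spe", view, code)
        else:
            raise ValueError(category)
        if ok:
            w = 1.0
            for k, (i, j) in enumerate(combo):
                w *= parent_rows[k][i] * child_rows[k][j]
            total += w
    return total


def sparse_distribution(rng, n_support=5, n_states=61):
    """Random distribution supported on a few codon states."""
    idx = rng.choice(n_states, size=n_support, replace=False)
    w = rng.random(n_support)
    row = np.zeros(n_states)
    row[idx] = w / w.sum()
    return row
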