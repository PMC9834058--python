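"""Independent branch combinations and the higher-order heuristic search.

Branches in a combination must be evolutionarily independent: no branch may
be an ancestor or descendant of another (an ancestor-descendant pair shares
its substitution history), and, optionally, no two branches may be sisters
(a convergent pair of sister branches is indistinguishable from a single
substitution in their shared parent).  K = 2 combinations are enumerated
exhaustively; higher orders are explored by a branch-and-bound scheme that
unions passing K-combinations sharing exactly K-1 branches, discards
dependent candidates, recomputes the metrics, and repeats until no
candidate clears the omega_C / O_C^N cut-offs.  The heuristic is sound
(every emitted combination passed its own cut-offs and independence rules)
but deliberately incomplete: a strong K+1 combination whose
sub-combinations fail the cut-offs is never generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import (
    CATEGORIES,
    QuantileMap,
    combination_record,
    correct_dsc,
    pair_table,
)
from .phylo_io import RootedTree
from .tensors import SubstitutionTensors


@dataclass
class SearchConfig:
    max_k: int = 10
    cutoff_omega: float = 5.0
    cutoff_ocn: float = 2.0
    exclude_sisters: bool = True
    category: str = "any2spe"

    def __post_init__(self) -> None:
        if self.max_k < 2:
            raise ValueError("max_k must be >= 2")
        if self.cutoff_omega < 0 or self.cutoff_ocn < 0:
            raise ValueError("cut-offs must be non-negative")


def is_independent(
    tree: RootedTree, branch_set, exclude_sisters: bool = True
) -> bool:
    """True when no two branches are in an ancestor-descendant relationship
    (nor sisters, if ``exclude_sisters``)."""
    branches = sorted(set(int(b) for b in branch_set))
    if len(branches) != len(set(branch_set)):
        return False
    for a, b in combinations(branches, 2):
        if tree.is_ancestor_of(a, b) or tree.is_ancestor_of(b, a):
            return False
        if exclude_sisters and tree.are_sisters(a, b):
            return False
    return True


def enumerate_pairs(tree: RootedTree, exclude_sisters: bool = False) -> np.ndarray:
    """All independent unordered branch pairs, sorted, as an (n, 2) array.

    The default exclusion removes only ancestor-descendant pairs; sister
    exclusion is the stricter mode used for metric analysis.
    """
    branches = tree.branches
    anc = {int(b): tree.ancestors(int(b)) for b in branches}
    out = []
    for a, b in combinations(branches.tolist(), 2):
        if a in anc[b] or b in anc[a]:
            continue
        if exclude_sisters and tree.are_sisters(a, b):
            continue
        out.append((a, b))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def branch_and_bound(
    obs: SubstitutionTensors,
    exp: SubstitutionTensors,
    tree: RootedTree,
    config: SearchConfig | None = None,
    categories=CATEGORIES,
) -> dict[int, pd.DataFrame]:
    """Exhaustive K = 2 analysis plus the higher-order heuristic search.

    Returns one table per K.  At K = 2 the dS_C quantile correction is
    applied (exhaustive enumeration is available); at K > 2 rates use the
    uncorrected dS_C.  Output order is deterministic.
    """
    config = config or SearchConfig()
    cat = config.category
    pairs = enumerate_pairs(tree, exclude_sisters=config.exclude_sisters)
    tables: dict[int, pd.DataFrame] = {}
    k2 = pair_table(obs, exp, pairs, categories=categories, correct=True)
    tables[2] = k2

    omega_col = f"omegaC_{cat}"
    ocn_col = f"OCN_{cat}"
    passing = k2[
        (k2[omega_col] >= config.cutoff_omega) & (k2[ocn_col] >= config.cutoff_ocn)
    ]
    current = sorted(
        frozenset((int(r.branch1), int(r.branch2)))
        for r in passing.itertuples(index=False)
    )

    k = 2
    while current and k < config.max_k:
        k += 1
        candidates = set()
        for ca, cb in combinations(current, 2):
            if len(ca & cb) == k - 2:  # share exactly K-1 of the K-1... i.e. K-2
                union = ca | cb
                if len(union) == k and is_independent(
                    tree, union, config.exclude_sisters
                ):
                    candidates.add(frozenset(union))
        if not candidates:
            break
        records = [
            combination_record(obs, exp, sorted(c), categories=categories)
            for c in sorted(candidates, key=lambda c: tuple(sorted(c)))
        ]
        table = pd.DataFrame(records)
        tables[k] = table
        passing = table[
            (table[f"omegaC_{cat}"] >= config.cutoff_omega)
            & (table[ocn_col] >= config.cutoff_ocn)
        ]
        current = sorted(frozenset(b) for b in passing["branches"])
    return tables
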