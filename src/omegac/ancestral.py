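"""Marginal empirical-Bayes ancestral codon-state posteriors.

``reconstruct`` computes, for every node (including the root) and codon
site, the marginal posterior distribution over the 61 sense codons given
the tip data, the codon model and per-site rates, using the pruning
algorithm with an outward (root-to-tip) second pass.  Tips are delta
distributions on their observed states.  ``load_external_posteriors``
ingests the equivalent table produced by an external reconstruction tool.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pruning import PruningEngine
from .codon_model import CodonModel, SiteRates
from .genetic_code import UNIVERSAL_CODE, GeneticCode
from .phylo_io import CodonAlignment, MISSING, RootedTree


@dataclass
class AncestralPosteriors:
    """Per-node, per-site codon-state posteriors P_mlj.

    ``probs[m, l]`` sums to 1, or is all-zero where ``missing[m, l]`` is
    set.  Node axis covers all nodes of the tree in node-id order (the root
    included; its posterior is used as the ancestral distribution of its
    child branches but contributes no branch of its own).
    """

    probs: np.ndarray        # (N, L, 61)
    missing: np.ndarray      # (N, L) bool
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.probs.shape[1]


def reconstruct(
    tree: RootedTree,
    alignment: CodonAlignment,
    model: CodonModel,
    site_rates: SiteRates | None = None,
) -> AncestralPosteriors:
    """Marginal posterior ancestral codon states at every node and site."""
    rates = (
        site_rates.rates if site_rates is not None
        else np.ones(alignment.n_sites)
    )
    engine = PruningEngine(tree, alignment)
    probs, missing = engine.marginal_posteriors(model, rates)
    return AncestralPosteriors(probs, missing, alignment.code)


def load_external_posteriors(
    table: str | pd.DataFrame,
    tree: RootedTree,
    alignment: CodonAlignment,
    tolerance: float = 1e-2,
) -> AncestralPosteriors:
    """Load per-node, per-site posteriors from a TSV table.

    The table needs columns ``node`` (node label), ``site`` (1-based codon
    site) and one column per sense codon; codon columns may appear in any
    order and are remapped through the shared codon indexing.  Rows must sum
    to 1 within ``tolerance`` (default 1%); they are renormalised.  Tip rows
    are filled from the alignment, so the table only needs internal nodes.
    """
    code = alignment.code
    if isinstance(table, str):
        table = pd.read_csv(io.StringIO(table), sep="\t")
    missing_cols = {"node", "site"} - set(table.columns)
    if missing_cols:
        raise ValueError(f"posterior table lacks columns: {sorted(missing_cols)}")
    codon_cols = [c for c in table.columns if c.upper() in code.codon_index]
    if len(codon_cols) != code.n_codons:
        raise ValueError(
            f"posterior table must have {code.n_codons} codon columns, "
            f"found {len(codon_cols)}"
        )
    order = np.argsort([code.codon_index[c.upper()] for c in codon_cols])
    mat = table[codon_cols].to_numpy(dtype=float)[:, order]

    sums = mat.sum(axis=1)
    nonzero = sums > 0
    bad = nonzero & (np.abs(sums - 1.0) > tolerance)
    if bad.any():
        rows = table.loc[bad, ["node", "site"]].itertuples(index=False)
        listing = ", ".join(f"{r.node}@{r.site}" for r in rows)
        raise ValueError(f"posterior rows not summing to 1: {listing}")
    mat[nonzero] /= sums[nonzero][:, None]

    name_to_id = {tree.node_name(v): v for v in range(tree.n_nodes)}
    L = alignment.n_sites
    probs = np.zeros((tree.n_nodes, L, code.n_codons))
    seen = np.zeros((tree.n_nodes, L), dtype=bool)
    for r, (node, site) in enumerate(zip(table["node"], table["site"])):
        if node not in name_to_id:
            raise ValueError(f"unknown node label in posterior table: {node!r}")
        site_i = int(site) - 1
        if not 0 <= site_i < L:
            raise ValueError(f"site {site} out of range 1..{L}")
        v = name_to_id[node]
        probs[v, site_i] = mat[r]
        seen[v, site_i] = True

    row_of = {sid: i for i, sid in enumerate(alignment.ids)}
    for v in tree.tip_ids:
        states = alignment.codes[row_of[tree.labels[v]]]
        obs = states != MISSING
        probs[v] = 0.0
        probs[v, np.flatnonzero(obs), states[obs]] = 1.0
        seen[v] = True

    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    not_seen = [
        (tree.node_name(v), l + 1)
        for v in internal for l in range(L) if not seen[v, l]
    ]
    if not_seen:
        raise ValueError(
            f"posterior table misses {len(not_seen)} internal rows, e.g. "
            f"{not_seen[:3]}"
        )
    missing = probs.sum(axis=2) == 0
    return AncestralPosteriors(probs, missing, code)


def posteriors_to_table(
    post: AncestralPosteriors, tree: RootedTree, internal_only: bool = True
) -> pd.DataFrame:
    """Inverse of ``load_external_posteriors`` (round-trip support)."""
    rows = []
    nodes = [
        v for v in range(tree.n_nodes)
        if not (internal_only and tree.is_tip(v))
    ]
    for v in nodes:
        for l in range(post.n_sites):
            rows.append((tree.node_name(v), l + 1, *post.probs[v, l]))
    cols = ["node", "site", *post.code.codons]
    return pd.DataFrame(rows, columns=cols)
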