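"""Branch-wise substitution-probability tensors A^N and A^S.

For branch *b* (child node *b*, parent node *n*) and site *l*, the posterior
probability of a single substitution from ancestral codon *i* to derived
codon *j* is approximated by the product of the two marginal posteriors,
P_i(parent) * P_j(child), with the diagonal (i = j) zeroed: a same-state
"transition" is not a substitution.  The 61 x 61 matrix is then split into

* ``AN`` (B x L x 20 x 20): non-synonymous substitutions, synonymous codons
  merged into their amino acid, same-amino-acid cells zero;
* ``AS`` (B x L x 20 x 6 x 6): synonymous substitutions, one codon-by-codon
  block per amino acid (slots beyond an amino acid's codon count stay
  zero-padded), codon diagonal zero.

Because the observed per-branch matrix is an outer product of marginals,
both arrays are built directly from group-aggregated posteriors without
materialising the 61 x 61 matrices.  Sites where either endpoint posterior
is missing give all-zero slices and are excluded from the branch-specific
effective site counts used when rescaling branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestral import AncestralPosteriors
from .genetic_code import MAX_SYNONYMS, UNIVERSAL_CODE, GeneticCode
from .phylo_io import RootedTree


@dataclass
class SubstitutionTensors:
    """A^N / A^S substitution-probability arrays for every branch."""

    AN: np.ndarray            # (B, L, 20, 20)
    AS: np.ndarray            # (B, L, 20, 6, 6)
    missing: np.ndarray       # (B, L) bool
    branches: np.ndarray      # (B,) branch ids, = node ids 1..B
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE, repr=False)
    _agg: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_branches(self) -> int:
        return self.AN.shape[0]

    @property
    def n_sites(self) -> int:
        return self.AN.shape[1]

    def branch_index(self, branch_id: int) -> int:
        idx = int(branch_id) - 1
        if not 0 <= idx < self.n_branches:
            raise KeyError(f"unknown branch id {branch_id}")
        return idx

    # per-branch, per-site aggregates used by the combination formulas ------

    def _cached(self, key: str, fn):
        if key not in self._agg:
            self._agg[key] = fn()
        return self._agg[key]

    def total_N(self) -> np.ndarray:
        """(B, L): total non-synonymous substitution probability."""
        return self._cached("tN", lambda: self.AN.sum(axis=(2, 3)))

    def derived_N(self) -> np.ndarray:
        """(B, L, 20): mass arriving at each derived amino acid."""
        return self._cached("dN", lambda: self.AN.sum(axis=2))

    def total_S(self) -> np.ndarray:
        """(B, L, 20): total synonymous mass per amino-acid group."""
        return self._cached("tS", lambda: self.AS.sum(axis=(3, 4)))

    def derived_S(self) -> np.ndarray:
        """(B, L, 20, 6): mass arriving at each derived synonymous codon."""
        return self._cached("dS", lambda: self.AS.sum(axis=3))

    def effective_sites(self) -> np.ndarray:
        """(B,) number of non-missing sites per branch."""
        return (~self.missing).sum(axis=1)


@dataclass
class RescaledBranchLengths:
    """Branch lengths in codon substitutions per site (rescaled:
    summed substitution probabilities over the branch's effective sites)."""

    t: np.ndarray         # (B,) total
    t_N: np.ndarray       # (B,) non-synonymous
    t_S: np.ndarray       # (B,) synonymous
    effective_sites: np.ndarray  # (B,)

    def for_branch(self, branch_id: int) -> tuple[float, float, float]:
        i = int(branch_id) - 1
        return float(self.t[i]), float(self.t_N[i]), float(self.t_S[i])


def branch_substitution_matrix(
    parent_row: np.ndarray, child_row: np.ndarray
) -> np.ndarray:
    """61 x 61 substitution probabilities for one branch and site: the outer
    product of the endpoint marginals with a zeroed diagonal.  All-zero
    (missing) endpoint rows give an all-zero matrix."""
    parent_row = np.asarray(parent_row, dtype=float)
    child_row = np.asarray(child_row, dtype=float)
    mat = np.outer(parent_row, child_row)
    np.fill_diagonal(mat, 0.0)
    return mat


def split_nonsyn_syn(
    sub_matrix: np.ndarray, code: GeneticCode = UNIVERSAL_CODE
) -> tuple[np.ndarray, np.ndarray]:
    """Split a 61 x 61 substitution matrix into its A^N (20 x 20) and A^S
    (20 x 6 x 6) slices."""
    ind = code.aa_indicator()
    an = ind.T @ sub_matrix @ ind
    np.fill_diagonal(an, 0.0)
    a_s = np.zeros((code.n_amino_acids, MAX_SYNONYMS, MAX_SYNONYMS))
    for g, idx in enumerate(code.aa_groups):
        block = sub_matrix[np.ix_(idx, idx)].copy()
        np.fill_diagonal(block, 0.0)
        a_s[g, : len(idx), : len(idx)] = block
    return an, a_s


def build_tensors(
    posteriors: AncestralPosteriors, tree: RootedTree
) -> SubstitutionTensors:
    """Observed substitution tensors from ancestral state posteriors."""
    code = posteriors.code
    branches = tree.branches
    parents = tree.parent[branches]
    P = posteriors.probs[parents]     # (B, L, 61) ancestral
    C = posteriors.probs[branches]    # (B, L, 61) derived
    missing = posteriors.missing[parents] | posteriors.missing[branches]

    ind = code.aa_indicator()
    PA = P @ ind                      # (B, L, 20)
    CA = C @ ind
    AN = np.einsum("bla,blc->blac", PA, CA)
    eye = np.eye(code.n_amino_acids, dtype=bool)
    AN[..., eye] = 0.0

    B, L = P.shape[:2]
    AS = np.zeros((B, L, code.n_amino_acids, MAX_SYNONYMS, MAX_SYNONYMS))
    for g, idx in enumerate(code.aa_groups):
        k = len(idx)
        block = np.einsum("bli,blj->blij", P[..., idx], C[..., idx])
        block[..., np.eye(k, dtype=bool)] = 0.0
        AS[:, :, g, :k, :k] = block

    AN[missing] = 0.0
    AS[missing] = 0.0
    return SubstitutionTensors(AN, AS, missing, branches, code)


def rescale_branch_lengths(tensors: SubstitutionTensors) -> RescaledBranchLengths:
    """Per-branch codon-substitution branch lengths t_b = t_b^N + t_b^S,
    dividing summed substitution probabilities by the branch's non-missing
    site count (zero, and flagged by a zero count, for all-missing branches).
    """
    eff = tensors.effective_sites().astype(float)
    sum_n = tensors.AN.sum(axis=(1, 2, 3))
    sum_s = tensors.AS.sum(axis=(1, 2, 3, 4))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_n = np.where(eff > 0, sum_n / np.maximum(eff, 1.0), 0.0)
        t_s = np.where(eff > 0, sum_s / np.maximum(eff, 1.0), 0.0)
    return RescaledBranchLengths(t_n + t_s, t_n, t_s, eff.astype(np.int64))
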