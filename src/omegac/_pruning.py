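"""Felsenstein pruning over codon states, shared by likelihood-based
parameter estimation and marginal ancestral reconstruction.

Partial likelihoods are rescaled per site (stored log-scalers) to avoid
underflow.  Missing tip states contribute a partial-likelihood vector of
ones.  Transition probabilities are applied through the model's cached
eigendecomposition so that per-site rate multipliers cost only one extra
elementwise product.
"""

from __future__ import annotations

import numpy as np

from .codon_model import CodonModel
from .phylo_io import CodonAlignment, MISSING, RootedTree, check_labels


class PruningEngine:
    """Reusable pruning workspace for one (tree, alignment) pair."""

    def __init__(self, tree: RootedTree, alignment: CodonAlignment):
        check_labels(tree, alignment)
        self.tree = tree
        self.L = alignment.n_sites
        self.n_states = alignment.code.n_codons
        # per-tip codon states aligned to node ids
        self.tip_states = np.full((tree.n_nodes, self.L), MISSING, dtype=np.int64)
        row_of = {sid: i for i, sid in enumerate(alignment.ids)}
        for v in tree.tip_ids:
            self.tip_states[v] = alignment.codes[row_of[tree.labels[v]]]
        self.postorder = tree.postorder()
        self.preorder = tree.preorder()

    # -- passes -------------------------------------------------------------

    def _branch_factors(self, model: CodonModel, rates: np.ndarray) -> np.ndarray:
        """(N, L, 61) eigenvalue factors exp(eig * t_b * r_l) per branch."""
        t = self.tree.lengths  # (N,)
        return np.exp(
            model.eigvals[None, None, :]
            * (t[:, None] * np.asarray(rates)[None, :])[:, :, None]
        )

    def down_pass(self, model: CodonModel, rates: np.ndarray):
        """Post-order partial likelihoods.

        Returns (D, M, logscale) where D[v] is the scaled partial likelihood
        at node v (L, 61), M[v] the message P_v @ D_v sent from v to its
        parent, and logscale (L,) the accumulated per-site log scalers.
        """
        tree = self.tree
        n, L, S = tree.n_nodes, self.L, self.n_states
        E = self._branch_factors(model, rates)
        D = np.empty((n, L, S))
        M = np.zeros((n, L, S))
        logscale = np.zeros(L)
        U, V = model.U, model.V
        for v in self.postorder:
            if tree.is_tip(v):
                Dv = np.zeros((L, S))
                st = self.tip_states[v]
                obs = st != MISSING
                Dv[obs, st[obs]] = 1.0
                Dv[~obs, :] = 1.0
            else:
                Dv = np.ones((L, S))
                for c in tree.children[v]:
                    Dv *= M[c]
                scal = Dv.max(axis=1)
                scal[scal <= 0] = 1.0
                Dv /= scal[:, None]
                logscale += np.log(scal)
            D[v] = Dv
            if tree.parent[v] >= 0:
                # M_v(i) = sum_j P_ij(t_v, r_l) D_v(l, j)
                M[v] = ((Dv @ V.T) * E[v]) @ U.T
                np.clip(M[v], 0.0, None, out=M[v])
        return D, M, logscale

    def site_log_likelihoods(self, model: CodonModel, rates: np.ndarray) -> np.ndarray:
        D, _, logscale = self.down_pass(model, rates)
        lik = D[0] @ model.pi
        return np.log(np.maximum(lik, 1e-300)) + logscale

    def marginal_posteriors(self, model: CodonModel, rates: np.ndarray):
        """Marginal (empirical-Bayes) posterior codon distributions.

        Returns (probs, missing): probs is (N, L, 61), rows normalised to 1
        or all-zero where flagged missing; tips are point masses on their
        observed states.  A tip site is missing if unobserved; an internal
        site is missing only when every tip is missing at that site.
        """
        tree = self.tree
        n, L, S = tree.n_nodes, self.L, self.n_states
        D, M, _ = self.down_pass(model, rates)
        E = self._branch_factors(model, rates)
        U, V = model.U, model.V

        Up = np.empty((n, L, S))
        Up[0] = model.pi[None, :]
        for v in self.preorder:
            kids = tree.children[v]
            for c in kids:
                G = Up[v].copy()
                for s in kids:
                    if s != c:
                        G *= M[s]
                # U_c(j) = sum_i P_ij(t_c, r_l) G(l, i)
                Uc = ((G @ U) * E[c]) @ V
                np.clip(Uc, 0.0, None, out=Uc)
                scal = Uc.max(axis=1)
                scal[scal <= 0] = 1.0
                Up[c] = Uc / scal[:, None]

        probs = D * Up
        tot = probs.sum(axis=2)
        safe = tot > 0
        probs[safe] /= tot[safe][:, None]
        probs[~safe] = 0.0

        tip_missing = np.zeros((n, L), dtype=bool)
        for v in tree.tip_ids:
            tip_missing[v] = self.tip_states[v] == MISSING
        all_missing = np.ones(L, dtype=bool)
        for v in tree.tip_ids:
            all_missing &= tip_missing[v]
        missing = np.zeros((n, L), dtype=bool)
        missing[:, all_missing] = True
        for v in tree.tip_ids:
            missing[v] |= tip_missing[v]
        probs[missing] = 0.0
        # tips: exact point masses on observed states
        for v in tree.tip_ids:
            st = self.tip_states[v]
            obs = st != MISSING
            probs[v][obs] = 0.0
            probs[v][obs, st[obs]] = 1.0
        return probs, missing
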