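"""Codon-sequence simulation for the four benchmark scenarios.

Sequences evolve along a rooted tree under a normalised codon model: the
root sequence is drawn from the equilibrium frequencies and each branch
applies its transition matrix site by site.  Scenarios:

* ``Neutral`` -- one constant model on every branch;
* ``Convergent`` -- as Neutral, except that a chosen fraction of sites on
  the two focal branches evolves under a convergence regime: one target
  amino acid is drawn per replicate, the non-synonymous flux into its
  codons is boosted to a fixed share (default 90%) of each state's total
  non-synonymous outflow (relative synonymous codon frequencies are
  untouched), omega is raised (default 5) and the site rate doubled;
* ``Transfer`` -- Neutral plus a copy-and-paste overwrite of one focal tip
  by the other, emulating a horizontal transfer the analysis tree ignores;
* ``Random`` -- Neutral data analysed on a tip-label-shuffled tree.

True node states are returned alongside the alignment so reconstruction
accuracy and parameter degeneracy can be tested against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_model import CodonModel, build_rate_matrix, transition_matrix
from .genetic_code import NUCLEOTIDES, UNIVERSAL_CODE, GeneticCode
from .phylo_io import CodonAlignment, RootedTree, balanced_tree

#: default branch length of the benchmark tree, codon substitutions per
#: site; a free parameter of the benchmark design (see docs/methods.md)
DEFAULT_BRANCH_LENGTH = 0.5

#: position-specific nucleotide frequencies (A, C, G, T) used to build the
#: default codon equilibrium frequencies, F3x4-style; chosen once to mimic
#: a GC3-rich vertebrate housekeeping gene
_POSITION_NT_FREQS = (
    (0.28, 0.21, 0.32, 0.19),
    (0.31, 0.22, 0.18, 0.29),
    (0.20, 0.28, 0.30, 0.22),
)


def default_codon_frequencies(code: GeneticCode = UNIVERSAL_CODE) -> np.ndarray:
    """Deterministic non-uniform codon frequencies (F3x4 construction)."""
    pi = np.empty(code.n_codons)
    for i, codon in enumerate(code.codons):
        p = 1.0
        for pos, nt in enumerate(codon):
            p *= _POSITION_NT_FREQS[pos][NUCLEOTIDES.index(nt)]
        pi[i] = p
    return pi / pi.sum()


@dataclass
class SimulationScenario:
    """Parameters of one benchmark replicate."""

    scenario: str = "Neutral"      # Neutral | Convergent | Transfer | Random
    n_tips: int = 32
    branch_length: float = DEFAULT_BRANCH_LENGTH
    tree: RootedTree | None = None
    n_codons: int = 500
    omega: float = 0.2
    model_family: str = "empirical"  # empirical (synthetic matrix) | MG | GY
    kappa: float | None = None       # GY only
    pi: np.ndarray | None = None
    conv_fraction: float = 0.05
    conv_rate: float = 2.0
    conv_omega: float = 5.0
    boost_share: float = 0.9
    focal_tips: tuple[str, str] = ("t1", "t32")
    target_per_site: bool = False
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.conv_fraction <= 1.0:
            raise ValueError("conv_fraction must be in [0, 1]")
        if not 0.0 <= self.boost_share <= 1.0:
            raise ValueError("boost_share must be in [0, 1]")
        if self.omega <= 0 or self.conv_omega <= 0 or self.conv_rate <= 0:
            raise ValueError("rate parameters must be positive")

    def resolved_tree(self) -> RootedTree:
        if self.tree is not None:
            return self.tree
        return balanced_tree(self.n_tips, self.branch_length)

    def exchangeabilities(self) -> np.ndarray | None:
        if self.model_family == "empirical":
            from .codon_model import synthetic_exchangeabilities

            return synthetic_exchangeabilities(self.code)
        return None

    def _build(self, omega: float) -> CodonModel:
        pi = self.pi if self.pi is not None else default_codon_frequencies(self.code)
        return build_rate_matrix(
            self.model_family, pi, omega=omega, kappa=self.kappa,
            s=self.exchangeabilities(), code=self.code,
        )

    def base_model(self) -> CodonModel:
        return self._build(self.omega)

    def focal_branches(self, tree: RootedTree | None = None) -> tuple[int, int]:
        """Branch ids (terminal branches) of the two focal tips."""
        tree = tree or self.resolved_tree()
        ids = []
        for lab in self.focal_tips:
            matches = [v for v in tree.tip_ids if tree.labels[v] == lab]
            if not matches:
                raise ValueError(f"focal tip {lab!r} not in tree")
            ids.append(matches[0])
        return tuple(ids)


def convergent_rate_matrix(
    scenario: SimulationScenario, target_aa: int
) -> CodonModel:
    """Convergence-regime model: omega raised and the non-synonymous flux
    into the target amino acid's codons boosted to ``boost_share`` of each
    state's non-synonymous outflow.

    Boosting scales all entries into the target codons by a common per-row
    factor (relative frequencies among the target's synonymous codons are
    preserved and synonymous rates are untouched) and shrinks the
    remaining non-synonymous entries so each row's total non-synonymous
    outflow is unchanged.  Rows with no direct exchangeability into the
    target amino acid (possible under purely single-nucleotide-change
    models) receive their target flux in proportion to the target codons'
    equilibrium frequencies.  The matrix is then normalised like any other
    model.
    """
    code = scenario.code
    pi = (
        scenario.pi if scenario.pi is not None
        else default_codon_frequencies(code)
    )
    pi = np.asarray(pi, dtype=float) / np.sum(pi)
    base = scenario._build(scenario.conv_omega)
    Q = base.Q.copy()
    np.fill_diagonal(Q, 0.0)
    syn = code.synonymous_mask()
    target_cols = code.aa_of_codon == target_aa
    share = scenario.boost_share
    target_pi = np.where(target_cols, pi, 0.0)
    target_pi = target_pi / target_pi.sum()
    for i in range(code.n_codons):
        if code.aa_of_codon[i] == target_aa:
            continue
        nonsyn = ~syn[i]
        total = Q[i, nonsyn].sum()
        into_target = Q[i, target_cols].sum()
        if total <= 0:
            continue
        other = total - into_target
        if other <= 0:
            continue  # already funnelled entirely into the target
        if into_target > 0:
            Q[i, target_cols] *= share * total / into_target
        else:
            Q[i, target_cols] = share * total * target_pi[target_cols]
        others = nonsyn & ~target_cols
        Q[i, others] *= (1.0 - share) * total / other
    # renormalise to one expected codon substitution per site per unit time
    scale = float(pi @ Q.sum(axis=1))
    Q /= scale
    np.fill_diagonal(Q, -Q.sum(axis=1))
    model = CodonModel(
        family=scenario.model_family, pi=pi, Q=Q, omega=scenario.conv_omega,
        kappa=scenario.kappa, code=code,
    )
    from .codon_model import _attach_eigen

    _attach_eigen(model)
    return model


def _sample_children(
    parent_states: np.ndarray, cum_P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(parent_states.shape[0])
    rows = cum_P[parent_states]          # (L, 61)
    return (rows > u[:, None]).argmax(axis=1)


def _evolve(
    tree: RootedTree,
    model: CodonModel,
    L: int,
    rng: np.random.Generator,
    special: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Simulate codon states at every node; ``special`` optionally maps a
    branch id to (site mask, cumulative transition matrix) overriding the
    neutral process at those sites."""
    states = np.empty((tree.n_nodes, L), dtype=np.int64)
    states[0] = rng.choice(model.pi.size, size=L, p=model.pi)
    cum_cache: dict[float, np.ndarray] = {}
    for v in tree.preorder():
        for c in tree.children[v]:
            t = float(tree.lengths[c])
            if t not in cum_cache:
                cum_cache[t] = np.cumsum(transition_matrix(model, t), axis=1)
            child = _sample_children(states[v], cum_cache[t], rng)
            if special and c in special:
                mask, cum_special = special[c]
                if mask.any():
                    child[mask] = _sample_children(
                        states[v][mask], cum_special, rng
                    )
            states[c] = child
    return states


def _to_alignment(
    tree: RootedTree, states: np.ndarray, code: GeneticCode
) -> CodonAlignment:
    tips = tree.tip_ids
    ids = [tree.labels[v] for v in tips]
    codes = states[tips].astype(np.int16)
    return CodonAlignment(ids, codes, code)


def simulate_neutral(
    scenario: SimulationScenario, seed: int | np.random.Generator
) -> tuple[CodonAlignment, np.ndarray, RootedTree]:
    """Neutral codon evolution; returns (alignment, true node states, tree)."""
    rng = np.random.default_rng(seed)
    tree = scenario.resolved_tree()
    model = scenario.base_model()
    states = _evolve(tree, model, scenario.n_codons, rng)
    return _to_alignment(tree, states, scenario.code), states, tree


def simulate_convergent(
    scenario: SimulationScenario, seed: int | np.random.Generator
) -> tuple[CodonAlignment, np.ndarray, RootedTree, dict]:
    """Convergent-scenario simulation.

    Returns (alignment, true states, tree, truth) where ``truth`` records
    the convergent site indices and the target amino acid(s).
    """
    rng = np.random.default_rng(seed)
    tree = scenario.resolved_tree()
    focal = scenario.focal_branches(tree)
    from .search import is_independent

    if not is_independent(tree, focal, exclude_sisters=True):
        raise ValueError(f"focal branches {focal} are not independent")
    model = scenario.base_model()
    L = scenario.n_codons
    n_conv = int(round(scenario.conv_fraction * L))
    conv_sites = np.sort(rng.choice(L, size=n_conv, replace=False))
    mask = np.zeros(L, dtype=bool)
    mask[conv_sites] = True

    if scenario.target_per_site:
        targets = rng.integers(0, scenario.code.n_amino_acids, size=n_conv)
    else:
        targets = np.full(n_conv, rng.integers(0, scenario.code.n_amino_acids))

    special: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if n_conv:
        unique_targets = np.unique(targets)
        cums = {}
        for ta in unique_targets:
            conv_model = convergent_rate_matrix(scenario, int(ta))
            t_eff = scenario.conv_rate  # multiplies every focal branch length
            for b in focal:
                t = float(tree.lengths[b]) * t_eff
                cums[(int(ta), b)] = np.cumsum(
                    transition_matrix(conv_model, t), axis=1
                )
        if len(unique_targets) == 1:
            for b in focal:
                special[b] = (mask, cums[(int(unique_targets[0]), b)])
            states = _evolve(tree, model, L, rng, special)
        else:
            # per-site targets: evolve neutrally, then redraw focal branches
            states = _evolve(tree, model, L, rng)
            for b in focal:
                parent = tree.parent[b]
                for site, ta in zip(conv_sites, targets):
                    cum = cums[(int(ta), b)]
                    u = rng.random()
                    states[b, site] = int(
                        (cum[states[parent, site]] > u).argmax()
                    )
    else:
        states = _evolve(tree, model, L, rng)

    truth = {"conv_sites": conv_sites, "target_aa": targets, "focal": focal}
    return _to_alignment(tree, states, scenario.code), states, tree, truth


def apply_transfer(
    alignment: CodonAlignment, donor_tip: str, acceptor_tip: str
) -> CodonAlignment:
    """Copy-and-paste the donor tip sequence over the acceptor's."""
    codes = alignment.codes.copy()
    codes[alignment.ids.index(acceptor_tip)] = alignment.row(donor_tip)
    return CodonAlignment(list(alignment.ids), codes, alignment.code)


def shuffle_tree_labels(
    tree: RootedTree, seed: int | np.random.Generator
) -> RootedTree:
    """Uniformly permute tip labels; topology and lengths unchanged."""
    rng = np.random.default_rng(seed)
    tips = tree.tip_ids
    perm = rng.permutation(len(tips))
    labels = list(tree.labels)
    old = [tree.labels[v] for v in tips]
    for pos, v in enumerate(tips):
        labels[v] = old[perm[pos]]
    return RootedTree(
        tree.parent.copy(), [list(c) for c in tree.children],
        tree.lengths.copy(), labels,
    )
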