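"""Rooted trees and in-frame codon alignments.

A branch is named by its child node: node ids are assigned in a stable
preorder with the root as node 0, and branch *b* is the edge above node *b*
(b = 1..B, so B equals the number of non-root nodes).  The root carries no
branch and never enters a branch combination.  Branch lengths are read as
nucleotide substitutions per codon site and later rescaled to codon
substitutions per site from the reconstructed substitution probabilities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genetic_code import UNIVERSAL_CODE, GeneticCode

MISSING = -1  # missing codon state in alignments and posteriors


class TreeError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class RootedTree:
    """Rooted phylogeny with preorder node ids (root = 0)."""

    parent: np.ndarray            # (N,) parent node id; -1 for the root
    children: list[list[int]]     # (N,) child ids in input order
    lengths: np.ndarray           # (N,) branch length above each node; 0 at root
    labels: list[str | None]      # tip labels (required); internal optional
    _anc_sets: list[set[int]] | None = field(default=None, repr=False)

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def branches(self) -> np.ndarray:
        """Branch ids (== non-root node ids), ascending."""
        return np.arange(1, self.n_nodes)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tip_ids(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_ids]

    def node_name(self, node: int) -> str:
        lab = self.labels[node]
        return lab if lab is not None else f"N{node}"

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    # -- relationships ------------------------------------------------------

    def ancestors(self, node: int) -> set[int]:
        if self._anc_sets is None:
            anc: list[set[int]] = [set() for _ in range(self.n_nodes)]
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    anc[v] = anc[p] | {p}
            self._anc_sets = anc
        return self._anc_sets[node]

    def is_ancestor_of(self, a: int, b: int) -> bool:
        return a in self.ancestors(b)

    def are_sisters(self, a: int, b: int) -> bool:
        return a != b and self.parent[a] == self.parent[b]

    # -- output -------------------------------------------------------------

    def _newick_node(self, v: int) -> str:
        lab = self.labels[v] or ""
        if self.children[v]:
            inner = ",".join(self._newick_node(c) for c in self.children[v])
            body = f"({inner}){lab}"
        else:
            body = lab
        if self.parent[v] >= 0:
            body += f":{self.lengths[v]:.10g}"
        return body

    def to_newick(self) -> str:
        return self._newick_node(0) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    parent: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    ids: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        vid = len(parent)
        ids[id(node)] = vid
        parent.append(ids[id(node.parent_node)] if node.parent_node else -1)
        children.append([])
        if node.parent_node:
            children[ids[id(node.parent_node)]].append(vid)
        bl = node.edge.length
        lengths.append(0.0 if (node.parent_node is None or bl is None) else float(bl))
        if node.taxon is not None:
            labels.append(node.taxon.label)
        else:
            labels.append(node.label or None)
    tree = RootedTree(
        parent=np.asarray(parent),
        children=children,
        lengths=np.asarray(lengths, dtype=float),
        labels=labels,
    )
    if (tree.lengths < 0).any():
        raise TreeError("negative branch lengths are not allowed")
    return tree


def read_rooted_tree(newick_text: str) -> RootedTree:
    """Parse a rooted Newick tree; branch ids follow stable preorder.

    Raises
    ------
    TreeError
        if the root has fewer than two children (unrooted/degenerate input)
        or tip labels are duplicated.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        if "Multiple occurrences of the same taxa" in str(exc):
            raise TreeError(f"duplicate tip labels: {exc}") from exc
        raise TreeError(f"could not parse Newick input: {exc}") from exc
    tree = _from_dendropy(dtree)
    root_degree = len(tree.children[0])
    if root_degree < 2:
        raise TreeError(
            f"tree root has degree {root_degree}; a rooted tree needs >= 2 "
            "children at the root"
        )
    tips = tree.tip_labels
    if any(lab is None for lab in tips):
        raise TreeError("every tip must be labelled")
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise TreeError(f"duplicate tip labels: {dup}")
    return tree


def balanced_tree(n_tips: int, branch_length: float = 0.25) -> RootedTree:
    """Fully balanced rooted binary tree with uniform branch lengths.

    Tips are labelled t1..t{n_tips} in left-to-right order.  ``n_tips`` must
    be a power of two.
    """
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise TreeError("balanced_tree requires a power-of-two tip count")

    parent = [-1]
    children: list[list[int]] = [[]]
    n_tip_seen = 0
    labels: list[str | None] = [None]
    # breadth-first construction keeps the preorder contract simple to state,
    # but ids must be preorder: build recursively instead.
    counter = {"tip": 0}

    def grow(node: int, tips_below: int) -> None:
        nonlocal parent, children, labels
        if tips_below == 1:
            counter["tip"] += 1
            labels[node] = f"t{counter['tip']}"
            return
        for _ in range(2):
            cid = len(parent)
            parent.append(node)
            children.append([])
            labels.append(None)
            children[node].append(cid)
            grow(cid, tips_below // 2)

    grow(0, n_tips)
    _ = n_tip_seen
    lengths = np.full(len(parent), float(branch_length))
    lengths[0] = 0.0
    return RootedTree(np.asarray(parent), children, lengths, labels)


# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """In-frame codon alignment over the 61 sense codons.

    ``codes[s, l]`` is the codon index of sequence ``s`` at codon site ``l``,
    or ``MISSING`` for gaps, stop codons and ambiguous codons.
    """

    ids: list[str]
    codes: np.ndarray  # (n_seq, L) int16
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE, repr=False)

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.codes[self.ids.index(seq_id)]

    def to_fasta(self) -> str:
        out = []
        for sid, row in zip(self.ids, self.codes):
            seq = "".join(
                self.code.codons[c] if c != MISSING else "---" for c in row
            )
            out.append(f">{sid}\n{seq}")
        return "\n".join(out) + "\n"


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise AlignmentError("FASTA sequence data before first header")
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def read_codon_alignment(
    fasta_text: str, code: GeneticCode = UNIVERSAL_CODE
) -> CodonAlignment:
    """Read an in-frame FASTA alignment.

    Stop codons, ambiguous codons (any character outside ACGT) and gap
    codons become missing states.  Sequence lengths must be equal and
    divisible by 3.
    """
    records = _parse_fasta(fasta_text)
    if not records:
        raise AlignmentError("empty alignment")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise AlignmentError(f"sequence lengths differ: {sorted(lengths)}")
    (nt_len,) = lengths
    if nt_len % 3:
        raise AlignmentError(
            f"alignment length {nt_len} is not divisible by 3; in-frame "
            "codon sequences are required"
        )
    ids = [name for name, _ in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in alignment")
    L = nt_len // 3
    codes = np.full((len(records), L), MISSING, dtype=np.int16)
    for s, (_, seq) in enumerate(records):
        seq = seq.upper()
        for l in range(L):
            codon = seq[3 * l : 3 * l + 3]
            codes[s, l] = code.codon_index.get(codon, MISSING)
    return CodonAlignment(ids, codes, code)


def check_labels(tree: RootedTree, alignment: CodonAlignment) -> None:
    """Require that alignment ids and tree tip labels match exactly."""
    tips = set(tree.tip_labels)
    seqs = set(alignment.ids)
    if tips != seqs:
        only_tree = sorted(tips - seqs)
        only_aln = sorted(seqs - tips)
        raise AlignmentError(
            "tree tips and alignment ids differ; "
            f"only in tree: {only_tree}; only in alignment: {only_aln}"
        )
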