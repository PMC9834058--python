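"""Universal genetic code with a fixed codon indexing shared by every module.

The 61 sense codons are ordered lexicographically by nucleotide (AAA, AAC,
AAG, ... TTT; alphabet ACGT, with T written as T rather than U) and indexed
0..60.  Amino acids are ordered alphabetically by one-letter code and indexed
0..19.  This bijection is the contract that external posterior tables and the
bundled exchangeability-file format are aligned against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: one-letter amino acid codes in the canonical (alphabetical) order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: largest number of codons encoding one amino acid (Leu, Ser, Arg)
MAX_SYNONYMS = 6


def _universal_table() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table)


@dataclass(frozen=True)
class GeneticCode:
    """Codon/amino-acid bookkeeping for one genetic code.

    Only the universal code is constructed by default.  The class is plain
    data so alternative codes could be instantiated, but none are tested.
    """

    codons: tuple[str, ...]
    aa_of_codon: np.ndarray        # (61,) amino-acid index per codon
    aa_groups: tuple[np.ndarray, ...]  # per amino acid, sorted codon indices
    slot_of_codon: np.ndarray      # (61,) position of codon within its group
    codon_index: dict[str, int] = field(repr=False)

    @classmethod
    def universal(cls) -> "GeneticCode":
        fwd = _universal_table()
        codons = tuple(sorted(fwd))  # lexicographic over ACGT; stops absent
        if len(codons) != 61:
            raise AssertionError("universal code must have 61 sense codons")
        codon_index = {c: i for i, c in enumerate(codons)}
        aa_of_codon = np.array([AMINO_ACIDS.index(fwd[c]) for c in codons])
        groups = tuple(
            np.flatnonzero(aa_of_codon == a) for a in range(len(AMINO_ACIDS))
        )
        slot = np.empty(61, dtype=np.int64)
        for g in groups:
            slot[g] = np.arange(len(g))
        return cls(codons, aa_of_codon, groups, slot, codon_index)

    # -- derived tables (computed lazily, cached on the instance dict is not
    #    possible for a frozen dataclass, so recompute: all are cheap) -------

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_amino_acids(self) -> int:
        return len(self.aa_groups)

    def synonymous_mask(self) -> np.ndarray:
        """(61, 61) boolean: codon pair encodes the same amino acid."""
        return self.aa_of_codon[:, None] == self.aa_of_codon[None, :]

    def aa_indicator(self) -> np.ndarray:
        """(61, 20) one-hot map from codon index to amino-acid index."""
        ind = np.zeros((self.n_codons, self.n_amino_acids))
        ind[np.arange(self.n_codons), self.aa_of_codon] = 1.0
        return ind

    def single_nt_mask(self) -> np.ndarray:
        """(61, 61) boolean: codons differ at exactly one position."""
        arr = np.array([[NUCLEOTIDES.index(n) for n in c] for c in self.codons])
        diff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        return diff == 1

    def transition_mask(self) -> np.ndarray:
        """(61, 61) boolean: single-nucleotide change that is a transition
        (A<->G or C<->T); False everywhere else."""
        arr = np.array([[NUCLEOTIDES.index(n) for n in c] for c in self.codons])
        diff = arr[:, None, :] != arr[None, :, :]
        single = diff.sum(axis=2) == 1
        purine = np.isin(arr, [0, 2])  # A, G
        same_class = purine[:, None, :] == purine[None, :, :]
        ts_at_diff = (diff & same_class).sum(axis=2) == 1
        return single & ts_at_diff

    def target_nt_index(self) -> np.ndarray:
        """(61, 61) int: for single-nucleotide-change pairs (i, j), the index
        in ``NUCLEOTIDES`` of the nucleotide gained in j; -1 elsewhere."""
        arr = np.array([[NUCLEOTIDES.index(n) for n in c] for c in self.codons])
        out = np.full((61, 61), -1, dtype=np.int64)
        single = self.single_nt_mask()
        for i, j in zip(*np.nonzero(single)):
            pos = int(np.flatnonzero(arr[i] != arr[j])[0])
            out[i, j] = arr[j, pos]
        return out


#: module-level singleton used as the default everywhere
UNIVERSAL_CODE = GeneticCode.universal()
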