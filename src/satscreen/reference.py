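"""Reference open reading frames and standard-code translation.

A screen operates on a single protein-coding ORF: start codon, a run of
sense codons, and one terminator.  Protein positions are 1-based; position
1 is the initiator methionine and position ``L`` is the last sense codon
(the terminator is not a protein position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

#: the 20 proteinogenic amino acids, alphabetical
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

_VALID_NT = frozenset("ACGT")


def translate_orf(nt_seq: str) -> str:
    """Translate a coding nucleotide sequence with the standard genetic code.

    A single terminal stop codon is stripped from the product; an internal
    stop raises, since the sequence would not encode a single ORF.

    Parameters
    ----------
    nt_seq
        Upper-case A/C/G/T string whose length is a multiple of 3.

    Returns
    -------
    str
        One-letter amino-acid string (terminal stop removed if present).
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} is not a multiple of 3")
    bad = set(nt_seq) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    aas = []
    n_codons = len(nt_seq) // 3
    for i in range(n_codons):
        codon = nt_seq[3 * i : 3 * i + 3]
        aa = CODON_TO_AA[codon]
        if aa == "*":
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
            break
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class ReferenceORF:
    """A validated reference ORF with its codon grid and translation.

    Invariants enforced at construction: length divisible by 3, A/C/G/T
    alphabet, initiator ATG, terminal stop, no internal stop.  The protein
    length ``L`` equals ``len(nt_seq) / 3 - 1``.
    """

    name: str
    nt_seq: str
    codons: tuple[str, ...] = field(init=False, repr=False)
    protein: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        nt = self.nt_seq.upper()
        object.__setattr__(self, "nt_seq", nt)
        protein = translate_orf(nt)  # raises on bad length/char/internal stop
        codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
        if codons[0] != "ATG":
            raise ValueError(f"ORF must begin with ATG, got {codons[0]}")
        if codons[-1] not in STOP_CODONS:
            raise ValueError(f"ORF must end with a stop codon, got {codons[-1]}")
        object.__setattr__(self, "codons", codons)
        object.__setattr__(self, "protein", protein)

    @property
    def length_aa(self) -> int:
        """Protein length L (terminator codon excluded)."""
        return len(self.protein)

    def codon_at(self, aa_pos: int) -> str:
        """Reference codon at 1-based protein position ``aa_pos``."""
        if not 1 <= aa_pos <= self.length_aa:
            raise IndexError(f"protein position {aa_pos} outside 1..{self.length_aa}")
        return self.codons[aa_pos - 1]

    def aa_at(self, aa_pos: int) -> str:
        return self.protein[aa_pos - 1]

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "ReferenceORF":
        """Load the single record of a FASTA file as a reference ORF."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
        rec = records[0]
        return cls(name=name or rec.id, nt_seq=str(rec.seq).upper())

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.nt_seq), 60):
                fh.write(self.nt_seq[i : i + 60] + "\n")
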