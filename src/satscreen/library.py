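"""Saturation-mutagenesis library design.

At every protein position except the initiator (and never the terminator
codon), the design places the 19 missense substitutions plus one nonsense
substitution — 20 variants per position.  Each substitution is realised by
a single designated codon taken from an embedded human codon-usage
preference table, mirroring how synthesis vendors pick one codon per
amino-acid change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .reference import AA_ALPHABET, CODON_TO_AA, ReferenceORF

#: Most-frequent human codon per amino acid (codon-usage preference), with
#: TGA as the designated nonsense codon.  Fixed so designs are stable
#: across runs and machines.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC",
    "C": "TGC",
    "D": "GAC",
    "E": "GAG",
    "F": "TTC",
    "G": "GGC",
    "H": "CAC",
    "I": "ATC",
    "K": "AAG",
    "L": "CTG",
    "M": "ATG",
    "N": "AAC",
    "P": "CCC",
    "Q": "CAG",
    "R": "AGA",
    "S": "AGC",
    "T": "ACC",
    "V": "GTG",
    "W": "TGG",
    "Y": "TAC",
    "*": "TGA",
}

#: column order of the library TSV
LIBRARY_COLUMNS = ["variant_id", "aa_pos", "ref_aa", "alt_aa", "ref_codon", "alt_codon", "name"]

_NAME_RE = re.compile(r"^([A-Y])(\d+)([A-Y*])$")


def choose_codon(alt_aa: str, ref_codon: str) -> str:
    """Designated codon for ``alt_aa`` from the embedded usage table.

    ``ref_codon`` is accepted for interface symmetry with designs that
    minimise nucleotide changes; the embedded single-codon table ignores it.
    """
    try:
        return PREFERRED_CODON[alt_aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {alt_aa!r}") from None


@dataclass(frozen=True)
class CodonVariant:
    """A single designed amino-acid substitution at one codon."""

    aa_pos: int
    ref_aa: str
    alt_aa: str
    ref_codon: str
    alt_codon: str

    def __post_init__(self) -> None:
        if self.alt_aa == self.ref_aa:
            raise ValueError(f"alt_aa equals ref_aa ({self.ref_aa}) at {self.aa_pos}")
        if CODON_TO_AA[self.alt_codon] != self.alt_aa:
            raise ValueError(
                f"alt_codon {self.alt_codon} does not encode {self.alt_aa}"
            )

    @property
    def name(self) -> str:
        return variant_name(self)


def variant_name(variant: CodonVariant) -> str:
    """Protein-change name, e.g. ``T790M`` or ``R675*`` for nonsense."""
    return f"{variant.ref_aa}{variant.aa_pos}{variant.alt_aa}"


def parse_variant_name(name: str) -> tuple[int, str, str]:
    """Parse ``T790M``-style names into ``(aa_pos, ref_aa, alt_aa)``.

    Exact inverse of :func:`variant_name` on designed variants.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable variant name {name!r}")
    ref_aa, pos, alt_aa = m.groups()
    return int(pos), ref_aa, alt_aa


@dataclass(frozen=True)
class VariantLibrary:
    """The full designed variant set over a reference ORF.

    ``variants`` is ordered by position, then alternate amino acid
    alphabetically with the nonsense '*' last — 20 per mutagenized position.
    """

    orf: ReferenceORF
    variants: tuple[CodonVariant, ...]
    positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[CodonVariant]:
        return iter(self.variants)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variants]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": i + 1,
                "aa_pos": v.aa_pos,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "ref_codon": v.ref_codon,
                "alt_codon": v.alt_codon,
                "name": v.name,
            }
            for i, v in enumerate(self.variants)
        ]
        return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def mutant_orf(self, variant: CodonVariant) -> str:
        """Full-length mutant nucleotide sequence for one variant."""
        i = 3 * (variant.aa_pos - 1)
        nt = self.orf.nt_seq
        return nt[:i] + variant.alt_codon + nt[i + 3 :]

    def write_mutant_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for v in self.variants:
                fh.write(f">{v.name}\n{self.mutant_orf(v)}\n")


def _alt_order(ref_aa: str) -> list[str]:
    # 19 missense alphabetically, then the nonsense substitution
    return [aa for aa in AA_ALPHABET if aa != ref_aa] + ["*"]


def enumerate_saturation_library(
    orf: ReferenceORF, positions: Iterable[int] | None = None
) -> VariantLibrary:
    """Enumerate the designed library: 19 missense + 1 nonsense per position.

    Positions default to ``2..L`` — the initiator is never mutagenized and
    the terminator codon is not a protein position.

    Parameters
    ----------
    orf
        Validated reference ORF.
    positions
        Optional subset of protein positions to mutagenize.
    """
    L = orf.length_aa
    if positions is None:
        pos_list = list(range(2, L + 1))
    else:
        pos_list = sorted(set(int(p) for p in positions))
        bad = [p for p in pos_list if not 2 <= p <= L]
        if bad:
            raise ValueError(f"positions outside 2..{L}: {bad}")
    variants = []
    for pos in pos_list:
        ref_codon = orf.codon_at(pos)
        ref_aa = orf.aa_at(pos)
        for alt_aa in _alt_order(ref_aa):
            variants.append(
                CodonVariant(
                    aa_pos=pos,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    ref_codon=ref_codon,
                    alt_codon=choose_codon(alt_aa, ref_codon),
                )
            )
    return VariantLibrary(orf=orf, variants=tuple(variants), positions=tuple(pos_list))


def read_library(path: str | Path) -> pd.DataFrame:
    """Read a designed-library TSV into a DataFrame (``LIBRARY_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t", dtype={"aa_pos": int})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    return df


def parse_position_range(text: str) -> list[int]:
    """Parse ``"2-1210"`` or ``"790"`` or ``"5-10,790"`` into positions."""
    out: list[int] = []
    for part in text.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return out
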