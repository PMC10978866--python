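"""Protein domain maps: named 1-based closed intervals for regional summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.name}: [{self.start}, {self.end}]")

    def __contains__(self, aa_pos: int) -> bool:
        return self.start <= aa_pos <= self.end


@dataclass(frozen=True)
class DomainMap:
    """Ordered list of named regions; regions may overlap or leave gaps."""

    regions: tuple[Region, ...]

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def regions_containing(self, aa_pos: int) -> list[Region]:
        return [r for r in self.regions if aa_pos in r]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.name, r.start, r.end) for r in self.regions],
            columns=["region", "start", "end"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainMap":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DomainMap":
        return cls(
            tuple(
                Region(str(row.region), int(row.start), int(row.end))
                for row in df.itertuples()
            )
        )


def egfr_domain_map() -> DomainMap:
    """Default EGFR domain map (1-based closed intervals on the 1210-aa protein).

    Dimerization domains II and IV, the transmembrane helix, the tyrosine
    kinase domain and the C-terminal tail — the regions where resistance
    variants concentrate in an EGFR inhibitor screen.
    """
    return DomainMap(
        (
            Region("domain_II", 189, 333),
            Region("domain_IV", 504, 644),
            Region("TM", 645, 668),
            Region("kinase", 718, 964),
            Region("C_terminal", 979, 1210),
        )
    )
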