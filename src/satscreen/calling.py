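"""Codon-level variant calling from aligned shotgun read pairs.

Each read pair interrogates only the codons it fully covers, so a pair is
classified rather than genotyped: it either supports wildtype over its
covered codons, carries exactly one amino-acid-changing codon (attributable
to a single library variant), carries several (uninterpretable for a
single-variant library), or is discarded by quality/coverage filters.
Counts per designed variant are the number of single-variant pairs
matching it; wildtype-supporting coverage is tracked per codon so that
frequencies can use per-position denominators.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .reference import CODON_TO_AA, ReferenceORF

logger = logging.getLogger(__name__)

WILDTYPE = "wildtype_supporting"
SINGLE = "single_variant"
MULTI = "multi_variant"
DISCARDED = "discarded"
CLASSIFICATIONS = (WILDTYPE, SINGLE, MULTI, DISCARDED)

DEFAULT_QUALITY_FLOOR = 10  # end trimming
DEFAULT_MIN_BASE_QUALITY = 20  # codon evaluation


@dataclass(frozen=True)
class MateAlignment:
    """One aligned mate: 0-based reference start, bases and qualities."""

    ref_start: int
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """A pair (or orphan) of match-only alignments on the same reference."""

    pair_id: str
    mates: tuple[MateAlignment, ...]
    indel_rejected: bool = False


@dataclass(frozen=True)
class VariantCall:
    """Classification of one read pair over the codons it fully covers."""

    classification: str
    variant: tuple[int, str] | None = None  # (aa_pos, alt_aa)
    covered_codons: tuple[int, ...] = ()
    silent: tuple[tuple[int, str], ...] = ()  # (aa_pos, observed codon)


def trim_read(mate: MateAlignment, quality_floor: int) -> MateAlignment:
    """Clip low-quality bases from both read ends (end trimming only).

    The longest prefix and suffix in which every base is below
    ``quality_floor`` are removed and the reference start adjusted;
    interior low-quality bases are retained (they are filtered per codon
    later).  May return an empty mate.
    """
    quals = np.asarray(mate.quals)
    keep = np.nonzero(quals >= quality_floor)[0]
    if keep.size == 0:
        return MateAlignment(ref_start=mate.ref_start, seq="", quals=())
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    return MateAlignment(
        ref_start=mate.ref_start + lo,
        seq=mate.seq[lo:hi],
        quals=tuple(mate.quals[lo:hi]),
    )


def call_codon_variants(
    pair: ReadPair,
    orf: ReferenceORF,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> VariantCall:
    """Classify one read pair against the reference codon grid.

    After end-trimming, only codons whose three bases are all covered (by
    either mate) at base quality >= ``min_base_quality`` are evaluated.
    Bases where the mates overlap and disagree discard the pair.  A
    mismatched codon translating to a different amino acid (or stop) is a
    variant codon; one translating to the same amino acid is silent —
    recorded but ignored for classification.  The terminator codon is not
    evaluated.
    """
    if pair.indel_rejected:
        return VariantCall(classification=DISCARDED)
    ref_len = len(orf.nt_seq)
    merged: dict[int, tuple[str, int]] = {}
    for mate in pair.mates:
        if mate.ref_start < 0 or mate.ref_start + len(mate) > ref_len:
            raise ValueError(
                f"pair {pair.pair_id}: alignment [{mate.ref_start}, "
                f"{mate.ref_start + len(mate)}) outside ORF of length {ref_len}"
            )
        trimmed = trim_read(mate, quality_floor)
        for i, (base, q) in enumerate(zip(trimmed.seq, trimmed.quals)):
            p = trimmed.ref_start + i
            if p in merged:
                prev_base, prev_q = merged[p]
                if prev_base != base:
                    return VariantCall(classification=DISCARDED)
                merged[p] = (prev_base, max(prev_q, q))
            else:
                merged[p] = (base, q)

    L = orf.length_aa  # sense codons only; terminator not evaluated
    covered: list[int] = []
    variants: list[tuple[int, str]] = []
    silent: list[tuple[int, str]] = []
    if merged:
        first_codon = max(1, min(merged) // 3 + 1)
        last_codon = min(L, (max(merged)) // 3 + 1)
        for aa_pos in range(first_codon, last_codon + 1):
            base0 = 3 * (aa_pos - 1)
            triplet = [merged.get(base0 + k) for k in range(3)]
            if any(t is None or t[1] < min_base_quality for t in triplet):
                continue
            covered.append(aa_pos)
            obs = "".join(t[0] for t in triplet)  # type: ignore[index]
            if obs == orf.codon_at(aa_pos):
                continue
            obs_aa = CODON_TO_AA[obs]
            if obs_aa == orf.aa_at(aa_pos):
                silent.append((aa_pos, obs))
            else:
                variants.append((aa_pos, obs_aa))

    if not covered:
        return VariantCall(classification=DISCARDED)
    if len(variants) == 0:
        cls, var = WILDTYPE, None
    elif len(variants) == 1:
        cls, var = SINGLE, variants[0]
    else:
        cls, var = MULTI, None
    return VariantCall(
        classification=cls,
        variant=var,
        covered_codons=tuple(covered),
        silent=tuple(silent),
    )


def read_sam_pairs(path: str | Path, reference_name: str | None = None) -> Iterator[ReadPair]:
    """Group a SAM file's alignments into read pairs by query name.

    Only match-only alignments (CIGAR M/=/X with optional soft clips) are
    accepted; alignments containing indels are rejected with a warning and
    their pairs flagged so the caller classifies them as discarded.
    Unmapped records are skipped.
    """
    groups: "OrderedDict[str, list]" = OrderedDict()
    n_indel = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if reference_name is not None and aln.reference_name != reference_name:
                continue
            groups.setdefault(aln.query_name, []).append(aln)
    for qname, alns in groups.items():
        mates = []
        rejected = False
        for aln in alns:
            ops = {op for op, _ in (aln.cigartuples or [])}
            # 0=M, 7==, 8=X, 4=S are substitution-only; anything else is an indel/skip
            if not ops <= {0, 4, 7, 8}:
                rejected = True
                n_indel += 1
                continue
            quals = aln.query_alignment_qualities
            mates.append(
                MateAlignment(
                    ref_start=aln.reference_start,
                    seq=(aln.query_alignment_sequence or "").upper(),
                    quals=tuple(quals) if quals is not None else tuple([93] * len(aln.query_alignment_sequence or "")),
                )
            )
        yield ReadPair(pair_id=qname, mates=tuple(mates), indel_rejected=rejected)
    if n_indel:
        logger.warning("rejected %d indel-containing alignments (substitution-only scope)", n_indel)


@dataclass
class TallyResult:
    """Per-sample deconvolution output: counts, depths and QC totals."""

    sample: str
    counts: pd.Series  # designed variant name -> single_variant pair count
    undesigned: pd.Series  # observed non-designed calls, name -> count
    wildtype_depth: pd.Series  # aa_pos -> wildtype-supporting pair depth
    qc: dict[str, int]  # classification totals, plus "total"

    def to_counts_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"name": self.counts.index, "sample": self.sample, "count": self.counts.values}
        )
        df.to_csv(path, sep="\t", index=False)

    def to_qc_tsv(self, totals_path: str | Path, depth_path: str | Path) -> None:
        pd.DataFrame(
            {"classification": list(self.qc), "count": list(self.qc.values())}
        ).to_csv(totals_path, sep="\t", index=False)
        pd.DataFrame(
            {"aa_pos": self.wildtype_depth.index, "wildtype_depth": self.wildtype_depth.values}
        ).to_csv(depth_path, sep="\t", index=False)


def tally_counts(
    pairs: Iterable[ReadPair],
    orf: ReferenceORF,
    library: pd.DataFrame,
    sample: str = "sample",
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> TallyResult:
    """Tally per-variant molecule counts for one sample's read pairs.

    A designed variant's count is the number of single-variant pairs
    matching its ``(aa_pos, alt_aa)``; calls outside the designed set are
    tallied separately as undesigned.  Wildtype depth at a codon counts
    pairs (wildtype-supporting or single-variant) that fully cover it and
    match the reference there.  Multi-variant and discarded pairs appear
    only in the QC totals.
    """
    designed = {
        (int(r.aa_pos), str(r.alt_aa)): str(r.name) for r in library.itertuples()
    }
    counts: Counter[str] = Counter()
    undesigned: Counter[str] = Counter()
    depth = np.zeros(orf.length_aa + 1, dtype=np.int64)  # index = aa_pos
    qc = {c: 0 for c in CLASSIFICATIONS}
    total = 0
    for pair in pairs:
        total += 1
        call = call_codon_variants(pair, orf, quality_floor, min_base_quality)
        qc[call.classification] += 1
        if call.classification == SINGLE:
            assert call.variant is not None
            key = call.variant
            if key in designed:
                counts[designed[key]] += 1
            else:
                undesigned[f"{orf.aa_at(key[0])}{key[0]}{key[1]}"] += 1
            for aa_pos in call.covered_codons:
                if aa_pos != key[0]:
                    depth[aa_pos] += 1
        elif call.classification == WILDTYPE:
            for aa_pos in call.covered_codons:
                depth[aa_pos] += 1
    qc["total"] = total
    count_series = pd.Series(
        [counts.get(n, 0) for n in library["name"]], index=pd.Index(library["name"], name="name"), dtype=int
    )
    undesigned_series = pd.Series(dict(undesigned), dtype=int).sort_index()
    depth_series = pd.Series(
        depth[1:], index=pd.RangeIndex(1, orf.length_aa + 1, name="aa_pos")
    )
    return TallyResult(
        sample=sample,
        counts=count_series,
        undesigned=undesigned_series,
        wildtype_depth=depth_series,
        qc=qc,
    )


def combine_tallies(tallies: Iterable[TallyResult]) -> "ScreenCounts":
    """Assemble per-sample tallies into one multi-sample count container."""
    from .enrichment import ScreenCounts

    tallies = list(tallies)
    counts = pd.DataFrame({t.sample: t.counts for t in tallies}).fillna(0).astype(int)
    depth = pd.DataFrame({t.sample: t.wildtype_depth for t in tallies})
    qc = {t.sample: t.qc for t in tallies}
    return ScreenCounts(counts=counts, wildtype_depth=depth, qc=qc)
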