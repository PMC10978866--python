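"""Enrichment scoring for pooled screens.

A variant's abundance change between a reference sample (plasmid pool or
early split) and a drug-treated sample is summarised as a log2 fold change
of relative frequencies (LFC), then standardised across all covered
variants into a z-score.  A variant is called significant when its z-score
reaches the screen's threshold (1.5 by default), so significance is always
relative to the behaviour of the pool as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .library import parse_variant_name

#: column order of the enrichment TSV
ENRICHMENT_COLUMNS = ["name", "aa_pos", "ref_aa", "alt_aa", "lfc", "z", "covered", "significant"]

DEFAULT_Z_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ScreenCounts:
    """Per-variant molecule tallies across the samples of one screen.

    ``counts`` is indexed by variant name with one integer column per
    sample.  ``wildtype_depth`` (optional, produced by read deconvolution)
    holds per-position wildtype-supporting pair depth, one column per
    sample, and enables per-codon frequency denominators.
    """

    counts: pd.DataFrame
    wildtype_depth: pd.DataFrame | None = None
    qc: dict | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample(self, name: str) -> pd.Series:
        return self.counts[name]

    @classmethod
    def from_samples(cls, samples: dict[str, pd.Series], **kw) -> "ScreenCounts":
        df = pd.DataFrame(samples).fillna(0).astype(int)
        return cls(counts=df, **kw)

    def to_tsv(self, path: str | Path) -> None:
        """Write long-format ``name  sample  count``."""
        long = (
            self.counts.rename_axis("name")
            .reset_index()
            .melt(id_vars="name", var_name="sample", value_name="count")
        )
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreenCounts":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot_table(
            index="name", columns="sample", values="count", fill_value=0, aggfunc="sum"
        ).astype(int)
        wide.columns.name = None
        # preserve first-appearance order of variants and samples
        wide = wide.reindex(index=long["name"].drop_duplicates(), columns=long["sample"].drop_duplicates())
        return cls(counts=wide)


def _positions_from_names(names: Iterable[str]) -> pd.Series:
    return pd.Series({n: parse_variant_name(n)[0] for n in names})


def compute_lfc(
    counts: ScreenCounts,
    reference_sample: str,
    treated_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    per_position: bool | None = None,
) -> pd.Series:
    """Per-variant log2 fold change of relative frequency, treated vs reference.

    ``LFC_v = log2((c_trt,v + p) / N_trt) - log2((c_ref,v + p) / N_ref)``.

    The denominator ``N`` is the sample total by default.  When the counts
    carry per-position wildtype depths (and ``per_position`` is not
    disabled), ``N`` is instead computed per codon as the sum of variant
    counts at that codon plus its wildtype depth, which removes
    fragment-coverage bias along the ORF.

    Zero counts with ``pseudocount=0`` yield ``-inf``/``nan`` entries; the
    caller marks those variants uncovered.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    for s in (reference_sample, treated_sample):
        if s not in counts.samples:
            raise KeyError(f"sample {s!r} not in counts ({counts.samples})")
    if per_position is None:
        per_position = counts.wildtype_depth is not None

    c_ref = counts.sample(reference_sample).astype(float)
    c_trt = counts.sample(treated_sample).astype(float)

    if per_position:
        if counts.wildtype_depth is None:
            raise ValueError("per-position denominators require wildtype depths")
        pos = _positions_from_names(counts.counts.index)
        denom = {}
        for s, c in ((reference_sample, c_ref), (treated_sample, c_trt)):
            per_pos_variant = c.groupby(pos).sum()
            wt = counts.wildtype_depth[s].reindex(per_pos_variant.index).fillna(0)
            denom[s] = (per_pos_variant + wt).reindex(pos.values).to_numpy()
        n_ref = denom[reference_sample]
        n_trt = denom[treated_sample]
    else:
        n_ref = float(c_ref.sum())
        n_trt = float(c_trt.sum())
    if np.any(np.asarray(n_ref) == 0) or np.any(np.asarray(n_trt) == 0):
        raise ValueError("zero denominator in LFC computation")

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((c_trt + pseudocount) / n_trt) - np.log2((c_ref + pseudocount) / n_ref)
    lfc.name = "lfc"
    return lfc


def compute_zscores(
    lfc: pd.Series, covered: pd.Series | None = None, robust: bool = False
) -> pd.Series:
    """Standardise LFCs into z-scores over the covered variants.

    Plain mean and sample standard deviation (n-1) by default, so the
    covered z-scores have mean 0 and SD 1 exactly by construction.  The
    robust alternative uses median and scaled MAD and does not have that
    property.  Uncovered variants get NaN.
    """
    if covered is None:
        covered = lfc.notna() & np.isfinite(lfc)
    covered = covered & lfc.notna() & np.isfinite(lfc)
    vals = lfc[covered]
    if len(vals) < 2:
        raise ValueError("need at least 2 covered variants with finite LFC")
    if robust:
        center = vals.median()
        scale = (vals - center).abs().median() * 1.4826
    else:
        center = vals.mean()
        scale = vals.std(ddof=1)
    if scale == 0:
        raise ValueError("zero spread among covered LFCs; z-scores undefined")
    z = (lfc - center) / scale
    z[~covered] = np.nan
    z.name = "z"
    return z


def call_significant(z: pd.Series, threshold: float = DEFAULT_Z_THRESHOLD) -> set[str]:
    """Variants whose z-score meets the significance threshold (z >= threshold)."""
    return set(z.index[z >= threshold])


def coverage_stats(
    counts: ScreenCounts,
    library: pd.DataFrame,
    min_count: int = 1,
    reference_sample: str | None = None,
) -> tuple[int, float]:
    """Number and fraction of designed variants detected in the reference sample."""
    if len(library) == 0:
        raise ValueError("empty designed library")
    if reference_sample is None:
        reference_sample = counts.samples[0]
    c = counts.sample(reference_sample).reindex(library["name"]).fillna(0)
    n_covered = int((c >= min_count).sum())
    return n_covered, n_covered / len(library)


def tail_summary(
    z: pd.Series,
    enrich_thresholds: Iterable[float] = (2, 3, 4),
    abs_thresholds: Iterable[float] = (2, 3),
) -> dict:
    """Tail statistics of the z distribution over covered variants.

    Returns counts of variants strictly above each enrichment threshold and
    the fraction with |z| strictly below each absolute threshold.
    """
    vals = z.dropna()
    n = len(vals)
    counts_above = {float(t): int((vals > t).sum()) for t in enrich_thresholds}
    frac_below = {float(t): float((vals.abs() < t).mean()) if n else float("nan") for t in abs_thresholds}
    return {"n": n, "counts_above": counts_above, "frac_below_abs": frac_below}


def score_screen(
    counts: ScreenCounts,
    library: pd.DataFrame,
    reference_sample: str,
    treated_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_count: int = 1,
    robust: bool = False,
    per_position: bool | None = None,
) -> pd.DataFrame:
    """Full enrichment table for one screen: LFC, z, coverage and significance.

    A designed variant is covered when its reference-sample count reaches
    ``min_count`` and its LFC is finite; z-scores are computed over covered
    variants only.  Designed variants absent from the count table get count
    0 in every sample.
    """
    full = counts.counts.reindex(library["name"]).fillna(0).astype(int)
    cc = ScreenCounts(counts=full, wildtype_depth=counts.wildtype_depth)
    lfc = compute_lfc(cc, reference_sample, treated_sample, pseudocount, per_position)
    c_ref = cc.sample(reference_sample)
    covered = (c_ref >= min_count) & lfc.notna() & np.isfinite(lfc)
    z = compute_zscores(lfc, covered, robust=robust)
    table = library[["name", "aa_pos", "ref_aa", "alt_aa"]].copy()
    table = table.set_index("name")
    table["lfc"] = lfc
    table["z"] = z
    table["covered"] = covered
    table["significant"] = z.ge(z_threshold).fillna(False)
    return table.reset_index()[ENRICHMENT_COLUMNS]


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    # distinguish missing z/lfc from 0 with an explicitly empty field
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_enrichment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["covered"] = df["covered"].astype(bool)
    df["significant"] = df["significant"].astype(bool)
    return df
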