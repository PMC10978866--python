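"""Aggregate views of an enrichment table.

Position x substitution matrix, per-position and per-domain average
z-scores, cysteine-substitution enrichment, and overlap with a patient
mutation catalog.  Missing cells (uncovered or undesigned substitutions)
are kept distinct from z = 0 throughout: they are NaN in memory and empty
fields in TSV output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .domains import DomainMap
from .library import parse_variant_name
from .reference import AA_ALPHABET, ReferenceORF

logger = logging.getLogger(__name__)

MATRIX_COLUMNS = list(AA_ALPHABET) + ["*"]


def substitution_matrix(enrichment: pd.DataFrame, orf: ReferenceORF | int) -> pd.DataFrame:
    """Position x substitution matrix of z-scores.

    Rows are protein positions 1..L, columns the 20 amino acids plus '*';
    cells hold the z-score of the covered designed variant at that (pos,
    alt) and are NaN where uncovered or undesigned — including every
    (pos, reference residue) cell.
    """
    L = orf if isinstance(orf, int) else orf.length_aa
    mat = pd.DataFrame(
        np.nan,
        index=pd.RangeIndex(1, L + 1, name="aa_pos"),
        columns=MATRIX_COLUMNS,
    )
    placed = enrichment[enrichment["z"].notna()]
    bad = placed[(placed["aa_pos"] < 1) | (placed["aa_pos"] > L)]
    if len(bad):
        raise ValueError(f"variant positions outside 1..{L}: {sorted(bad['aa_pos'].unique())}")
    for row in placed.itertuples():
        mat.at[int(row.aa_pos), str(row.alt_aa)] = float(row.z)
    return mat


def matrix_to_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Flatten the matrix back to (aa_pos, alt_aa, z) rows over populated cells."""
    long = matrix.stack().rename("z").reset_index()
    long.columns = ["aa_pos", "alt_aa", "z"]
    return long


def position_average(matrix: pd.DataFrame) -> pd.Series:
    """Mean z per position over populated cells; all-missing rows stay NaN."""
    return matrix.mean(axis=1, skipna=True).rename("mean_z")


def domain_average(enrichment: pd.DataFrame, domain_map: DomainMap) -> pd.DataFrame:
    """Mean z of covered variants per region (1-based closed intervals)."""
    cov = enrichment[enrichment["z"].notna()]
    rows = []
    for region in domain_map:
        sel = cov[(cov["aa_pos"] >= region.start) & (cov["aa_pos"] <= region.end)]
        rows.append(
            {
                "region": region.name,
                "start": region.start,
                "end": region.end,
                "n": len(sel),
                "mean_z": float(sel["z"].mean()) if len(sel) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["region", "start", "end", "n", "mean_z"])


def cysteine_enrichment(enrichment: pd.DataFrame, regions: DomainMap | Iterable) -> pd.DataFrame:
    """Per-region contrast of X->C substitutions against all other substitutions.

    Reports group sizes, group mean z-scores and their difference (NaN when
    a group is empty) for each region — the signature of disulfide-driven
    dimerization in cysteine-rich domains.
    """
    cov = enrichment[enrichment["z"].notna()]
    rows = []
    for region in regions:
        sel = cov[(cov["aa_pos"] >= region.start) & (cov["aa_pos"] <= region.end)]
        to_cys = sel[sel["alt_aa"] == "C"]
        other = sel[sel["alt_aa"] != "C"]
        mean_cys = float(to_cys["z"].mean()) if len(to_cys) else np.nan
        mean_other = float(other["z"].mean()) if len(other) else np.nan
        diff = mean_cys - mean_other if len(to_cys) and len(other) else np.nan
        rows.append(
            {
                "region": region.name,
                "n_cys": len(to_cys),
                "mean_z_cys": mean_cys,
                "n_other": len(other),
                "mean_z_other": mean_other,
                "difference": diff,
            }
        )
    return pd.DataFrame(
        rows, columns=["region", "n_cys", "mean_z_cys", "n_other", "mean_z_other", "difference"]
    )


def normalize_catalog_name(name: str) -> str:
    """Normalise a protein-change string: strip whitespace and a 'p.' prefix."""
    name = str(name).strip()
    if name.startswith("p."):
        name = name[2:]
    return name


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a patient mutation catalog TSV (``name  count  [cohort]``)."""
    df = pd.read_csv(path, sep="\t")
    if "name" not in df.columns or "count" not in df.columns:
        raise ValueError("catalog must have 'name' and 'count' columns")
    df["name"] = df["name"].map(normalize_catalog_name)
    return df


def catalog_overlap(
    significant: Iterable[str],
    catalog: pd.DataFrame,
    min_observations: int = 2,
) -> dict[str, object]:
    """Intersect screen-significant variants with a patient mutation catalog.

    Keeps catalog rows observed at least ``min_observations`` times whose
    (normalised, parseable) name is significant in the screen; also
    reports the significant-but-unobserved and observed-but-not-significant
    name sets.  Unparseable catalog names are skipped with a warning.
    """
    sig = set(significant)
    names = catalog["name"].map(normalize_catalog_name) if len(catalog) else pd.Series(dtype=str)
    keep = []
    for raw, name in zip(catalog.get("name", pd.Series(dtype=str)), names):
        ok = True
        try:
            parse_variant_name(name)
        except ValueError:
            logger.warning("skipping unparseable catalog name %r", raw)
            ok = False
        keep.append(ok)
    cat = catalog.assign(name=names)[pd.Series(keep, index=catalog.index, dtype=bool)] if len(catalog) else catalog
    if len(cat) == 0:
        observed = set()
        overlap = catalog.iloc[0:0].copy()
    else:
        eligible = cat[cat["count"] >= min_observations]
        observed = set(eligible["name"])
        overlap = eligible[eligible["name"].isin(sig)].sort_values("name").reset_index(drop=True)
    return {
        "overlap": overlap,
        "significant_not_observed": sorted(sig - observed),
        "observed_not_significant": sorted(observed - sig),
    }


def render_heatmap(matrix: pd.DataFrame, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Thin presentation layer: render the substitution matrix as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(matrix) / 60), 6))
    data = np.ma.masked_invalid(matrix.to_numpy(dtype=float).T)
    vmax = np.nanmax(np.abs(matrix.to_numpy(dtype=float))) if matrix.notna().any().any() else 1.0
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
                   extent=(0.5, len(matrix) + 0.5, len(matrix.columns) - 0.5, -0.5))
    ax.set_yticks(range(len(matrix.columns)), matrix.columns)
    ax.set_xlabel("protein position")
    ax.set_ylabel("substitution")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
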