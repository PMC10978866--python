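"""Ground-truthed synthetic screens.

The simulator generates everything the analysis consumes — a reference
ORF, true per-variant growth rates, selection dynamics, sequencing counts
and shotgun read pairs — from explicit seeds, so every downstream stage
can be tested against known truth.

The selection model is deterministic exponential growth: a variant with
growth rate ``r`` (doublings/day) changes its relative abundance by
``2**(r * days)`` over the selection window.  Drug-sensitive variants
carry the (typically negative) background rate; a configurable minority of
drug-insensitive variants, concentrated in chosen protein domains, draw
positive rates.  Stochasticity enters through lognormal pre-selection
representation and multinomial sequencing sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .domains import DomainMap, egfr_domain_map
from .enrichment import ScreenCounts
from .library import VariantLibrary, parse_variant_name
from .reference import AA_ALPHABET, CODON_TO_AA, ReferenceORF

WT_NAME = "WT"

# Residues of the 1210-aa EGFR protein that anchor canonical variant names
# (controls and hotspots such as T790M, L858R, R675*, A289V, G598V, C311R).
EGFR_ANCHOR_RESIDUES: dict[int, str] = {
    108: "R", 222: "R", 229: "S", 237: "A", 277: "M", 289: "A",
    302: "T", 311: "C", 333: "C", 447: "S", 582: "C", 595: "C",
    598: "G", 620: "C", 624: "C", 628: "C", 644: "P", 675: "R",
    677: "R", 709: "E", 718: "L", 719: "G", 725: "T", 747: "L",
    768: "S", 769: "V", 773: "H", 774: "V", 779: "G", 790: "T",
    858: "L", 861: "L",
}

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)


def synthetic_orf(
    length_aa: int = 1210,
    seed: int = 0,
    anchors: Mapping[int, str] | None = None,
    name: str = "EGFR_synthetic",
) -> ReferenceORF:
    """Deterministic synthetic stand-in for the EGFR coding sequence.

    Builds a ``length_aa``-residue protein (3 * (length_aa + 1) nt with the
    terminator) whose residues are drawn from a seeded generator, except at
    ``anchors`` — by default the EGFR hotspot positions — where the true
    EGFR residue is planted so canonical variant names (T790M, L858R,
    R675*, ...) exist on the synthetic sequence.  Codons are sampled
    uniformly among the synonymous codons of each residue.
    """
    if anchors is None:
        anchors = EGFR_ANCHOR_RESIDUES if length_aa >= max(EGFR_ANCHOR_RESIDUES) else {}
    rng = np.random.default_rng(seed)
    aas = list(rng.choice(list(AA_ALPHABET), size=length_aa))
    aas[0] = "M"
    for pos, aa in anchors.items():
        if not 1 <= pos <= length_aa:
            raise ValueError(f"anchor position {pos} outside 1..{length_aa}")
        aas[pos - 1] = aa
    codons = [str(rng.choice(_CODONS_FOR_AA[aa])) for aa in aas]
    codons[0] = "ATG"
    codons.append("TAA")
    return ReferenceORF(name=name, nt_seq="".join(codons))


def default_region_probs() -> dict[str, float]:
    """Default per-region insensitivity probabilities (EGFR-like structure)."""
    return {
        "domain_II": 0.04,
        "domain_IV": 0.04,
        "TM": 0.08,
        "kinase": 0.05,
        "C_terminal": 0.01,
    }


@dataclass(frozen=True)
class EffectConfig:
    """Configuration of true variant effects under drug selection.

    Rates are net growth rates in doublings/day.  ``region_effect_probs``
    maps domain-map region names to the probability that a substitution
    there is drug-insensitive; positions outside every named region use
    ``baseline_prob``.  ``cysteine_boost`` adds insensitivity probability
    for X->C substitutions inside ``cysteine_regions`` (disulfide-prone
    dimerization domains).  ``representation_dispersion`` is the lognormal
    sigma of pre-selection abundances.  The seed is mandatory.
    """

    seed: int
    background_rate: float = -0.3
    insensitive_rate_range: tuple[float, float] = (0.3, 1.0)
    region_effect_probs: Mapping[str, float] = field(default_factory=default_region_probs)
    cysteine_boost: float = 0.08
    cysteine_regions: tuple[str, ...] = ("domain_II", "domain_IV")
    baseline_prob: float = 0.005
    representation_dispersion: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.insensitive_rate_range
        if lo > hi:
            raise ValueError("insensitive_rate_range low > high")
        for name, p in {**dict(self.region_effect_probs), "baseline": self.baseline_prob}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name} outside [0, 1]: {p}")
        if self.cysteine_boost < 0:
            raise ValueError("cysteine_boost must be >= 0")


@dataclass(frozen=True)
class ScreenDesign:
    """Selection duration, drug label, reference convention and read depths."""

    depth_ref: int
    depth_treated: int
    days: float = 10.0
    drug_label: str = "erlotinib 200 nM"
    reference: str = "pdna"  # or "early_split"
    treated_label: str = "erlotinib_d10"
    nb_dispersion: float | None = None  # per-sample gamma overdispersion, off by default

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("days must be > 0")
        if self.depth_ref <= 0 or self.depth_treated <= 0:
            raise ValueError("depths must be > 0")
        if self.reference not in ("pdna", "early_split"):
            raise ValueError("reference must be 'pdna' or 'early_split'")


@dataclass
class TruthTable:
    """Simulator ground truth: per-variant rate, class and initial weight.

    A variant is classed ``insensitive`` iff its growth rate is at or above
    ``classification_cutoff``.
    """

    frame: pd.DataFrame  # name, aa_pos, alt_aa, growth_rate, effect_class, initial_weight
    classification_cutoff: float

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> pd.Series:
        return self.frame["name"]

    def to_tsv(self, path: str | Path) -> None:
        cols = ["name", "growth_rate", "effect_class", "initial_weight"]
        self.frame[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, classification_cutoff: float = 0.0) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        parsed = df["name"].map(parse_variant_name)
        df["aa_pos"] = [p[0] for p in parsed]
        df["alt_aa"] = [p[2] for p in parsed]
        return cls(frame=df, classification_cutoff=classification_cutoff)


def assign_true_effects(
    library: VariantLibrary, cfg: EffectConfig, domain_map: DomainMap
) -> TruthTable:
    """Draw per-variant effect classes, growth rates and initial weights.

    Each variant is independently Bernoulli-insensitive with the
    probability of its region (maximum over overlapping named regions,
    ``baseline_prob`` elsewhere), plus ``cysteine_boost`` for X->C
    substitutions in the listed regions (capped at 1).  Insensitive rates
    are uniform over ``insensitive_rate_range``; sensitive variants grow at
    ``background_rate``.  Initial weights are lognormal(0, dispersion).
    """
    known = set(domain_map.names)
    for rname in list(cfg.region_effect_probs) + list(cfg.cysteine_regions):
        if rname not in known:
            raise ValueError(f"unknown region name {rname!r} (domain map has {sorted(known)})")

    rng = np.random.default_rng(cfg.seed)
    n = len(library)
    pos = np.array([v.aa_pos for v in library])
    alt = np.array([v.alt_aa for v in library])

    prob = np.full(n, cfg.baseline_prob)
    for rname, p in cfg.region_effect_probs.items():
        region = domain_map[rname]
        in_region = (pos >= region.start) & (pos <= region.end)
        prob[in_region] = np.maximum(prob[in_region], p)
    cys_mask = np.zeros(n, dtype=bool)
    for rname in cfg.cysteine_regions:
        region = domain_map[rname]
        cys_mask |= (pos >= region.start) & (pos <= region.end) & (alt == "C")
    prob[cys_mask] = np.minimum(1.0, prob[cys_mask] + cfg.cysteine_boost)

    insensitive = rng.random(n) < prob
    lo, hi = cfg.insensitive_rate_range
    rates = np.full(n, cfg.background_rate, dtype=float)
    rates[insensitive] = rng.uniform(lo, hi, size=int(insensitive.sum()))
    weights = rng.lognormal(mean=0.0, sigma=cfg.representation_dispersion, size=n)

    frame = pd.DataFrame(
        {
            "name": [v.name for v in library],
            "aa_pos": pos,
            "alt_aa": alt,
            "growth_rate": rates,
            "effect_class": np.where(insensitive, "insensitive", "sensitive"),
            "initial_weight": weights,
        }
    )
    cutoff = (cfg.background_rate + lo) / 2.0
    return TruthTable(frame=frame, classification_cutoff=cutoff)


def expected_insensitive_fraction(
    library: VariantLibrary, cfg: EffectConfig, domain_map: DomainMap
) -> float:
    """Closed-form expected fraction of insensitive variants under ``cfg``."""
    pos = np.array([v.aa_pos for v in library])
    alt = np.array([v.alt_aa for v in library])
    prob = np.full(len(library), cfg.baseline_prob)
    for rname, p in cfg.region_effect_probs.items():
        region = domain_map[rname]
        m = (pos >= region.start) & (pos <= region.end)
        prob[m] = np.maximum(prob[m], p)
    cys = np.zeros(len(library), dtype=bool)
    for rname in cfg.cysteine_regions:
        region = domain_map[rname]
        cys |= (pos >= region.start) & (pos <= region.end) & (alt == "C")
    prob[cys] = np.minimum(1.0, prob[cys] + cfg.cysteine_boost)
    return float(prob.mean())


def simulate_counts(truth: TruthTable, design: ScreenDesign, seed: int) -> ScreenCounts:
    """Sample reference and treated sequencing counts from the growth model.

    Treated weights are ``initial_weight * 2**(growth_rate * days)``; both
    samples are multinomial draws of the configured depth from the
    normalised weights.  With ``nb_dispersion`` set, weights are
    gamma-perturbed per sample first (negative-binomial-style
    overdispersion).  The reference sample represents the pre-selection
    pool; under this deterministic growth model the plasmid-pool and
    early-split conventions are distributionally identical and differ only
    in the sample label.
    """
    if len(truth) == 0:
        raise ValueError("empty truth table")
    rng = np.random.default_rng(seed)
    w0 = truth.frame["initial_weight"].to_numpy(dtype=float)
    if not np.any(w0 > 0):
        raise ValueError("all initial weights are zero")
    rates = truth.frame["growth_rate"].to_numpy(dtype=float)
    w_treated = w0 * np.exp2(rates * design.days)

    def draw(depth: int, w: np.ndarray) -> np.ndarray:
        if design.nb_dispersion:
            shape = 1.0 / design.nb_dispersion
            w = w * rng.gamma(shape, scale=1.0 / shape, size=len(w))
        return rng.multinomial(depth, w / w.sum())

    names = truth.frame["name"]
    ref = pd.Series(draw(design.depth_ref, w0), index=names)
    trt = pd.Series(draw(design.depth_treated, w_treated), index=names)
    return ScreenCounts.from_samples({design.reference: ref, design.treated_label: trt})


@dataclass(frozen=True)
class ReadSimConfig:
    """Shotgun read-pair geometry and error model."""

    fragment_mean: float = 350.0
    fragment_sd: float = 80.0
    read_length: int = 150
    error_rate: float = 0.001
    base_quality: int = 37

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    orf: ReferenceORF,
    library: VariantLibrary,
    counts: pd.Series,
    read_cfg: ReadSimConfig,
    seed: int,
    sam_path: str | Path,
) -> pd.DataFrame:
    """Emit aligned shotgun read pairs for a counted molecule population.

    ``counts`` maps variant names (plus the optional ``WT`` entry) to
    molecule tallies.  Each molecule yields one fragment placed uniformly
    on the (mutant) ORF, with paired reads taken from the fragment ends,
    independent per-base substitution errors, and match-only alignments
    written as SAM with true 1-based positions.

    Returns the per-molecule truth table: variant name, fragment interval
    and both read intervals (1-based closed), for exact downstream checks.
    """
    if read_cfg.read_length > len(orf.nt_seq):
        raise ValueError("read length exceeds ORF length")
    by_name = {v.name: v for v in library}
    mutant_seqs: dict[str, str] = {}

    def seq_for(name: str) -> str:
        if name not in mutant_seqs:
            if name == WT_NAME:
                mutant_seqs[name] = orf.nt_seq
            else:
                v = by_name[name]
                i = 3 * (v.aa_pos - 1)
                mutant_seqs[name] = orf.nt_seq[:i] + v.alt_codon + orf.nt_seq[i + 3 :]
        return mutant_seqs[name]

    rng = np.random.default_rng(seed)
    ref_len = len(orf.nt_seq)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": orf.name, "LN": ref_len}],
        }
    )
    truth_rows = []
    mol = 0
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for name, count in counts.items():
            if name != WT_NAME and name not in by_name:
                raise KeyError(f"count entry {name!r} is not a library variant or WT")
            template = seq_for(str(name))
            for _ in range(int(count)):
                frag_len = int(round(rng.normal(read_cfg.fragment_mean, read_cfg.fragment_sd)))
                frag_len = int(np.clip(frag_len, read_cfg.read_length, ref_len))
                start = int(rng.integers(0, ref_len - frag_len + 1))
                end = start + frag_len
                rl = min(read_cfg.read_length, frag_len)
                r1_start, r2_start = start, end - rl
                qname = f"mol{mol:07d}"
                for idx, rstart in ((1, r1_start), (2, r2_start)):
                    a = pysam.AlignedSegment(header)
                    a.query_name = qname
                    a.query_sequence = _inject_errors(
                        template[rstart : rstart + rl], read_cfg.error_rate, rng
                    )
                    a.flag = 99 if idx == 1 else 147
                    a.reference_id = 0
                    a.reference_start = rstart
                    a.mapping_quality = 60
                    a.cigarstring = f"{rl}M"
                    a.next_reference_id = 0
                    a.next_reference_start = r2_start if idx == 1 else r1_start
                    a.template_length = frag_len if idx == 1 else -frag_len
                    a.query_qualities = pysam.qualitystring_to_array(
                        chr(read_cfg.base_quality + 33) * rl
                    )
                    out.write(a)
                truth_rows.append(
                    {
                        "pair_id": qname,
                        "name": name,
                        "frag_start": start + 1,
                        "frag_end": end,
                        "r1_start": r1_start + 1,
                        "r1_end": r1_start + rl,
                        "r2_start": r2_start + 1,
                        "r2_end": r2_start + rl,
                    }
                )
                mol += 1
    return pd.DataFrame(
        truth_rows,
        columns=[
            "pair_id", "name", "frag_start", "frag_end",
            "r1_start", "r1_end", "r2_start", "r2_end",
        ],
    )


def load_screen_config(
    path: str | Path,
) -> tuple[EffectConfig | None, ScreenDesign | None, ReadSimConfig]:
    """Load EffectConfig / ScreenDesign / ReadSimConfig from one YAML file.

    Top-level keys ``effect``, ``design`` and ``reads`` each hold the
    corresponding dataclass fields; omitted fields use the defaults.  The
    ``effect`` and ``design`` sections are optional (None when absent) so a
    read-geometry-only file is valid.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    effect = None
    if "effect" in raw:
        eff = dict(raw["effect"])
        if "insensitive_rate_range" in eff:
            eff["insensitive_rate_range"] = tuple(eff["insensitive_rate_range"])
        if "cysteine_regions" in eff:
            eff["cysteine_regions"] = tuple(eff["cysteine_regions"])
        effect = EffectConfig(**eff)
    design = ScreenDesign(**raw["design"]) if "design" in raw else None
    reads = ReadSimConfig(**raw.get("reads", {}))
    return effect, design, reads


def default_screen(
    seed: int,
    length_aa: int = 1210,
    depth_per_variant: float = 200.0,
    domain_map: DomainMap | None = None,
) -> tuple[ReferenceORF, VariantLibrary, DomainMap, EffectConfig, ScreenDesign]:
    """Bundle the default EGFR-like study conditions for one seeded screen."""
    from .library import enumerate_saturation_library

    orf = synthetic_orf(length_aa=length_aa, seed=seed)
    lib = enumerate_saturation_library(orf)
    dmap = domain_map or egfr_domain_map()
    cfg = EffectConfig(seed=seed + 1)
    depth = int(depth_per_variant * len(lib))
    design = ScreenDesign(depth_ref=depth, depth_treated=depth)
    return orf, lib, dmap, cfg, design
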