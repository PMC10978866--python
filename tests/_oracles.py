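"""Independent brute-force oracles used only by the tests.

Deliberately written with plain string/loop logic, sharing no code with
the package implementations they cross-check.
"""

from __future__ import annotations

import numpy as np

GENETIC_CODE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_aas):
    GENETIC_CODE[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a


def brute_force_call(mates, ref_nt, quality_floor, min_base_quality):
    """Re-derive a read pair's classification by direct string comparison.

    ``mates`` is a list of (ref_start0, seq, quals).  Returns a dict with
    classification, variant, covered codon positions and silent codons.
    """
    n_codons = len(ref_nt) // 3 - 1  # sense codons only
    # per-reference-base observations after independent end trimming
    obs = {}
    for start, seq, quals in mates:
        if start < 0 or start + len(seq) > len(ref_nt):
            raise ValueError("out of bounds")
        lo = 0
        while lo < len(seq) and quals[lo] < quality_floor:
            lo += 1
        hi = len(seq)
        while hi > lo and quals[hi - 1] < quality_floor:
            hi -= 1
        for k in range(lo, hi):
            p = start + k
            obs.setdefault(p, []).append((seq[k], quals[k]))
    for p, hits in obs.items():
        if len({b for b, _ in hits}) > 1:
            return {"classification": "discarded", "variant": None,
                    "covered": [], "silent": []}
    covered, variants, silent = [], [], []
    for codon_i in range(n_codons):
        triple = []
        ok = True
        for k in range(3):
            p = 3 * codon_i + k
            if p not in obs or max(q for _, q in obs[p]) < min_base_quality:
                ok = False
                break
            triple.append(obs[p][0][0])
        if not ok:
            continue
        aa_pos = codon_i + 1
        covered.append(aa_pos)
        codon = "".join(triple)
        ref_codon = ref_nt[3 * codon_i : 3 * codon_i + 3]
        if codon != ref_codon:
            if GENETIC_CODE[codon] == GENETIC_CODE[ref_codon]:
                silent.append((aa_pos, codon))
            else:
                variants.append((aa_pos, GENETIC_CODE[codon]))
    if not covered:
        cls, var = "discarded", None
    elif len(variants) == 0:
        cls, var = "wildtype_supporting", None
    elif len(variants) == 1:
        cls, var = "single_variant", variants[0]
    else:
        cls, var = "multi_variant", None
    return {"classification": cls, "variant": var, "covered": covered, "silent": silent}


def brute_force_tally(pair_mates, ref_nt, designed, quality_floor, min_base_quality):
    """Tally counts/depths from raw mate tuples, independent of the package.

    ``designed`` maps (aa_pos, alt_aa) -> variant name.
    """
    counts = {}
    undesigned = {}
    depth = {}
    qc = {"wildtype_supporting": 0, "single_variant": 0, "multi_variant": 0, "discarded": 0}
    for mates in pair_mates:
        res = brute_force_call(mates, ref_nt, quality_floor, min_base_quality)
        qc[res["classification"]] += 1
        if res["classification"] == "single_variant":
            key = res["variant"]
            if key in designed:
                counts[designed[key]] = counts.get(designed[key], 0) + 1
            else:
                nm = GENETIC_CODE[ref_nt[3 * (key[0] - 1): 3 * (key[0] - 1) + 3]] + str(key[0]) + key[1]
                undesigned[nm] = undesigned.get(nm, 0) + 1
            for aa_pos in res["covered"]:
                if aa_pos != key[0]:
                    depth[aa_pos] = depth.get(aa_pos, 0) + 1
        elif res["classification"] == "wildtype_supporting":
            for aa_pos in res["covered"]:
                depth[aa_pos] = depth.get(aa_pos, 0) + 1
    return counts, undesigned, depth, qc


def straight_line_scores(c_ref, c_trt, pseudocount, min_count):
    """Frequencies -> LFC -> z in one unvectorised pass (sample SD).

    Returns (lfc, z, covered) as float/bool arrays; uncovered entries NaN.
    """
    c_ref = np.asarray(c_ref, dtype=float)
    c_trt = np.asarray(c_trt, dtype=float)
    n_ref = c_ref.sum()
    n_trt = c_trt.sum()
    lfc = np.empty(len(c_ref))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(len(c_ref)):
            f_ref = (c_ref[i] + pseudocount) / n_ref
            f_trt = (c_trt[i] + pseudocount) / n_trt
            lfc[i] = np.log2(f_trt) - np.log2(f_ref)
    covered = (c_ref >= min_count) & np.isfinite(lfc)
    vals = lfc[covered]
    mean = vals.sum() / len(vals)
    sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
    z = np.full(len(lfc), np.nan)
    z[covered] = (lfc[covered] - mean) / sd
    return lfc, z, covered
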