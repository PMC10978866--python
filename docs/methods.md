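# Methods

`satscreen` implements the computational core of a full-length saturation-
mutagenesis drug-resistance screen: enumerating the designed variant
library, recovering per-variant molecule counts from aligned shotgun read
pairs, scoring enrichment under drug selection as LFC/z-scores, and
aggregating the result into positional, domain and patient-catalog views.
A seeded synthetic-screen generator provides ground-truthed inputs for
every stage.

## Library design

At each protein position except the initiator — and never the terminator
codon, which is not a protein position — the design places the 19 missense
substitutions plus one nonsense substitution: 20 variants per position,
`20 × (L − 1)` in total, 24,180 for a 1,210-residue receptor such as EGFR.
Each substitution is realised by a single codon taken from an embedded
table of the most-frequent human codon per amino acid (stop = TGA), which
mirrors synthesis-vendor practice and keeps the library one codon per
variant. Variants are named `<ref><pos><alt>` (e.g. `T790M`, `R675*`),
with 1-based protein coordinates and 1-based closed intervals for all
region arithmetic; `parse_variant_name` is the exact inverse of the namer.

The EGFR-scale test sequence is a *synthetic* stand-in built by
`synthetic_orf`: a deterministic 1,210-residue protein with the EGFR
hotspot residues (T790, L858, R675, A289, C311, the domain II/IV
cysteines, …) planted at their true positions so canonical variant names
exist, and all other residues drawn from a seeded generator. It reproduces
the length, codon structure and variant nomenclature of the real ORF but
not its actual sequence; nothing in the pipeline depends on the filler
residues.

## Selection and sampling model

Selection is modelled as deterministic exponential growth: a variant with
net growth rate `r` doublings/day changes relative abundance by
`2^(r·days)` over the selection window (default 10 days, matching a
10-day 200 nM erlotinib selection). Drug-sensitive variants carry the
background rate (default −0.3 doublings/day, a pool that shrinks under
drug); drug-insensitive variants draw uniform rates from 0.3–1.0
doublings/day, bracketing one doubling per day as the realistic ceiling
for a lung-cancer line.

Which variants are insensitive is Bernoulli per variant, with
probabilities attached to named domains: defaults of 4% in dimerization
domains II and IV, 8% in the transmembrane helix, 5% in the kinase domain,
1% in the C-terminal tail and 0.5% elsewhere, plus an extra 8% for X→C
substitutions inside domains II and IV (the disulfide-dimerization
signature). These defaults were chosen once to give roughly 2–3%
insensitive variants overall — the scale implied by ~560 enriched
variants among ~22,500 scored — and to concentrate them in the domains
where resistance variants cluster. Overlapping regions take the maximum
probability.

Biological noise enters in exactly two places: lognormal pre-selection
representation (sigma 0.5 by default, a moderate spread around the ~1000×
colony representation typical of pooled cloning) and multinomial
sequencing sampling at the configured depth. Growth itself is noise-free;
an optional gamma-perturbation (`nb_dispersion`) adds negative-binomial-
style overdispersion per sample but is off by default since the screen
design gives no replicate structure to fit a dispersion to. Under this
model the plasmid-pool and early-split reference conventions are
distributionally identical (no selection acts before day 0), so the
`reference` switch only changes the sample label.

Read simulation draws one fragment per counted molecule, uniform over the
(mutant) ORF with Gaussian length (default 350 ± 80 nt, clipped to the
read length and ORF), takes paired reads from the fragment ends (default
2 × 150 nt), injects independent per-base substitution errors (default
10⁻³) and writes match-only SAM alignments at true positions with fixed
base quality (default Q37). Insertion-site bias, PCR amplification bias
and quality decay along the read are deliberately not modelled, so
passing tests demonstrate correctness of the accounting, not robustness
to those artefacts.

Every stochastic operation takes an explicit integer seed and builds its
own `numpy.random.Generator`; there is no global random state.

## Deconvolution

Read pairs are classified, not genotyped, because a pair interrogates
only the codons it fully covers:

1. End trimming removes the lowest-quality prefix/suffix (bases below
   quality 10 by default); interior low-quality bases are retained and
   handled per codon.
2. Mates are merged base-by-base; any overlap disagreement discards the
   pair — the simplest auditable rule, rather than arbitration by quality.
3. Only codons with all three bases covered at quality ≥ 20 are
   evaluated. Zero mismatched codons ⇒ wildtype-supporting; exactly one
   amino-acid-changing codon (including to stop) ⇒ single-variant;
   two or more ⇒ multi-variant (excluded from tallies — a single-codon
   library should not produce them); no fully covered codon ⇒ discarded.
   Silent codon changes are recorded but never counted, as the design
   contains no silent variants. Indel-containing alignments are rejected
   with a warning (substitution-only scope). Alignments extending beyond
   the ORF are an error.

Counts per designed variant are single-variant calls matching its
`(position, substitution)`; calls outside the design are tallied
separately as "undesigned". Wildtype depth at a codon counts pairs —
wildtype-supporting or single-variant — that fully cover it and match the
reference there; a single-variant pair therefore supports wildtype at its
other covered codons, which keeps the per-codon denominator (variant
counts + wildtype depth) an unbiased coverage measure. The four
classifications always sum to the pair total.

## Enrichment scoring

`LFC_v = log2((c_trt,v + p)/N_trt) − log2((c_ref,v + p)/N_ref)`, with
pseudocount `p = 0.5` by default (keeps dropouts finite without
distorting well-covered variants; `p = 0` reproduces the pure formula).
`N` is the sample total when only count tables are available; when
deconvolution supplies wildtype depths, `N` is per codon (variant counts
at that codon + wildtype depth), which removes fragment-coverage bias
along the ORF.

z-scores standardise the LFCs over *covered* variants — designed variants
with reference count ≥ 1 and finite LFC — using the plain mean and sample
(n−1) standard deviation, so mean 0 and SD 1 hold exactly by
construction. Nonsense variants stay in the normalization set (truncation
depletion is part of the screen's signal). A median/MAD alternative is
available but off by default, matching the plain z-score convention.
Significance is `z ≥ 1.5` (configurable); coverage is fraction of the
designed library detected in the reference sample at ≥ 1 count. Whether
the original analysis used a pseudocount, population SD, or a different
coverage definition is not stated anywhere we could find; the defaults
above are declared conventions of this package, all config-exposed.

## Summaries

The substitution matrix is positions × 21 substitutions with NaN for
uncovered/undesigned cells — missingness is everywhere distinct from
z = 0, and TSV output writes empty fields. Position averages are row
means over populated cells; domain averages and the X→C contrast use the
editable EGFR domain table (domain II 189–333, domain IV 504–644, TM
645–668, kinase 718–964, C-terminal tail 979–1210; 1-based closed).
Catalog overlap joins screen-significant variants against any
protein-change table (`name  count  cohort`) after normalising names
(whitespace, `p.` prefix), keeping entries observed at least twice by
default; transcript-isoform reconciliation is out of scope.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: full-scale 24,180-variant screens at 200× mean depth for null
calibration and coverage (multinomial draws of ~4.8 M reads), a
1,000-variant screen at 500× for planted-variant recovery, 1,000 read
pairs for the deconvolution-vs-brute-force equivalence, and a 1,025-
variant analytic toy whose resistant variant's LFC has the closed form
`log2(0.5 × 1025) ≈ 9.00`. Coverage runs calibrate depth by solving
`E[exp(−depth · w_v)] = 0.07` over the drawn representation weights
(bisection), i.e. a 7% expected Poisson dropout. Enrichment output is
cross-checked against an independent straight-line recomputation to
1e-12, and the codon caller against a string-comparison oracle exactly.

## Known limitations

- The generator emulates the statistical structure of a resistance
  screen, not real sequencing: no PCR/insertion bias, uniform base
  quality, deterministic growth. Recovery results bound what the analysis
  can do under its own assumptions, not on real libraries.
- Indels, complex variants and UMIs are out of scope; alignment itself is
  consumed, not performed.
- Single-screen z-scores carry no replicate variance model; the
  significance call is a pool-relative threshold, not an error-controlled
  test. Empirical-Bayes or FDR layers are natural extension points.
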