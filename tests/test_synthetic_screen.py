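"""Ground-truth assignment, selection/count simulation and read simulation."""

import numpy as np
import pandas as pd
import pytest

from satscreen import (
    DomainMap,
    EffectConfig,
    ReadSimConfig,
    Region,
    ScreenDesign,
    TruthTable,
    assign_true_effects,
    compute_lfc,
    egfr_domain_map,
    enumerate_saturation_library,
    score_screen,
    simulate_counts,
    simulate_reads,
    synthetic_orf,
)
from satscreen.enrichment import ScreenCounts
from satscreen.simulate import expected_insensitive_fraction


def neutral_config(seed=1, **kw):
    kw.setdefault("region_effect_probs", {})
    kw.setdefault("cysteine_regions", ())
    kw.setdefault("baseline_prob", 0.0)
    return EffectConfig(seed=seed, **kw)


def flat_truth(names, rates, seed=None, weights=None):
    """Truth table with explicit rates (and optionally explicit weights)."""
    if weights is None:
        weights = np.ones(len(names))
    frame = pd.DataFrame(
        {
            "name": names,
            "growth_rate": rates,
            "effect_class": np.where(np.asarray(rates) > 0, "insensitive", "sensitive"),
            "initial_weight": weights,
        }
    )
    return TruthTable(frame=frame, classification_cutoff=0.0)


class TestAssignTrueEffects:
    def test_zero_probabilities_give_all_sensitive(self, small_library):
        cfg = neutral_config()
        truth = assign_true_effects(small_library, cfg, egfr_domain_map())
        assert (truth.frame["effect_class"] == "sensitive").all()
        assert (truth.frame["growth_rate"] == cfg.background_rate).all()

    def test_certain_region_makes_all_twenty_variants_insensitive(self, small_library):
        dmap = DomainMap((Region("hot", 5, 5),))
        cfg = neutral_config(region_effect_probs={"hot": 1.0})
        truth = assign_true_effects(small_library, cfg, dmap)
        at5 = truth.frame[truth.frame["aa_pos"] == 5]
        assert len(at5) == 20
        assert (at5["effect_class"] == "insensitive").all()
        lo, hi = cfg.insensitive_rate_range
        assert at5["growth_rate"].between(lo, hi).all()
        assert (truth.frame[truth.frame["aa_pos"] != 5]["effect_class"] == "sensitive").all()

    def test_default_config_fraction_matches_expectation(self, egfr_library):
        cfg = EffectConfig(seed=1)
        dmap = egfr_domain_map()
        truth = assign_true_effects(egfr_library, cfg, dmap)
        frac = (truth.frame["effect_class"] == "insensitive").mean()
        expected = expected_insensitive_fraction(egfr_library, cfg, dmap)
        se = np.sqrt(expected * (1 - expected) / len(egfr_library))
        assert abs(frac - expected) < 3 * se

    def test_reproducible_from_seed(self, small_library):
        cfg = EffectConfig(seed=11)
        dmap = egfr_domain_map()
        a = assign_true_effects(small_library, cfg, dmap)
        b = assign_true_effects(small_library, cfg, dmap)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_unknown_region_raises(self, small_library):
        cfg = neutral_config(region_effect_probs={"nonexistent": 0.5})
        with pytest.raises(ValueError, match="unknown region"):
            assign_true_effects(small_library, cfg, egfr_domain_map())

    def test_class_consistent_with_rate_and_cutoff(self, egfr_library):
        cfg = EffectConfig(seed=5)
        truth = assign_true_effects(egfr_library, cfg, egfr_domain_map())
        above = truth.frame["growth_rate"] >= truth.classification_cutoff
        assert (above == (truth.frame["effect_class"] == "insensitive")).all()


class TestSimulateCounts:
    def test_equal_rates_give_zero_mean_lfc(self):
        n = 200
        names = [f"A{i + 2}V" for i in range(n)]
        truth = flat_truth(names, np.full(n, 0.2))
        design = ScreenDesign(depth_ref=n * 500, depth_treated=n * 500)
        counts = simulate_counts(truth, design, seed=3)
        lfc = compute_lfc(counts, "pdna", "erlotinib_d10", pseudocount=0.5)
        se = np.sqrt(2.0 / 500) / np.log(2) / np.sqrt(n)  # delta-method s.e. of the mean
        assert abs(lfc.mean()) < 3 * se

    def test_single_resistant_variant_analytic_lfc(self):
        # 1025 equal-weight variants, one at 1 doubling/day for 10 days:
        # treated frequency 1024/2048 = 1/2, reference 1/1025,
        # LFC -> log2(0.5 * 1025) = 9.0014
        n = 1025
        names = [f"A{i + 2}V" for i in range(n)]
        rates = np.zeros(n)
        rates[0] = 1.0
        truth = flat_truth(names, rates)
        design = ScreenDesign(depth_ref=2_000_000, depth_treated=2_000_000)
        counts = simulate_counts(truth, design, seed=9)
        lfc = compute_lfc(counts, "pdna", "erlotinib_d10", pseudocount=0)
        expected = np.log2(0.5 * n)
        se = np.sqrt(1 / (2e6 / n) + 1 / 1e6) / np.log(2)
        assert abs(lfc.iloc[0] - expected) < 3 * se

    def test_depth_change_leaves_frequencies_unchanged(self):
        n = 100
        names = [f"A{i + 2}V" for i in range(n)]
        rng = np.random.default_rng(0)
        truth = flat_truth(names, np.zeros(n), weights=rng.lognormal(0, 0.5, n))
        expected = truth.frame["initial_weight"] / truth.frame["initial_weight"].sum()
        for depth in (100_000, 200_000):
            counts = simulate_counts(truth, ScreenDesign(depth_ref=depth, depth_treated=depth), seed=5)
            freq = counts.sample("pdna") / depth
            se = np.sqrt(expected * (1 - expected) / depth)
            assert (np.abs(freq.to_numpy() - expected.to_numpy()) < 5 * se.to_numpy()).all()
            assert counts.totals.tolist() == [depth, depth]

    def test_all_zero_weights_raise(self):
        truth = flat_truth(["A2V"], [0.0], weights=[0.0])
        with pytest.raises(ValueError, match="zero"):
            simulate_counts(truth, ScreenDesign(depth_ref=10, depth_treated=10), seed=1)


class TestSimulateReads:
    def test_zero_error_variant_molecule_differs_only_at_its_codon(self, egfr_orf, egfr_library, tmp_path):
        counts = pd.Series({"T790M": 1})
        cfg = ReadSimConfig(
            fragment_mean=len(egfr_orf.nt_seq), fragment_sd=0, read_length=1900, error_rate=0
        )
        truth = simulate_reads(egfr_orf, egfr_library, counts, cfg, seed=2, sam_path=tmp_path / "t.sam")
        assert len(truth) == 1
        import pysam

        with pysam.AlignmentFile(str(tmp_path / "t.sam"), check_sq=False) as sam:
            mismatched = set()
            for aln in sam:
                ref = egfr_orf.nt_seq[aln.reference_start : aln.reference_start + len(aln.query_sequence)]
                for i, (a, b) in enumerate(zip(aln.query_sequence, ref)):
                    if a != b:
                        mismatched.add(aln.reference_start + i)
        codon_790 = set(range(3 * 789, 3 * 789 + 3))
        assert mismatched and mismatched <= codon_790

    def test_zero_error_wildtype_reads_match_reference(self, small_orf, small_library, tmp_path):
        counts = pd.Series({"WT": 50})
        cfg = ReadSimConfig(fragment_mean=60, fragment_sd=10, read_length=40, error_rate=0)
        simulate_reads(small_orf, small_library, counts, cfg, seed=4, sam_path=tmp_path / "wt.sam")
        import pysam

        with pysam.AlignmentFile(str(tmp_path / "wt.sam"), check_sq=False) as sam:
            for aln in sam:
                ref = small_orf.nt_seq[aln.reference_start : aln.reference_start + len(aln.query_sequence)]
                assert aln.query_sequence == ref

    def test_error_rate_reproduced_in_mismatch_count(self, small_orf, small_library, tmp_path):
        n_pairs, rl, err = 10_000, 45, 0.001
        counts = pd.Series({"WT": n_pairs})
        cfg = ReadSimConfig(fragment_mean=len(small_orf.nt_seq), fragment_sd=0, read_length=rl, error_rate=err)
        simulate_reads(small_orf, small_library, counts, cfg, seed=6, sam_path=tmp_path / "e.sam")
        import pysam

        total_bases = 2 * n_pairs * rl
        n_mismatch = 0
        with pysam.AlignmentFile(str(tmp_path / "e.sam"), check_sq=False) as sam:
            for aln in sam:
                ref = small_orf.nt_seq[aln.reference_start : aln.reference_start + len(aln.query_sequence)]
                n_mismatch += sum(a != b for a, b in zip(aln.query_sequence, ref))
        expected = err * total_bases
        se = np.sqrt(total_bases * err * (1 - err))
        assert abs(n_mismatch - expected) < 3 * se

    def test_read_length_exceeding_orf_raises(self, small_orf, small_library, tmp_path):
        cfg = ReadSimConfig(read_length=10_000)
        with pytest.raises(ValueError, match="read length"):
            simulate_reads(small_orf, small_library, pd.Series({"WT": 1}), cfg, 0, tmp_path / "x.sam")


class TestScreenStatisticalStructure:
    def test_null_screen_z_calibration_small_scale(self):
        """All-neutral screen at 200x depth: |z| < 2 for 90-99% of variants."""
        orf = synthetic_orf(length_aa=101, seed=3, anchors={})
        lib = enumerate_saturation_library(orf)  # 2000 variants
        cfg = neutral_config(seed=8, representation_dispersion=0.5)
        truth = assign_true_effects(lib, cfg, egfr_domain_map())
        depth = 200 * len(lib)
        counts = simulate_counts(truth, ScreenDesign(depth_ref=depth, depth_treated=depth), seed=9)
        table = score_screen(counts, lib.to_frame(), "pdna", "erlotinib_d10")
        z = table["z"].dropna()
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=1) - 1) < 1e-9
        assert 0.90 <= (z.abs() < 2).mean() <= 0.99

    def test_average_z_nondecreasing_in_planted_growth_rate(self):
        n = 400
        names = [f"A{i + 2}V" for i in range(n)]
        means = []
        for rate in (-0.3, -0.2, -0.1):  # 0 / 1 / 2 doublings above background over 10 d
            reps = []
            for seed in (1, 2, 3):
                rates = np.full(n, -0.3)
                rates[0] = rate
                rng = np.random.default_rng(100 + seed)
                truth = flat_truth(names, rates, weights=rng.lognormal(0, 0.5, n))
                counts = simulate_counts(
                    truth, ScreenDesign(depth_ref=n * 300, depth_treated=n * 300), seed=seed
                )
                table = score_screen(counts, _frame_for(names), "pdna", "erlotinib_d10")
                reps.append(table.set_index("name")["z"].iloc[0])
            means.append(np.mean(reps))
        assert means[0] <= means[1] <= means[2]


def _frame_for(names):
    import pandas as pd

    from satscreen import parse_variant_name

    rows = []
    for i, n in enumerate(names):
        pos, ref, alt = parse_variant_name(n)
        rows.append({"variant_id": i + 1, "aa_pos": pos, "ref_aa": ref, "alt_aa": alt,
                     "ref_codon": "NNN", "alt_codon": "NNN", "name": n})
    return pd.DataFrame(rows)
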