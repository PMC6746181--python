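"""Tests of the synthetic-data generator: references, libraries, bins, tumors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctdnakit import (
    BenchmarkDesign,
    SimConfig,
    classify_clonality,
    make_reference,
    simulate_benchmark,
    simulate_library,
    simulate_multiregion,
    simulate_ulp_bins,
)
from ctdnakit._genome import PROSTATE_SCNA_PROFILE


class TestMakeReference:
    @pytest.mark.parametrize("n_loci,length", [(8, 400), (1, 200)])
    def test_counts_and_flanks(self, n_loci, length):
        reference, alleles = make_reference(n_loci, length, seed=1)
        assert len(reference) == n_loci and len(alleles) == n_loci
        for a in alleles:
            seq = reference[a.chrom]
            assert len(seq) == length
            assert seq[a.pos - 1] == a.ref
            assert a.pos - 1 >= 70 and length - a.pos >= 70

    def test_deterministic(self):
        assert make_reference(4, 300, seed=7) == make_reference(4, 300, seed=7)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_reference(2, 150, seed=1)


class TestSimulateLibrary:
    def test_zero_molecules_empty(self, small_sim_config):
        assert simulate_library(0, small_sim_config) == []

    def test_zero_error_reads_match_template(self, reference8, clean_sim_config):
        reference, alleles, amplicons = reference8
        amp, allele = amplicons[0], alleles[0]
        reads = simulate_library(100, clean_sim_config, amplicon=amp, allele=allele)
        mutant_template = (
            amp.sequence[: amp.target_offset] + allele.alt
            + amp.sequence[amp.target_offset + 1 :]
        )
        umis = set()
        for name, seq in reads:
            umi = name.rsplit(":", 1)[1]
            umis.add(umi)
            assert seq[: len(umi)] == umi  # inline UMI matches the name tag
            assert mutant_template.startswith(seq[len(umi):])
        assert 0 < len(umis) <= 100

    def test_umi_capacity_never_exceeded(self, reference8):
        reference, alleles, amplicons = reference8
        cfg = SimConfig(
            seed=2, seq_error_rate=0.0, prep_error_rate=0.0,
            capture_efficiency=1.0, reads_per_library=100_000,
        )
        reads = simulate_library(
            1_000_000, cfg, amplicon=amplicons[0], allele=alleles[0]
        )
        distinct = {seq[:7] for _, seq in reads}
        assert len(distinct) <= 16_384
        assert len(distinct) > 16_000  # saturation approached

    def test_umi_marginals_uniform(self, rng):
        # chi-square goodness of fit of 1e5 UMI draws against uniform
        draws = rng.integers(0, 4**7, size=100_000)
        observed = np.bincount(draws, minlength=4**7)
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01

    def test_error_separability(self, reference8):
        # seq errors alone: families are internally discordant, but the
        # consensus of large families always matches the template truth
        reference, alleles, amplicons = reference8
        cfg = SimConfig(
            seed=9, seq_error_rate=0.005, prep_error_rate=0.0,
            capture_efficiency=1.0, mean_reads_per_molecule=30.0,
            reads_per_library=None,
        )
        amp, allele = amplicons[0], alleles[0]
        reads = simulate_library(200, cfg, amplicon=amp, allele=allele)
        by_molecule: dict[str, list[str]] = {}
        for name, seq in reads:
            by_molecule.setdefault(name.rsplit(":", 1)[1], []).append(seq)
        discordant = 0
        for umi, seqs in by_molecule.items():
            bases = [s[7 + amp.target_offset] for s in seqs if len(s) > 7 + amp.target_offset]
            if len(set(bases)) > 1:
                discordant += 1
            if len(bases) >= 10:
                consensus = max(set(bases), key=bases.count)
                assert consensus == allele.alt
        assert discordant > 0


@pytest.fixture(scope="module")
def small_benchmark(reference8):
    reference, alleles, _ = reference8
    design = BenchmarkDesign(
        sources=("A",), spike_levels=(10, 100, 1000),
        replicates_per_condition=2, negative_controls=2, preps_per_sample=2,
        background_wt_per_locus=50,
    )
    cfg = SimConfig(seed=21, reads_per_library=3_000)
    return design, simulate_benchmark(design, cfg, reference=reference, alleles=alleles)


class TestSimulateBenchmark:
    def test_library_count_formula(self, small_benchmark):
        design, result = small_benchmark
        expected = (1 * 3 * 2 + 2) * 2
        assert design.n_libraries == expected
        assert len(result.libraries) == expected

    def test_minimal_design_single_library(self, reference8):
        reference, alleles, _ = reference8
        design = BenchmarkDesign(
            sources=("A",), spike_levels=(100,), replicates_per_condition=1,
            negative_controls=0, preps_per_sample=1,
        )
        result = simulate_benchmark(
            design, SimConfig(seed=1, reads_per_library=1000),
            reference=reference, alleles=alleles,
        )
        assert len(result.libraries) == 1

    def test_negative_controls_have_no_mutant_truth(self, small_benchmark):
        _, result = small_benchmark
        negative_ids = {l.library_id for l in result.libraries if l.is_negative}
        for t in result.truth:
            if t.library_id in negative_ids:
                assert t.true_template_molecules == 0 and not t.true_mutant

    def test_truth_conservation(self, small_benchmark):
        # per-library truth molecules sum to the designed spike level
        _, result = small_benchmark
        levels = {l.library_id: l.spike_level for l in result.libraries}
        totals: dict[str, int] = {}
        for t in result.truth:
            totals[t.library_id] = totals.get(t.library_id, 0) + t.true_template_molecules
        for lib_id, total in totals.items():
            assert total == levels[lib_id]

    def test_byte_identical_given_seed(self, reference8):
        reference, alleles, _ = reference8
        design = BenchmarkDesign(
            sources=("A",), spike_levels=(10, 100, 1000),
            replicates_per_condition=1, negative_controls=1, preps_per_sample=1,
        )
        cfg = SimConfig(seed=7, reads_per_library=1_000)
        r1 = simulate_benchmark(design, cfg, reference=reference, alleles=alleles)
        r2 = simulate_benchmark(design, cfg, reference=reference, alleles=alleles)
        assert all(a.reads == b.reads for a, b in zip(r1.libraries, r2.libraries))
        assert r1.truth == r2.truth


class TestSimulateUlpBins:
    def test_neutral_profile_flat(self):
        bins = simulate_ulp_bins(0.0, None, mean_reads_per_bin=5000, seed=1)
        by_chrom = bins.groupby("chrom")["count"].mean()
        assert by_chrom.max() / by_chrom.min() < 1.02

    def test_loss_depth_ratio_closed_form(self):
        # single-copy loss at f=0.30: expected depth ratio (2*0.7 + 0.3)/2 = 0.85
        profile = [("chr1", 0, 100_000_000, 1)]
        bins = simulate_ulp_bins(0.30, profile, mean_reads_per_bin=20_000, seed=2)
        inside = bins[(bins.chrom == "chr1") & (bins.start < 100_000_000)]["count"].mean()
        outside = bins[bins.chrom == "chr2"]["count"].mean()
        assert inside / outside == pytest.approx(0.85, abs=0.01)

    def test_batch_artifacts_shift_bins(self):
        art = [("chr5", 0, 50_000_000, 0.5)]
        plain = simulate_ulp_bins(0.0, None, 10_000, seed=3)
        shifted = simulate_ulp_bins(0.0, None, 10_000, batch_artifacts=art, seed=3)
        sel = (plain.chrom == "chr5") & (plain.start < 50_000_000)
        ratio = shifted[sel]["count"].mean() / plain[sel]["count"].mean()
        assert ratio == pytest.approx(2**0.5, rel=0.02)

    def test_invalid_profile_interval(self):
        with pytest.raises(ValueError):
            simulate_ulp_bins(0.1, [("chrX", 0, 1000, 1)], seed=1)
        with pytest.raises(ValueError):
            simulate_ulp_bins(0.1, [("chr1", 0, 10**10, 1)], seed=1)

    def test_prostate_profile_covers_altered_regions(self):
        bins = simulate_ulp_bins(0.3, PROSTATE_SCNA_PROFILE, 5000, seed=4)
        loss = bins[(bins.chrom == "chr8") & (bins.end <= 40_000_000)]["count"].mean()
        gain = bins[(bins.chrom == "chr8") & (bins.start >= 60_000_000)]["count"].mean()
        neutral = bins[bins.chrom == "chr2"]["count"].mean()
        assert loss < neutral < gain


class TestSimulateMultiregion:
    def test_truncal_present_in_all_foci(self):
        matrix, tree, classes = simulate_multiregion(4, 20, "linear", seed=1)
        for mut, cls in classes.items():
            if cls == "trunk":
                assert matrix.column(mut).all()
        assert any(c == "trunk" for c in classes.values())

    def test_two_foci_only_trunk_and_leaf(self):
        _, _, classes = simulate_multiregion(2, 15, "linear", seed=2)
        assert set(classes.values()) <= {"trunk", "leaf"}

    @pytest.mark.parametrize("seed", range(10))
    def test_classifier_recovers_truth_labels(self, seed):
        matrix, _, classes = simulate_multiregion(5, 30, "random", seed=seed)
        assert classify_clonality(matrix) == classes
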