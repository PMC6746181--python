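"""Tests of the ULP-WGS copy-number stage: binning, normalisation,
segmentation, artifact flagging, state calls and tumor-content estimation."""

import numpy as np
import pandas as pd
import pytest

from ctdnakit import (
    CnaConfig,
    Segment,
    bin_counts,
    call_states,
    estimate_ptc,
    flag_artifacts,
    gc_normalize,
    profile_sample,
    segment_bins,
    sensitive_config,
    simulate_ulp_bins,
)
from ctdnakit._genome import DEFAULT_EDTA_ARTIFACTS, PROSTATE_SCNA_PROFILE

MB = 1_000_000


class TestBinCounts:
    def test_hand_enumerated_positions(self):
        genome = {"chrT": 3 * MB}
        pos = [0, 10, MB - 1] * 10 + [MB, MB + 5] * 30 + [2 * MB] * 10
        df = bin_counts(pd.DataFrame({"chrom": "chrT", "pos": pos}), MB, genome)
        assert list(df["count"]) == [30, 60, 10]
        assert df["count"].sum() == len(pos)

    def test_empty_input_zero_bins(self):
        genome = {"chrT": 2 * MB}
        df = bin_counts(pd.DataFrame({"chrom": [], "pos": []}), MB, genome)
        assert (df["count"] == 0).all() and len(df) == 2

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            bin_counts(pd.DataFrame({"chrom": ["chrZ"], "pos": [5]}), MB, {"chrT": MB})

    def test_precomputed_table_passthrough(self):
        df = simulate_ulp_bins(0.0, None, 100, seed=1)
        out = bin_counts(df)
        assert out["count"].equals(df["count"])


class TestGcNormalize:
    def test_no_bias_centred_at_zero(self):
        bins = simulate_ulp_bins(0.0, None, mean_reads_per_bin=5000, seed=2)
        normed = gc_normalize(bins)
        assert abs(normed["norm_log2"].mean()) < 0.02

    def test_monotone_gc_bias_removed(self):
        bins = simulate_ulp_bins(
            0.0, None, mean_reads_per_bin=5000, gc_bias_params=(0.5, 0.0), seed=3
        )
        raw_corr = np.corrcoef(bins["gc"], np.log2(bins["count"] + 1))[0, 1]
        normed = gc_normalize(bins)
        corr = np.corrcoef(normed["gc"], normed["norm_log2"])[0, 1]
        assert abs(raw_corr) > 0.3 and abs(corr) < 0.05

    def test_single_copy_loss_log_ratio(self):
        # log2 of the f=0.30 loss depth ratio: log2(0.85) = -0.234
        profile = [("chr2", 0, 240 * MB, 1)]
        bins = simulate_ulp_bins(0.30, profile, mean_reads_per_bin=20_000, seed=4)
        normed = gc_normalize(bins)
        loss = normed[normed.chrom == "chr2"]["norm_log2"].mean()
        assert loss == pytest.approx(np.log2(0.85), abs=0.02)


class TestSegmentBins:
    def test_flat_input_one_segment_per_chromosome(self):
        bins = simulate_ulp_bins(0.0, None, 5000, seed=5)
        segs = segment_bins(gc_normalize(bins))
        assert len(segs) == bins["chrom"].nunique()
        assert {s.chrom for s in segs} == set(bins["chrom"])

    def test_step_breakpoint_recovered(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.05, 120), rng.normal(0.5, 0.05, 50)])
        bins = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(170) * MB,
                "end": (np.arange(170) + 1) * MB,
                "gc": 0.41,
                "count": 1000,
                "norm_log2": x,
            }
        )
        segs = segment_bins(bins, CnaConfig(segment_penalty=0.3))
        assert len(segs) == 2
        assert abs(segs[0].end // MB - 120) <= 2

    def test_segments_never_span_chromosomes(self):
        bins = simulate_ulp_bins(0.3, PROSTATE_SCNA_PROFILE, 3000, seed=7)
        segs = segment_bins(gc_normalize(bins), sensitive_config())
        by_chrom = bins.groupby("chrom")["end"].max()
        assert all(s.end <= by_chrom[s.chrom] for s in segs)
        assert all(s.start >= 0 for s in segs)


class TestCallStates:
    @pytest.mark.parametrize(
        "mean_log2,expected", [(0.0, "neutral"), (-0.234, "loss"), (0.05, "neutral"), (0.3, "gain")]
    )
    def test_thresholding(self, mean_log2, expected):
        seg = Segment("chr1", 0, MB, 1, mean_log2)
        assert call_states([seg])[0].state == expected

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            call_states([], gain_cut=-0.1, loss_cut=0.1)


class TestFlagArtifacts:
    def _cohort(self, n_edta=5, n_streck=5, tumor_in=None):
        cohort, batches = {}, {}
        for i in range(n_edta + n_streck):
            sample = f"S{i}"
            batch = "EDTA" if i < n_edta else "STRECK"
            batches[sample] = batch
            art = DEFAULT_EDTA_ARTIFACTS if batch == "EDTA" else None
            f = 0.3 if sample == tumor_in else 0.0
            profile = PROSTATE_SCNA_PROFILE if f else None
            bins = simulate_ulp_bins(f, profile, 3000, batch_artifacts=art, seed=100 + i)
            segs, _ = profile_sample(bins, sensitive_config())
            cohort[sample] = segs
        return cohort, batches

    def test_batch_shared_artifacts_flagged_everywhere(self):
        cohort, batches = self._cohort()
        flag_artifacts(cohort, batches)
        for sample, batch in batches.items():
            flagged = [s for s in cohort[sample] if s.artifact]
            altered = [s for s in cohort[sample] if s.state != "neutral"]
            if batch == "EDTA":
                assert flagged and len(flagged) == len(altered)
            else:
                assert not flagged

    def test_private_alteration_not_flagged_and_ptc_preserved(self):
        cohort, batches = self._cohort(tumor_in="S7")
        flag_artifacts(cohort, batches)
        tumor_segs = cohort["S7"]
        assert not any(s.artifact for s in tumor_segs if s.state != "neutral")
        summary = estimate_ptc(tumor_segs)
        assert summary.ptc == pytest.approx(0.30, abs=0.05)

    def test_small_batch_rejected(self):
        seg = Segment("chr1", 0, MB, 1, 0.0)
        with pytest.raises(ValueError):
            flag_artifacts({"S0": [seg]}, {"S0": "solo"})


class TestEstimatePtc:
    def test_no_alterations_indeterminate(self):
        segs = call_states([Segment("chr1", 0, 100 * MB, 100, 0.001)])
        summary = estimate_ptc(segs)
        assert summary.ptc is None and summary.pga == 0.0

    def test_single_loss_inverts_closed_form(self):
        # r = log2(0.85) implies f = 2(1 - 2^r) = 0.30
        segs = call_states(
            [
                Segment("chr1", 0, 50 * MB, 50, float(np.log2(0.85))),
                Segment("chr2", 0, 50 * MB, 50, 0.0),
            ]
        )
        summary = estimate_ptc(segs)
        assert summary.ptc == pytest.approx(0.30, abs=1e-9)
        assert summary.pga == pytest.approx(0.5)

    def test_artifact_segments_excluded(self):
        loss = Segment("chr1", 0, 50 * MB, 50, -0.3, state="loss", artifact=True)
        neutral = Segment("chr2", 0, 50 * MB, 50, 0.0, state="neutral")
        summary = estimate_ptc([loss, neutral])
        assert summary.ptc is None and summary.pga == 0.0

    @pytest.mark.parametrize("f", [0.07, 0.14, 0.30])
    def test_parameter_recovery(self, f):
        cfg = sensitive_config()
        errors = []
        for seed in range(10):
            bins = simulate_ulp_bins(
                f, PROSTATE_SCNA_PROFILE, 3000, gc_bias_params=(0.8, -2.0), seed=seed
            )
            _, summary = profile_sample(bins, cfg)
            assert summary.ptc is not None
            errors.append(abs(summary.ptc - f))
        assert max(errors) <= 0.05

    def test_zero_tumor_specificity(self):
        indeterminate = 0
        for seed in range(20):
            bins = simulate_ulp_bins(0.0, None, 3000, gc_bias_params=(0.8, -2.0), seed=seed)
            _, summary = profile_sample(bins, sensitive_config())
            indeterminate += summary.ptc is None
        assert indeterminate >= 19

    def test_ptc_monotone_in_tumor_fraction(self):
        fractions = [0.07, 0.10, 0.14, 0.20, 0.30]
        ptcs = []
        for f in fractions:
            bins = simulate_ulp_bins(f, PROSTATE_SCNA_PROFILE, 3000, seed=8)
            _, summary = profile_sample(bins, sensitive_config())
            ptcs.append(summary.ptc)
        assert all(p is not None for p in ptcs)
        from scipy.stats import spearmanr

        assert spearmanr(fractions, ptcs).statistic > 0.9
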