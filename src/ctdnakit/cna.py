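"""Ultra-low-pass WGS copy-number profiling and tumor-content estimation.

Reads are counted in fixed genomic bins (1 Mb default), GC-normalised by
decile medians, segmented by deterministic recursive binary splitting, and
thresholded into loss/neutral/gain states.  Recurrent segments shared by most
samples of a collection batch are flagged as artifacts and excluded from the
summary statistics.  Percent tumor content (PTC) inverts the single-copy
mixture relation: a region with tumor copy number c at tumor fraction f has
depth ratio (2(1-f) + c*f)/2, so a single-copy loss (c=1) implies
f = 2(1 - 2**r) and a single-copy gain (c=3) implies f = 2(2**r - 1) at
observed log-ratio r.  PTC is the bin-length-weighted mean of the
per-segment estimates; with no qualifying altered segment PTC is
indeterminate.  Percent genome altered (PGA) is the fraction of binned
genome in non-neutral, non-artifact segments.  Ploidy is reported
uncorrected (genome-wide mean copy estimate, no purity adjustment).
Autosomes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CnaProfileSummary, Segment


@dataclass
class CnaConfig:
    """Analysis thresholds of the copy-number stage.

    ``segment_penalty`` is the minimum |mean log2 difference| for accepting
    a split; ``gain_cut``/``loss_cut`` threshold segment states.  The
    defaults (±0.1) call only events visible at tumor fractions above ~25%
    under the single-copy model; :func:`sensitive_config` lowers them to the
    shallow-depth noise floor for low-burden plasma.
    """

    bin_size: int = 1_000_000
    segment_penalty: float = 0.1
    min_segment_bins: int = 10
    gain_cut: float = 0.1
    loss_cut: float = -0.1
    recurrence_threshold: float = 0.8
    min_reciprocal_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (self.loss_cut < 0.0 < self.gain_cut):
            raise ValueError("need loss_cut < 0 < gain_cut")
        if not (0.0 < self.recurrence_threshold <= 1.0):
            raise ValueError("recurrence_threshold must lie in (0, 1]")


def sensitive_config(**overrides) -> CnaConfig:
    """Thresholds tuned for low tumor fractions (detects f >= ~0.06 events)."""
    params = dict(segment_penalty=0.04, gain_cut=0.04, loss_cut=-0.04)
    params.update(overrides)
    return CnaConfig(**params)


# ---------------------------------------------------------------------------
# Binning and normalisation


def bin_counts(
    data: pd.DataFrame,
    bin_size: int = 1_000_000,
    genome: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Build a bin-count table from read positions or validate a precomputed one.

    ``data`` is either a precomputed table (columns chrom/start/end/gc/count,
    passed through after validation) or a read-position table (columns
    chrom/pos, 0-based) counted into ``bin_size`` bins tiling ``genome``.
    Total read count is conserved; unknown chromosomes are an error.
    """
    if {"chrom", "start", "end", "count"} <= set(data.columns):
        df = data.copy()
        if (df["count"] < 0).any():
            raise ValueError("raw counts must be >= 0")
        return df
    if not {"chrom", "pos"} <= set(data.columns):
        raise ValueError("expected columns chrom/start/end/gc/count or chrom/pos")
    if genome is None:
        raise ValueError("a genome (chrom -> length) is required to bin positions")
    unknown = set(data["chrom"]) - set(genome)
    if unknown:
        raise ValueError(f"positions on unknown chromosomes: {sorted(unknown)}")
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, bin_size)
        pos = data.loc[data["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= length).any():
            raise ValueError(f"positions outside {chrom}")
        counts = np.bincount(pos // bin_size, minlength=len(starts))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, length),
                    "gc": np.nan,
                    "count": counts,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gc_normalize(bins: pd.DataFrame, n_deciles: int = 10) -> pd.DataFrame:
    """Add a GC-corrected ``norm_log2`` column.

    Counts are divided by the median count of their GC decile, then log2-
    transformed against the genome-wide median of the corrected values.
    Bins in deciles with zero median are masked (NaN).
    """
    if "gc" not in bins.columns or bins["gc"].isna().all():
        raise ValueError("gc_fraction must be populated for GC normalisation")
    out = bins.copy()
    decile = pd.qcut(out["gc"], q=n_deciles, labels=False, duplicates="drop")
    med = out.groupby(decile)["count"].transform("median")
    corrected = np.where(med > 0, out["count"] / med, np.nan)
    overall = np.nanmedian(corrected)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["norm_log2"] = np.log2(corrected / overall)
    out.loc[~np.isfinite(out["norm_log2"]), "norm_log2"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Segmentation


def _best_split(x: np.ndarray, min_bins: int) -> Optional[tuple[int, float]]:
    """Most significant two-sample split point of one chromosome arm of bins.

    Returns (index, |mean difference|) of the split maximising the pooled
    two-sample t statistic, or None when the series is too short.
    """
    n = len(x)
    if n < 2 * min_bins:
        return None
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(min_bins, n - min_bins + 1)
    n1, n2 = k, n - k
    s1, s2 = cs[k - 1], cs[-1] - cs[k - 1]
    q1, q2 = css[k - 1], css[-1] - css[k - 1]
    m1, m2 = s1 / n1, s2 / n2
    var = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
    pooled = np.sqrt(np.maximum(var / np.maximum(n - 2, 1), 1e-12))
    t = np.abs(m1 - m2) / (pooled * np.sqrt(1.0 / n1 + 1.0 / n2))
    j = int(np.argmax(t))
    return int(k[j]), float(abs(m1[j] - m2[j]))


def _segment_values(x: np.ndarray, penalty: float, min_bins: int) -> list[tuple[int, int]]:
    """Recursive binary segmentation; returns half-open bin-index intervals."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        best = _best_split(x[lo:hi], min_bins)
        if best is None or best[1] < penalty:
            out.append((lo, hi))
            continue
        cut = lo + best[0]
        stack.append((cut, hi))
        stack.append((lo, cut))
    return sorted(out)


def segment_bins(bins: pd.DataFrame, config: Optional[CnaConfig] = None) -> list[Segment]:
    """Segment normalised bins, never crossing chromosome boundaries.

    Deterministic recursive binary splitting: each candidate split maximises
    the two-sample t statistic and is accepted while the between-side mean
    difference reaches ``segment_penalty``.  Masked (NaN) bins are skipped.
    """
    cfg = config or CnaConfig()
    if "norm_log2" not in bins.columns:
        raise ValueError("run gc_normalize first (norm_log2 missing)")
    segments: list[Segment] = []
    for chrom in bins["chrom"].unique():
        sub = bins[(bins["chrom"] == chrom) & bins["norm_log2"].notna()]
        if sub.empty:
            continue
        x = sub["norm_log2"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for lo, hi in _segment_values(x, cfg.segment_penalty, cfg.min_segment_bins):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_bins=hi - lo,
                    mean_log2=float(x[lo:hi].mean()),
                )
            )
    return segments


def call_states(
    segments: Sequence[Segment],
    gain_cut: float = 0.1,
    loss_cut: float = -0.1,
) -> list[Segment]:
    """Assign loss/neutral/gain states by thresholding segment means."""
    if not loss_cut < 0 < gain_cut:
        raise ValueError("need loss_cut < 0 < gain_cut")
    for s in segments:
        if s.mean_log2 <= loss_cut:
            s.state = "loss"
        elif s.mean_log2 >= gain_cut:
            s.state = "gain"
        else:
            s.state = "neutral"
    return list(segments)


# ---------------------------------------------------------------------------
# Cohort artifact flagging


def _reciprocal_overlap(a: Segment, b: Segment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def flag_artifacts(
    cohort_segments: dict[str, list[Segment]],
    batches: dict[str, str],
    recurrence_threshold: float = 0.8,
    min_reciprocal_overlap: float = 0.5,
) -> dict[str, list[Segment]]:
    """Flag recurrent batch-shared non-neutral segments as artifacts.

    A non-neutral segment is flagged when non-neutral segments with
    reciprocal overlap >= ``min_reciprocal_overlap`` occur in at least
    ``recurrence_threshold`` of the samples of its collection batch
    (batches need >= 2 samples).  Flags are set in place; the mapping is
    returned for convenience.
    """
    batch_members: dict[str, list[str]] = {}
    for sample, batch in batches.items():
        batch_members.setdefault(batch, []).append(sample)
    for batch, members in batch_members.items():
        if len(members) < 2:
            raise ValueError(f"batch {batch} has fewer than 2 samples")
    for sample, segments in cohort_segments.items():
        members = batch_members[batches[sample]]
        for seg in segments:
            if seg.state == "neutral":
                continue
            support = 0
            for other in members:
                hits = (
                    o
                    for o in cohort_segments[other]
                    if o.state != "neutral"
                    and _reciprocal_overlap(seg, o) >= min_reciprocal_overlap
                )
                if any(hits):
                    support += 1
            if support / len(members) >= recurrence_threshold:
                seg.artifact = True
    return cohort_segments


# ---------------------------------------------------------------------------
# Tumor-content summary


def estimate_ptc(segments: Sequence[Segment]) -> CnaProfileSummary:
    """Summarise a profile into PTC, PGA and uncorrected ploidy.

    Per non-artifact altered segment the tumor fraction implied by a
    single-copy event is ``2(1 - 2**r)`` for losses and ``2(2**r - 1)`` for
    gains (r = mean log2 ratio), clipped to [0, 1]; PTC is the
    bin-length-weighted mean over those segments and indeterminate (None)
    when none qualify.
    """
    total_bins = sum(s.n_bins for s in segments)
    if total_bins == 0:
        raise ValueError("no segments to summarise")
    altered = [s for s in segments if s.state != "neutral" and not s.artifact]
    n_artifact = sum(1 for s in segments if s.artifact)

    if altered:
        weights = np.array([s.n_bins for s in altered], dtype=float)
        f_hat = np.array(
            [
                2.0 * (1.0 - 2.0**s.mean_log2)
                if s.state == "loss"
                else 2.0 * (2.0**s.mean_log2 - 1.0)
                for s in altered
            ]
        )
        ptc = float(np.clip(np.average(np.clip(f_hat, 0.0, 1.0), weights=weights), 0.0, 1.0))
    else:
        ptc = None

    pga = sum(s.n_bins for s in altered) / total_bins
    copy = np.array([2.0 * 2.0**s.mean_log2 for s in segments])
    wts = np.array([s.n_bins for s in segments], dtype=float)
    ploidy = float(np.average(copy, weights=wts))
    return CnaProfileSummary(
        ptc=ptc,
        pga=float(pga),
        ploidy_uncorrected=ploidy,
        n_altered_segments=len(altered),
        n_artifact_segments=n_artifact,
    )


def profile_sample(
    bins: pd.DataFrame, config: Optional[CnaConfig] = None
) -> tuple[list[Segment], CnaProfileSummary]:
    """Single-sample convenience pipeline: normalise, segment, call, summarise.

    No cohort-level artifact flagging is applied here; use
    :func:`flag_artifacts` across samples before summarising when batch
    labels are available.
    """
    cfg = config or CnaConfig()
    normed = gc_normalize(bins)
    segs = call_states(segment_bins(normed, cfg), cfg.gain_cut, cfg.loss_cut)
    return segs, estimate_ptc(segs)
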