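"""Re-evaluation of mutant-allele detection under reduced sequencing depth.

Depth reduction is modelled as uniform sampling of raw reads without
replacement (discarding sequencer output), applied before UMI grouping,
either over the whole library or independently within each target's assigned
reads.  ``detection_vs_depth`` reruns the full caller at each depth of a grid
and reports deduplicated mutant counts, their retention relative to full
depth, and binary detection.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import CallerConfig
from .types import AmpliconDesign, TargetAllele
from .umi import AnchorIndex, call_reads

Read = Union[str, tuple[str, str]]


def _seq(read: Read) -> str:
    return read[1] if isinstance(read, tuple) else read


def downsample_library(
    reads: Sequence[Read], n_total: int, seed: int = 0
) -> list[Read]:
    """Uniform subsample of ``n_total`` reads without replacement.

    Keeps the original read order; requesting at least the library size
    returns all reads unchanged.  Deterministic in ``seed``.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    reads = list(reads)
    if n_total >= len(reads):
        return reads
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n_total, replace=False))
    return [reads[i] for i in keep]


def downsample_per_target(
    reads: Sequence[Read],
    n_per_target: int,
    amplicons: Union[Sequence[AmpliconDesign], AnchorIndex],
    caller_config: Optional[CallerConfig] = None,
    seed: int = 0,
) -> list[Read]:
    """Independent uniform subsampling within each locus's assigned reads.

    Reads that cannot be assigned to any target (or are too short) are kept
    out of the output entirely; each assigned group is capped at
    ``n_per_target`` reads.
    """
    if n_per_target < 0:
        raise ValueError("n_per_target must be >= 0")
    cfg = caller_config or CallerConfig()
    index = amplicons if isinstance(amplicons, AnchorIndex) else AnchorIndex(
        amplicons, cfg.anchor_max_mismatch
    )
    groups: dict[str, list[int]] = defaultdict(list)
    for i, read in enumerate(reads):
        seq = _seq(read)
        if len(seq) < cfg.min_usable_read_length:
            continue
        locus = index.assign(seq[cfg.umi_length : cfg.umi_length + index.anchor_length])
        if locus is not None:
            groups[locus].append(i)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for locus in sorted(groups):
        idx = groups[locus]
        if n_per_target >= len(idx):
            keep.extend(idx)
        else:
            keep.extend(np.array(idx)[rng.choice(len(idx), n_per_target, replace=False)])
    return [reads[i] for i in sorted(keep)]


def detection_vs_depth(
    reads: Sequence[Read],
    depth_grid: Sequence[Optional[int]],
    alleles: Sequence[TargetAllele],
    amplicons: Sequence[AmpliconDesign],
    caller_config: Optional[CallerConfig] = None,
    scope: str = "per_target",
    seed: int = 0,
) -> pd.DataFrame:
    """Rerun the caller across a grid of sequencing depths.

    ``depth_grid`` entries are read budgets (``None`` = full depth); a
    full-depth baseline row set is always included.  ``scope`` selects
    whole-library or per-target subsampling.  Returns one row per
    (depth, locus) with ``mutant_families``, ``detected`` and
    ``retention`` = mutant families over the full-depth baseline.
    """
    if len(depth_grid) == 0:
        raise ValueError("depth grid must be non-empty")
    if scope not in ("per_target", "library"):
        raise ValueError("scope must be 'per_target' or 'library'")
    cfg = caller_config or CallerConfig()
    reads = list(reads)

    baseline = call_reads(reads, alleles, amplicons, cfg).reports
    grid: list[Optional[int]] = [None]
    grid += [d for d in depth_grid if d is not None]

    rows = []
    for depth in grid:
        if depth is None:
            reports = baseline
        else:
            if scope == "library":
                sub = downsample_library(reads, depth, seed=seed)
            else:
                sub = downsample_per_target(reads, depth, amplicons, cfg, seed=seed)
            reports = call_reads(sub, alleles, amplicons, cfg).reports
        for locus_id, rep in reports.items():
            base = baseline[locus_id].mutant_families
            rows.append(
                {
                    "depth": -1 if depth is None else depth,
                    "locus_id": locus_id,
                    "mutant_families": rep.mutant_families,
                    "detected": rep.detected,
                    "retention": rep.mutant_families / base if base else np.nan,
                }
            )
    return pd.DataFrame(rows)
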