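"""Synthetic genome model for the ULP-WGS simulator.

Autosome lengths approximate the human reference (GRCh37, rounded to 1 Mb).
Sex chromosomes are excluded throughout: tumor-content and genome-altered
fractions are computed over autosomes only.  ``PROSTATE_SCNA_PROFILE`` is a
stylised prostate-cancer copy-number landscape built from single-copy events
at recurrently altered regions (8p/6q/10q/13q/16q/17p losses, 8q gain).
"""

from __future__ import annotations

MB = 1_000_000

# autosome -> length in Mb (GRCh37, rounded)
AUTOSOME_MB: dict[str, int] = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51,
}


def autosome_lengths_bp() -> dict[str, int]:
    return {c: n * MB for c, n in AUTOSOME_MB.items()}


# (chrom, start_bp, end_bp, tumor copy number); diploid elsewhere
PROSTATE_SCNA_PROFILE: list[tuple[str, int, int, int]] = [
    ("chr6", 90 * MB, 150 * MB, 1),    # 6q loss
    ("chr8", 0, 40 * MB, 1),           # 8p loss (NKX3-1)
    ("chr8", 60 * MB, 146 * MB, 3),    # 8q gain (MYC)
    ("chr10", 80 * MB, 120 * MB, 1),   # 10q loss (PTEN)
    ("chr13", 30 * MB, 90 * MB, 1),    # 13q loss (RB1)
    ("chr16", 55 * MB, 90 * MB, 1),    # 16q loss
    ("chr17", 0, 22 * MB, 1),          # 17p loss (TP53)
]

# Recurrent collection-batch artifact signature: spurious log2 shifts shared
# by every sample of an affected batch (direction/magnitude are free
# parameters of the simulator, not matched to any particular dataset).
DEFAULT_EDTA_ARTIFACTS: list[tuple[str, int, int, float]] = [
    ("chr5", 40 * MB, 100 * MB, -0.12),
    ("chr6", 0, 60 * MB, 0.12),
    ("chr8", 100 * MB, 146 * MB, 0.12),
    ("chr12", 30 * MB, 100 * MB, -0.12),
]
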