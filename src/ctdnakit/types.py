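"""Core domain types shared across the pipeline.

A *target allele* is one patient-specific somatic SNV to be resequenced in
plasma.  A *UMI family* is the set of reads sharing one unique molecular
identifier at one locus, presumed to derive from a single template molecule.
A *locus call report* summarises deduplicated mutant-molecule counting and
binary detection for one target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

BASES = "ACGT"

CLONALITY_CLASSES = ("trunk", "branch", "leaf", "unknown")


@dataclass(frozen=True)
class TargetAllele:
    """One patient-specific somatic SNV targeted by the bespoke assay."""

    locus_id: str
    chrom: str
    pos: int  # 1-based position of the variant on ``chrom``
    ref: str
    alt: str
    clonality: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref and alt must be single bases")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be one of {BASES}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.clonality not in CLONALITY_CLASSES:
            raise ValueError(f"clonality must be one of {CLONALITY_CLASSES}")


@dataclass(frozen=True)
class AmpliconDesign:
    """A short amplicon window around one target allele.

    Coordinates are 0-based half-open on the reference sequence named
    ``chrom``.  ``anchor`` is the primer-proximal k-mer used for
    alignment-free locus assignment; reads are expected to begin with it
    (after UMI removal).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    target_offset: int  # 0-based offset of the target base within the amplicon
    anchor: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("sequence length must equal end - start")
        if not (0 <= self.target_offset < len(self.sequence)):
            raise ValueError("target_offset must fall inside the amplicon")
        if not self.sequence.startswith(self.anchor):
            raise ValueError("anchor must be a prefix of the amplicon sequence")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UmiFamily:
    """All reads sharing one (merged) UMI at one locus."""

    locus_id: str
    umi: str
    read_count: int
    consensus_base: Optional[str]  # None when the vote at the target base ties
    agreement_fraction: float
    is_mutant: bool

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if not (0.0 <= self.agreement_fraction <= 1.0):
            raise ValueError("agreement_fraction must lie in [0, 1]")


@dataclass
class LocusCallReport:
    """Per-locus deduplicated mutant counting and binary detection.

    ``wildtype_ignored`` records that wild-type families are tallied but play
    no role in detection or molecule-number accounting (only mutant families
    are quantified against the spike-in curve).
    """

    locus_id: str
    total_reads: int
    assigned_reads: int
    total_families: int
    mutant_families: int
    detected: bool
    wildtype_ignored: bool = True
    interpolated_molecules: Optional[float] = None
    at_or_above_saturation: bool = False

    def __post_init__(self) -> None:
        if self.mutant_families > self.total_families:
            raise ValueError("mutant_families cannot exceed total_families")

    @property
    def dedup_mutant_count(self) -> int:
        return self.mutant_families

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dedup_mutant_count"] = self.dedup_mutant_count
        return d


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one (library, locus) pair of a simulated experiment."""

    library_id: str
    locus_id: str
    true_template_molecules: int
    true_mutant: bool


@dataclass
class Segment:
    """One copy-number segment of a binned genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    state: str = "neutral"  # {loss, neutral, gain}
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("a segment must contain at least one bin")
        if self.state not in ("loss", "neutral", "gain"):
            raise ValueError("state must be loss/neutral/gain")


@dataclass
class CnaProfileSummary:
    """Sample-level summary of a ULP-WGS copy-number profile.

    ``ptc`` is the estimated percent tumor content as a fraction of cfDNA; it
    is ``None`` (indeterminate) when no non-artifact altered segment exists.
    ``pga`` is the fraction of the binned genome in non-neutral, non-artifact
    segments.  ``ploidy_uncorrected`` is the genome-wide mean copy estimate
    with no tumor-fraction or purity correction applied.
    """

    ptc: Optional[float]
    pga: float
    ploidy_uncorrected: float
    n_altered_segments: int = 0
    n_artifact_segments: int = 0

    def __post_init__(self) -> None:
        if self.ptc is not None and not (0.0 <= self.ptc <= 1.0):
            raise ValueError("ptc must lie in [0, 1] when determinate")
        if not (0.0 <= self.pga <= 1.0):
            raise ValueError("pga must lie in [0, 1]")
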