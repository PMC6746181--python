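"""Configuration objects for simulation and calling.

``SimConfig`` describes the molecular error model of the cfDNA library
simulator: ~165 bp fragments, an inline UMI occupying the first bases of each
read, first-cycle library-prep errors shared by a whole UMI family, and
independent per-read-base sequencing errors.  ``BenchmarkDesign`` describes
the spike-in experiment layout (genotype sources x log-spaced input amounts x
replicates, plus negative controls, each prepped more than once).
``CallerConfig`` holds the error-suppression thresholds of the UMI caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .types import TargetAllele


def _check_rate(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cfDNA read simulator.

    Parameters
    ----------
    seed : master seed; the same seed yields bit-identical outputs.
    fragment_len_mean, fragment_len_sd : cfDNA fragment length (bp), normal,
        truncated at the amplicon length.
    umi_length : bases of inline UMI at the start of every read.
    seq_error_rate : per-base substitution probability per sequenced read.
    prep_error_rate : per-base probability of a first-cycle library-prep
        substitution; such an error is copied into every read of the family.
    pcr_cycles : nominal amplification cycles (drives jackpot overdispersion
        bookkeeping only; read-count spread is set by the geometric model).
    capture_efficiency : fraction of input molecules converted to families.
    mean_reads_per_molecule : expected sequenced reads per captured molecule.
    reads_per_library : total sequencing depth budget per library; when set,
        per-family read counts are allocated multinomially over jackpot
        weights so that the library totals this many reads.
    """

    seed: int = 0
    fragment_len_mean: float = 165.0
    fragment_len_sd: float = 10.0
    umi_length: int = 7
    seq_error_rate: float = 1e-3
    prep_error_rate: float = 1e-4
    pcr_cycles: int = 25
    capture_efficiency: float = 0.5
    mean_reads_per_molecule: float = 50.0
    reads_per_library: Optional[int] = 100_000

    def __post_init__(self) -> None:
        _check_rate("seq_error_rate", self.seq_error_rate)
        _check_rate("prep_error_rate", self.prep_error_rate)
        _check_rate("capture_efficiency", self.capture_efficiency)
        if self.fragment_len_mean <= 0:
            raise ValueError("fragment_len_mean must be > 0")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.mean_reads_per_molecule < 1:
            raise ValueError("mean_reads_per_molecule must be >= 1")
        if self.reads_per_library is not None and self.reads_per_library < 0:
            raise ValueError("reads_per_library must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BenchmarkDesign:
    """Layout of the spike-in benchmarking experiment.

    The default emulates two genotype sources spiked at six log-spaced
    amounts (10^1..10^6 molecules) in duplicate, plus four negative controls,
    with two library preparations per sample: 24 spike-in samples and
    (24 + 4) * 2 = 56 libraries.

    ``level_scope`` controls the meaning of a spike level: ``"library"``
    (default) distributes the level's molecules multinomially over the target
    loci, so per-library truth totals equal the level; ``"locus"`` gives
    every locus the full level (used for per-locus sensitivity experiments).
    ``background_wt_per_locus`` adds wild-type template molecules at every
    locus of every library, mimicking the abundant wild-type cfDNA of donor
    plasma that competes for sequencing depth.
    """

    sources: Sequence[str] = ("PC3", "DU145")
    spike_levels: Sequence[int] = (10, 100, 1_000, 10_000, 100_000, 1_000_000)
    replicates_per_condition: int = 2
    negative_controls: int = 4
    preps_per_sample: int = 2
    alleles: Optional[Sequence[TargetAllele]] = None  # default: 8 synthetic loci
    level_scope: str = "library"
    background_wt_per_locus: int = 500

    def __post_init__(self) -> None:
        levels = list(self.spike_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("spike_levels must be strictly increasing")
        if not self.sources:
            raise ValueError("at least one genotype source is required")
        if self.replicates_per_condition < 1 or self.preps_per_sample < 1:
            raise ValueError("replicates and preps must be >= 1")
        if self.negative_controls < 0:
            raise ValueError("negative_controls must be >= 0")
        if self.level_scope not in ("library", "locus"):
            raise ValueError("level_scope must be 'library' or 'locus'")
        if self.background_wt_per_locus < 0:
            raise ValueError("background_wt_per_locus must be >= 0")

    @property
    def n_spike_samples(self) -> int:
        return len(self.sources) * len(self.spike_levels) * self.replicates_per_condition

    @property
    def n_samples(self) -> int:
        return self.n_spike_samples + self.negative_controls

    @property
    def n_libraries(self) -> int:
        return self.n_samples * self.preps_per_sample

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        if self.alleles is not None:
            d["alleles"] = [asdict(a) for a in self.alleles]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


@dataclass
class CallerConfig:
    """Error-suppression thresholds of the UMI consensus caller.

    A molecule is only counted as mutant when its family has at least
    ``min_reads`` reads agreeing at ``min_agreement`` or better on the
    alternate base, and a locus is only called detected when at least
    ``min_mutant_families`` independent UMI families are mutant -- isolated
    consensus-surviving library-prep errors therefore never trigger a call.
    """

    umi_length: int = 7
    anchor_length: int = 15
    anchor_max_mismatch: int = 1
    umi_merge_distance: int = 1
    min_reads: int = 2
    min_agreement: float = 0.9
    min_mutant_families: int = 2

    def __post_init__(self) -> None:
        if not (0.5 < self.min_agreement <= 1.0):
            raise ValueError("min_agreement must lie in (0.5, 1]")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.min_reads < 1 or self.min_mutant_families < 0:
            raise ValueError("min_reads >= 1 and min_mutant_families >= 0 required")

    @property
    def min_usable_read_length(self) -> int:
        # reads shorter than UMI + 20 usable bases are discarded with a QC tally
        return self.umi_length + 20

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CallerConfig":
        return cls(**json.loads(Path(path).read_text()))
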