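"""UMI consensus caller: single-molecule mutant-allele counting from amplicon reads.

Reads carry an inline UMI in their first bases.  After UMI extraction, reads
are assigned to target loci alignment-free via the amplicon's primer-proximal
anchor k-mer (at most one mismatch), grouped into UMI families (exact
grouping followed by a directional merge that absorbs sequencing-error
satellites of a UMI into their parent), and reduced to a per-family consensus
at the target base.  A family only counts as a mutant molecule when it is
large and internally concordant enough; a locus is only called detected when
at least two independent mutant families exist, which suppresses
consensus-surviving library-prep errors.  Wild-type families are tallied but
otherwise ignored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .config import CallerConfig
from .types import AmpliconDesign, LocusCallReport, TargetAllele, UmiFamily

_AMBIGUOUS = "__ambiguous__"
_BASES = "ACGT"

LocusRead = tuple[str, Optional[str]]  # (umi, base observed at the target position)


# ---------------------------------------------------------------------------
# UMI extraction and locus assignment


def extract_umi(
    read: str, umi_length: int, min_usable: int = 20
) -> Optional[tuple[str, str]]:
    """Split a read into its inline UMI and the remaining template sequence.

    Returns ``None`` for reads shorter than ``umi_length + min_usable``
    (too short to be usable; callers tally these in QC).  With
    ``umi_length == 0`` the whole read is retained under an empty UMI.
    """
    if len(read) < umi_length + min_usable:
        return None
    return read[:umi_length], read[umi_length:]


class AnchorIndex:
    """Alignment-free locus assignment by anchor k-mer with <= 1 mismatch.

    Every read start within ``max_mismatch`` of exactly one amplicon anchor
    is assigned to that amplicon; ambiguous or unmatched prefixes return
    ``None``.  Two amplicons sharing an identical anchor are a configuration
    error, raised at build time.
    """

    def __init__(self, amplicons: Sequence[AmpliconDesign], max_mismatch: int = 1):
        if not amplicons:
            raise ValueError("at least one amplicon design is required")
        self.anchor_length = len(amplicons[0].anchor)
        seen: dict[str, str] = {}
        for a in amplicons:
            if len(a.anchor) != self.anchor_length:
                raise ValueError("all anchors must share one length")
            if a.anchor in seen:
                raise ValueError(
                    f"amplicons {seen[a.anchor]} and {a.locus_id} share anchor {a.anchor}"
                )
            seen[a.anchor] = a.locus_id
        self._lookup: dict[str, str] = {}
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        for a in amplicons:
            for variant in self._variants(a.anchor, max_mismatch):
                prev = self._lookup.get(variant)
                if prev is not None and prev != a.locus_id:
                    self._lookup[variant] = _AMBIGUOUS
                else:
                    self._lookup[variant] = a.locus_id

    @staticmethod
    def _variants(anchor: str, max_mismatch: int) -> Iterable[str]:
        yield anchor
        if max_mismatch >= 1:
            for i, orig in enumerate(anchor):
                for b in _BASES:
                    if b != orig:
                        yield anchor[:i] + b + anchor[i + 1 :]

    def assign(self, prefix: str) -> Optional[str]:
        locus = self._lookup.get(prefix)
        return None if locus is None or locus == _AMBIGUOUS else locus


def assign_locus(
    read: str, amplicons: Union[Sequence[AmpliconDesign], AnchorIndex],
    max_mismatch: int = 1,
) -> Optional[str]:
    """Assign one UMI-trimmed read to a locus, or ``None`` if no unique match."""
    index = amplicons if isinstance(amplicons, AnchorIndex) else AnchorIndex(
        amplicons, max_mismatch
    )
    return index.assign(read[: index.anchor_length])


# ---------------------------------------------------------------------------
# Family grouping


@dataclass
class RawFamily:
    """Aggregated reads of one merged UMI cluster, before consensus."""

    umi: str
    read_count: int
    votes: dict[str, int] = field(default_factory=dict)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mergeable(count_a: int, count_b: int) -> bool:
    # directional rule: the smaller UMI is absorbed when the larger has
    # at least 2a - 1 reads (a = smaller count)
    big, small = max(count_a, count_b), min(count_a, count_b)
    return big >= 2 * small - 1


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _cluster_umis(counts: dict[str, int], merge_distance: int) -> list[list[str]]:
    umis = sorted(counts)
    if merge_distance == 0 or len(umis) <= 1:
        return [[u] for u in umis]
    dsu = _DSU(umis)
    if merge_distance == 1:
        umi_set = set(umis)
        for u in umis:
            for i, orig in enumerate(u):
                for b in _BASES:
                    if b == orig:
                        continue
                    v = u[:i] + b + u[i + 1 :]
                    if v in umi_set and v > u and _mergeable(counts[u], counts[v]):
                        dsu.union(u, v)
    else:
        for i, u in enumerate(umis):
            for v in umis[i + 1 :]:
                if _hamming(u, v) <= merge_distance and _mergeable(counts[u], counts[v]):
                    dsu.union(u, v)
    groups: dict[str, list[str]] = defaultdict(list)
    for u in umis:
        groups[dsu.find(u)].append(u)
    return list(groups.values())


def group_families(
    reads: Sequence[LocusRead], umi_merge_distance: int = 1
) -> list[RawFamily]:
    """Group reads from one locus into UMI families.

    Exact-UMI grouping, then merging of UMI clusters connected by the
    directional rule (Hamming distance within ``umi_merge_distance`` and the
    larger count at least ``2a - 1`` of the smaller); merged families pool
    their read counts and target-base votes.  Deterministic: output sorted
    by descending read count then UMI.
    """
    counts: dict[str, int] = defaultdict(int)
    votes: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for umi, base in reads:
        counts[umi] += 1
        if base is not None:
            votes[umi][base] += 1
    families = []
    for group in _cluster_umis(dict(counts), umi_merge_distance):
        rep = max(group, key=lambda u: (counts[u], [-ord(c) for c in u]))
        pooled: dict[str, int] = defaultdict(int)
        for u in group:
            for b, n in votes[u].items():
                pooled[b] += n
        families.append(RawFamily(rep, sum(counts[u] for u in group), dict(pooled)))
    families.sort(key=lambda f: (-f.read_count, f.umi))
    return families


# ---------------------------------------------------------------------------
# Consensus and detection


def consensus_family(
    family: RawFamily,
    allele: TargetAllele,
    min_reads: int = 2,
    min_agreement: float = 0.9,
) -> UmiFamily:
    """Reduce a family to its consensus base at the target position.

    The consensus is the majority base among reads covering the target; a
    tie yields an ambiguous consensus which is never mutant.  A family is a
    mutant molecule only when its consensus equals the alternate base, it
    has at least ``min_reads`` reads, and the agreement fraction (consensus
    votes over total family reads) reaches ``min_agreement``.
    """
    if not (0.5 < min_agreement <= 1.0):
        raise ValueError("min_agreement must lie in (0.5, 1]")
    consensus: Optional[str] = None
    agreement = 0.0
    if family.votes:
        top = max(family.votes.values())
        leaders = sorted(b for b, n in family.votes.items() if n == top)
        if len(leaders) == 1:
            consensus = leaders[0]
            agreement = top / family.read_count
    is_mutant = (
        consensus == allele.alt
        and family.read_count >= min_reads
        and agreement >= min_agreement
    )
    return UmiFamily(
        locus_id=allele.locus_id,
        umi=family.umi,
        read_count=family.read_count,
        consensus_base=consensus,
        agreement_fraction=agreement,
        is_mutant=is_mutant,
    )


def count_and_detect(
    families: Sequence[UmiFamily],
    allele: TargetAllele,
    min_mutant_families: int = 2,
    total_reads: int = 0,
    assigned_reads: int = 0,
) -> LocusCallReport:
    """Count deduplicated mutant molecules and emit binary detection.

    Detection requires at least ``min_mutant_families`` independent mutant
    UMI families.  Wild-type families contribute to family totals only.
    """
    mutant = sum(f.is_mutant for f in families)
    return LocusCallReport(
        locus_id=allele.locus_id,
        total_reads=total_reads,
        assigned_reads=assigned_reads,
        total_families=len(families),
        mutant_families=mutant,
        detected=mutant >= min_mutant_families,
    )


# ---------------------------------------------------------------------------
# Whole-library pipeline


@dataclass
class CallResult:
    reports: dict[str, LocusCallReport]
    families: dict[str, list[UmiFamily]]
    qc: dict[str, int]


def call_reads(
    reads: Iterable[Union[str, tuple[str, str]]],
    alleles: Sequence[TargetAllele],
    amplicons: Sequence[AmpliconDesign],
    config: Optional[CallerConfig] = None,
) -> CallResult:
    """Run the full caller over a library of reads.

    ``reads`` may be raw sequences or ``(name, sequence)`` pairs.  Returns
    per-locus call reports, per-family detail, and QC tallies
    (``total_reads``, ``discarded_short``, ``unassigned``).
    """
    cfg = config or CallerConfig()
    allele_by_locus = {a.locus_id: a for a in alleles}
    amp_by_locus = {a.locus_id: a for a in amplicons}
    missing = set(amp_by_locus) - set(allele_by_locus)
    if missing:
        raise ValueError(f"amplicons without a target allele: {sorted(missing)}")
    index = AnchorIndex(amplicons, cfg.anchor_max_mismatch)
    ul = cfg.umi_length
    alen = index.anchor_length
    offsets = {lid: amp_by_locus[lid].target_offset for lid in amp_by_locus}

    locus_reads: dict[str, list[LocusRead]] = defaultdict(list)
    total = short = unassigned = 0
    min_len = cfg.min_usable_read_length
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        total += 1
        if len(seq) < min_len:
            short += 1
            continue
        locus = index.assign(seq[ul : ul + alen])
        if locus is None:
            unassigned += 1
            continue
        t = ul + offsets[locus]
        base = seq[t] if t < len(seq) and seq[t] in _BASES else None
        locus_reads[locus].append((seq[:ul], base))

    reports: dict[str, LocusCallReport] = {}
    families_out: dict[str, list[UmiFamily]] = {}
    for locus_id, allele in allele_by_locus.items():
        lreads = locus_reads.get(locus_id, [])
        fams = [
            consensus_family(f, allele, cfg.min_reads, cfg.min_agreement)
            for f in group_families(lreads, cfg.umi_merge_distance)
        ]
        families_out[locus_id] = fams
        reports[locus_id] = count_and_detect(
            fams,
            allele,
            cfg.min_mutant_families,
            total_reads=total,
            assigned_reads=len(lreads),
        )
    qc = {"total_reads": total, "discarded_short": short, "unassigned": unassigned}
    return CallResult(reports, families_out, qc)


def call_fastq(
    fastq_path,
    alleles: Sequence[TargetAllele],
    amplicons: Sequence[AmpliconDesign],
    config: Optional[CallerConfig] = None,
) -> CallResult:
    """Run the caller on a FASTQ(.gz) file."""
    from . import io as ckio

    return call_reads(ckio.read_fastq(fastq_path), alleles, amplicons, config)
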