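"""Multiregion clonality analysis and bespoke-assay target selection.

Somatic mutations observed across several tumor foci are classified by the
set of foci that carry them: *trunk* mutations are present in every focus,
*leaf* mutations in exactly one, and *branch* mutations in some intermediate
subset.  A conflict-free binary focus-by-mutation matrix admits a unique
perfect phylogeny (no pair of mutation columns shows all three of the 10/01/11
gamete patterns); :func:`build_tree` reconstructs it and greedily drops the
minimal offending columns otherwise.  Trunk and major-branch mutations are
then prioritised for the patient-specific plasma assay, and short amplicon
windows (<= 139 bp by default, sized for ~165 bp cfDNA fragments) are placed
around each selected variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AmpliconDesign, TargetAllele

# ---------------------------------------------------------------------------
# Focus-by-mutation matrix


@dataclass
class FocusMutationMatrix:
    """Binary presence matrix of mutations (columns) across tumor foci (rows)."""

    foci: list[str]
    mutations: list[str]
    presence: np.ndarray  # bool, shape (n_foci, n_mutations)
    alleles: Optional[dict[str, TargetAllele]] = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(self.foci) < 2:
            raise ValueError("at least two foci are required")
        if self.presence.shape != (len(self.foci), len(self.mutations)):
            raise ValueError("presence matrix shape must be (n_foci, n_mutations)")
        if self.presence.size and not self.presence.any(axis=0).all():
            bad = [m for m, ok in zip(self.mutations, self.presence.any(axis=0)) if not ok]
            raise ValueError(f"all-zero mutation columns are invalid: {bad}")

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    def column(self, mutation: str) -> np.ndarray:
        return self.presence[:, self.mutations.index(mutation)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.presence.astype(int), index=self.foci, columns=self.mutations
        ).to_csv(path, sep="\t", index_label="focus")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FocusMutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=bool))


def classify_clonality(matrix: FocusMutationMatrix) -> dict[str, str]:
    """Classify each mutation as trunk / branch / leaf by focus sharing.

    Present in all foci -> trunk; in exactly one -> leaf; otherwise branch.
    """
    counts = matrix.presence.sum(axis=0)
    out: dict[str, str] = {}
    for mut, c in zip(matrix.mutations, counts):
        if c == 0:
            raise ValueError(f"mutation {mut} is present in no focus")
        if c == matrix.n_foci:
            out[mut] = "trunk"
        elif c == 1:
            out[mut] = "leaf"
        else:
            out[mut] = "branch"
    return out


# ---------------------------------------------------------------------------
# Clone trees


@dataclass
class CloneNode:
    node_id: int
    clade: frozenset
    parent: Optional[int]
    mutations: list[str] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    focus: Optional[str] = None  # set on leaf nodes that represent a focus


@dataclass
class CloneTree:
    """Rooted clone tree; the root is the germline (no somatic mutations).

    Every mutation is attached to exactly one edge (stored on the child node
    of that edge).  Focus leaves hang below the node whose mutation set they
    carry in full.
    """

    nodes: dict[int, CloneNode]
    root_id: int = 0

    def clades(self, nontrivial: bool = True) -> set[frozenset]:
        """Clades (focus sets) carrying at least one mutation."""
        out = set()
        for n in self.nodes.values():
            if n.mutations and (not nontrivial or len(n.clade) >= 1):
                out.add(n.clade)
        return out

    def mutations_by_edge(self) -> dict[frozenset, list[str]]:
        out: dict[frozenset, list[str]] = {}
        for n in self.nodes.values():
            if n.mutations:
                out.setdefault(n.clade, []).extend(n.mutations)
        return out

    def to_newick(self) -> str:
        def render(nid: int) -> str:
            node = self.nodes[nid]
            label = node.focus if node.focus is not None else f"node{nid}"
            if not node.children:
                return label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}"

        return render(self.root_id) + ";"

    def edge_mutations_json(self) -> dict[str, list[str]]:
        """Sidecar mapping of node label -> mutations on the edge above it."""
        return {
            (n.focus if n.focus is not None else f"node{nid}"): list(n.mutations)
            for nid, n in self.nodes.items()
            if n.mutations
        }


def tree_from_clades(
    clade_mutations: dict[frozenset, list[str]], foci: Sequence[str]
) -> CloneTree:
    """Assemble a clone tree from a laminar family of mutation-bearing clades."""
    all_foci = frozenset(foci)
    nodes = {0: CloneNode(0, all_foci, None)}
    order = sorted(
        clade_mutations,
        key=lambda c: (-len(c), sorted(c)),
    )
    placed = [0]
    for clade in order:
        parent = None
        # smallest superset; on equal clades the deepest (most recent) wins
        for nid in placed:
            pc = nodes[nid].clade
            if clade <= pc and (parent is None or len(pc) <= len(nodes[parent].clade)):
                parent = nid
        nid = len(nodes)
        nodes[nid] = CloneNode(nid, clade, parent, list(clade_mutations[clade]))
        nodes[parent].children.append(nid)
        placed.append(nid)
    # attach each focus as a leaf under its deepest containing node
    for focus in sorted(all_foci):
        best = 0
        for nid in placed:
            c = nodes[nid].clade
            if focus in c and len(c) <= len(nodes[best].clade):
                best = nid
        nid = len(nodes)
        nodes[nid] = CloneNode(nid, frozenset([focus]), best, focus=focus)
        nodes[best].children.append(nid)
    return CloneTree(nodes)


def _three_gamete_conflict(p: int, q: int) -> bool:
    # bitmask columns conflict when 10, 01 and 11 focus patterns all occur
    return bool(p & q) and bool(p & ~q) and bool(q & ~p)


def build_tree(matrix: FocusMutationMatrix) -> tuple[CloneTree, list[str]]:
    """Build the perfect phylogeny of a focus-by-mutation matrix.

    Returns the tree plus the list of mutations dropped to restore
    conflict-freeness (empty when the matrix already satisfies the
    three-gamete condition).  Dropping is greedy: the column pattern involved
    in the most pairwise conflicts is removed first; deterministic
    tie-breaking by mutation multiplicity, then clade size, then pattern.
    """
    masks: dict[int, list[str]] = {}
    for j, mut in enumerate(matrix.mutations):
        mask = 0
        for i in range(matrix.n_foci):
            if matrix.presence[i, j]:
                mask |= 1 << i
        masks.setdefault(mask, []).append(mut)

    dropped: list[str] = []
    while True:
        patterns = sorted(masks)
        conflicts = {p: 0 for p in patterns}
        any_conflict = False
        for i, p in enumerate(patterns):
            for q in patterns[i + 1 :]:
                if _three_gamete_conflict(p, q):
                    conflicts[p] += 1
                    conflicts[q] += 1
                    any_conflict = True
        if not any_conflict:
            break
        victim = max(
            patterns,
            key=lambda p: (conflicts[p], -len(masks[p]), -bin(p).count("1"), -p),
        )
        dropped.extend(masks.pop(victim))

    clade_mutations = {
        frozenset(matrix.foci[i] for i in range(matrix.n_foci) if mask >> i & 1): muts
        for mask, muts in masks.items()
    }
    return tree_from_clades(clade_mutations, matrix.foci), dropped


# ---------------------------------------------------------------------------
# Target selection and amplicon design

_CLASS_RANK = {"trunk": 0, "branch": 1, "leaf": 2}


def select_targets(
    matrix: FocusMutationMatrix,
    k: int,
    classes_allowed: Sequence[str] = ("trunk", "branch"),
) -> list[str]:
    """Pick up to ``k`` mutations for the bespoke assay.

    Trunk mutations come first, then branches by descending focus count
    (prevalence proxies clone size); leaves are excluded unless explicitly
    allowed.  Ties break by genomic coordinate when allele records are
    attached, otherwise by mutation id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    classes = classify_clonality(matrix)
    counts = dict(zip(matrix.mutations, matrix.presence.sum(axis=0)))

    def sort_key(mut: str):
        if matrix.alleles and mut in matrix.alleles:
            a = matrix.alleles[mut]
            coord = (a.chrom, a.pos)
        else:
            coord = ("", 0)
        return (_CLASS_RANK[classes[mut]], -int(counts[mut]), coord, mut)

    eligible = sorted(
        (m for m in matrix.mutations if classes[m] in classes_allowed), key=sort_key
    )
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} eligible mutations for k={k}; returning all",
            stacklevel=2,
        )
    return eligible[:k]


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def design_amplicons(
    reference: dict[str, str],
    targets: Sequence[TargetAllele],
    max_amplicon_len: int = 139,
    anchor_length: int = 15,
    min_flank: int = 20,
    max_homopolymer: int = 7,
) -> tuple[list[AmpliconDesign], list[tuple[str, str]]]:
    """Place one short amplicon window around each target allele.

    Each window is at most ``max_amplicon_len`` bp (sized so the target
    region fits inside a cfDNA fragment), contains the target with at least
    ``min_flank`` bp on each side where the reference permits, and starts
    with an anchor k-mer that is unique across the design and free of
    homopolymer runs longer than ``max_homopolymer``; offending anchors shift
    the window.  Returns ``(designs, failures)`` where failures are
    ``(locus_id, reason)`` pairs.
    """
    if max_amplicon_len < 60:
        raise ValueError("max_amplicon_len must be >= 60")
    designs: list[AmpliconDesign] = []
    failures: list[tuple[str, str]] = []
    used_anchors: set[str] = set()

    for allele in targets:
        seq = reference.get(allele.chrom)
        if seq is None:
            failures.append((allele.locus_id, f"unknown reference {allele.chrom}"))
            continue
        L = len(seq)
        t = allele.pos - 1
        if not (0 <= t < L):
            failures.append((allele.locus_id, "target outside reference"))
            continue
        if seq[t] != allele.ref:
            failures.append((allele.locus_id, "reference base mismatch"))
            continue
        amp_len = min(max_amplicon_len, L)
        left_req = min(min_flank, t)
        right_req = min(min_flank, L - 1 - t)
        lo = max(0, t + right_req - amp_len + 1)
        hi = min(L - amp_len, t - left_req)
        if hi < lo:
            failures.append((allele.locus_id, "no window satisfies flank rules"))
            continue
        ideal = int(np.clip(t - amp_len // 2, lo, hi))
        # search outward from the centred window, deterministically
        offsets = sorted(range(lo - ideal, hi - ideal + 1), key=lambda d: (abs(d), d))
        chosen = None
        for d in offsets:
            s = ideal + d
            anchor = seq[s : s + anchor_length]
            if _max_homopolymer(anchor) > max_homopolymer:
                continue
            if anchor in used_anchors:
                continue
            chosen = s
            break
        if chosen is None:
            failures.append((allele.locus_id, "no unique low-complexity anchor window"))
            continue
        anchor = seq[chosen : chosen + anchor_length]
        used_anchors.add(anchor)
        designs.append(
            AmpliconDesign(
                locus_id=allele.locus_id,
                chrom=allele.chrom,
                start=chosen,
                end=chosen + amp_len,
                sequence=seq[chosen : chosen + amp_len],
                target_offset=t - chosen,
                anchor=anchor,
            )
        )
    return designs, failures
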