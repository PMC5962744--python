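"""Lowest-common-ancestor (LCA) taxonomic profiling of alignment hits.

Each read's retained hits — those passing the minimum bitscore and falling
within the top-percent score window of the read's best hit — are mapped to
species via the reference catalog and assigned the deepest taxon common to
all of them.  Taxa are then reported only when their subtree gathers at
least ``min_support`` reads; reads at unsupported taxa are pushed up to the
nearest supported ancestor (conserving reads) or counted unassigned when no
ancestor qualifies.  Rarefaction curves subsample the assigned reads to show
how the number of reported taxa grows with sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import AlignmentHit, ReferenceCatalog, TaxonomyTable

DEFAULT_MIN_BITSCORE = 60.0
DEFAULT_TOP_PERCENT = 10.0
DEFAULT_MIN_SUPPORT = 207


@dataclass(frozen=True)
class ReadAssignment:
    """Per-read LCA result; ``taxon_id`` is None when unassigned."""

    read_id: str
    taxon_id: Optional[int]
    retained_hit_count: int


@dataclass
class TaxonProfile:
    """Read counts per reported taxon (after min-support push-up)."""

    counts: dict[int, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned

    @property
    def n_taxa(self) -> int:
        return len(self.counts)

    def subtree_totals(self, taxonomy: TaxonomyTable) -> dict[int, int]:
        """Counts summed over each taxon's subtree (path-accumulation)."""
        totals: dict[int, int] = {}
        for tid, count in self.counts.items():
            for anc in taxonomy.root_path(tid):
                totals[anc] = totals.get(anc, 0) + count
        return totals


@dataclass
class RarefactionCurve:
    """Mean/sd of reported-taxon counts at increasing subsampling depths."""

    points: list[tuple[int, float, float]]
    replicates: int
    parameters: dict

    @property
    def depths(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def means(self) -> list[float]:
        return [p[1] for p in self.points]


def retained_hits(
    hits_for_read: Sequence[AlignmentHit],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> list[AlignmentHit]:
    """Hits passing the bitscore floor and the top-percent window.

    A hit is retained when its bitscore is at least *min_bitscore* and at
    least ``(1 - top_percent/100)`` of the read's best bitscore.  The empty
    list is a legal result.
    """
    if not 0 <= top_percent <= 100:
        raise ValueError("top_percent must be in [0, 100]")
    if not hits_for_read:
        return []
    best = max(h.bitscore for h in hits_for_read)
    floor = max(min_bitscore, (1.0 - top_percent / 100.0) * best)
    return [h for h in hits_for_read if h.bitscore >= floor]


def lca(taxon_ids: Iterable[int], taxonomy: TaxonomyTable) -> int:
    """Deepest taxon on every input taxon's root path (see TaxonomyTable.lca)."""
    return taxonomy.lca(taxon_ids)


def group_hits_by_read(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Group hits per read, preserving first-seen read order."""
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.read_id, []).append(h)
    return grouped


def assign_reads(
    alignments: Iterable[AlignmentHit],
    taxonomy: TaxonomyTable,
    catalog: ReferenceCatalog,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> list[ReadAssignment]:
    """LCA-assign every read appearing in *alignments*.

    Reads whose hits all fall below the cutoffs come back unassigned.  The
    result order follows first appearance in the input and the assignment of
    each read is independent of hit order.
    """
    assignments = []
    for read_id, hits in group_hits_by_read(alignments).items():
        retained = retained_hits(hits, min_bitscore=min_bitscore, top_percent=top_percent)
        if not retained:
            assignments.append(ReadAssignment(read_id, None, 0))
            continue
        taxa = {catalog.taxon_of(h.subject_id) for h in retained}
        assignments.append(ReadAssignment(read_id, taxonomy.lca(taxa), len(retained)))
    return assignments


def apply_min_support(
    assignments: Iterable[ReadAssignment],
    taxonomy: TaxonomyTable,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> TaxonProfile:
    """Report only taxa whose subtree gathers at least *min_support* reads.

    Reads at an unsupported taxon move to the nearest ancestor whose subtree
    total reaches the threshold; reads for which not even the root qualifies
    are counted unassigned.  Reads are conserved:
    ``sum(profile.counts) + profile.unassigned == len(assignments)``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    direct: dict[int, int] = {}
    unassigned = 0
    for a in assignments:
        if a.taxon_id is None:
            unassigned += 1
        else:
            direct[a.taxon_id] = direct.get(a.taxon_id, 0) + 1

    # Subtree totals are invariant under upward moves, so one pass suffices.
    subtree: dict[int, int] = {}
    for tid, count in direct.items():
        for anc in taxonomy.root_path(tid):
            subtree[anc] = subtree.get(anc, 0) + count

    profile = TaxonProfile(unassigned=unassigned)
    for tid, count in direct.items():
        target = None
        for anc in reversed(taxonomy.root_path(tid)):
            if subtree.get(anc, 0) >= min_support:
                target = anc
                break
        if target is None:
            profile.unassigned += count
        else:
            profile.counts[target] = profile.counts.get(target, 0) + count
    return profile


def rarefaction(
    assignments: Sequence[ReadAssignment],
    depths: Sequence[int],
    replicates: int,
    seed: int,
    taxonomy: TaxonomyTable,
    min_support: int = DEFAULT_MIN_SUPPORT,
    scale_support: bool = True,
) -> RarefactionCurve:
    """Rarefaction of reported-taxon counts over subsampling depths.

    At each depth the assigned reads are subsampled without replacement
    *replicates* times and the profile recomputed.  With *scale_support*
    (default) the support threshold scales proportionally to depth
    (``ceil(min_support * depth / total)``, at least 1) so the curve stays
    informative at shallow depths; pass ``scale_support=False`` to hold the
    absolute threshold fixed instead.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    assigned = [a for a in assignments if a.taxon_id is not None]
    total = len(assigned)
    depths = sorted(depths)
    if depths and depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds assigned read count {total}")
    rng = np.random.default_rng(seed)
    points = []
    for depth in depths:
        taxa_counts = []
        for _ in range(replicates):
            if depth == 0:
                taxa_counts.append(0)
                continue
            idx = rng.choice(total, size=depth, replace=False)
            sub = [assigned[i] for i in idx]
            support = (
                max(1, math.ceil(min_support * depth / total)) if scale_support else min_support
            )
            profile = apply_min_support(sub, taxonomy, min_support=support)
            taxa_counts.append(profile.n_taxa)
        arr = np.asarray(taxa_counts, dtype=float)
        sd = float(arr.std(ddof=1)) if replicates > 1 else 0.0
        points.append((depth, float(arr.mean()), sd))
    return RarefactionCurve(
        points=points,
        replicates=replicates,
        parameters={
            "min_support": min_support,
            "scale_support": scale_support,
            "seed": seed,
            "total_assigned": total,
        },
    )


def write_rarefaction(curve: RarefactionCurve, path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#depth\tmean_taxa\tsd_taxa\n")
        for depth, mean, sd in curve.points:
            fh.write(f"{depth}\t{mean:.4f}\t{sd:.4f}\n")
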