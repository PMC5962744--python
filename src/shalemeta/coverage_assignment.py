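"""Unique-coverage-weighted redistribution of multi-mapping reads.

This module implements the study-style coverage accounting for protein
references hit by metagenomic reads:

1. per read, hits below the minimum bitscore are discarded and the best
   hits selected (maximal bitscore, then minimal e-value, maximal percent
   identity, maximal alignment length);
2. *unique coverage* counts reads whose best set contains a single
   reference;
3. each multi-mapping read's unit mass is then redistributed in three
   tiers: (a) over the best-hit references that themselves have unique
   coverage, weighted by that unique coverage; (b) failing that, over the
   species represented in the best set that have species-level unique
   coverage, proportionally to it and uniformly within a species; (c)
   failing that, the read is dropped and contributes nothing.

"Coverage" here is a fractional read count per reference, not per-base
depth: the redistribution operates on hit tables alone.  The default is a
single pass with weights frozen at the unique-coverage stage; an optional
EM-style mode re-weights tier-1 reads by updated total coverage until
convergence, for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import AlignmentHit, ReferenceCatalog

DEFAULT_MIN_BITSCORE = 60.0

#: Read fates recorded in the ledger.
FATES = ("unique", "weighted", "species_fallback", "dropped", "unaligned")


@dataclass
class CoverageLedger:
    """Output of the redistribution: per-reference coverage plus the fate
    and weight vector of every read.

    Invariants: each non-dropped aligned read's weights sum to 1 (to 1e-9);
    unique reads contribute exactly 1.0 to exactly one reference; total
    coverage equals the number of unique + weighted + fallback reads.
    """

    reference_coverage: dict[str, float] = field(default_factory=dict)
    unique_counts: dict[str, int] = field(default_factory=dict)
    read_fate: dict[str, str] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def fate_counts(self) -> dict[str, int]:
        counts = {fate: 0 for fate in FATES}
        for fate in self.read_fate.values():
            counts[fate] += 1
        return counts

    @property
    def total_coverage(self) -> float:
        return sum(self.reference_coverage.values())


def select_best_hits(
    hits: Iterable[AlignmentHit],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
) -> dict[str, list[AlignmentHit]]:
    """Best-hit table: per read, the surviving best-tier hits.

    Hits below *min_bitscore* are discarded first; a read whose hits all
    fall below the floor keeps an empty list (it will be ledgered as
    unaligned).  Among the remainder the maximal-bitscore hits are kept,
    then successively filtered to minimal e-value, maximal percent
    identity and maximal alignment length.  More than one survivor makes
    the read multi-mapping.
    """
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.read_id, []).append(h)

    best_table: dict[str, list[AlignmentHit]] = {}
    for read_id, read_hits in grouped.items():
        candidates = [h for h in read_hits if h.bitscore >= min_bitscore]
        if candidates:
            for key, pick in (
                (lambda h: h.bitscore, max),
                (lambda h: h.evalue, min),
                (lambda h: h.percent_identity, max),
                (lambda h: h.alignment_length, max),
            ):
                target = pick(key(h) for h in candidates)
                candidates = [h for h in candidates if key(h) == target]
        best_table[read_id] = candidates
    return best_table


def unique_coverage(best_hits: dict[str, list[AlignmentHit]]) -> dict[str, int]:
    """Count reads whose best set names a single reference, per reference."""
    cov: dict[str, int] = {}
    for read_hits in best_hits.values():
        subjects = {h.subject_id for h in read_hits}
        if len(subjects) == 1:
            (subject,) = subjects
            cov[subject] = cov.get(subject, 0) + 1
    return cov


def redistribute(
    best_hits: dict[str, list[AlignmentHit]],
    unique_cov: dict[str, int],
    catalog: ReferenceCatalog,
    em: bool = False,
    length_normalize: bool = False,
    em_tol: float = 1e-6,
    em_max_iter: int = 100,
) -> CoverageLedger:
    """Redistribute multi-mapping reads over references by unique coverage.

    Tier 1: a read whose best set intersects the uniquely-covered reference
    set U spreads its unit mass over that intersection with weights
    proportional to unique coverage (optionally divided by protein length
    when *length_normalize* is set).  Tier 2: otherwise, if any best-hit
    reference belongs to a species with positive species-summed unique
    coverage, mass is split over those species proportionally to species
    coverage and uniformly within each species' best-hit references.
    Tier 3: otherwise the read is dropped.

    With ``em=True`` tier-1 weights are iteratively re-derived from updated
    total coverage until the L1 change falls below *em_tol* (fates are
    unchanged; only tier-1 weights move).
    """
    for subject in unique_cov:
        if subject not in catalog:
            raise ValueError(f"unique coverage references unknown subject {subject!r}")

    def norm(subject: str, count: float) -> float:
        if length_normalize:
            return count / catalog[subject].length_aa
        return count

    covered = {s for s, c in unique_cov.items() if c > 0}
    species_cov: dict[int, float] = {}
    for subject in covered:
        sp = catalog.taxon_of(subject)
        species_cov[sp] = species_cov.get(sp, 0.0) + unique_cov[subject]

    ledger = CoverageLedger(unique_counts={s: c for s, c in unique_cov.items() if c > 0})
    tier1_reads: list[str] = []

    for read_id, read_hits in best_hits.items():
        subjects = sorted({h.subject_id for h in read_hits})
        if not subjects:
            ledger.read_fate[read_id] = "unaligned"
            continue
        if len(subjects) == 1:
            ledger.read_fate[read_id] = "unique"
            ledger.weights[read_id] = {subjects[0]: 1.0}
            continue
        in_u = [s for s in subjects if s in covered]
        if in_u:
            total = sum(norm(s, unique_cov[s]) for s in in_u)
            ledger.read_fate[read_id] = "weighted"
            ledger.weights[read_id] = {s: norm(s, unique_cov[s]) / total for s in in_u}
            tier1_reads.append(read_id)
            continue
        by_species: dict[int, list[str]] = {}
        for s in subjects:
            sp = catalog.taxon_of(s)
            if species_cov.get(sp, 0.0) > 0:
                by_species.setdefault(sp, []).append(s)
        if by_species:
            total_sp = sum(species_cov[sp] for sp in by_species)
            w: dict[str, float] = {}
            for sp, members in by_species.items():
                share = species_cov[sp] / total_sp
                for s in members:
                    w[s] = share / len(members)
            ledger.read_fate[read_id] = "species_fallback"
            ledger.weights[read_id] = w
        else:
            ledger.read_fate[read_id] = "dropped"

    if em and tier1_reads:
        _em_reweight(ledger, best_hits, unique_cov, covered, norm, em_tol, em_max_iter)

    # Sum contributions in sorted read order so the ledger is independent of
    # input read order down to the last bit.
    coverage: dict[str, float] = {}
    for read_id in sorted(ledger.weights):
        for subject, w in ledger.weights[read_id].items():
            coverage[subject] = coverage.get(subject, 0.0) + w
    ledger.reference_coverage = coverage
    return ledger


def _em_reweight(ledger, best_hits, unique_cov, covered, norm, tol, max_iter) -> None:
    """Iteratively re-weight tier-1 reads by updated total coverage."""
    tier1 = [r for r, fate in ledger.read_fate.items() if fate == "weighted"]
    for _ in range(max_iter):
        coverage: dict[str, float] = {}
        for read_id in sorted(ledger.weights):
            for subject, w in ledger.weights[read_id].items():
                coverage[subject] = coverage.get(subject, 0.0) + w
        delta = 0.0
        for read_id in tier1:
            subjects = sorted({h.subject_id for h in best_hits[read_id]} & covered)
            total = sum(norm(s, coverage.get(s, 0.0)) for s in subjects)
            if total <= 0:
                continue
            new = {s: norm(s, coverage.get(s, 0.0)) / total for s in subjects}
            old = ledger.weights[read_id]
            delta += sum(abs(new[s] - old.get(s, 0.0)) for s in subjects)
            ledger.weights[read_id] = new
        if delta < tol:
            break


def run_coverage_pipeline(
    hits: Iterable[AlignmentHit],
    catalog: ReferenceCatalog,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    em: bool = False,
    length_normalize: bool = False,
) -> CoverageLedger:
    """Convenience wrapper: best-hit selection, unique coverage, redistribution."""
    best = select_best_hits(hits, min_bitscore=min_bitscore)
    ucov = unique_coverage(best)
    return redistribute(best, ucov, catalog, em=em, length_normalize=length_normalize)


def write_coverage_table(ledger: CoverageLedger, path) -> None:
    """Coverage TSV: subject_id, unique_reads, redistributed_mass, total."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#subject_id\tunique_reads\tredistributed_mass\ttotal_coverage\n")
        for subject in sorted(ledger.reference_coverage):
            total = ledger.reference_coverage[subject]
            uniq = ledger.unique_counts.get(subject, 0)
            fh.write(f"{subject}\t{uniq}\t{total - uniq:.6f}\t{total:.6f}\n")


def read_coverage_table(path) -> tuple[dict[str, float], dict[str, int]]:
    """Read a coverage TSV back into (total coverage, unique counts) maps."""
    from pathlib import Path

    from .io_formats import FormatError

    coverage: dict[str, float] = {}
    unique: dict[str, int] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, found {len(cols)}")
            coverage[cols[0]] = float(cols[3])
            unique[cols[0]] = int(cols[1])
    return coverage, unique


def write_fate_table(ledger: CoverageLedger, path) -> None:
    """Fate TSV: read_id, fate, weight vector as ``subject:weight`` pairs."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#read_id\tfate\tweights\n")
        for read_id in sorted(ledger.read_fate):
            fate = ledger.read_fate[read_id]
            w = ledger.weights.get(read_id, {})
            pairs = ";".join(f"{s}:{w[s]:.6f}" for s in sorted(w))
            fh.write(f"{read_id}\t{fate}\t{pairs}\n")
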