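"""Rule-based functional aggregation of protein references.

Protein descriptions in non-redundant databases are free text, so the
functional grouping that a curator would do by eye is expressed here as an
ordered table of categories, each with case-insensitive include patterns
(substring by default, regex with a ``re:`` prefix) and optional exclude
patterns.  A reference contributes its unique-read count and fractional
coverage to every category it matches (multi-counting is deliberate and
reported in the matrix margins), at a taxon lifted to the requested rank.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .coverage_assignment import CoverageLedger
from .io_formats import FormatError, ReferenceCatalog, TaxonomyTable

logger = logging.getLogger(__name__)

_REGEX_PREFIX = "re:"


@dataclass
class CategoryRule:
    """One functional category: include/exclude patterns over descriptions."""

    category: str
    include: list[str]
    exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError(f"rule {self.category!r}: at least one include pattern required")
        self._include_re = [self._compile(p) for p in self.include]
        self._exclude_re = [self._compile(p) for p in self.exclude]

    def _compile(self, pattern: str) -> re.Pattern:
        if pattern.startswith(_REGEX_PREFIX):
            body = pattern[len(_REGEX_PREFIX):]
        else:
            body = re.escape(pattern)
        try:
            return re.compile(body, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"rule {self.category!r}: invalid pattern {pattern!r}: {exc}") from exc

    def matches(self, description: str) -> bool:
        if not any(rx.search(description) for rx in self._include_re):
            return False
        return not any(rx.search(description) for rx in self._exclude_re)


class CategoryRuleSet:
    """Ordered, uniquely-named category rules."""

    def __init__(self, rules: Sequence[CategoryRule]):
        names = [r.category for r in rules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate categories: {sorted(dupes)}")
        self.rules = list(rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def categories(self) -> list[str]:
        return [r.category for r in self.rules]


def compile_rules(path: str | Path) -> CategoryRuleSet:
    """Read a rule TSV: category, include patterns (``;`` joined), excludes."""
    path = Path(path)
    rules = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2-3 columns, found {len(cols)}")
            include = [p for p in cols[1].split(";") if p]
            exclude = [p for p in cols[2].split(";") if p] if len(cols) == 3 else []
            try:
                rules.append(CategoryRule(cols[0], include, exclude))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return CategoryRuleSet(rules)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def default_rules() -> CategoryRuleSet:
    """The shipped rule set covering the enzyme groups the pipeline reports:
    hydrocarbon/alcohol/aldehyde oxidation and inorganic sulfur oxidation."""
    ref = resources.files("shalemeta.data").joinpath("default_rules.tsv")
    with resources.as_file(ref) as path:
        return compile_rules(path)


def categorize_reference(description: str, rules: CategoryRuleSet) -> list[str]:
    """All categories whose include patterns match *description* (and no
    exclude pattern does), in rule order.  Empty list is legal."""
    return [r.category for r in rules if r.matches(description)]


@dataclass
class FunctionTaxonMatrix:
    """Aggregated (category, taxon) cells of unique reads and coverage.

    A reference matching k categories contributes to k cells, so category
    margins can exceed the read total; ``multi_category_references`` records
    how many references multi-counted.  ``unresolved_rank_references``
    counts references whose lineage lacks the requested rank (they aggregate
    at the nearest available ancestor instead).
    """

    rank: str
    cells: dict[tuple[str, int], tuple[int, float]] = field(default_factory=dict)
    multi_category_references: int = 0
    unresolved_rank_references: int = 0

    def add(self, category: str, taxon_id: int, unique_reads: int, coverage: float) -> None:
        u, c = self.cells.get((category, taxon_id), (0, 0.0))
        self.cells[(category, taxon_id)] = (u + unique_reads, c + coverage)

    def category_margins(self) -> dict[str, tuple[int, float]]:
        out: dict[str, tuple[int, float]] = {}
        for (cat, _), (u, c) in self.cells.items():
            pu, pc = out.get(cat, (0, 0.0))
            out[cat] = (pu + u, pc + c)
        return out

    def taxon_margins(self) -> dict[int, tuple[int, float]]:
        out: dict[int, tuple[int, float]] = {}
        for (_, tid), (u, c) in self.cells.items():
            pu, pc = out.get(tid, (0, 0.0))
            out[tid] = (pu + u, pc + c)
        return out


def aggregate(
    ledger: CoverageLedger,
    catalog: ReferenceCatalog,
    rules: CategoryRuleSet,
    taxonomy: TaxonomyTable,
    rank: str = "genus",
    first_match: bool = False,
) -> FunctionTaxonMatrix:
    """Aggregate ledger coverage into a category x taxon matrix at *rank*.

    For each covered reference, its description decides the categories (all
    matches, or just the first when *first_match*), its species is lifted to
    the requested rank (falling back to the species node itself when the
    lineage lacks that rank, with a log note), and the cell accumulates the
    reference's unique reads and total coverage.
    """
    matrix = FunctionTaxonMatrix(rank=rank)
    for subject in sorted(ledger.reference_coverage):
        if subject not in catalog:
            raise ValueError(f"ledger references unknown subject {subject!r}")
        entry = catalog[subject]
        cats = categorize_reference(entry.description, rules)
        if not cats:
            continue
        if first_match:
            cats = cats[:1]
        if len(cats) > 1:
            matrix.multi_category_references += 1
        taxon = taxonomy.ancestor_at_rank(entry.taxon_id, rank)
        if taxon is None:
            taxon = entry.taxon_id
            matrix.unresolved_rank_references += 1
            logger.info(
                "reference %s: no %s ancestor for taxon %d; using the taxon itself",
                subject, rank, entry.taxon_id,
            )
        uniq = ledger.unique_counts.get(subject, 0)
        cov = ledger.reference_coverage[subject]
        for cat in cats:
            matrix.add(cat, taxon, uniq, cov)
    return matrix


def write_matrix(matrix: FunctionTaxonMatrix, taxonomy: TaxonomyTable, path) -> None:
    """Matrix TSV sorted by category then taxon id, with margin notes."""
    with Path(path).open("w") as fh:
        fh.write("#category\ttaxon_id\ttaxon_name\tunique_reads\tcoverage\n")
        fh.write(f"#rank\t{matrix.rank}\n")
        fh.write(f"#multi_category_references\t{matrix.multi_category_references}\n")
        fh.write(f"#unresolved_rank_references\t{matrix.unresolved_rank_references}\n")
        for (cat, tid) in sorted(matrix.cells):
            u, c = matrix.cells[(cat, tid)]
            name = taxonomy.name(tid) if tid in taxonomy else str(tid)
            fh.write(f"{cat}\t{tid}\t{name}\t{u}\t{c:.6f}\n")
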