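"""Readers and writers for the external formats the pipeline consumes and emits.

Formats covered:

* FASTQ (Phred+33, strict 4-line records) for sequencing reads;
* 12-column tabular protein alignments (the standard blast ``outfmt 6``
  column order: qseqid sseqid pident length mismatch gapopen qstart qend
  sstart send evalue bitscore);
* a taxonomy table in the NCBI ``nodes.dmp`` / ``names.dmp`` pipe-delimited
  dialect;
* a reference catalog TSV mapping protein accessions to species-level taxa,
  free-text descriptions and protein lengths;
* taxon profiles as diff-able TSV or Krona-importable text;
* Rock-Eval / sulfur geochemistry records as TSV.

Parsing is strict: malformed records raise :class:`FormatError` carrying the
offending line number, and taxonomy files are validated structurally (single
root, acyclic, no orphan parents).  All writers emit deterministically
ordered output with a ``#``-prefixed header so that re-runs are
byte-identical and diff-able.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

#: Rank hierarchy used throughout, from shallowest to deepest.
RANKS = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

PHRED_OFFSET = 33


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class TaxonomyStructureError(ValueError):
    """A taxonomy table violates its structural invariants."""


# ---------------------------------------------------------------------------
# Sequence reads
# ---------------------------------------------------------------------------


@dataclass
class SequenceRead:
    """A single sequencing read with per-base Phred qualities."""

    read_id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream 4-line FASTQ records (Phred+33) from *path* in file order.

    Raises :class:`FormatError` with the line number on truncated records,
    malformed headers, or base/quality length mismatches.  An empty file
    yields nothing.
    """
    path = Path(path)
    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@") or len(header) < 2:
                raise FormatError(f"{path}:{lineno}: expected '@<id>' header, got {header!r}")
            read_id = header[1:].split()[0]
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}:{lineno}: truncated record for read {read_id!r}")
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno + 2}: expected '+' separator for read {read_id!r}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno + 3}: read {read_id!r} has {len(seq)} bases "
                    f"but {len(qual)} quality characters"
                )
            lineno += 3
            yield SequenceRead(
                read_id=read_id,
                bases=seq,
                qualities=[ord(c) - PHRED_OFFSET for c in qual],
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    """Write reads as 4-line Phred+33 FASTQ, preserving input order."""
    with Path(path).open("w") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Alignment hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-protein alignment row: the pipeline's atomic input."""

    read_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise ValueError(f"hit {self.read_id}->{self.subject_id}: bitscore not finite")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.read_id}->{self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length <= 0:
            raise ValueError(f"hit {self.read_id}->{self.subject_id}: non-positive alignment length")
        if self.evalue < 0:
            raise ValueError(f"hit {self.read_id}->{self.subject_id}: negative e-value")


_N_ALN_COLUMNS = 12


def read_alignment_table(
    path: str | Path,
    catalog: Optional["ReferenceCatalog"] = None,
    unknown_subject: str = "drop",
) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into :class:`AlignmentHit` rows.

    When *catalog* is given, rows whose subject accession is absent from the
    catalog are handled per *unknown_subject*: ``"drop"`` excludes them and
    logs the total count, ``"error"`` raises.  Lines starting with ``#`` are
    ignored.
    """
    if unknown_subject not in ("drop", "error"):
        raise ValueError("unknown_subject must be 'drop' or 'error'")
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_unknown = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _N_ALN_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_N_ALN_COLUMNS} columns, found {len(cols)}"
                )
            try:
                hit = AlignmentHit(
                    read_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if catalog is not None and hit.subject_id not in catalog:
                if unknown_subject == "error":
                    raise FormatError(
                        f"{path}:{lineno}: subject {hit.subject_id!r} absent from catalog"
                    )
                n_unknown += 1
                continue
            hits.append(hit)
    if n_unknown:
        logger.warning(
            "%s: dropped %d alignment rows with subjects absent from catalog", path, n_unknown
        )
    return hits


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect, preserving input order.

    Only the six fields the pipeline consumes are stored on
    :class:`AlignmentHit`; the remaining columns (mismatch, gapopen,
    coordinates) are emitted as neutral placeholders so the row count and
    column layout stay standard.
    """
    with Path(path).open("w") as fh:
        for h in hits:
            mismatch = 0
            gapopen = 0
            qstart, qend = 1, h.alignment_length * 3
            sstart, send = 1, h.alignment_length
            fh.write(
                f"{h.read_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t"
                f"{h.alignment_length}\t{mismatch}\t{gapopen}\t{qstart}\t{qend}\t"
                f"{sstart}\t{send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Reference catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    taxon_id: int
    description: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError("protein length must be positive")


class ReferenceCatalog:
    """Protein reference metadata: accession -> (species taxon, description, length).

    Stands in for the protein records of a large non-redundant database: the
    pipeline only needs each subject's source species and free-text
    description.
    """

    def __init__(self, entries: dict[str, CatalogEntry]):
        self.entries = dict(entries)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.entries

    def __getitem__(self, subject_id: str) -> CatalogEntry:
        return self.entries[subject_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def taxon_of(self, subject_id: str) -> int:
        return self.entries[subject_id].taxon_id

    def validate_against(self, taxonomy: "TaxonomyTable") -> None:
        """Raise if any catalog taxon is not resolvable in *taxonomy*."""
        for sid, entry in self.entries.items():
            if entry.taxon_id not in taxonomy.nodes:
                raise ValueError(f"catalog entry {sid!r}: taxon {entry.taxon_id} not in taxonomy")


def read_catalog(path: str | Path) -> ReferenceCatalog:
    """Read a catalog TSV: subject_id, taxon_id, description, length_aa."""
    path = Path(path)
    entries: dict[str, CatalogEntry] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, found {len(cols)}")
            sid = cols[0]
            if sid in entries:
                raise FormatError(f"{path}:{lineno}: duplicate subject id {sid!r}")
            try:
                entries[sid] = CatalogEntry(
                    taxon_id=int(cols[1]), description=cols[2], length_aa=int(cols[3])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ReferenceCatalog(entries)


def write_catalog(catalog: ReferenceCatalog, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#subject_id\ttaxon_id\tdescription\tlength_aa\n")
        for sid in sorted(catalog.entries):
            e = catalog.entries[sid]
            fh.write(f"{sid}\t{e.taxon_id}\t{e.description}\t{e.length_aa}\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonNode:
    parent_id: int
    rank: str
    name: str


class TaxonomyTable:
    """A rooted tree of taxa with named ranks.

    Backbone for lowest-common-ancestor assignment, min-support push-up and
    rank lifting.  Validated on construction: exactly one root (its own
    parent), every other node's parent present, no cycles, ranks drawn from
    :data:`RANKS`.
    """

    def __init__(self, nodes: dict[int, TaxonNode]):
        if not nodes:
            raise TaxonomyStructureError("taxonomy is empty")
        self.nodes = dict(nodes)
        roots = [tid for tid, n in self.nodes.items() if n.parent_id == tid]
        if len(roots) != 1:
            raise TaxonomyStructureError(f"expected exactly one root, found {roots}")
        self.root_id = roots[0]
        for tid, node in self.nodes.items():
            if node.rank not in RANKS:
                raise TaxonomyStructureError(f"taxon {tid}: unknown rank {node.rank!r}")
            if node.parent_id not in self.nodes:
                raise TaxonomyStructureError(
                    f"taxon {tid}: parent {node.parent_id} absent (orphan)"
                )
        self._check_acyclic()
        self._paths: dict[int, tuple[int, ...]] = {}

    def _check_acyclic(self) -> None:
        color: dict[int, int] = {}
        for start in self.nodes:
            if start in color:
                continue
            trail = []
            tid = start
            while tid not in color and tid != self.root_id:
                color[tid] = 1
                trail.append(tid)
                tid = self.nodes[tid].parent_id
                if tid in trail:
                    cycle = trail[trail.index(tid):] + [tid]
                    raise TaxonomyStructureError(f"cycle detected: {cycle}")
            color[start] = 2

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def root_path(self, taxon_id: int) -> tuple[int, ...]:
        """Path of taxon ids from the root down to *taxon_id* (inclusive)."""
        cached = self._paths.get(taxon_id)
        if cached is not None:
            return cached
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon id {taxon_id}")
        rev = []
        tid = taxon_id
        while True:
            rev.append(tid)
            if tid == self.root_id:
                break
            tid = self.nodes[tid].parent_id
        path = tuple(reversed(rev))
        self._paths[taxon_id] = path
        return path

    def depth(self, taxon_id: int) -> int:
        return len(self.root_path(taxon_id)) - 1

    def lca(self, taxon_ids: Iterable[int]) -> int:
        """Deepest node lying on every input taxon's root path."""
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of empty taxon set")
        paths = [self.root_path(t) for t in ids]
        lca = self.root_id
        for level in range(min(len(p) for p in paths)):
            tier = {p[level] for p in paths}
            if len(tier) != 1:
                break
            lca = tier.pop()
        return lca

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> Optional[int]:
        """The ancestor (or the node itself) carrying *rank*, or None."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        for tid in self.root_path(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def name(self, taxon_id: int) -> str:
        return self.nodes[taxon_id].name

    def lineage_names(self, taxon_id: int) -> list[str]:
        return [self.nodes[t].name for t in self.root_path(taxon_id)]


def _parse_dmp_row(line: str) -> list[str]:
    # nodes.dmp dialect: fields separated by "\t|\t", row terminated "\t|"
    return [f.strip() for f in line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")]


def read_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTable:
    """Read a pipe-delimited nodes/names dump pair into a validated table.

    The nodes file carries ``taxid | parent | rank |`` rows; the names file
    maps ``taxid | name |``.  Structural problems (duplicate ids, cycles,
    orphan parents, multiple roots) raise :class:`TaxonomyStructureError`.
    """
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    names: dict[int, str] = {}
    with names_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _parse_dmp_row(line)
            if len(parts) < 2:
                raise FormatError(f"{names_path}:{lineno}: expected 'taxid | name |' row")
            names[int(parts[0])] = parts[1]

    raw: dict[int, TaxonNode] = {}
    with nodes_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _parse_dmp_row(line)
            if len(parts) < 3:
                raise FormatError(f"{nodes_path}:{lineno}: expected 'taxid | parent | rank |' row")
            tid = int(parts[0])
            if tid in raw:
                raise TaxonomyStructureError(f"{nodes_path}:{lineno}: duplicate taxon id {tid}")
            raw[tid] = TaxonNode(
                parent_id=int(parts[1]), rank=parts[2], name=names.get(tid, f"taxon_{tid}")
            )
    return TaxonomyTable(raw)


def write_taxonomy(taxonomy: TaxonomyTable, nodes_path: str | Path, names_path: str | Path) -> None:
    with Path(nodes_path).open("w") as fh:
        for tid in sorted(taxonomy.nodes):
            n = taxonomy.nodes[tid]
            fh.write(f"{tid}\t|\t{n.parent_id}\t|\t{n.rank}\t|\n")
    with Path(names_path).open("w") as fh:
        for tid in sorted(taxonomy.nodes):
            fh.write(f"{tid}\t|\t{taxonomy.nodes[tid].name}\t|\n")


# ---------------------------------------------------------------------------
# Taxon profiles
# ---------------------------------------------------------------------------


def write_profile(profile, taxonomy: TaxonomyTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a taxon profile.

    ``dialect="tsv"``: columns taxon_id, rank, name, count, lineage (``;``
    joined names, root first), sorted by count descending then taxon id
    ascending, with a ``#`` header and the unassigned tally as a comment.

    ``dialect="krona-text"``: one ``count<TAB>lineage...`` line per taxon,
    importable by Krona's text importer.
    """
    for tid in profile.counts:
        if tid not in taxonomy:
            raise ValueError(f"profile references unknown taxon {tid}")
    order = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    path = Path(path)
    if dialect == "tsv":
        with path.open("w") as fh:
            fh.write("#taxon_id\trank\tname\tcount\tlineage\n")
            fh.write(f"#unassigned\t{profile.unassigned}\n")
            for tid, count in order:
                node = taxonomy.nodes[tid]
                lineage = ";".join(taxonomy.lineage_names(tid))
                fh.write(f"{tid}\t{node.rank}\t{node.name}\t{count}\t{lineage}\n")
    elif dialect == "krona-text":
        with path.open("w") as fh:
            for tid, count in order:
                fh.write(str(count) + "\t" + "\t".join(taxonomy.lineage_names(tid)) + "\n")
    else:
        raise ValueError(f"unknown profile dialect {dialect!r}")


def read_profile(path: str | Path):
    """Read a profile TSV written by :func:`write_profile` (dialect ``tsv``)."""
    from .taxonomic_profiling import TaxonProfile

    path = Path(path)
    counts: dict[int, int] = {}
    unassigned = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#unassigned\t"):
                unassigned = int(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, found {len(cols)}")
            counts[int(cols[0])] = int(cols[3])
    return TaxonProfile(counts=counts, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Geochemistry records
# ---------------------------------------------------------------------------


@dataclass
class GeochemRecord:
    """One sample's programmed-pyrolysis and sulfur measurements.

    S1/S2 are in mg HC per g rock, S3CO2 in mg CO2/g, S3CO in mg CO/g,
    TOC and the sulfur fractions in wt%, Tmax in deg C.  Missing
    measurements are ``None``.
    """

    sample_id: str = ""
    S1: Optional[float] = None
    S2: Optional[float] = None
    S3CO2: Optional[float] = None
    S3CO: Optional[float] = None
    TOC: Optional[float] = None
    Tmax: Optional[float] = None
    S_total: Optional[float] = None
    S_sulfate: Optional[float] = None
    S_pyritic: Optional[float] = None
    S_sulfidic: Optional[float] = None
    Fe_pyrite: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("sample_id", "Tmax"):
                continue
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id or 'record'}: {f.name} negative ({v})")


_GEOCHEM_COLS = [
    "sample_id", "S1", "S2", "S3CO2", "S3CO", "TOC", "Tmax",
    "S_total", "S_sulfate", "S_pyritic", "S_sulfidic", "Fe_pyrite",
]


def read_geochem_records(path: str | Path) -> list[GeochemRecord]:
    """Read geochemistry records from TSV; ``NA`` marks absent fields."""
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(_GEOCHEM_COLS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_GEOCHEM_COLS)} columns, found {len(cols)}"
                )
            kwargs = {"sample_id": cols[0]}
            for name, value in zip(_GEOCHEM_COLS[1:], cols[1:]):
                kwargs[name] = None if value == "NA" else float(value)
            try:
                records.append(GeochemRecord(**kwargs))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_geochem_records(records: Iterable[GeochemRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(_GEOCHEM_COLS) + "\n")
        for rec in records:
            row = [rec.sample_id]
            for name in _GEOCHEM_COLS[1:]:
                v = getattr(rec, name)
                row.append("NA" if v is None else f"{v:.6g}")
            fh.write("\t".join(row) + "\n")
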