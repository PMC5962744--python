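"""Synthetic data with known ground truth for every pipeline stage.

Generates taxonomies with full eight-rank lineages, protein reference
catalogs with realistic free-text descriptions, reads plus their alignment
hit tables (the aligner itself is out of scope: hits are drawn directly
from a score model), QC contaminants planted in exact counts, geochemistry
records with known arithmetic relations, and GC-MS spectra with planted
characteristic ions.

The score model: a read's true hit draws its bitscore from a normal
distribution truncated at zero; with probability ``multimap_rate`` the read
additionally hits 1-3 homologous references restricted to the same genus,
the first with an exactly tied score (so the multi-mapping fraction equals
``multimap_rate``) and later ones tied with probability ``tie_fraction`` or
reduced by an exponential decrement.  A single integer seed drives one root
RNG; sub-generators derive child seeds deterministically so partial reruns
reproduce.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .geochemistry import DEFAULT_CLASS_IONS, PYRITE_S_PER_FE, Spectrum
from .io_formats import (
    AlignmentHit,
    CatalogEntry,
    GeochemRecord,
    RANKS,
    ReferenceCatalog,
    SequenceRead,
    TaxonNode,
    TaxonomyTable,
)

CONTAMINANT_KINDS = ("short", "duplicate", "low_complexity", "low_quality")

#: Free-text protein descriptions sampled for reference catalogs.  Mixes
#: the enzyme families the pipeline aggregates (oxygenases, dehydrogenases,
#: sulfur-oxidation systems) with housekeeping descriptions that match no
#: category.
DEFAULT_VOCABULARY = (
    "alcohol dehydrogenase class III",
    "zinc-containing alcohol dehydrogenase",
    "aldehyde dehydrogenase family protein",
    "catechol 2,3-dioxygenase",
    "quercetin 2,3-dioxygenase",
    "phenol 2-monooxygenase",
    "4-hydroxyacetophenone monooxygenase",
    "monooxygenase flavin-binding family protein",
    "cytochrome P450",
    "laccase",
    "sulfide:quinone oxidoreductase",
    "flavocytochrome c sulfide dehydrogenase",
    "sulfur oxidation protein SoxB",
    "cytochrome SoxA",
    "adenylylsulfate reductase alpha subunit",
    "sulfate adenylyltransferase",
    "sulfite oxidase",
    "dissimilatory sulfite reductase DsrA",
    "sulfur relay protein TusE",
    "dienelactone hydrolase",
    "haloacid dehalogenase",
    "4-carboxymuconolactone decarboxylase",
    "acyl-CoA dehydrogenase",
    "long-chain fatty acid CoA ligase",
    "ABC transporter ATP-binding protein",
    "DNA polymerase III subunit alpha",
    "30S ribosomal protein S12",
    "elongation factor Tu",
)

HYPOTHETICAL = "hypothetical protein"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Conditions for one simulated sequencing experiment.

    Defaults are the package's standard desk-scale benchmark: 20 species,
    10 references each, 50,000 aligned reads, a 0.4 multi-mapping rate with
    half of the extra homologous hits exactly tied, and true-hit bitscores
    around 90 +/- 15 bits (comfortably above the 60-bit reporting floor).
    ``n_reads`` counts aligned (non-contaminant) reads; contaminants are
    planted on top in the exact configured counts.
    """

    seed: int
    n_species: int = 20
    references_per_species: int = 10
    n_reads: int = 50_000
    multimap_rate: float = 0.4
    bitscore_mean: float = 90.0
    bitscore_sd: float = 15.0
    homolog_decrement_rate: float = 0.2
    tie_fraction: float = 0.5
    hypothetical_fraction: float = 0.30
    read_length_range: tuple[int, int] = (100, 200)
    quality_range: tuple[int, int] = (30, 40)
    contaminant_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.references_per_species < 1:
            raise ValueError("references_per_species must be >= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0.0 <= self.multimap_rate <= 1.0:
            raise ValueError("multimap_rate must be in [0, 1]")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise ValueError("tie_fraction must be in [0, 1]")
        if self.homolog_decrement_rate <= 0:
            raise ValueError("homolog_decrement_rate must be positive")
        if not 0.0 <= self.hypothetical_fraction <= 1.0:
            raise ValueError("hypothetical_fraction must be in [0, 1]")
        for kind, count in self.contaminant_counts.items():
            if kind not in CONTAMINANT_KINDS:
                raise ValueError(f"unknown contaminant kind {kind!r}")
            if count < 0:
                raise ValueError(f"contaminant count for {kind!r} must be >= 0")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated read."""

    true_subject_id: Optional[str]
    true_taxon_id: Optional[int]
    contaminant_kind: str = "none"


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive a deterministic child RNG from the root seed and a label."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def generate_taxonomy(config: SimulationConfig) -> TaxonomyTable:
    """A full eight-rank taxonomy with ``n_species`` species.

    Species are spread over roughly ``n_species / 3`` genera (every genus
    receives at least one species when possible), genera over families and
    so on up to one root, mirroring the shape of rank-level community
    profiles.  Deterministic under a fixed seed.
    """
    rng = _child_rng(config.seed, "taxonomy")
    n = config.n_species
    level_sizes = {"species": n, "genus": max(1, math.ceil(n / 3))}
    level_sizes["family"] = max(1, math.ceil(level_sizes["genus"] / 2))
    level_sizes["order"] = max(1, math.ceil(level_sizes["family"] / 2))
    level_sizes["class"] = max(1, math.ceil(level_sizes["order"] / 2))
    level_sizes["phylum"] = max(1, math.ceil(level_sizes["class"] / 2))
    level_sizes["superkingdom"] = min(2, level_sizes["phylum"])

    nodes: dict[int, TaxonNode] = {1: TaxonNode(parent_id=1, rank="root", name="root")}
    next_id = 2
    level_ids: dict[str, list[int]] = {"root": [1]}
    for rank in RANKS[1:]:
        size = level_sizes[rank]
        parents = level_ids[RANKS[RANKS.index(rank) - 1]]
        # round-robin over a shuffled parent list: every parent is used when
        # there are enough children, and the pairing is still randomized
        shuffled = [parents[i] for i in rng.permutation(len(parents))]
        ids = []
        assignment = [shuffled[i % len(shuffled)] for i in range(size)]
        assignment = [assignment[i] for i in rng.permutation(size)]
        for i in range(size):
            tid = next_id
            next_id += 1
            nodes[tid] = TaxonNode(
                parent_id=assignment[i],
                rank=rank,
                name=f"{rank.capitalize()}_{i + 1:03d}",
            )
            ids.append(tid)
        level_ids[rank] = ids
    return TaxonomyTable(nodes)


def random_taxonomy(n_nodes: int, seed: int) -> TaxonomyTable:
    """An arbitrary random rooted tree with valid ranks, for stress tests."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = {1: TaxonNode(parent_id=1, rank="root", name="root")}
    depths = {1: 0}
    for tid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, tid))
        depth = depths[parent] + 1
        depths[tid] = depth
        rank = RANKS[min(depth, len(RANKS) - 1)]
        nodes[tid] = TaxonNode(parent_id=parent, rank=rank, name=f"node_{tid}")
    return TaxonomyTable(nodes)


# ---------------------------------------------------------------------------
# Reference catalog
# ---------------------------------------------------------------------------


def generate_references(
    taxonomy: TaxonomyTable,
    config: SimulationConfig,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> ReferenceCatalog:
    """``references_per_species`` protein entries per species.

    Descriptions are drawn from *vocabulary* except that a configurable
    fraction (default 30%) are "hypothetical protein", mirroring the large
    un-annotatable share of environmental protein catalogs.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    species = sorted(
        tid for tid, node in taxonomy.nodes.items() if node.rank == "species"
    )
    if not species:
        raise ValueError("taxonomy contains no species")
    rng = _child_rng(config.seed, "references")
    entries: dict[str, CatalogEntry] = {}
    idx = 0
    for sp in species:
        for _ in range(config.references_per_species):
            idx += 1
            if rng.random() < config.hypothetical_fraction:
                desc = HYPOTHETICAL
            else:
                desc = vocabulary[int(rng.integers(len(vocabulary)))]
            entries[f"P{idx:05d}"] = CatalogEntry(
                taxon_id=sp,
                description=desc,
                length_aa=int(rng.integers(150, 601)),
            )
    return ReferenceCatalog(entries)


# ---------------------------------------------------------------------------
# Reads + alignments
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _evalue_from_bitscore(bitscore: float) -> float:
    return 10.0 ** (-bitscore / 10.0)


def simulate_reads_and_alignments(
    catalog: ReferenceCatalog,
    taxonomy: TaxonomyTable,
    config: SimulationConfig,
) -> tuple[list[SequenceRead], list[AlignmentHit], dict[str, TruthEntry]]:
    """Simulate reads, their alignment hit table, and the truth table.

    Every non-contaminant read has one true hit whose subject is recorded
    in the truth table; multi-mapping reads additionally hit homologous
    references of the same genus, the first one exactly tied on every
    best-hit key.  Contaminants of each configured kind are planted in the
    exact configured counts, after the clean reads: reads shorter than 34
    nt, exact duplicates of clean reads, homopolymer/dinucleotide repeats,
    and reads whose 3' low-quality tail spans the whole read.
    """
    rng = _child_rng(config.seed, "reads")
    ref_ids = sorted(catalog.entries)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=len(ref_ids))
    abundance /= abundance.sum()

    genus_members: dict[Optional[int], list[str]] = {}
    genus_of_ref: dict[str, Optional[int]] = {}
    for ref in ref_ids:
        genus = taxonomy.ancestor_at_rank(catalog.taxon_of(ref), "genus")
        genus_of_ref[ref] = genus
        genus_members.setdefault(genus, []).append(ref)

    reads: list[SequenceRead] = []
    hits: list[AlignmentHit] = []
    truth: dict[str, TruthEntry] = {}

    lo_len, hi_len = config.read_length_range
    lo_q, hi_q = config.quality_range
    true_refs = rng.choice(len(ref_ids), size=config.n_reads, p=abundance)
    multimap_flags = rng.random(config.n_reads) < config.multimap_rate

    for i in range(config.n_reads):
        read_id = f"read_{i:07d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        reads.append(
            SequenceRead(
                read_id,
                _random_bases(rng, length),
                list(rng.integers(lo_q, hi_q + 1, size=length)),
            )
        )
        subject = ref_ids[int(true_refs[i])]
        truth[read_id] = TruthEntry(subject, catalog.taxon_of(subject), "none")

        bitscore = max(0.01, float(rng.normal(config.bitscore_mean, config.bitscore_sd)))
        pident = round(float(rng.uniform(80.0, 100.0)), 1)
        aln_len = max(11, length // 3)
        evalue = _evalue_from_bitscore(bitscore)
        hits.append(AlignmentHit(read_id, subject, pident, aln_len, evalue, bitscore))

        if multimap_flags[i]:
            pool = [r for r in genus_members[genus_of_ref[subject]] if r != subject]
            if pool:
                k = min(int(rng.integers(1, 4)), len(pool))
                picks = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
                for j, homolog in enumerate(picks):
                    tied = j == 0 or rng.random() < config.tie_fraction
                    if tied:
                        hits.append(
                            AlignmentHit(read_id, homolog, pident, aln_len, evalue, bitscore)
                        )
                    else:
                        b2 = max(
                            0.01,
                            bitscore - float(rng.exponential(1.0 / config.homolog_decrement_rate)),
                        )
                        p2 = max(0.0, pident - round(float(rng.uniform(0.5, 5.0)), 1))
                        hits.append(
                            AlignmentHit(
                                read_id, homolog, round(p2, 1), aln_len,
                                _evalue_from_bitscore(b2), b2,
                            )
                        )

    _plant_contaminants(reads, truth, config)
    return reads, hits, truth


def _plant_contaminants(
    reads: list[SequenceRead],
    truth: dict[str, TruthEntry],
    config: SimulationConfig,
) -> None:
    rng = _child_rng(config.seed, "contaminants")
    n_clean = config.n_reads

    for idx in range(config.contaminant_counts.get("short", 0)):
        length = int(rng.integers(10, 34))
        rid = f"contam_short_{idx:05d}"
        reads.append(
            SequenceRead(rid, _random_bases(rng, length), list(rng.integers(30, 41, size=length)))
        )
        truth[rid] = TruthEntry(None, None, "short")

    n_dup = config.contaminant_counts.get("duplicate", 0)
    if n_dup:
        if n_dup > n_clean:
            raise ValueError("cannot plant more duplicates than clean reads")
        sources = rng.choice(n_clean, size=n_dup, replace=False)
        for idx, src in enumerate(sources):
            rid = f"contam_duplicate_{idx:05d}"
            src_read = reads[int(src)]
            reads.append(SequenceRead(rid, src_read.bases, list(src_read.qualities)))
            truth[rid] = TruthEntry(None, None, "duplicate")

    for idx in range(config.contaminant_counts.get("low_complexity", 0)):
        length = int(rng.integers(60, 121))
        rid = f"contam_lowcomplexity_{idx:05d}"
        if idx % 2 == 0:
            base = str(_BASES[int(rng.integers(0, 4))])
            bases = base * length
        else:
            pair = rng.choice(4, size=2, replace=False)
            motif = str(_BASES[pair[0]]) + str(_BASES[pair[1]])
            bases = (motif * (length // 2 + 1))[:length]
        reads.append(SequenceRead(rid, bases, list(rng.integers(30, 41, size=length))))
        truth[rid] = TruthEntry(None, None, "low_complexity")

    for idx in range(config.contaminant_counts.get("low_quality", 0)):
        length = int(rng.integers(80, 151))
        rid = f"contam_lowquality_{idx:05d}"
        reads.append(
            SequenceRead(rid, _random_bases(rng, length), list(rng.integers(0, 3, size=length)))
        )
        truth[rid] = TruthEntry(None, None, "low_quality")


def true_reference_counts(truth: dict[str, TruthEntry]) -> dict[str, int]:
    """Reads per true reference, contaminants excluded."""
    counts: dict[str, int] = {}
    for entry in truth.values():
        if entry.true_subject_id is not None:
            counts[entry.true_subject_id] = counts.get(entry.true_subject_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Geochemistry records
# ---------------------------------------------------------------------------


def generate_geochem_record(seed: int, weathered: bool = True) -> tuple[GeochemRecord, float]:
    """A synthetic Rock-Eval + sulfur record and its true organic sulfur.

    Weathered records emulate an oxidized shale: low hydrogen index (< 50
    mg HC/g TOC downstream), high oxygen index, TOC around 1.5 wt%, no
    sulfidic sulfur.  Unweathered records emulate an oil-prone type II
    source rock: HI 350-550, TOC around 10 wt%, sulfidic and pyritic sulfur
    present.  The sulfur fractions sum exactly to the total, so the organic
    fraction recovered downstream by subtraction equals the returned truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E0C]))
    if weathered:
        toc = float(rng.uniform(1.0, 1.8))
        hi = float(rng.uniform(15.0, 45.0))
        oi = float(rng.uniform(120.0, 220.0))
        s1 = float(rng.uniform(0.02, 0.08))
        s3co = float(rng.uniform(0.1, 0.4))
        tmax = float(rng.uniform(420.0, 440.0))
        s_sulfate = float(rng.uniform(0.01, 0.06))
        s_pyritic = float(rng.uniform(0.1, 0.3))
        s_sulfidic = 0.0
        s_organic = float(rng.uniform(1.0, 1.6))
    else:
        toc = float(rng.uniform(8.0, 12.0))
        hi = float(rng.uniform(350.0, 550.0))
        oi = float(rng.uniform(10.0, 40.0))
        s1 = float(rng.uniform(0.8, 1.5))
        s3co = float(rng.uniform(0.2, 0.6))
        tmax = float(rng.uniform(425.0, 435.0))
        s_sulfate = float(rng.uniform(0.15, 0.25))
        s_pyritic = float(rng.uniform(0.4, 0.6))
        s_sulfidic = float(rng.uniform(0.3, 0.5))
        s_organic = float(rng.uniform(1.4, 2.0))
    # Store the organic truth as the exact floating-point remainder of the
    # same subtraction chain the speciation performs, so recovery is bitwise.
    s_total = s_sulfate + s_pyritic + s_sulfidic + s_organic
    s_organic = s_total - s_sulfate - s_pyritic - s_sulfidic
    record = GeochemRecord(
        sample_id=f"{'weathered' if weathered else 'unweathered'}_{seed}",
        S1=s1,
        S2=hi * toc / 100.0,
        S3CO2=oi * toc / 100.0,
        S3CO=s3co,
        TOC=toc,
        Tmax=tmax,
        S_total=s_total,
        S_sulfate=s_sulfate,
        S_pyritic=s_pyritic,
        S_sulfidic=s_sulfidic,
        Fe_pyrite=s_pyritic / PYRITE_S_PER_FE,
    )
    return record, s_organic


# ---------------------------------------------------------------------------
# GC-MS spectra
# ---------------------------------------------------------------------------

#: The ion forced into each planted spectrum's dominant set.  For classes
#: whose ion list is a subset of another's, the most class-specific ion
#: available keeps the planted class recoverable.
_DIAGNOSTIC_ION = {
    "aromatic": 77,
    "aliphatic": 99,
    "alcohol": 45,
    "aldehyde": 44,
    "carboxylic_acid": 60,
}


def generate_spectra(
    classes: Optional[Sequence[str]] = None,
    per_class: int = 5,
    seed: int = 0,
    score_range: tuple[float, float] = (50.0, 79.0),
    background_mz: tuple[int, int] = (101, 300),
) -> list[Spectrum]:
    """Peak tables with planted class-characteristic dominant ions.

    Each spectrum's dominant ions are its class's diagnostic ion plus up to
    three more from the class list (intensities 40-100% of base peak), over
    a background of five off-list ions (5-35%) and two sub-threshold noise
    ions (< 3%, exercising the intensity cutoff).  Background m/z default
    to 101-300, disjoint from every class list.  Match scores are drawn
    from *score_range*; the 50-79 default forces class-level assignment.
    """
    if classes is None:
        classes = sorted(DEFAULT_CLASS_IONS)
    for cls in classes:
        if cls not in DEFAULT_CLASS_IONS:
            raise ValueError(f"unknown compound class {cls!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5bec]))
    spectra = []
    bg_pool = np.arange(background_mz[0], background_mz[1] + 1)
    for cls in classes:
        ions = sorted(DEFAULT_CLASS_IONS[cls])
        diagnostic = _DIAGNOSTIC_ION[cls]
        others = [mz for mz in ions if mz != diagnostic]
        for i in range(per_class):
            n_extra = min(3, len(others))
            extra = [others[j] for j in rng.choice(len(others), size=n_extra, replace=False)]
            dominant = [diagnostic] + extra
            peaks = {dominant[0]: 100.0}
            for mz in dominant[1:]:
                peaks[mz] = round(float(rng.uniform(40.0, 95.0)), 2)
            bg = rng.choice(bg_pool, size=7, replace=False)
            for mz in bg[:5]:
                peaks[int(mz)] = round(float(rng.uniform(5.0, 35.0)), 2)
            for mz in bg[5:]:
                peaks[int(mz)] = round(float(rng.uniform(0.5, 2.4)), 2)
            spectra.append(
                Spectrum(
                    compound_id=f"spec_{cls}_{i:03d}",
                    match_score=round(float(rng.uniform(*score_range)), 1),
                    library_name=f"library match for {cls} {i}",
                    peaks=sorted(peaks.items()),
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# Truth-table and config serialization
# ---------------------------------------------------------------------------


def write_truth_table(truth: dict[str, TruthEntry], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#read_id\ttrue_subject_id\ttrue_taxon_id\tcontaminant_kind\n")
        for rid in sorted(truth):
            t = truth[rid]
            fh.write(
                f"{rid}\t{t.true_subject_id or 'NA'}\t"
                f"{t.true_taxon_id if t.true_taxon_id is not None else 'NA'}\t"
                f"{t.contaminant_kind}\n"
            )


def read_truth_table(path: str | Path) -> dict[str, TruthEntry]:
    truth: dict[str, TruthEntry] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, subject, taxon, kind = line.split("\t")
            truth[rid] = TruthEntry(
                None if subject == "NA" else subject,
                None if taxon == "NA" else int(taxon),
                kind,
            )
    return truth


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Flat key=value dump of the simulation conditions."""
    with Path(path).open("w") as fh:
        for key in (
            "seed", "n_species", "references_per_species", "n_reads", "multimap_rate",
            "bitscore_mean", "bitscore_sd", "homolog_decrement_rate", "tie_fraction",
            "hypothetical_fraction",
        ):
            fh.write(f"{key}={getattr(config, key)}\n")
        for kind in CONTAMINANT_KINDS:
            fh.write(f"contaminant.{kind}={config.contaminant_counts.get(kind, 0)}\n")
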