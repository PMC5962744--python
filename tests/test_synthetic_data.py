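import numpy as np
import pytest

from shalemeta.coverage_assignment import select_best_hits
from shalemeta.geochemistry import (
    DEFAULT_CLASS_IONS,
    rock_eval_indices,
    sulfur_speciation,
)
from shalemeta.synthetic_data import (
    HYPOTHETICAL,
    SimulationConfig,
    TruthEntry,
    generate_geochem_record,
    generate_references,
    generate_spectra,
    generate_taxonomy,
    random_taxonomy,
    read_truth_table,
    simulate_reads_and_alignments,
    write_truth_table,
)


def _cfg(**kwargs):
    defaults = dict(seed=1, n_species=3, references_per_species=4, n_reads=50)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateTaxonomy:
    def test_species_count_and_single_root(self):
        tax = generate_taxonomy(_cfg(n_species=3))
        species = [t for t, n in tax.nodes.items() if n.rank == "species"]
        assert len(species) == 3
        assert all(tax.root_path(s)[0] == tax.root_id for s in species)

    def test_full_eight_rank_lineages(self):
        tax = generate_taxonomy(_cfg(n_species=5))
        for tid, node in tax.nodes.items():
            if node.rank == "species":
                ranks = [tax.nodes[t].rank for t in tax.root_path(tid)]
                assert ranks == list(
                    ("root", "superkingdom", "phylum", "class", "order", "family", "genus", "species")
                )

    def test_deterministic_under_fixed_seed(self):
        assert generate_taxonomy(_cfg()).nodes == generate_taxonomy(_cfg()).nodes

    def test_every_node_reachable_no_cycles_at_scale(self):
        tax = generate_taxonomy(_cfg(seed=7, n_species=50))
        # graph-traversal oracle: children map walked from the root
        children = {}
        for tid, node in tax.nodes.items():
            if tid != tax.root_id:
                children.setdefault(node.parent_id, []).append(tid)
        seen = set()
        stack = [tax.root_id]
        while stack:
            tid = stack.pop()
            assert tid not in seen, "cycle"
            seen.add(tid)
            stack.extend(children.get(tid, []))
        assert seen == set(tax.nodes)

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_species=0)

    def test_random_taxonomy_valid_and_sized(self):
        tax = random_taxonomy(50, seed=7)
        assert len(tax) == 50


class TestGenerateReferences:
    def test_counts_and_unique_ids(self):
        cfg = _cfg()
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        assert len(cat) == 12
        species = {cat.taxon_of(r) for r in cat}
        assert all(tax.nodes[s].rank == "species" for s in species)

    def test_deterministic_descriptions(self):
        cfg = _cfg()
        tax = generate_taxonomy(cfg)
        a = generate_references(tax, cfg)
        b = generate_references(tax, cfg)
        assert a.entries == b.entries

    def test_hypothetical_fraction_near_configured(self):
        cfg = _cfg(seed=3, n_species=100, references_per_species=10)
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        frac = sum(
            1 for r in cat if cat[r].description == HYPOTHETICAL
        ) / len(cat)
        assert abs(frac - 0.30) <= 0.05

    def test_empty_vocabulary_rejected(self):
        cfg = _cfg()
        tax = generate_taxonomy(cfg)
        with pytest.raises(ValueError):
            generate_references(tax, cfg, vocabulary=[])


class TestSimulateReadsAndAlignments:
    def test_no_multimapping_means_one_hit_per_read(self):
        cfg = _cfg(n_reads=100, multimap_rate=0.0)
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        _, hits, truth = simulate_reads_and_alignments(cat, tax, cfg)
        per_read = {}
        for h in hits:
            per_read[h.read_id] = per_read.get(h.read_id, 0) + 1
        assert set(per_read.values()) == {1}
        assert len(per_read) == 100

    def test_planted_short_reads_exact_count(self):
        cfg = _cfg(n_reads=50, contaminant_counts={"short": 10})
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        reads, _, truth = simulate_reads_and_alignments(cat, tax, cfg)
        assert sum(1 for r in reads if len(r) < 34) == 10
        assert sum(1 for t in truth.values() if t.contaminant_kind == "short") == 10

    def test_multimap_fraction_matches_rate(self):
        cfg = SimulationConfig(
            seed=42, n_species=10, references_per_species=8, n_reads=10_000, multimap_rate=0.4
        )
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        _, hits, _ = simulate_reads_and_alignments(cat, tax, cfg)
        # independent tally: reads whose retained best tier names >= 2 subjects
        best = select_best_hits(hits, min_bitscore=0.0)
        multi = sum(1 for v in best.values() if len({h.subject_id for h in v}) >= 2)
        assert abs(multi / len(best) - 0.4) <= 0.02

    def test_truth_subject_always_in_best_tier(self):
        cfg = _cfg(n_reads=300, multimap_rate=0.5)
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        _, hits, truth = simulate_reads_and_alignments(cat, tax, cfg)
        best = select_best_hits(hits, min_bitscore=0.0)
        for read_id, entry in truth.items():
            if entry.contaminant_kind != "none":
                continue
            top = {h.subject_id for h in best[read_id]}
            assert entry.true_subject_id in top

    def test_homolog_hits_stay_within_genus(self):
        cfg = _cfg(n_reads=300, multimap_rate=1.0, n_species=10)
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        _, hits, truth = simulate_reads_and_alignments(cat, tax, cfg)
        for h in hits:
            true_subject = truth[h.read_id].true_subject_id
            g1 = tax.ancestor_at_rank(cat.taxon_of(h.subject_id), "genus")
            g2 = tax.ancestor_at_rank(cat.taxon_of(true_subject), "genus")
            assert g1 == g2

    def test_byte_identical_under_same_config(self):
        cfg = _cfg(contaminant_counts={"short": 3, "low_quality": 2})
        tax = generate_taxonomy(cfg)
        cat = generate_references(tax, cfg)
        a = simulate_reads_and_alignments(cat, tax, cfg)
        b = simulate_reads_and_alignments(cat, tax, cfg)
        assert a == b

    def test_truth_table_round_trip(self, tmp_path):
        truth = {
            "r1": TruthEntry("P00001", 8, "none"),
            "c1": TruthEntry(None, None, "short"),
        }
        write_truth_table(truth, tmp_path / "truth.tsv")
        assert read_truth_table(tmp_path / "truth.tsv") == truth


class TestGenerateGeochemRecord:
    def test_weathered_record_reads_as_degraded_kerogen(self):
        record, _ = generate_geochem_record(seed=1, weathered=True)
        indices = rock_eval_indices(record)
        assert indices.HI < 50
        assert indices.kerogen_type == "IV"

    def test_unweathered_record_reads_as_oil_prone(self):
        record, _ = generate_geochem_record(seed=1, weathered=False)
        indices = rock_eval_indices(record)
        assert 300 < indices.HI <= 600
        assert indices.kerogen_type == "II"

    def test_deterministic(self):
        assert generate_geochem_record(5) == generate_geochem_record(5)

    def test_sulfur_fractions_consistent(self):
        for seed in range(5):
            record, organic_truth = generate_geochem_record(seed, weathered=False)
            parts = record.S_sulfate + record.S_pyritic + record.S_sulfidic
            assert parts <= record.S_total
            spec = sulfur_speciation(
                record.S_total, record.S_sulfate, record.S_pyritic, record.S_sulfidic
            )
            assert spec.S_organic == organic_truth
            assert not spec.flags


class TestGenerateSpectra:
    def test_aromatic_dominant_ions_from_class_list(self):
        (spec,) = generate_spectra(["aromatic"], per_class=1, seed=0)
        base = max(i for _, i in spec.peaks)
        dominant = sorted(
            (p for p in spec.peaks if p[1] >= 0.03 * base), key=lambda p: -p[1]
        )[:4]
        assert {mz for mz, _ in dominant} <= DEFAULT_CLASS_IONS["aromatic"]

    def test_spectrum_count_and_determinism(self):
        a = generate_spectra(per_class=5, seed=3)
        b = generate_spectra(per_class=5, seed=3)
        assert len(a) == 25
        assert a == b

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="ketone"):
            generate_spectra(["ketone"], per_class=1, seed=0)
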