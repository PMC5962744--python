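"""Best-hit selection and the three-tier multi-mapping redistribution,
checked against an independently coded brute-force oracle."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from shalemeta.coverage_assignment import (
    redistribute,
    run_coverage_pipeline,
    select_best_hits,
    unique_coverage,
)
from shalemeta.io_formats import AlignmentHit, CatalogEntry, ReferenceCatalog
from shalemeta.synthetic_data import (
    SimulationConfig,
    generate_references,
    generate_taxonomy,
    simulate_reads_and_alignments,
    true_reference_counts,
)


def _hit(read, subject, bitscore, evalue=1e-20, pident=95.0, length=50):
    return AlignmentHit(read, subject, pident, length, evalue, bitscore)


def _catalog(species_of: dict[str, int]) -> ReferenceCatalog:
    return ReferenceCatalog(
        {ref: CatalogEntry(sp, "protein", 300) for ref, sp in species_of.items()}
    )


# ---------------------------------------------------------------------------
# Independent oracle: a direct transcription of the three-tier rule over
# plain sets, sharing no code with the implementation.
# ---------------------------------------------------------------------------


def oracle_redistribute(best_sets: dict[str, set], species_of: dict[str, int]):
    """Returns (coverage, fates) computed tier by tier from first principles."""
    unique = {}
    for read, refs in best_sets.items():
        if len(refs) == 1:
            (ref,) = refs
            unique[ref] = unique.get(ref, 0) + 1
    coverage = dict(unique)
    fates = {}
    u_set = set(unique)
    sp_cov = {}
    for ref, c in unique.items():
        sp_cov[species_of[ref]] = sp_cov.get(species_of[ref], 0) + c
    for read, refs in best_sets.items():
        if not refs:
            fates[read] = "unaligned"
            continue
        if len(refs) == 1:
            fates[read] = "unique"
            continue
        overlap = refs & u_set
        if overlap:
            denom = sum(unique[r] for r in overlap)
            for r in overlap:
                coverage[r] = coverage.get(r, 0) + unique[r] / denom
            fates[read] = "weighted"
            continue
        spp = {species_of[r] for r in refs if sp_cov.get(species_of[r], 0) > 0}
        if spp:
            denom = sum(sp_cov[s] for s in spp)
            for s in spp:
                members = [r for r in refs if species_of[r] == s]
                for r in members:
                    coverage[r] = coverage.get(r, 0) + (sp_cov[s] / denom) / len(members)
            fates[read] = "species_fallback"
        else:
            fates[read] = "dropped"
    return coverage, fates


def random_instance(seed, max_reads=10, max_refs=6, max_species=3):
    rng = np.random.default_rng(seed)
    n_refs = int(rng.integers(1, max_refs + 1))
    refs = [f"p{i}" for i in range(n_refs)]
    species_of = {r: int(rng.integers(1, max_species + 1)) for r in refs}
    n_reads = int(rng.integers(1, max_reads + 1))
    best_sets = {}
    for i in range(n_reads):
        size = int(rng.integers(0, min(4, n_refs) + 1))
        picked = rng.choice(n_refs, size=size, replace=False)
        best_sets[f"r{i}"] = {refs[j] for j in picked}
    return best_sets, species_of


def ledger_from_sets(best_sets, species_of):
    """Run the implementation path on an instance expressed as best sets."""
    best_hits = {
        read: [_hit(read, ref, 100.0) for ref in sorted(refs)]
        for read, refs in best_sets.items()
    }
    ucov = unique_coverage(best_hits)
    return redistribute(best_hits, ucov, _catalog(species_of))


class TestSelectBestHits:
    def test_strict_maximum_is_unique(self):
        best = select_best_hits([_hit("r", "p1", 100.0), _hit("r", "p2", 90.0)])
        assert [h.subject_id for h in best["r"]] == ["p1"]

    def test_full_tie_is_multimapping(self):
        best = select_best_hits([_hit("r", "p1", 100.0), _hit("r", "p2", 100.0)])
        assert {h.subject_id for h in best["r"]} == {"p1", "p2"}

    def test_evalue_breaks_bitscore_tie(self):
        best = select_best_hits(
            [_hit("r", "p1", 100.0, evalue=1e-30), _hit("r", "p2", 100.0, evalue=1e-20)]
        )
        assert [h.subject_id for h in best["r"]] == ["p1"]

    def test_identity_then_length_break_remaining_ties(self):
        hits = [
            _hit("r", "p1", 100.0, pident=98.0, length=60),
            _hit("r", "p2", 100.0, pident=98.0, length=50),
            _hit("r", "p3", 100.0, pident=95.0, length=80),
        ]
        best = select_best_hits(hits)
        assert [h.subject_id for h in best["r"]] == ["p1"]

    def test_all_hits_below_floor_leave_empty_set(self):
        best = select_best_hits([_hit("r", "p1", 40.0)], min_bitscore=60)
        assert best["r"] == []


class TestUniqueCoverage:
    def test_counts_unique_reads_per_reference(self):
        best = {
            "r1": [_hit("r1", "A", 90.0)],
            "r2": [_hit("r2", "A", 91.0)],
            "r3": [_hit("r3", "A", 92.0)],
            "r4": [_hit("r4", "B", 90.0)],
            "r5": [_hit("r5", "A", 90.0), _hit("r5", "B", 90.0)],
        }
        assert unique_coverage(best) == {"A": 3, "B": 1}

    def test_no_unique_reads_yields_empty_map(self):
        best = {"r1": [_hit("r1", "A", 90.0), _hit("r1", "B", 90.0)]}
        assert unique_coverage(best) == {}


class TestRedistribute:
    def test_tier1_weights_follow_unique_coverage(self):
        # unique coverage {A:3, B:1}; a tied read adds 0.75 to A, 0.25 to B
        species = {"A": 1, "B": 1}
        best_sets = {
            "u1": {"A"}, "u2": {"A"}, "u3": {"A"}, "u4": {"B"},
            "m1": {"A", "B"},
        }
        ledger = ledger_from_sets(best_sets, species)
        assert ledger.weights["m1"] == pytest.approx({"A": 0.75, "B": 0.25})
        assert ledger.reference_coverage == pytest.approx({"A": 3.75, "B": 1.25})

    def test_tier2_species_fallback_routes_full_mass(self):
        # C has no unique coverage but shares species 1 with covered D
        species = {"C": 1, "D": 1, "E": 2}
        best_sets = {"u1": {"D"}, "u2": {"D"}, "m1": {"C"}}
        # make m1 multi-mapping over two refs of species 1 so tier 1 fails:
        best_sets["m1"] = {"C", "X"}
        species["X"] = 1
        ledger = ledger_from_sets(best_sets, species)
        assert ledger.read_fate["m1"] == "species_fallback"
        assert sum(ledger.weights["m1"].values()) == pytest.approx(1.0)
        assert ledger.weights["m1"] == pytest.approx({"C": 0.5, "X": 0.5})

    def test_tier3_dropped_contributes_nothing(self):
        species = {"A": 1, "F": 2, "G": 2}
        best_sets = {"u1": {"A"}, "m1": {"F", "G"}}
        ledger = ledger_from_sets(best_sets, species)
        assert ledger.read_fate["m1"] == "dropped"
        assert ledger.total_coverage == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(300))
    def test_matches_brute_force_oracle(self, seed):
        best_sets, species_of = random_instance(seed)
        ledger = ledger_from_sets(best_sets, species_of)
        expected_cov, expected_fates = oracle_redistribute(best_sets, species_of)
        assert ledger.read_fate == expected_fates
        assert set(ledger.reference_coverage) == set(expected_cov)
        for ref, cov in expected_cov.items():
            assert ledger.reference_coverage[ref] == pytest.approx(cov, abs=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_mass_conservation(self, seed):
        best_sets, species_of = random_instance(seed, max_reads=50, max_refs=10, max_species=4)
        ledger = ledger_from_sets(best_sets, species_of)
        fates = ledger.fate_counts()
        contributing = fates["unique"] + fates["weighted"] + fates["species_fallback"]
        assert ledger.total_coverage == pytest.approx(contributing, abs=1e-9)

    def test_order_invariance(self):
        best_sets, species_of = random_instance(123, max_reads=30)
        forward = ledger_from_sets(best_sets, species_of)
        reversed_sets = dict(reversed(list(best_sets.items())))
        backward = ledger_from_sets(reversed_sets, species_of)
        assert forward.reference_coverage == backward.reference_coverage
        assert forward.read_fate == backward.read_fate

    def test_extra_unique_read_never_lowers_its_reference(self):
        species = {"A": 1, "B": 1}
        base_sets = {"u1": {"A"}, "u2": {"B"}, "m1": {"A", "B"}}
        before = ledger_from_sets(base_sets, species)
        boosted = dict(base_sets)
        boosted["u3"] = {"A"}
        after = ledger_from_sets(boosted, species)
        assert after.reference_coverage["A"] >= before.reference_coverage["A"]

    def test_inconsistent_unique_coverage_rejected(self, small_catalog):
        with pytest.raises(ValueError, match="ghost"):
            redistribute({}, {"ghost": 2}, small_catalog)


class TestEmMode:
    def test_em_conserves_mass_and_shifts_weights(self):
        species = {"A": 1, "B": 1}
        best_sets = {
            "u1": {"A"}, "u2": {"A"}, "u3": {"A"}, "u4": {"B"},
            "m1": {"A", "B"}, "m2": {"A", "B"},
        }
        best_hits = {
            read: [_hit(read, ref, 100.0) for ref in sorted(refs)]
            for read, refs in best_sets.items()
        }
        ucov = unique_coverage(best_hits)
        single = redistribute(best_hits, ucov, _catalog(species))
        em = redistribute(best_hits, ucov, _catalog(species), em=True)
        assert em.total_coverage == pytest.approx(single.total_coverage, abs=1e-9)
        # EM reinforces the better-covered reference beyond the single pass
        assert em.reference_coverage["A"] >= single.reference_coverage["A"] - 1e-12


class TestParameterRecovery:
    def test_reference_and_species_recovery_on_small_benchmark(self):
        config = SimulationConfig(
            seed=42, n_species=10, references_per_species=8, n_reads=5000
        )
        taxonomy = generate_taxonomy(config)
        catalog = generate_references(taxonomy, config)
        _, hits, truth = simulate_reads_and_alignments(catalog, taxonomy, config)
        ledger = run_coverage_pipeline(hits, catalog)
        true_counts = true_reference_counts(truth)
        refs = sorted(catalog.entries)
        r_ref = pearsonr(
            [true_counts.get(r, 0) for r in refs],
            [ledger.reference_coverage.get(r, 0.0) for r in refs],
        )[0]
        assert r_ref >= 0.95
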