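import pytest

from shalemeta.io_formats import (
    CatalogEntry,
    ReferenceCatalog,
    TaxonNode,
    TaxonomyTable,
)


@pytest.fixture
def two_phyla_taxonomy() -> TaxonomyTable:
    """Hand-built 15-node taxonomy: two phyla, two Pseudomonas sister
    species plus one Microbacterium species."""
    nodes = {
        1: TaxonNode(1, "root", "root"),
        2: TaxonNode(1, "superkingdom", "Bacteria"),
        3: TaxonNode(2, "phylum", "Proteobacteria"),
        4: TaxonNode(3, "class", "Gammaproteobacteria"),
        5: TaxonNode(4, "order", "Pseudomonadales"),
        6: TaxonNode(5, "family", "Pseudomonadaceae"),
        7: TaxonNode(6, "genus", "Pseudomonas"),
        8: TaxonNode(7, "species", "Pseudomonas stutzeri"),
        9: TaxonNode(7, "species", "Pseudomonas putida"),
        10: TaxonNode(2, "phylum", "Actinobacteria"),
        11: TaxonNode(10, "class", "Actinomycetia"),
        12: TaxonNode(11, "order", "Micrococcales"),
        13: TaxonNode(12, "family", "Microbacteriaceae"),
        14: TaxonNode(13, "genus", "Microbacterium"),
        15: TaxonNode(14, "species", "Microbacterium oxydans"),
    }
    return TaxonomyTable(nodes)


@pytest.fixture
def small_catalog() -> ReferenceCatalog:
    """Four proteins over the three species of the hand-built taxonomy."""
    return ReferenceCatalog(
        {
            "pA1": CatalogEntry(8, "alcohol dehydrogenase class III", 350),
            "pA2": CatalogEntry(8, "catechol 2,3-dioxygenase", 310),
            "pB1": CatalogEntry(9, "sulfide:quinone oxidoreductase", 430),
            "pC1": CatalogEntry(15, "hypothetical protein", 210),
        }
    )
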