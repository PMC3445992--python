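import pytest

from lgtscreen.lgt_classify import ScreenConfig
from lgtscreen.trees import TaxonRecord, annotate, parse_newick


def taxon(leaf_id, domain, phylum="", genus="", species=""):
    """Terse TaxonRecord builder for hand-drawn test trees."""
    if domain == "Bacteria":
        phylum = phylum or "Firmicutes"
        genus = genus or f"G{leaf_id}"
    elif domain == "Archaea":
        phylum = phylum or "Euryarchaeota"
        genus = genus or f"G{leaf_id}"
    species = species or f"{genus} {leaf_id}"
    return TaxonRecord(leaf_id, species, genus, phylum, domain)


FOCAL = TaxonRecord(
    "Focal", "Methanosphaera stadtmanae", "Methanosphaera", "Euryarchaeota", "Archaea"
)
MSMITHII = TaxonRecord(
    "Msmithii", "Methanobrevibacter smithii", "Methanobrevibacter",
    "Euryarchaeota", "Archaea",
)
MRUMINANTIUM = TaxonRecord(
    "Mrum", "Methanobrevibacter ruminantium", "Methanobrevibacter",
    "Euryarchaeota", "Archaea",
)


def annotated_tree(newick, records, gene_id="g1"):
    """Parse a Newick string and attach the given TaxonRecords."""
    gtree = parse_newick(newick, gene_id=gene_id)
    annotate(gtree, {r.leaf_id: r for r in records}, strict=True)
    return gtree


@pytest.fixture
def config_as_provided():
    """Screen config that keeps the tree's rooting as written."""
    return ScreenConfig(rooting="as-provided")


@pytest.fixture
def config_default():
    return ScreenConfig()
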