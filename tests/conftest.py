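import numpy as np
import pytest

from otukit.simulate import presence_table_from_venn
from otukit.stats import VennSpec
from otukit.taxonomy import TaxonomyTree

ACTINO_LINEAGES = [
    "Bacteria;Actinobacteria;Actinobacteria;Corynebacteriales;Nocardiaceae;Rhodococcus",
    "Bacteria;Actinobacteria;Actinobacteria;Corynebacteriales;Nocardiaceae;Nocardia",
    "Bacteria;Actinobacteria;Actinobacteria;Pseudonocardiales;Pseudonocardiaceae;Pseudonocardia",
    "Bacteria;Actinobacteria;Actinobacteria;Pseudonocardiales;Pseudonocardiaceae;Amycolatopsis",
    "Bacteria;Actinobacteria;Actinobacteria;Streptomycetales;Streptomycetaceae;Streptomyces",
    "Bacteria;Actinobacteria;Acidimicrobiia;Acidimicrobiales;Iamiaceae;Iamia",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae;Rhizobium",
]

#: Venn regions consistent with the published three-site bacterial
#: richness/unique/pairwise-shared marginals (unique solution).
BACTERIAL_VENN = VennSpec(238, 134, 584, 66, 318, 251, 710)
ACTINO_VENN = VennSpec(14, 15, 54, 3, 28, 24, 105)
SITES = ("COL1", "COL3", "COL4")


def tree_from_lineages(lineages):
    tree = TaxonomyTree()
    for line in lineages:
        tree.add_lineage([p for p in line.split(";")])
    tree.validate()
    return tree


@pytest.fixture(scope="session")
def actino_tree():
    return tree_from_lineages(ACTINO_LINEAGES)


@pytest.fixture(scope="session")
def bacterial_presence():
    return presence_table_from_venn(BACTERIAL_VENN, SITES, seed=11).presence()


@pytest.fixture(scope="session")
def actino_presence():
    return presence_table_from_venn(ACTINO_VENN, SITES, seed=13).presence()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
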