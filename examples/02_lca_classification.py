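"""Classify OTUs from BLAST-tabular hits with the majority-LCA rules.

Shows the three behaviours that matter in practice: a clean genus
assignment, an uncultured database entry being skipped in favour of an
informative hit, and a two-genus conflict resolving to the family.
"""

from otukit import HitRecord, LcaParams, classify_otu
from otukit.taxonomy import TaxonomyTree

tree = TaxonomyTree()
for lineage in [
    "Bacteria;Actinobacteria;Actinobacteria;Corynebacteriales;Nocardiaceae;Rhodococcus",
    "Bacteria;Actinobacteria;Actinobacteria;Corynebacteriales;Nocardiaceae;Nocardia",
    "Bacteria;Actinobacteria;Actinobacteria;Pseudonocardiales;Pseudonocardiaceae;Pseudonocardia",
]:
    tree.add_lineage(lineage.split(";"))


def hit(sid, taxon, bits=400.0, ident=99.0):
    (tid,) = tree.find_by_name(taxon) if taxon in ("Rhodococcus", "Nocardia",
                                                   "Pseudonocardia") else [""]
    return HitRecord("OTU1", sid, ident, 250, bits, 1e-40, tid, taxon)


params = LcaParams()  # E<=1e-15, id>=95.5%, bits>=200, 99% band, 95% majority

# 20 hits to one genus, 1 outlier to a sister genus: the outlier is
# below the 5% tolerance and is removed before the LCA
hits = [hit(f"s{i}", "Rhodococcus") for i in range(20)] + [hit("x", "Nocardia")]
res = classify_otu(hits, tree, params)
print("outlier removed ->", res.rank_path["genus"])        # Rhodococcus

# an uncultured entry outscored by nothing, but an informative hit also
# passes: the uncultured hit is skipped
(pid,) = tree.find_by_name("Pseudonocardia")
hits = [
    HitRecord("OTU2", "u1", 99.5, 250, 401.0, 1e-40, "", "uncultured bacterium"),
    HitRecord("OTU2", "s1", 99.0, 250, 400.0, 1e-40, pid, "Pseudonocardia"),
]
res = classify_otu(hits, tree, params, query_id="OTU2")
print("uncultured skipped ->", res.rank_path["genus"], f"({res.status})")

# an even split between two genera of one family: the majority rule
# cannot drop either side, so the assignment climbs to the family
hits = [hit(f"a{i}", "Rhodococcus") for i in range(10)]
hits += [hit(f"b{i}", "Nocardia") for i in range(10)]
res = classify_otu(hits, tree, params)
print("two-genus conflict ->", res.rank_path["family"],
      "/ genus:", res.rank_path["genus"])   # Nocardiaceae / unclassified
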