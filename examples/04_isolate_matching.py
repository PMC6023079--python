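"""Match cultured-isolate 16S sequences to amplicon OTUs.

Trims full-length isolate sequences to the amplified region via
IUPAC-aware primer search, then co-clusters them with OTU centroids at
97% — answering "which of the sequenced OTUs did we actually culture?".
"""

import numpy as np

from otukit import RegionSpec, cocluster, extract_region
from otukit.cluster import OTU
from otukit.isolates import reverse_complement

rng = np.random.default_rng(5)


def rand_seq(n):
    return "".join(rng.choice(list("ACGT"), n))


# synthetic primer pair delimiting a 252-nt region (not biological primers)
spec = RegionSpec(forward_primer="GGATTAGAWACCCBNGTA",
                  reverse_primer="CRRCACGAGCTGACGAC",
                  max_mismatches=2, expected_length=252)

# two OTU centroids over the amplified region
core1, core2 = rand_seq(252), rand_seq(252)
otus = [OTU("OTU15", core1, {"COL1": 120}), OTU("OTU21", core2, {"COL1": 80})]

# three "cultured isolates" as full-length sequences: flanking sequence +
# primers + core; MM1 matches OTU15, MM2 is a near-variant of OTU21,
# MM24 is unrelated (a lineage the amplicon survey never captured)
fwd = spec.forward_primer.replace("W", "A").replace("B", "C").replace("N", "G")
rev = reverse_complement(spec.reverse_primer.replace("R", "A"))
variant = core2[:3] + "T" + core2[4:]
full = {
    "MM1": rand_seq(40) + fwd + core1 + rev + rand_seq(30),
    "MM2": rand_seq(35) + fwd + variant + rev + rand_seq(25),
    "MM24": rand_seq(40) + fwd + rand_seq(252) + rev + rand_seq(30),
}

fragments = {name: extract_region(seq, spec) for name, seq in full.items()}
print("trimmed fragment lengths:",
      {k: len(v) for k, v in fragments.items()})  # all 252 nt

clusters, matches = cocluster(otus, fragments, threshold=0.97)
for isolate, otu in sorted(matches.items()):
    print(f"{isolate}: {'matches ' + otu if otu else 'unmatched'}")
# MM24 founds its own cluster: a cultured strain invisible to the
# amplicon survey, exactly the complementarity the comparison measures
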