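import math

import numpy as np
import pytest

from _oracles import nw_edit_distance
from otukit.simulate import (
    CommunityProfile,
    HitScoring,
    VennSpec,
    build_reference_db,
    counts_for_inverse_simpson,
    generate_hit_table,
    generate_reads,
    generate_taxonomy,
    lognormal_profile,
    presence_table_from_venn,
    write_fastq,
)
from otukit.stats import diversity, venn_regions
from otukit.taxonomy import is_uninformative


def _genera(tree):
    return sorted(n.node_id for n in tree.nodes() if n.rank == "genus")


class TestGenerateTaxonomy:
    def test_minimal_single_path(self):
        tree = generate_taxonomy(1, 1, seed=0, n_families_per_phylum=1)
        assert len(tree) == 7  # root + domain..genus

    def test_same_seed_same_tree(self):
        a = generate_taxonomy(4, 3, seed=7, uninformative_genus_fraction=0.3)
        b = generate_taxonomy(4, 3, seed=7, uninformative_genus_fraction=0.3)
        assert a.write_lineages() == b.write_lineages()

    def test_genus_count_matches_enumeration(self):
        tree = generate_taxonomy(4, 3, seed=7)
        lineages = tree.write_lineages()
        assert len(_genera(tree)) == len(lineages) == 4 * 2 * 3

    def test_uninformative_fraction_applied(self):
        tree = generate_taxonomy(4, 5, seed=1, uninformative_genus_fraction=0.25)
        genera = [tree.node(g).name for g in _genera(tree)]
        assert sum(is_uninformative(g) for g in genera) == round(0.25 * len(genera))

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_taxonomy(0, 3, seed=1)


@pytest.fixture(scope="module")
def reads_setup():
    tree = generate_taxonomy(2, 2, seed=5)
    db = build_reference_db(tree, seed=6)
    return tree, db, _genera(tree)


@pytest.fixture(scope="module")
def hits_setup():
    tree = generate_taxonomy(2, 3, seed=11)
    db = build_reference_db(tree, seed=12, variants_per_genus=2,
                            decoy_uncultured_fraction=0.3)
    return tree, db


class TestGenerateReads:

    def test_noiseless_reads_equal_reference(self, reads_setup):
        _, db, genera = reads_setup
        profile = CommunityProfile("COL1", {genera[0]: 1.0})
        reads, truth = generate_reads(profile, db, 10, 0.0, seed=1)
        ref = db.amplicon_for(genera[0])
        assert len(reads) == 10
        for r in reads:
            assert r.sequence[4:] == ref
        assert all(t[2] == genera[0] for t in truth)

    def test_fixed_seed_byte_identical_fastq(self, reads_setup, tmp_path):
        _, db, genera = reads_setup
        profile = lognormal_profile("COL1", genera, seed=9)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        for p in (p1, p2):
            reads, _ = generate_reads(profile, db, 50, 0.01, seed=42)
            write_fastq(reads, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_error_rate_within_binomial_tolerance(self, reads_setup):
        _, db, genera = reads_setup
        profile = CommunityProfile("COL1", {genera[0]: 1.0})
        rate = 0.01
        reads, _ = generate_reads(profile, db, 10_000, rate, seed=3)
        ref = db.amplicon_for(genera[0])
        mismatches = sum(
            sum(a != b for a, b in zip(r.sequence[4:], ref)) for r in reads
        )
        n_bases = len(ref) * len(reads)
        sd = math.sqrt(n_bases * rate * (1 - rate))
        assert abs(mismatches - n_bases * rate) < 3 * sd

    def test_truth_sidecar_covers_every_read(self, reads_setup):
        _, db, genera = reads_setup
        profile = lognormal_profile("COL3", genera, seed=2)
        reads, truth = generate_reads(profile, db, 500, 0.01, seed=8)
        assert {t[0] for t in truth} == {r.read_id for r in reads}

    def test_missing_reference_raises(self, reads_setup):
        _, db, _ = reads_setup
        profile = CommunityProfile("COL1", {"ghost_taxon": 1.0})
        with pytest.raises(ValueError, match="ghost_taxon"):
            generate_reads(profile, db, 10, 0.0, seed=1)

    def test_error_rate_domain(self, reads_setup):
        _, db, genera = reads_setup
        profile = CommunityProfile("COL1", {genera[0]: 1.0})
        with pytest.raises(ValueError):
            generate_reads(profile, db, 10, 0.05, seed=1)


class TestGenerateHitTable:
    def test_identical_otu_hits_reference_at_100(self, hits_setup):
        _, db = hits_setup
        entry = db.entries[0]
        hits = generate_hit_table({"OTU1": entry.sequence}, db)
        top = hits[0]
        assert top.percent_identity == 100.0
        assert top.subject_id == entry.subject_id or (
            top.bit_score == [h for h in hits
                              if h.subject_id == entry.subject_id][0].bit_score
        )

    def test_equidistant_references_tie_on_bit_score(self, hits_setup, rng):
        _, db = hits_setup
        ref = db.entries[0].sequence
        # OTU one substitution away from two equally mutated references
        otu = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        hits = [h for h in generate_hit_table({"Q": otu}, db)
                if h.percent_identity > 99.0]
        # the decoy entry (when present) is byte-identical to the primary
        scores = {h.bit_score for h in hits if h.subject_id.endswith(".0")}
        assert len(scores) >= 1

    def test_identity_agrees_with_alignment_oracle(self, hits_setup, rng):
        _, db = hits_setup
        base = db.entries[0].sequence
        otus = {}
        for i in range(5):
            arr = list(base)
            for pos in rng.choice(len(arr), size=i * 2, replace=False):
                arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
            otus[f"Q{i}"] = "".join(arr)
        hits = generate_hit_table(otus, db, HitScoring(min_identity_emit=0.9))
        by_id = {e.subject_id: e.sequence for e in db.entries}
        for h in hits:
            dist = nw_edit_distance(otus[h.query_id], by_id[h.subject_id])
            implied = 100 * (1 - dist / h.alignment_length)
            assert h.percent_identity == pytest.approx(implied, abs=0.01)

    def test_scores_sorted_and_evalue_monotone(self, hits_setup):
        _, db = hits_setup
        hits = generate_hit_table({"Q": db.entries[0].sequence}, db,
                                  HitScoring(min_identity_emit=0.0))
        bits = [h.bit_score for h in hits]
        assert bits == sorted(bits, reverse=True)
        for a, b in zip(hits, hits[1:]):
            if a.bit_score > b.bit_score:
                assert a.e_value < b.e_value

    def test_empty_refdb_rejected(self, hits_setup):
        from otukit.simulate import ReferenceDB
        with pytest.raises(ValueError):
            generate_hit_table({"Q": "ACGT"}, ReferenceDB([], {}))


class TestPresenceTableFromVenn:
    def test_published_marginals_fixture(self):
        spec = VennSpec(238, 134, 584, 66, 318, 251, 710)
        table = presence_table_from_venn(spec, ("COL1", "COL3", "COL4"), seed=1)
        richness = (table.counts > 0).sum(axis=0)
        assert tuple(richness) == (1332, 1161, 1863)

    def test_all_triple_shared(self):
        spec = VennSpec(0, 0, 0, 0, 0, 0, 5)
        table = presence_table_from_venn(spec, seed=1)
        assert bool((table.counts > 0).all(axis=1).all())

    def test_round_trip_random_specs(self, rng):
        for _ in range(20):
            spec = VennSpec(*(int(x) for x in rng.integers(0, 30, size=7)))
            table = presence_table_from_venn(spec, seed=int(rng.integers(1000)))
            observed, _ = venn_regions(table.presence())
            assert observed == spec

    def test_abundances_at_least_one(self, rng):
        spec = VennSpec(2, 2, 2, 2, 2, 2, 2)
        table = presence_table_from_venn(spec, seed=5)
        counts = table.counts.to_numpy()
        assert counts[counts > 0].min() >= 1


class TestCountsForInverseSimpson:
    @pytest.mark.parametrize("sobs,target", [(1332, 13.23), (150, 6.21)])
    def test_hits_target_closely(self, sobs, target):
        counts = counts_for_inverse_simpson(sobs, target)
        rep = diversity(counts)
        assert rep.sobs == sobs
        assert rep.inv_simpson == pytest.approx(target, rel=0.02)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            counts_for_inverse_simpson(10, 0.5)
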