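import numpy as np
import pytest

from _oracles import brute_filter_hits, greedy_majority_taxa, root_path_lca
from otukit.classify import (
    ClassificationResult,
    HitRecord,
    LcaParams,
    classify_all,
    classify_otu,
    filter_hits,
    majority_lca,
    read_hit_table,
    resolve_uninformative,
    write_classification_tsv,
)
from otukit.simulate import generate_taxonomy

PARAMS = LcaParams()


def _hit(q="Q1", sid="s1", ident=99.0, bits=400.0, ev=1e-40,
         taxid="", name="Pseudonocardia"):
    return HitRecord(q, sid, ident, 250, bits, ev, taxid, name)


def _genus_id(tree, name):
    return tree.find_by_name(name)[0]


@pytest.fixture(scope="module")
def random_tree():
    return generate_taxonomy(3, 3, seed=17, n_families_per_phylum=2)


class TestFilterHits:
    def test_bitscore_band_drops_close_second(self):
        hits = [_hit(sid="a", bits=400), _hit(sid="b", bits=390)]
        kept = filter_hits(hits, PARAMS)
        assert [h.subject_id for h in kept] == ["a"]  # 390 < 0.99 * 400

    def test_absolute_thresholds_are_inclusive(self):
        h = _hit(ident=95.5, bits=200.0, ev=1e-15)
        assert filter_hits([h], PARAMS) == [h]

    def test_band_relative_to_best_passing_hit(self):
        # a high-scoring hit failing the identity threshold must not
        # suppress the best hit that actually passes
        bad = _hit(sid="bad", ident=80.0, bits=500)
        good = _hit(sid="good", ident=99.0, bits=300)
        assert filter_hits([bad, good], PARAMS) == [good]

    def test_cap_applies_before_thresholds(self):
        params = LcaParams(max_hits=2)
        hits = [
            _hit(sid="a", bits=500, ident=80.0),   # capped in, fails identity
            _hit(sid="b", bits=450, ident=99.0),
            _hit(sid="c", bits=449, ident=99.0),   # pushed out by the cap
        ]
        assert [h.subject_id for h in filter_hits(hits, params)] == ["b"]

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([_hit(q="Q1"), _hit(q="Q2")], PARAMS)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            hits = [
                _hit(
                    sid=f"s{i}",
                    ident=float(rng.uniform(90, 100)),
                    bits=float(rng.uniform(150, 500)),
                    ev=10.0 ** -float(rng.uniform(10, 40)),
                )
                for i in range(300)
            ]
            params = LcaParams(max_hits=int(rng.integers(5, 150)))
            expected = brute_filter_hits(
                hits, params.max_hits, params.max_evalue, params.min_identity,
                params.min_bitscore, params.bitscore_fraction,
            )
            assert filter_hits(hits, params) == expected


class TestResolveUninformative:
    def test_informative_hit_displaces_uncultured(self):
        unc = _hit(sid="u", bits=400, name="uncultured bacterium")
        inf = _hit(sid="i", bits=398, name="Pseudonocardia sp.")
        kept, flag = resolve_uninformative([unc, inf], PARAMS)
        assert kept == [inf] and flag is False

    def test_all_uninformative_kept_and_flagged(self):
        hits = [_hit(sid=f"u{i}", name="uncultured bacterium") for i in range(3)]
        kept, flag = resolve_uninformative(hits, PARAMS)
        assert kept == hits and flag is True

    def test_random_mixtures_match_two_branch_oracle(self, rng):
        names = ["uncultured soil bacterium", "Rhodococcus", "unidentified",
                 "Streptomyces", "Unclassified Nocardiaceae"]
        from otukit.taxonomy import is_uninformative
        for _ in range(50):
            hits = [
                _hit(sid=f"s{i}", name=str(rng.choice(names)))
                for i in range(int(rng.integers(1, 10)))
            ]
            kept, flag = resolve_uninformative(hits, PARAMS)
            informative = [h for h in hits if not is_uninformative(h.subject_name)]
            if informative:
                assert kept == informative and not flag
            else:
                assert kept == hits and flag

    def test_skipping_can_be_disabled(self):
        unc = _hit(sid="u", name="uncultured bacterium")
        inf = _hit(sid="i", name="Rhodococcus")
        kept, flag = resolve_uninformative(
            [unc, inf], LcaParams(skip_uninformative=False)
        )
        assert kept == [unc, inf] and flag is False


class TestMajorityLca:
    def test_rare_outlier_removed(self, actino_tree):
        a = _genus_id(actino_tree, "Rhodococcus")
        b = _genus_id(actino_tree, "Streptomyces")
        hits = [_hit(sid=f"s{i}", taxid=a) for i in range(20)]
        hits.append(_hit(sid="x", taxid=b))
        # B is 1/21 ~ 4.8%; dropping it leaves 95.2% >= 95% -> genus A
        node = majority_lca(hits, actino_tree, 0.95)
        assert actino_tree.node(node).name == "Rhodococcus"

    def test_balanced_split_falls_back_to_lca(self, actino_tree):
        a = _genus_id(actino_tree, "Rhodococcus")
        b = _genus_id(actino_tree, "Nocardia")
        hits = [_hit(sid=f"a{i}", taxid=a) for i in range(10)]
        hits += [_hit(sid=f"b{i}", taxid=b) for i in range(10)]
        node = majority_lca(hits, actino_tree, 0.95)
        assert actino_tree.node(node).name == "Nocardiaceae"

    def test_single_taxon(self, actino_tree):
        a = _genus_id(actino_tree, "Iamia")
        assert majority_lca([_hit(taxid=a)], actino_tree, 0.95) == a

    def test_empty_raises(self, actino_tree):
        with pytest.raises(ValueError):
            majority_lca([], actino_tree, 0.95)


def _random_hits(rng, tree, genera, n, q="Q1"):
    hits = []
    for i in range(n):
        gid = str(rng.choice(genera))
        hits.append(
            HitRecord(
                query_id=q,
                subject_id=f"s{i}",
                percent_identity=float(rng.uniform(92, 100)),
                alignment_length=250,
                bit_score=float(np.round(rng.uniform(150, 500), 1)),
                e_value=10.0 ** -float(rng.uniform(10, 40)),
                subject_taxon_id=gid,
                subject_name=tree.node(gid).name,
            )
        )
    return hits


class TestClassifyOtu:
    def test_nothing_passes(self, actino_tree):
        hits = [_hit(ident=80.0)]
        res = classify_otu(hits, actino_tree, PARAMS)
        assert res.status == "no_hits_passed"
        assert set(res.rank_path.values()) == {"unclassified"}

    def test_family_level_assignment_leaves_genus_unclassified(self, actino_tree):
        a = _genus_id(actino_tree, "Pseudonocardia")
        b = _genus_id(actino_tree, "Amycolatopsis")
        hits = [_hit(sid=f"a{i}", taxid=a, name="Pseudonocardia") for i in range(10)]
        hits += [_hit(sid=f"b{i}", taxid=b, name="Amycolatopsis") for i in range(10)]
        res = classify_otu(hits, actino_tree, PARAMS)
        assert res.status == "classified"
        assert res.rank_path["family"] == "Pseudonocardiaceae"
        assert res.rank_path["genus"] == "unclassified"

    def test_uncultured_only_reported_under_uncultured(self, actino_tree):
        # all surviving hits are environmental-clone entries under one family
        a = _genus_id(actino_tree, "Pseudonocardia")
        hits = [
            _hit(sid=f"u{i}", taxid=a, name="uncultured Pseudonocardiaceae")
            for i in range(5)
        ]
        res = classify_otu(hits, actino_tree, PARAMS)
        assert res.status == "uncultured_only"

    def test_assignment_is_ancestor_of_all_lca_taxa(self, random_tree, rng):
        genera = [n.node_id for n in random_tree.nodes() if n.rank == "genus"]
        for _ in range(30):
            hits = _random_hits(rng, random_tree, genera, int(rng.integers(1, 20)))
            res = classify_otu(hits, random_tree, PARAMS)
            if res.assigned_node_id is None:
                continue
            kept = filter_hits(hits, PARAMS)
            surviving = greedy_majority_taxa(kept, PARAMS.majority_fraction)
            for gid in surviving:
                assert random_tree.is_ancestor(res.assigned_node_id, gid)

    def test_order_invariance(self, random_tree, rng):
        genera = [n.node_id for n in random_tree.nodes() if n.rank == "genus"]
        hits = _random_hits(rng, random_tree, genera, 30)
        res1 = classify_otu(hits, random_tree, PARAMS)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        res2 = classify_otu(shuffled, random_tree, PARAMS)
        assert res1 == res2

    def test_tightening_band_never_shallower(self, random_tree, rng):
        # plain-LCA mode: a tighter bit-score band keeps a subset of
        # hits, so the assignment can only stay or get deeper
        genera = [n.node_id for n in random_tree.nodes() if n.rank == "genus"]
        base = dict(majority_fraction=1.0, skip_uninformative=False)
        for _ in range(20):
            hits = _random_hits(rng, random_tree, genera, 25)
            loose = classify_otu(hits, random_tree, LcaParams(bitscore_fraction=0.90, **base))
            tight = classify_otu(hits, random_tree, LcaParams(bitscore_fraction=0.999, **base))
            if loose.assigned_node_id and tight.assigned_node_id:
                assert random_tree.is_ancestor(
                    loose.assigned_node_id, tight.assigned_node_id
                )


class TestClassifyAll:
    def test_composition_equals_per_query_runs(self, random_tree, rng):
        genera = [n.node_id for n in random_tree.nodes() if n.rank == "genus"]
        hits = []
        for q in ("OTU1", "OTU2", "OTU3"):
            hits += _random_hits(rng, random_tree, genera, 8, q=q)
        combined = classify_all(hits, random_tree, PARAMS)
        for q in ("OTU1", "OTU2", "OTU3"):
            solo = classify_otu([h for h in hits if h.query_id == q],
                                random_tree, PARAMS)
            assert combined[q] == solo

    def test_absent_queries_reported_unclassified(self, random_tree):
        queries = [f"OTU{i}" for i in range(1, 6)]
        results = classify_all([], random_tree, PARAMS, query_ids=queries)
        assert set(results) == set(queries)
        assert all(r.status == "no_hits_passed" for r in results.values())


def test_hit_table_roundtrip(tmp_path, random_tree, rng):
    from otukit.simulate import write_hit_table
    genera = [n.node_id for n in random_tree.nodes() if n.rank == "genus"]
    hits = _random_hits(rng, random_tree, genera, 20)
    path = tmp_path / "hits.tsv"
    write_hit_table(hits, path)
    back = read_hit_table(path)
    assert [(h.query_id, h.subject_id, h.bit_score, h.subject_taxon_id)
            for h in back] == [
        (h.query_id, h.subject_id, h.bit_score, h.subject_taxon_id)
        for h in hits
    ]


def test_classification_tsv_layout(tmp_path, actino_tree):
    a = _genus_id(actino_tree, "Rhodococcus")
    res = classify_otu([_hit(taxid=a, name="Rhodococcus")], actino_tree, PARAMS)
    path = tmp_path / "cls.tsv"
    write_classification_tsv({"Q1": res}, path)
    header, row = path.read_text().splitlines()
    assert header.split("\t") == [
        "query_id", "status", "domain", "phylum", "class", "order",
        "family", "genus",
    ]
    assert row.split("\t")[-1] == "Rhodococcus"
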