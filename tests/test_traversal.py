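"""Traversal tests: route weights, annotation records, plant backtracking."""

import itertools

import numpy as np
import pytest

from herbnet.network_model import Edge, NodeRef, TripartiteNetwork
from herbnet.protein_weighting import load_t2dm_table, normalize_weights
from herbnet.scoring import formula_score
from herbnet.traversal import annotate_compounds, backtrack_to_plants


def P(nid, net="C"):
    return NodeRef("protein", nid, net)


def C(nid, net="A"):
    return NodeRef("compound", nid, net)


def T(nid):
    return NodeRef("plant", nid, "A")


def seeds_for(*rows):
    """Weight table whose protein ids equal the gene symbols by default."""
    return normalize_weights(rows)


class TestAnnotateCompounds:
    def test_direct_interaction_gives_weight_one(self):
        net = TripartiteNetwork()
        net.add_edge(Edge(P("s1", "C"), P("s1", "A"), 1.0, "protein_identity"))
        net.add_edge(Edge(P("s1", "A"), C("c1"), 1.0, "compound_protein"))
        ann = annotate_compounds(net, seeds_for(("s1", 0.2, 0.4)))
        assert ann["c1"].proteins["s1"][2] == 1.0

    def test_similarity_route_records_published_akt1_example(self):
        """A compound reachable only through a 0.9 similarity link stores
        (gene, protein weight, 0.9) — the record shape the method keeps."""
        table = load_t2dm_table()
        net = TripartiteNetwork()
        akt1 = P("AKT1", "C")
        net.add_edge(Edge(akt1, P("AKT1", "B"), 1.0, "protein_identity"))
        net.add_edge(Edge(P("AKT1", "B"), C("cb", "B"), 1.0, "compound_protein"))
        net.add_edge(Edge(C("cb", "B"), C("73399", "A"), 0.9, "compound_similarity"))
        with pytest.warns(UserWarning):  # the 20 other seeds are absent here
            ann = annotate_compounds(net, table)
        gene, p_weight, e_weight = ann["73399"].proteins["AKT1"]
        assert gene == "AKT1"
        assert e_weight == 0.9
        # recomputed from rounded printed centralities; the stored reference
        # value is 0.7993787198
        assert p_weight == pytest.approx(0.7993787198, abs=1e-4)
        assert ann["73399"].traced == {"AKT1"}

    def test_direct_route_beats_similarity_route(self):
        net = TripartiteNetwork()
        net.add_edge(Edge(P("s1", "C"), P("s1", "A"), 1.0, "protein_identity"))
        net.add_edge(Edge(P("s1", "A"), C("c1"), 1.0, "compound_protein"))
        net.add_edge(Edge(P("s1", "C"), P("s1", "B"), 1.0, "protein_identity"))
        net.add_edge(Edge(P("s1", "B"), C("cb", "B"), 1.0, "compound_protein"))
        net.add_edge(Edge(C("cb", "B"), C("c1"), 0.9, "compound_similarity"))
        ann = annotate_compounds(net, seeds_for(("s1", 0.2, 0.4)))
        assert ann["c1"].proteins["s1"][2] == 1.0

    def test_seed_network_compounds_relay_but_are_not_annotated(self):
        net = TripartiteNetwork()
        net.add_edge(Edge(P("s1", "C"), C("cc", "C"), 1.0, "compound_protein"))
        net.add_edge(Edge(C("cc", "C"), C("ca", "A"), 0.95, "compound_similarity"))
        ann = annotate_compounds(net, seeds_for(("s1", 0.2, 0.4)))
        assert "cc" not in ann
        assert ann["ca"].proteins["s1"][2] == pytest.approx(0.95)

    def test_absent_seed_skipped_with_warning(self):
        net = TripartiteNetwork()
        net.add_node(P("other", "C"))
        with pytest.warns(UserWarning, match="ghost"):
            ann = annotate_compounds(net, seeds_for(("ghost", 0.1, 0.1)))
        assert ann == {}

    def test_matches_exhaustive_route_enumeration(self):
        """Random fixture: per-compound weights equal a brute-force max over
        all protein-closure x direct-compound x similarity-path routes."""
        rng = np.random.default_rng(12)
        n_prot, n_comp = 6, 30
        net = TripartiteNetwork()
        prot_nodes = {}
        for i in range(n_prot):
            pc = P(f"s{i}", "C")
            pa = P(f"s{i}", "A")
            prot_nodes[f"s{i}"] = (pc, pa)
            net.add_edge(Edge(pc, pa, 1.0, "protein_identity"))
        comps = [C(f"c{j}", "A") for j in range(n_comp)]
        direct = {}  # protein -> set of compound indices
        for i in range(n_prot):
            hits = rng.choice(n_comp, size=rng.integers(1, 5), replace=False)
            direct[f"s{i}"] = set(int(h) for h in hits)
            for h in hits:
                net.add_edge(Edge(prot_nodes[f"s{i}"][1], comps[int(h)], 1.0, "compound_protein"))
        sims = {}
        for _ in range(25):
            a, b = rng.integers(0, n_comp, 2)
            if a == b:
                continue
            w = float(rng.uniform(0.85, 1.0))
            key = (min(int(a), int(b)), max(int(a), int(b)))
            sims[key] = max(sims.get(key, 0.0), w)
            net.add_edge(Edge(comps[int(a)], comps[int(b)], sims[key], "compound_similarity"))

        # oracle: best product over all simple similarity paths from any
        # directly-hit compound, by exhaustive relaxation
        def oracle(protein):
            best = {j: (1.0 if j in direct[protein] else 0.0) for j in range(n_comp)}
            for _ in range(n_comp):
                for (a, b), w in sims.items():
                    if best[a] * w > best[b]:
                        best[b] = best[a] * w
                    if best[b] * w > best[a]:
                        best[a] = best[b] * w
            return {j: v for j, v in best.items() if v > 0}

        ann = annotate_compounds(net, seeds_for(*[(f"s{i}", 0.1, 0.5) for i in range(n_prot)]))
        for i in range(n_prot):
            want = oracle(f"s{i}")
            got = {
                int(cid[1:]): rec[2]
                for cid, a in ann.items()
                for pid, rec in a.proteins.items()
                if pid == f"s{i}"
            }
            assert got.keys() == want.keys()
            for j in want:
                assert got[j] == pytest.approx(want[j])


class TestBacktrackToPlants:
    def build_plant_net(self, plant_compounds):
        net = TripartiteNetwork()
        for plant, comps in plant_compounds.items():
            for c in comps:
                net.add_edge(Edge(T(plant), C(c), 1.0, "plant_compound"))
        return net

    def annotations(self, net, spec):
        """spec: {protein: {compound: weight}} realized via direct/similarity edges."""
        for prot, hits in spec.items():
            pc = P(prot, "C")
            pa = P(prot, "A")
            net.add_edge(Edge(pc, pa, 1.0, "protein_identity"))
            for comp, w in hits.items():
                if w == 1.0:
                    net.add_edge(Edge(pa, C(comp), 1.0, "compound_protein"))
                else:
                    relay = C(f"relay-{prot}-{comp}", "B")
                    pb = P(prot, "B")
                    net.add_edge(Edge(pc, pb, 1.0, "protein_identity"))
                    net.add_edge(Edge(pb, relay, 1.0, "compound_protein"))
                    net.add_edge(Edge(relay, C(comp), w, "compound_similarity"))
        rows = [(p, 0.1, 0.5) for p in spec]
        return annotate_compounds(net, seeds_for(*rows))

    def test_single_compound_plant_profile_equals_annotation(self):
        net = self.build_plant_net({"t1": ["c1"]})
        ann = self.annotations(net, {"s1": {"c1": 0.9}})
        (prof,) = backtrack_to_plants(ann, net)
        assert prof.plant_id == "t1"
        assert prof.proteins == ann["c1"].proteins

    def test_two_compounds_same_protein_keep_max(self):
        net = self.build_plant_net({"t1": ["c1", "c2"]})
        ann = self.annotations(net, {"s1": {"c1": 0.9, "c2": 1.0}})
        (prof,) = backtrack_to_plants(ann, net)
        assert prof.proteins["s1"][2] == 1.0

    def test_untraceable_plants_omitted(self):
        net = self.build_plant_net({"t1": ["c1"], "t2": ["c9"]})
        ann = self.annotations(net, {"s1": {"c1": 1.0}})
        assert [p.plant_id for p in backtrack_to_plants(ann, net)] == ["t1"]

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(9)
        plants = {f"t{i}": [f"c{j}" for j in rng.choice(12, size=rng.integers(1, 5), replace=False)] for i in range(6)}
        spec = {}
        for s in range(4):
            hits = {}
            for j in rng.choice(12, size=rng.integers(1, 6), replace=False):
                w = 1.0 if rng.random() < 0.5 else float(np.round(rng.uniform(0.9, 1.0), 6))
                hits[f"c{int(j)}"] = w
            spec[f"s{s}"] = hits
        net = self.build_plant_net(plants)
        ann = self.annotations(net, spec)
        profiles = {p.plant_id: p for p in backtrack_to_plants(ann, net)}
        for plant, comps in plants.items():
            want = {}
            for comp, prot in itertools.product(comps, spec):
                if comp in ann and prot in ann[comp].proteins:
                    w = ann[comp].proteins[prot][2]
                    want[prot] = max(want.get(prot, 0.0), w)
            if not want:
                assert plant not in profiles
                continue
            got = {pid: rec[2] for pid, rec in profiles[plant].proteins.items()}
            assert got == pytest.approx(want)

    def test_profile_weights_bounded_and_positive(self):
        net = self.build_plant_net({"t1": ["c1", "c2"]})
        ann = self.annotations(net, {"s1": {"c1": 0.93}, "s2": {"c2": 1.0}})
        (prof,) = backtrack_to_plants(ann, net)
        for _, _, ew in prof.proteins.values():
            assert 0.0 < ew <= 1.0
        assert prof.proteins["s2"][2] == 1.0

    def test_total_value_equals_singleton_formula_score(self):
        net = self.build_plant_net({"t1": ["c1", "c2"]})
        ann = self.annotations(net, {"s1": {"c1": 0.9}, "s2": {"c2": 1.0}})
        (prof,) = backtrack_to_plants(ann, net)
        score, covered = formula_score(["t1"], [prof])
        assert score == pytest.approx(prof.total_value)
        assert covered == set(prof.proteins)
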