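import itertools

import numpy as np
import pytest

from mircnet.network_loops import (
    ACTIVATION,
    REPRESSION,
    RegNetwork,
    SignConflictError,
    SignedEdge,
    assemble_network,
    find_feedback_loops,
    find_feedforward_loops,
    network_summary,
)
from mircnet.target_integration import TFRegRecord


def mt(src, dst, sign=REPRESSION, ev="validated"):
    return SignedEdge(src, dst, sign, "mirna_target", ev)


def tm(src, dst, sign=ACTIVATION, ev="validated"):
    return SignedEdge(src, dst, sign, "tf_mirna", ev)


def tg(src, dst, sign=ACTIVATION, ev="predicted"):
    return SignedEdge(src, dst, sign, "tf_gene", ev)


def paper_scale_network() -> RegNetwork:
    """A network with the worked-example component sizes: 13 miRNAs,
    78 targets, 43 TFs of which 4 are also targets; 82 + 37 + 190 edges."""
    mirnas = [f"miR-{i}" for i in range(13)]
    tfs = [f"TF{i}" for i in range(43)]
    genes = [f"G{i}" for i in range(74)]
    targets = genes + tfs[:4]  # 78 targets, 4 of them TFs
    target_edges = []
    for k in range(78):
        target_edges.append(mt(mirnas[k % 13], targets[k % 78]))
    for k in range(78, 82):  # 4 extra pairs, offset to avoid collisions
        target_edges.append(mt(mirnas[k % 13], targets[(k + 1) % 78]))
    assert len({(e.src, e.dst) for e in target_edges}) == 82
    tf_mirna_edges = [tm(tfs[k % 43], mirnas[k % 13]) for k in range(37)]
    tf_gene_edges = [tg(tfs[k % 43], genes[k % 74]) for k in range(190)]
    return assemble_network([target_edges, tf_mirna_edges, tf_gene_edges])


class TestAssembleNetwork:
    def test_component_sizes_yield_130_nodes_309_edges(self):
        net = paper_scale_network()
        s = network_summary(net)
        assert s["n_nodes"] == 130
        assert s["nodes_by_role"]["mirna"] == 13
        assert s["nodes_by_role"]["target"] == 78
        assert s["nodes_by_role"]["tf"] == 43
        assert s["n_tf_also_target"] == 4
        assert s["n_edges"] == 309
        assert s["edges_by_category"] == {
            "mirna_target": 82, "tf_mirna": 37, "tf_gene": 190
        }

    def test_empty_inputs_give_empty_network(self):
        net = assemble_network([])
        assert not net.nodes and not net.edges

    def test_single_edge_summary(self):
        s = network_summary(assemble_network([[mt("miR-1", "G1")]]))
        assert s["n_nodes"] == 2 and s["n_edges"] == 1

    def test_curated_record_overrides_tf_default_sign(self):
        edges = [tm("ESR1", "miR-221-3p", ACTIVATION)]
        rec = TFRegRecord("ESR1", "miR-221-3p", REPRESSION)
        net = assemble_network([edges], overrides=[rec])
        assert net.edges[0].sign == REPRESSION

    def test_validated_plus_predicted_merge_to_both(self):
        net = assemble_network(
            [[mt("miR-1", "G1", ev="validated")], [mt("miR-1", "G1", ev="predicted")]]
        )
        assert len(net.edges) == 1 and net.edges[0].evidence == "both"

    def test_contradictory_signs_rejected(self):
        with pytest.raises(SignConflictError, match="miR-1"):
            assemble_network(
                [[tm("TF1", "miR-1", ACTIVATION)], [tm("TF1", "miR-1", REPRESSION)]]
            )

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            mt("X", "X")

    def test_summary_matches_naive_recount(self):
        rng = np.random.default_rng(0)
        edges = []
        for _ in range(40):
            kind = rng.integers(3)
            if kind == 0:
                edges.append(mt(f"miR-{rng.integers(5)}", f"G{rng.integers(10)}"))
            elif kind == 1:
                edges.append(tm(f"TF{rng.integers(5)}", f"miR-{rng.integers(5)}"))
            else:
                edges.append(tg(f"TF{rng.integers(5)}", f"G{rng.integers(10)}"))
        net = assemble_network([edges])
        s = network_summary(net)
        uniq = {(e.src, e.dst): e for e in edges}
        assert s["n_edges"] == len(uniq)
        nodes = {n for k in uniq for n in k}
        assert s["n_nodes"] == len(nodes)


class TestFeedbackLoops:
    def test_mutual_regulation_mixed_signs_is_negative(self):
        # TF activates the miRNA, miRNA represses the TF back
        net = assemble_network(
            [[tm("SRSF1", "miR-221-3p", ACTIVATION)],
             [mt("miR-221-3p", "SRSF1", REPRESSION)]]
        )
        loops = find_feedback_loops(net)
        assert len(loops) == 1 and loops[0].sign == "negative"

    def test_double_repression_is_positive(self):
        net = assemble_network(
            [[tm("LIN28A", "let-7b-5p", REPRESSION)],
             [mt("let-7b-5p", "LIN28A", REPRESSION)]]
        )
        loops = find_feedback_loops(net)
        assert len(loops) == 1 and loops[0].sign == "positive"

    def test_acyclic_network_has_no_loops(self):
        net = assemble_network([[tm("TF1", "miR-1"), tg("TF1", "G1")],
                                [mt("miR-1", "G1")]])
        assert find_feedback_loops(net) == []

    def test_flipping_one_edge_sign_flips_class(self):
        for s1, s2 in itertools.product([ACTIVATION, REPRESSION], repeat=2):
            net = assemble_network([[tm("T", "m", s1)], [mt("m", "T", s2)]])
            loop = find_feedback_loops(net)[0]
            flipped = assemble_network([[tm("T", "m", -s1)], [mt("m", "T", s2)]])
            loop2 = find_feedback_loops(flipped)[0]
            assert loop.sign != loop2.sign

    def test_longer_cycles_found_with_max_len(self):
        net = assemble_network(
            [[tm("TF1", "miR-1")], [mt("miR-1", "G1")],
             [SignedEdge("G1", "TF1", ACTIVATION, "tf_gene", "predicted")]]
        )
        assert find_feedback_loops(net, max_len=2) == []
        loops = find_feedback_loops(net, max_len=3)
        assert len(loops) == 1
        assert loops[0].sign == "negative"  # one repression edge


class TestFeedForwardLoops:
    def test_all_activation_is_coherent(self):
        net = assemble_network(
            [[tg("X", "G1"), SignedEdge("X", "Y", 1, "tf_gene", "predicted")],
             [SignedEdge("Y", "G1", 1, "tf_gene", "predicted")]]
        )
        ffls = find_feedforward_loops(net)
        assert len(ffls) == 1 and ffls[0].coherent

    def test_sign_mismatch_is_incoherent(self):
        net = assemble_network(
            [[SignedEdge("X", "Y", 1, "tf_mirna", "validated"),
              SignedEdge("X", "Z", 1, "tf_gene", "predicted")],
             [SignedEdge("Y", "Z", -1, "mirna_target", "validated")]]
        )
        ffls = find_feedforward_loops(net)
        assert len(ffls) == 1 and not ffls[0].coherent
        assert ffls[0].contains_mirna  # Y carries the mirna role

    def test_enumeration_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            net = random_signed_network(rng, n=10, p=0.3)
            got = {
                (f.regulator, f.intermediate, f.target, f.coherent)
                for f in find_feedforward_loops(net)
            }
            assert got == bruteforce_ffls(net)

    def test_coherent_plus_incoherent_equals_total(self):
        rng = np.random.default_rng(13)
        net = random_signed_network(rng, n=12, p=0.3)
        ffls = find_feedforward_loops(net)
        n_coh = sum(f.coherent for f in ffls)
        n_inc = sum(not f.coherent for f in ffls)
        assert n_coh + n_inc == len(ffls)


def random_signed_network(rng: np.random.Generator, n: int, p: float) -> RegNetwork:
    """Random signed digraph; TF→gene edges so any topology is allowed."""
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                sign = ACTIVATION if rng.random() < 0.5 else REPRESSION
                edges.append(SignedEdge(f"n{i}", f"n{j}", sign, "tf_gene",
                                        "predicted"))
    return assemble_network([edges])


def bruteforce_ffls(net: RegNetwork) -> set:
    """O(n^3) oracle over all ordered node triples."""
    ed = net.edge_dict()
    nodes = list(net.nodes)
    out = set()
    for x in nodes:
        for y in nodes:
            for z in nodes:
                if len({x, y, z}) < 3:
                    continue
                if (x, y) in ed and (y, z) in ed and (x, z) in ed:
                    coherent = ed[(x, z)].sign == ed[(x, y)].sign * ed[(y, z)].sign
                    out.add((x, y, z, coherent))
    return out


def bruteforce_fbl2(net: RegNetwork) -> set:
    """Oracle for length-2 feedback loops: mutual (a,b) pairs with parity sign."""
    ed = net.edge_dict()
    out = set()
    for (a, b) in ed:
        if a < b and (b, a) in ed:
            n_rep = (ed[(a, b)].sign == REPRESSION) + (ed[(b, a)].sign == REPRESSION)
            out.add((a, b, "positive" if n_rep % 2 == 0 else "negative"))
    return out


def test_fbl_enumeration_matches_bruteforce_oracle():
    rng = np.random.default_rng(21)
    for _ in range(20):
        net = random_signed_network(rng, n=10, p=0.3)
        got = {
            (min(l.cycle), max(l.cycle), l.sign)
            for l in find_feedback_loops(net, max_len=2)
        }
        assert got == bruteforce_fbl2(net)
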