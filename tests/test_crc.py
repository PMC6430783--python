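"""PWM scanning, CRC graph construction, cliques and TF ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from secircuit.crc import (
    PWM,
    build_crc_graph,
    clique_scores,
    coexpression,
    crc_from_sequences,
    enumerate_cliques,
    rank_core_tfs,
    read_jaspar,
    read_meme,
    scan_motifs,
    score_tfs,
    write_jaspar,
    CRCGraph,
    TFScore,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _one_hot(consensus, name="tf", pseudocount=0.0):
    order = "ACGT"
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, order.index(b)] = 1.0
    return PWM(name=name, matrix=mat, pseudocount=pseudocount)


class TestPWM:
    def test_one_hot_consensus_scores_log2_inverse_background(self):
        pwm = _one_hot("ACGT")
        hits = scan_motifs("ACGT", pwm, threshold=7.9)
        (hit,) = [h for h in hits if h.strand == "+"]
        assert hit.score == pytest.approx(4 * math.log2(4))  # 8 bits
        assert pwm.max_score == pytest.approx(8.0)

    def test_mismatch_with_zero_pseudocount_is_minus_infinity(self):
        pwm = _one_hot("ACGT")
        hits = scan_motifs("TTTT", pwm, threshold=-1e9)
        fwd = [h for h in hits if h.strand == "+"]
        assert all(h.score == -math.inf for h in fwd)

    def test_columns_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM("bad", np.full((6, 4), 0.3))

    def test_consensus_roundtrip_through_jaspar(self, tmp_path):
        rng = np.random.default_rng(0)
        mats = []
        for i in range(3):
            m = rng.dirichlet([1, 1, 1, 1], size=8)
            mats.append(PWM(f"tf{i}", m))
        path = tmp_path / "m.jaspar"
        write_jaspar(mats, path)
        back = read_jaspar(path)
        assert [p.name for p in back] == [p.name for p in mats]
        for a, b in zip(mats, back):
            assert a.consensus == b.consensus

    def test_meme_minimal_format(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF M1 TFA\n"
            "letter-probability matrix: alength= 4 w= 4\n"
            "1.0 0.0 0.0 0.0\n0.0 1.0 0.0 0.0\n0.0 0.0 1.0 0.0\n0.0 0.0 0.0 1.0\n"
            "\n"
        )
        (pwm,) = read_meme(path)
        assert pwm.name == "TFA" and pwm.consensus == "ACGT"


class TestScan:
    def test_planted_consensus_found_on_both_strands(self, rng):
        cons = "ACGTACGTAC"
        pwm = _one_hot(cons, pseudocount=0.01)
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), 300))
        seq = seq[:50] + cons + seq[60:150] + \
            cons.translate(_COMP)[::-1] + seq[160:]
        hits = scan_motifs(seq, pwm)          # default 80% threshold
        positions = {(h.offset, h.strand) for h in hits}
        assert (50, "+") in positions
        assert (150, "-") in positions

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            cons = "".join(rng.choice(list("ACGT"), 8))
            pwm = _one_hot(cons, pseudocount=0.01)
            seq = "".join(rng.choice(list("ACGTN"), 500, p=[0.24] * 4 + [0.04]))
            pos = int(rng.integers(0, 490))
            seq = seq[:pos] + cons + seq[pos + 8:]
            threshold = 0.8 * pwm.max_score
            got = sorted((h.offset, h.strand, round(h.score, 9)) for h in
                         scan_motifs(seq, pwm, threshold))
            expected = [(o, s, round(v, 9)) for o, s, v in
                        oracles.bf_scan(seq, pwm.matrix, 0.01, threshold)]
            assert got == expected

    def test_motif_longer_than_sequence_gives_no_hits(self):
        assert scan_motifs("ACG", _one_hot("ACGTACGT"), 0.0) == []

    def test_revcomp_sequence_swaps_strands_preserving_scores(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        pwm = _one_hot("ACGTAGGT", pseudocount=0.01)
        fwd = scan_motifs(seq, pwm, threshold=5.0)
        rev = scan_motifs(seq.translate(_COMP)[::-1], pwm, threshold=5.0)
        m = len(pwm)
        mapped = sorted((len(seq) - m - h.offset,
                         "+" if h.strand == "-" else "-",
                         round(h.score, 9)) for h in rev)
        assert mapped == sorted((h.offset, h.strand, round(h.score, 9))
                                for h in fwd)


class TestGraph:
    def _graph(self, edges, nodes=None):
        tfs = nodes or sorted({t for e in edges for t in e})
        counts = {e: 1 for e in edges}
        return build_crc_graph({tf: ["se"] for tf in tfs}, counts,
                               expressed_tfs=set(tfs))

    def test_self_hit_only_keeps_single_node(self):
        g = self._graph({("A", "A")})
        assert g.nodes == ["A"]
        assert not g.has_edge("A", "B")

    def test_non_autoregulated_tf_excluded_even_if_targeted(self):
        g = self._graph({("A", "A"), ("A", "B"), ("B", "A")}, nodes=["A", "B"])
        assert g.nodes == ["A"]  # B lacks a self-hit

    def test_planted_mutual_pair(self):
        g = self._graph({("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")})
        assert g.nodes == ["A", "B"]
        assert g.mutual_graph().has_edge("A", "B")

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning):
            g = build_crc_graph({"A": ["se"]}, {}, expressed_tfs={"A"})
        assert g.nodes == []


class TestCliques:
    def test_triangle_plus_isolated_node(self):
        g = self._mutual({"A": "BC", "B": "AC", "C": "AB", "D": ""})
        cliques = enumerate_cliques(g)
        assert set(cliques) == {frozenset("ABC"), frozenset("D")}

    def test_complete_graph_is_one_clique(self):
        nodes = list("ABCDE")
        g = self._mutual({a: "".join(b for b in nodes if b != a) for a in nodes})
        assert enumerate_cliques(g) == [frozenset(nodes)]

    def test_node_cap(self):
        g = self._mutual({str(i): "" for i in range(30)})
        with pytest.raises(ValueError, match="cap"):
            enumerate_cliques(g, cap=25)

    def test_matches_subset_enumeration_oracle(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 11))
            nodes = [f"t{i}" for i in range(n)]
            mutual = set()
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.4:
                    mutual.add(frozenset((a, b)))
            g = self._mutual_from_edges(nodes, mutual)
            assert set(enumerate_cliques(g)) == oracles.bf_max_cliques(nodes, mutual)

    @staticmethod
    def _mutual(spec):
        import networkx as nx

        dg = nx.DiGraph()
        for node, partners in spec.items():
            dg.add_edge(node, node, hits=1)
            for p in partners:
                dg.add_edge(node, p, hits=1)
        return CRCGraph(graph=dg)

    @staticmethod
    def _mutual_from_edges(nodes, mutual):
        import networkx as nx

        dg = nx.DiGraph()
        for n in nodes:
            dg.add_edge(n, n, hits=1)
        for e in mutual:
            a, b = tuple(e)
            dg.add_edge(a, b, hits=1)
            dg.add_edge(b, a, hits=1)
        return CRCGraph(graph=dg)


class TestScores:
    def test_clique_fraction_counts(self):
        cliques = [frozenset("ABC"), frozenset("D")]
        fr = clique_scores(cliques, list("ABCD"))
        assert fr == {"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5}
        single = clique_scores([frozenset("AB")], list("AB"))
        assert single == {"A": 1.0, "B": 1.0}

    def test_zero_cliques_flagged(self):
        with pytest.warns(UserWarning):
            fr = clique_scores([], ["A"])
        assert math.isnan(fr["A"])

    def test_fraction_identity(self, rng):
        nodes = [f"t{i}" for i in range(8)]
        cliques = [frozenset(rng.choice(nodes, size=3, replace=False))
                   for _ in range(6)]
        fr = clique_scores(cliques, nodes)
        assert sum(fr[t] * len(cliques) for t in nodes) == \
            pytest.approx(sum(len(c) for c in cliques))

    def test_coexpression_closed_form(self):
        # r on log2(x+1): hand-computed Pearson for two short vectors
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        expr = pd.DataFrame([x, y], index=["A", "B"],
                            columns=["s1", "s2", "s3"])
        lx, ly = np.log2(x + 1), np.log2(y + 1)
        expected = (np.mean(lx * ly) - lx.mean() * ly.mean()) / (lx.std() * ly.std())
        mat = coexpression(expr, ["A", "B"])
        assert mat.loc["A", "B"] == pytest.approx(expected)
        assert mat.loc["A", "A"] == 1.0
        assert mat.equals(mat.T)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 3.0, 7.0])
        expr = pd.DataFrame(
            [2.0 ** x - 1, 2.0 ** (10 - x) - 1], index=["A", "B"],
            columns=["s1", "s2", "s3"])
        mat = coexpression(expr, ["A", "B"])
        assert mat.loc["A", "B"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["A", "B"], columns=list("xyz"))
        with pytest.warns(UserWarning):
            mat = coexpression(expr, ["A", "B"])
        assert math.isnan(mat.loc["A", "B"])


class TestRanking:
    def test_dominant_tf_ranks_first(self):
        scores = [TFScore("A", 1.0, 0.9, 1), TFScore("B", 0.5, 0.1, 5)]
        assert [s.tf for s in rank_core_tfs(scores)] == ["A", "B"]

    def test_clique_tie_broken_by_coexpression_then_se_rank(self):
        scores = [TFScore("A", 0.5, 0.2, 1), TFScore("B", 0.5, 0.8, 9),
                  TFScore("C", 0.5, 0.8, 2)]
        assert [s.tf for s in rank_core_tfs(scores)] == ["C", "B", "A"]

    def test_partnerless_tf_sorts_below_cooperative(self):
        cliques = [frozenset("AB"), frozenset("D")]
        coexpr = pd.DataFrame(np.eye(3) * 0.0 + 0.7, index=list("ABD"),
                              columns=list("ABD"))
        scores = score_tfs(cliques, coexpr, {"A": 1, "B": 2, "D": 3},
                           list("ABD"))
        ranked = rank_core_tfs(scores)
        assert ranked[-1].tf == "D"
        assert math.isnan(ranked[-1].mean_coexpression)


class TestEndToEnd:
    def test_planted_circuit_recovered_from_sequences(self, rng):
        """Planted 2-TF mutual circuit among decoys lands on top."""
        tfs = ["A", "B", "d1", "d2"]
        pwms = {}
        for t in tfs:
            cons = "".join(rng.choice(list("ACGT"), 10))
            mat = np.full((10, 4), 0.01)
            for i, b in enumerate(cons):
                mat[i, "ACGT".index(b)] = 0.97
            pwms[t] = PWM(t, mat)
        seqs = {}
        for t in tfs:
            seq = "".join(rng.choice(list("ACGT"), 600))
            plant = [pwms[t].consensus]           # auto-regulation
            if t in "AB":
                other = "B" if t == "A" else "A"
                plant.append(pwms[other].consensus)
            for i, word in enumerate(plant):
                pos = 50 + 100 * i
                seq = seq[:pos] + word + seq[pos + len(word):]
            seqs[t] = [("se_" + t, seq)]
        graph, hits = crc_from_sequences(seqs, pwms)
        assert set(graph.nodes) == set(tfs)
        assert graph.has_edge("A", "B") and graph.has_edge("B", "A")
        cliques = enumerate_cliques(graph)
        assert frozenset("AB") in cliques
        rng2 = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(10)]
        latent = rng2.normal(size=10)
        rows = {}
        for t in tfs:
            base = rng2.normal(5, 1, size=10)
            if t in "AB":
                base = base + 2 * latent
            rows[t] = 2.0 ** base
        expr = pd.DataFrame(rows).T
        expr.columns = samples
        coexpr = coexpression(expr, graph.nodes)
        ranked = rank_core_tfs(score_tfs(cliques, coexpr,
                                         {t: i + 1 for i, t in enumerate(tfs)},
                                         graph.nodes))
        assert {s.tf for s in ranked[:2]} == {"A", "B"}
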