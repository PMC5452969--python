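"""Tree parsing, cumulative variants, assignment scoring and P_mismatch."""

import numpy as np
import pytest

from mitoprofile import (
    HaploTree,
    ReferenceGenome,
    SimulationConfig,
    assign_haplogroup,
    assignment_accuracy,
    build_consensus,
    build_pileup,
    haplotype_from_tree,
    p_mismatch,
    parse_haplotree,
    random_haplotree,
    score_haplogroup,
    simulate_reads,
)
from mitoprofile.haplogroup import HaploNode, parse_token, write_haplotree

from conftest import make_read


class TestParseToken:
    def test_substitution(self):
        t = parse_token("A73G")
        assert (t.kind, t.position, t.allele, t.back_mutation) == ("substitution", 73, "G", False)

    def test_back_mutation(self):
        assert parse_token("A5G!").back_mutation

    def test_deletion(self):
        t = parse_token("A249d")
        assert (t.kind, t.allele) == ("deletion", "-")

    def test_insertion_parsed(self):
        t = parse_token("16182.1C")
        assert (t.kind, t.position, t.allele) == ("insertion", 16182, "C")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError, match="unparseable"):
            parse_token("Q5A")


class TestParseTree:
    def test_toy_tree_cumulative_union(self, toy_tree_file):
        tree = parse_haplotree(toy_tree_file)
        assert tree.root == "R"
        assert tree.cumulative_variants("B") == {5: "A", 7: "C"}
        assert tree.cumulative_variants("A") == {5: "A"}
        assert tree.cumulative_variants("R") == {}

    def test_back_mutation_cancels_along_path(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("R\t\t\nA\tR\tG5A\nB\tA\tA5G!,T7C\n")
        tree = parse_haplotree(p)
        assert 5 not in tree.cumulative_variants("B")
        assert tree.cumulative_variants("B") == {7: "C"}

    def test_insertion_excluded_from_positional_state(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("R\t\t\nA\tR\tG5A,16182.1C\n")
        tree = parse_haplotree(p)
        assert tree.cumulative_variants("A") == {5: "A"}
        assert [t.raw for t in tree.cumulative_insertions("A")] == ["16182.1C"]

    @pytest.mark.parametrize("content,match", [
        ("R\t\t\nA\tR\tG5A\nA\tR\tT7C\n", "line 3.*duplicate"),
        ("R\t\t\nA\tZed\tG5A\n", "unknown parent"),
        ("R\t\t\nA\tR\tnot_a_token\n", "line 2.*unparseable"),
        ("A\tB\tG5A\nB\tA\tT7C\n", "cycle|root"),
        ("R\t\t\nS\t\t\n", "exactly one root"),
    ])
    def test_malformed_trees_rejected(self, tmp_path, content, match):
        p = tmp_path / "bad.tsv"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            parse_haplotree(p)

    def test_positions_validated_against_reference(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("R\t\t\nA\tR\tG500A\n")
        ref = ReferenceGenome("r", "ACGT" * 25)
        with pytest.raises(ValueError, match="outside reference"):
            parse_haplotree(p, ref)

    def test_roundtrip_through_writer(self, tmp_path, small_ref):
        tree = random_haplotree(small_ref, n_nodes=8, seed=3)
        p = tmp_path / "rt.tsv"
        write_haplotree(tree, p)
        back = parse_haplotree(p, small_ref)
        for name in tree.names():
            assert back.cumulative_variants(name) == tree.cumulative_variants(name)


def _brute_force_cumulative(tree, name):
    """Replay the root-to-node path token by token (independent oracle)."""
    chain = []
    cur = name
    while cur is not None:
        chain.append(tree.nodes[cur])
        cur = tree.nodes[cur].parent
    state = {}
    for node in reversed(chain):
        for tok in node.defining_variants:
            if tok.kind == "insertion":
                continue
            if tok.back_mutation:
                state.pop(tok.position, None)
            else:
                state[tok.position] = tok.allele
    return state


class TestCumulativeOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_path_replay_on_random_trees(self, small_ref, seed):
        tree = random_haplotree(small_ref, n_nodes=20, variants_per_branch=3, seed=seed)
        for name in tree.names():
            assert tree.cumulative_variants(name) == _brute_force_cumulative(tree, name)


def _consensus_with(tree, ref, node, toy_positions=None):
    seq = list(ref.sequence)
    for pos, allele in tree.cumulative_variants(node).items():
        seq[pos - 1] = allele
    return "".join(seq)


class _FakeConsensus:
    """Minimal consensus stand-in: a plain string scored positionally."""

    def __init__(self, seq):
        self._seq = seq

    def sequence(self):
        return self._seq


def _string_consensus(seq):
    from mitoprofile.consensus import ConsensusSequence, CONSENSUS_ALPHABET
    from mitoprofile import FilterPolicy

    codes = np.array([CONSENSUS_ALPHABET.index(c) for c in seq], dtype=np.int8)
    n = len(seq)
    return ConsensusSequence(
        codes=codes,
        n_agree=np.zeros(n, dtype=np.int64),
        filtered_depth=np.ones(n, dtype=np.int64),
        mode="majority",
        policy=FilterPolicy(),
        reference_name="r",
    )


class TestScoring:
    @pytest.fixture
    def toy(self, toy_tree_file):
        return parse_haplotree(toy_tree_file)

    def test_exact_carrier_scores_clean(self, toy):
        seq = list("ACGTACGTAC")
        seq[4] = "A"
        seq[6] = "C"
        cons = _string_consensus("".join(seq))
        assert score_haplogroup(cons, toy, "B") == (2, 0, 0)

    def test_root_state_sample_mismatches(self, toy):
        cons = _string_consensus("ACGTGCTTAC")  # reference state at 5 (G) and 7 (T)
        assert score_haplogroup(cons, toy, "B") == (0, 2, 0)

    def test_nocall_bookkeeping(self, toy):
        seq = list("ACGTACGTAC")
        seq[4] = "A"
        seq[6] = "N"
        cons = _string_consensus("".join(seq))
        assert score_haplogroup(cons, toy, "B") == (1, 0, 1)

    def test_unknown_node_errors(self, toy):
        with pytest.raises(KeyError):
            score_haplogroup(_string_consensus("ACGTACGTAC"), toy, "Z")


class TestAssign:
    def test_reference_state_picks_root(self, toy_tree_file, small_ref):
        tree = parse_haplotree(toy_tree_file)
        cons = _string_consensus(small_ref.sequence)
        call = assign_haplogroup(cons, tree)
        assert call.best == "R"

    def test_error_free_simulation_recovers_node(self, small_ref):
        tree = random_haplotree(small_ref, n_nodes=8, variants_per_branch=3, seed=6)
        hap = haplotype_from_tree(small_ref, tree, "HG05")
        cfg = SimulationConfig(haplotype=hap, seed=9, depth=50, read_length=30,
                               error_rate=0.0)
        reads, _ = simulate_reads(cfg, small_ref)
        pile = build_pileup(reads, small_ref)
        call = assign_haplogroup(pile, tree)
        assert call.best == "HG05"
        top = call.ranking[0]
        assert top["n_mismatch"] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_self_consistency_every_node_ranks_first(self, small_ref, seed):
        """A consensus synthesized from any node's variants ranks that node first."""
        tree = random_haplotree(small_ref, n_nodes=12, variants_per_branch=3, seed=seed)
        for name in tree.names():
            cons = _string_consensus(haplotype_from_tree(small_ref, tree, name))
            assert assign_haplogroup(cons, tree).best == name

    def test_scores_sorted_non_increasing(self, small_ref):
        tree = random_haplotree(small_ref, n_nodes=10, seed=2)
        cons = _string_consensus(haplotype_from_tree(small_ref, tree, "HG03"))
        call = assign_haplogroup(cons, tree)
        scores = [r["score"] for r in call.ranking]
        assert scores == sorted(scores, reverse=True)
        counts = call.ranking[0]
        assert counts["n_match"] + counts["n_mismatch"] + counts["n_nocall"] == counts["k_covered"] + counts["n_nocall"]


class TestPMismatch:
    def test_clean_sample_is_exactly_zero(self, small_ref):
        tree = random_haplotree(small_ref, n_nodes=6, seed=4)
        hap = haplotype_from_tree(small_ref, tree, "HG03")
        cfg = SimulationConfig(haplotype=hap, seed=2, depth=40, read_length=30,
                               error_rate=0.0)
        reads, _ = simulate_reads(cfg, small_ref)
        pile = build_pileup(reads, small_ref)
        pm, k, excluded = p_mismatch(pile, tree, "HG03")
        assert pm == 0.0
        assert k == len(tree.cumulative_variants("HG03"))

    def test_printed_formula_arithmetic(self, small_ref, tmp_path):
        # k=2 sites with ratios 1/9 and 0/10 -> (0.111..+0)/2*100 = 5.555..%
        p = tmp_path / "t.tsv"
        ref_b1, ref_b5 = small_ref.base(1), small_ref.base(5)
        alt1 = "A" if ref_b1 != "A" else "G"
        alt5 = "A" if ref_b5 != "A" else "G"
        p.write_text(f"R\t\t\nX\tR\t{ref_b1}1{alt1},{ref_b5}5{alt5}\n")
        tree = parse_haplotree(p, small_ref)
        reads = [make_read(1, alt1, 40, rid=f"m{i}") for i in range(9)]
        reads += [make_read(1, ref_b1, 40, rid="mm")]  # 1 mismatching base at site 1
        reads += [make_read(5, alt5, 40, rid=f"n{i}") for i in range(10)]
        pile = build_pileup(reads, small_ref)
        pm, k, excluded = p_mismatch(pile, tree, "X")
        assert k == 2 and excluded == 0
        assert pm == pytest.approx((1 / 9 + 0) / 2 * 100)

    def test_zero_match_sites_dropped_from_k(self, small_ref, tmp_path):
        p = tmp_path / "t.tsv"
        b1, b5 = small_ref.base(1), small_ref.base(5)
        a1 = "A" if b1 != "A" else "G"
        a5 = "A" if b5 != "A" else "G"
        p.write_text(f"R\t\t\nX\tR\t{b1}1{a1},{b5}5{a5}\n")
        tree = parse_haplotree(p, small_ref)
        reads = [make_read(1, a1, 40, rid=f"m{i}") for i in range(5)]
        reads += [make_read(5, b5, 40, rid="ref5")]  # site 5: zero matching bases
        pile = build_pileup(reads, small_ref)
        pm, k, excluded = p_mismatch(pile, tree, "X")
        assert (k, excluded) == (1, 1)
        assert pm == 0.0

    def test_no_scorable_sites_errors(self, small_ref, tmp_path):
        p = tmp_path / "t.tsv"
        b1 = small_ref.base(1)
        a1 = "A" if b1 != "A" else "G"
        p.write_text(f"R\t\t\nX\tR\t{b1}1{a1}\n")
        tree = parse_haplotree(p, small_ref)
        pile = build_pileup([], small_ref)
        with pytest.raises(ValueError, match="no scorable"):
            p_mismatch(pile, tree, "X")

    def test_monotone_in_contamination(self, small_ref):
        tree = random_haplotree(small_ref, n_nodes=6, variants_per_branch=6, seed=10)
        host = haplotype_from_tree(small_ref, tree, "HG02")
        values = []
        for frac in (0.0, 0.1, 0.2, 0.3):
            cfg = SimulationConfig(
                haplotype=host, contaminant=small_ref.sequence,
                contamination_fraction=frac, seed=33, depth=80, read_length=30,
                error_rate=0.01,
            )
            reads, _ = simulate_reads(cfg, small_ref)
            pile = build_pileup(reads, small_ref)
            pm, _, _ = p_mismatch(pile, tree, "HG02")
            values.append(pm)
        assert values == sorted(values)
        assert values[-1] > values[0]


class TestAccuracy:
    def test_perfect(self):
        assert assignment_accuracy(["a"] * 10, ["a"] * 10) == 1.0

    def test_nine_of_ten(self):
        truth = ["a"] * 9 + ["b"]
        pred = ["a"] * 9 + ["c"]
        assert assignment_accuracy(truth, pred) == pytest.approx(0.9)

    def test_all_wrong(self):
        assert assignment_accuracy(["a", "b"], ["b", "a"]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assignment_accuracy([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assignment_accuracy(["a"], ["a", "b"])


class TestDepthAccuracyMonotonicity:
    def test_mean_accuracy_non_decreasing_in_depth(self, small_ref):
        tree = random_haplotree(small_ref, n_nodes=10, variants_per_branch=3, seed=7)
        names = [n for n in tree.names() if n != "ROOT"]
        rng = np.random.default_rng(99)
        accs = []
        for depth in (1, 5, 10, 50):
            truth, pred = [], []
            for i in range(30):
                node = names[int(rng.integers(0, len(names)))]
                hap = haplotype_from_tree(small_ref, tree, node)
                cfg = SimulationConfig(haplotype=hap, seed=int(rng.integers(2**31)),
                                       depth=depth, read_length=30, error_rate=0.01)
                reads, _ = simulate_reads(cfg, small_ref)
                pile = build_pileup(reads, small_ref)
                truth.append(node)
                pred.append(assign_haplogroup(pile, tree).best)
            accs.append(assignment_accuracy(truth, pred))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:])), accs
        assert accs[-1] >= 0.95
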