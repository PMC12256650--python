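import numpy as np
import pytest

from lossmap.core import ABSENT, PRESENT, UNKNOWN, CharacterMatrix
from lossmap import dollo
from lossmap.dollo import (
    DolloError,
    PolaritySpec,
    count_branch_events,
    cumulative_tip_losses,
    map_losses,
    reconstruct_states,
    shared_missing,
)

from conftest import brute_force_min_losses, random_tree


def matrix_from_rows(taxa, chars, rows):
    return CharacterMatrix(taxa, chars, np.array(rows, dtype=np.int8))


class TestReconstructStates:
    def test_all_present_no_events(self, small_tree):
        m = matrix_from_rows(small_tree.tips, ["c1"], [[1]] * 5)
        table = map_losses(m, small_tree)
        assert table.total_losses == 0
        assert table.total_gains == 0

    def test_clade_loss_single_stem_event(self, syndermatan_tree):
        taxa = syndermatan_tree.tips
        col = [0 if t in ("Seisonidea", "Acanthocephala") else 1 for t in taxa]
        m = matrix_from_rows(taxa, ["c1"], [[v] for v in col])
        table = map_losses(m, syndermatan_tree)
        assert table.losses["Pararotatoria"] == 1
        assert table.total_losses == 1

    def test_terminal_loss(self, small_tree):
        col = {t: 1 for t in small_tree.tips}
        col["D"] = 0
        m = matrix_from_rows(small_tree.tips, ["c1"], [[col[t]] for t in small_tree.tips])
        table = map_losses(m, small_tree)
        assert table.losses["D"] == 1
        assert table.total_losses == 1

    def test_unknown_does_not_generate_event(self, small_tree):
        col = {t: 1 for t in small_tree.tips}
        col["D"] = UNKNOWN
        m = matrix_from_rows(small_tree.tips, ["c1"], [[col[t]] for t in small_tree.tips])
        table = map_losses(m, small_tree)
        assert table.total_losses == 0

    def test_unknown_does_not_rescue_presence(self, small_tree):
        # D unknown, E absent: the DE node must be absent -> one loss at DE
        col = {"A": 1, "B": 1, "C": 1, "D": UNKNOWN, "E": ABSENT}
        m = matrix_from_rows(small_tree.tips, ["c1"], [[col[t]] for t in small_tree.tips])
        table = map_losses(m, small_tree)
        assert table.losses["DE"] == 1
        assert table.total_losses == 1

    def test_gain_at_mrca_of_possessing_tips(self, small_tree):
        col = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}
        m = matrix_from_rows(small_tree.tips, ["c1"], [[col[t]] for t in small_tree.tips])
        polarity = PolaritySpec(overrides={"c1": "absent"})
        table = map_losses(m, small_tree, polarity)
        assert table.gains["CDE"] == 1
        assert table.total_losses == 0

    def test_gain_with_later_loss(self, small_tree):
        col = {"A": 0, "B": 0, "C": 1, "D": 0, "E": 1}
        m = matrix_from_rows(small_tree.tips, ["c1"], [[col[t]] for t in small_tree.tips])
        polarity = PolaritySpec(overrides={"c1": "absent"})
        table = map_losses(m, small_tree, polarity)
        assert table.gains["CDE"] == 1
        assert table.losses["D"] == 1

    def test_ancestrally_absent_no_possessing_tips(self, small_tree, caplog):
        m = matrix_from_rows(small_tree.tips, ["c1"], [[0]] * 5)
        polarity = PolaritySpec(overrides={"c1": "absent"})
        with caplog.at_level("WARNING"):
            table = map_losses(m, small_tree, polarity)
        assert table.total_losses == 0 and table.total_gains == 0
        assert any("no possessing tips" in r.message for r in caplog.records)

    def test_taxon_not_in_tree(self, small_tree):
        m = matrix_from_rows(["ZZZ"], ["c1"], [[1]])
        with pytest.raises(DolloError, match="ZZZ"):
            reconstruct_states(m, small_tree)


class TestOutgroupPolarity:
    def test_outgroup_present_polarizes_present(self, syndermatan_tree):
        taxa = syndermatan_tree.tips
        col = {t: 0 for t in taxa}
        col["Outgroup"] = 1
        m = matrix_from_rows(taxa, ["c1"], [[col[t]] for t in taxa])
        polarity = PolaritySpec(mode="outgroup", outgroups=("Outgroup",))
        table = map_losses(m, syndermatan_tree, polarity)
        # ancestrally present, absent in all five ingroup tips -> one loss
        assert table.losses["Syndermata"] == 1

    def test_disagreeing_outgroups_skip_character(self):
        from lossmap.tree import PhyloTree

        tree = PhyloTree.from_newick("(O1,(O2,(A,B)In)Mid)Root;")
        taxa = tree.tips
        col = {"O1": 1, "O2": 0, "A": 0, "B": 0}
        m = matrix_from_rows(taxa, ["c1"], [[col[t]] for t in taxa])
        polarity = PolaritySpec(mode="outgroup", outgroups=("O1", "O2"))
        recon = reconstruct_states(m, tree, polarity)
        assert recon.skipped == ["c1"]
        assert count_branch_events(recon).total_losses == 0

    def test_missing_outgroup_errors(self, small_tree):
        m = matrix_from_rows(small_tree.tips, ["c1"], [[1]] * 5)
        polarity = PolaritySpec(mode="outgroup", outgroups=("NOPE",))
        with pytest.raises(DolloError, match="NOPE"):
            reconstruct_states(m, small_tree, polarity)


class TestCumulativeTipLosses:
    def test_all_present_zero(self, small_tree):
        m = matrix_from_rows(small_tree.tips, ["c1"], [[1]] * 5)
        table = map_losses(m, small_tree)
        assert all(cumulative_tip_losses(table, t) == 0 for t in small_tree.tips)

    def test_path_sum(self, syndermatan_tree):
        taxa = syndermatan_tree.tips
        cols = {
            "stem": [0 if t != "Outgroup" else 1 for t in taxa],
            "para": [0 if t in ("Seisonidea", "Acanthocephala") else 1 for t in taxa],
            "term": [0 if t == "Acanthocephala" else 1 for t in taxa],
        }
        m = CharacterMatrix(
            taxa, list(cols), np.array(list(zip(*cols.values())), dtype=np.int8)
        )
        table = map_losses(m, syndermatan_tree)
        assert cumulative_tip_losses(table, "Acanthocephala") == 3
        assert cumulative_tip_losses(table, "Seisonidea") == 2
        assert cumulative_tip_losses(table, "Monogononta") == 1
        assert cumulative_tip_losses(table, "Outgroup") == 0

    def test_unknown_tip_errors(self, small_tree):
        m = matrix_from_rows(small_tree.tips, ["c1"], [[1]] * 5)
        table = map_losses(m, small_tree)
        with pytest.raises(DolloError):
            cumulative_tip_losses(table, "nope")

    def test_monotone_in_absences(self, small_tree):
        rng = np.random.default_rng(5)
        values = rng.choice([0, 1], size=(5, 6), p=[0.3, 0.7]).astype(np.int8)
        m1 = CharacterMatrix(small_tree.tips, [f"c{j}" for j in range(6)], values)
        t1 = map_losses(m1, small_tree)
        # add one absence at tip D
        values2 = values.copy()
        d = small_tree.tips.index("D")
        present_cols = np.nonzero(values2[d] == 1)[0]
        values2[d, present_cols[0]] = 0
        m2 = CharacterMatrix(small_tree.tips, [f"c{j}" for j in range(6)], values2)
        t2 = map_losses(m2, small_tree)
        assert cumulative_tip_losses(t2, "D") >= cumulative_tip_losses(t1, "D")


class TestSharedMissing:
    def test_hand_built_intersection(self):
        m = matrix_from_rows(
            ["a", "b", "c"],
            ["c1", "c2", "c3", "c4", "c5"],
            [
                [0, 0, 1, 0, 1],
                [0, 1, 0, 0, 1],
                [1, 0, 0, 0, 1],
            ],
        )
        assert shared_missing(m, ["a", "b"]) == ["c1", "c4"]
        assert shared_missing(m, ["a", "b", "c"]) == ["c4"]

    def test_all_present_empty(self, small_tree):
        m = matrix_from_rows(["a", "b"], ["c1"], [[1], [1]])
        assert shared_missing(m, ["a", "b"]) == []

    def test_empty_set_errors(self):
        m = matrix_from_rows(["a"], ["c1"], [[1]])
        with pytest.raises(DolloError):
            shared_missing(m, [])

    def test_unknown_not_counted_as_absent(self):
        m = matrix_from_rows(["a", "b"], ["c1"], [[0], [-1]])
        assert shared_missing(m, ["a", "b"]) == []


class TestBruteForceOracle:
    """Total event counts equal exhaustive minimal placement."""

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(2024)
        n_cases = 0
        while n_cases < 520:
            n_tips = int(rng.integers(3, 7))
            tree = random_tree(rng, n_tips)
            n_chars = int(rng.integers(1, 9))
            values = rng.choice(
                [PRESENT, ABSENT, UNKNOWN], size=(n_tips, n_chars),
                p=[0.5, 0.35, 0.15],
            ).astype(np.int8)
            m = CharacterMatrix(tree.tips, [f"c{j}" for j in range(n_chars)], values)
            recon = reconstruct_states(m, tree)
            for j, char in enumerate(m.characters):
                absent = {t for i, t in enumerate(tree.tips) if values[i, j] == ABSENT}
                present = {t for i, t in enumerate(tree.tips) if values[i, j] == PRESENT}
                expected = brute_force_min_losses(tree, absent, present)
                assert len(recon.loss_branches[char]) == expected, (
                    tree.to_newick(), values[:, j].tolist()
                )
                n_cases += 1

    def test_gain_placement_minimal(self):
        # single-gain: MRCA placement plus Dollo losses below is minimal
        # over all admissible gain nodes
        rng = np.random.default_rng(7)
        for _ in range(120):
            n_tips = int(rng.integers(3, 7))
            tree = random_tree(rng, n_tips)
            values = rng.choice([PRESENT, ABSENT], size=(n_tips, 1), p=[0.5, 0.5])
            if not (values == PRESENT).any():
                continue
            m = CharacterMatrix(tree.tips, ["c1"], values.astype(np.int8))
            polarity = PolaritySpec(overrides={"c1": "absent"})
            recon = reconstruct_states(m, tree, polarity)
            impl = 1 + len(recon.loss_branches["c1"])
            present = {t for i, t in enumerate(tree.tips) if values[i, 0] == PRESENT}
            absent = {t for i, t in enumerate(tree.tips) if values[i, 0] == ABSENT}
            best = None
            for node in [n.name for n in tree.preorder()]:
                leaves = set(tree.leaves_under(node))
                if not present <= leaves:
                    continue
                sub_absent = absent & leaves
                # oracle restricted to the gained subtree
                k = _min_losses_in_subtree(tree, node, sub_absent, present)
                total = 1 + k
                best = total if best is None else min(best, total)
            assert impl == best


def _min_losses_in_subtree(tree, root_name, absent, present):
    import itertools

    def under(node, tip):
        return node == tip or tree.is_strict_ancestor(node, tip)

    sub_nodes = [
        n.name for n in tree.preorder()
        if n.name != root_name and tree.is_strict_ancestor(root_name, n.name)
    ]
    for k in range(len(sub_nodes) + 1):
        for combo in itertools.combinations(sub_nodes, k):
            if any(under(c, t) for c in combo for t in present):
                continue
            if all(any(under(c, t) for c in combo) for t in absent):
                return k
    raise AssertionError("unreachable")


class TestBranchOrdering:
    def test_preorder_deterministic(self, syndermatan_tree):
        m = matrix_from_rows(
            syndermatan_tree.tips, ["c1"], [[1]] * len(syndermatan_tree.tips)
        )
        table = map_losses(m, syndermatan_tree)
        expected = ["Root"] + [c for _p, c in syndermatan_tree.branches()]
        assert table.branches == expected
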