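"""The levelwise miner: instance enumeration, tree construction, metrics."""

import numpy as np
import pytest

from tirpscope import (
    STI,
    STIDatabase,
    TIRP,
    TemporalRelation as TR,
    Transaction,
    MiningConfig,
    compute_metrics,
    find_instances,
    mine_tree,
)
from tirpscope.io_formats import canonical_json, tree_to_document

from oracles import exhaustive_frequent_patterns, random_small_db

AB = TIRP(("A", "B"), (TR.BEFORE,))


class TestFindInstances:
    def test_single_pair(self):
        txn = Transaction("t", (STI("A", 1, 2), STI("B", 3, 4)))
        assert len(find_instances(AB, txn, max_gap=20)) == 1

    def test_hand_enumerated_three_instances(self):
        txn = Transaction(
            "t",
            (STI("A", 1, 2), STI("A", 10, 11), STI("B", 3, 4), STI("B", 12, 13)),
        )
        insts = find_instances(AB, txn, max_gap=20)
        spans = sorted((i.stis[0].start, i.stis[1].start) for i in insts)
        assert spans == [(1, 3), (1, 12), (10, 12)]  # HS = 3

    def test_no_matching_symbol(self):
        txn = Transaction("t", (STI("A", 1, 2), STI("C", 3, 4)))
        assert find_instances(AB, txn, max_gap=20) == []

    def test_gap_excludes_distant_pairs(self):
        txn = Transaction("t", (STI("A", 1, 2), STI("B", 50, 51)))
        assert find_instances(AB, txn, max_gap=20) == []


class TestMineTree:
    def test_three_identical_transactions(self):
        stis = (STI("A", 1, 3), STI("B", 5, 7))
        db = STIDatabase([Transaction(f"t{i}", stis) for i in range(3)])
        tree = mine_tree(db, MiningConfig(min_vs=2, max_gap=20))
        patterns = {str(n.tirp) for n in tree}
        assert patterns == {"<A>", "<B>", "<A b B>"}
        assert all(n.metrics.vs == 3 for n in tree)

    def test_empty_database(self):
        tree = mine_tree(STIDatabase([]), MiningConfig(min_vs=1, max_gap=20))
        assert tree.n == 0

    def test_single_transaction_single_sti(self):
        db = STIDatabase([Transaction("t", (STI("A", 1, 3),))])
        tree = mine_tree(db, MiningConfig(min_vs=1, max_gap=20))
        assert tree.n == 1
        node = next(iter(tree))
        assert (node.metrics.vs, node.metrics.mhs) == (1, 1.0)

    def test_threshold_above_db_size_gives_empty_tree(self):
        db = STIDatabase([Transaction("t", (STI("A", 1, 3),))])
        tree = mine_tree(db, MiningConfig(min_vs=5, max_gap=20))
        assert tree.n == 0

    def test_fractional_min_vs_uses_ceiling(self):
        assert MiningConfig(min_vs=0.4, max_gap=20).resolve_min_vs(5) == 2
        assert MiningConfig(min_vs=0.5, max_gap=20).resolve_min_vs(5) == 3

    def test_max_size_caps_lmax(self):
        stis = (STI("A", 1, 2), STI("B", 4, 5), STI("C", 8, 9))
        db = STIDatabase([Transaction("t", stis)])
        tree = mine_tree(db, MiningConfig(min_vs=1, max_gap=20, max_size=2))
        assert tree.lmax == 2

    def test_determinism_byte_identical(self):
        rng = np.random.default_rng(5)
        db = random_small_db(rng)
        cfg = MiningConfig(min_vs=1, max_gap=10)
        doc1 = canonical_json(tree_to_document(mine_tree(db, cfg)))
        doc2 = canonical_json(tree_to_document(mine_tree(db, cfg)))
        assert doc1 == doc2

    def test_anti_monotone_vs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            db = random_small_db(rng)
            tree = mine_tree(db, MiningConfig(min_vs=1, max_gap=8))
            for node in tree:
                if node.parent is not None:
                    assert node.metrics.vs <= tree[node.parent].metrics.vs

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        """Pattern set, VS and per-transaction HS equal brute-force subset
        enumeration on tiny random databases."""
        rng = np.random.default_rng(seed)
        db = random_small_db(rng, max_txns=4, max_stis=8)
        min_vs = int(rng.integers(1, 4))
        gap = float(rng.integers(2, 12))
        tree = mine_tree(db, MiningConfig(min_vs=min_vs, max_gap=gap))
        mined = {
            (n.tirp.symbols, n.tirp.relations): {
                tid: len(insts) for tid, insts in n.instances.items()
            }
            for n in tree
        }
        assert mined == exhaustive_frequent_patterns(db, min_vs, gap)


class TestMetrics:
    def test_hand_enumerated_mhs_and_mmd(self, metric_example_db):
        tree = mine_tree(metric_example_db, MiningConfig(min_vs=1, max_gap=20))
        node = tree.find(AB)
        assert node is not None
        assert node.metrics.mhs == pytest.approx(2.0)  # (3 + 1) / 2
        assert node.metrics.mmd == pytest.approx(5.0)  # (mean{3,12,3} + 4) / 2
        assert node.metrics.vs == 2
        assert node.metrics.relative_vs == pytest.approx(1.0)

    def test_single_instance_duration_spans_min_start_to_max_end(self):
        db = STIDatabase([Transaction("t", (STI("A", 1, 2), STI("B", 5, 7)))])
        tree = mine_tree(db, MiningConfig(min_vs=1, max_gap=20))
        assert tree.find(AB).metrics.mmd == pytest.approx(6.0)  # 7 - 1

    def test_recompute_without_stored_instances(self, metric_example_db):
        tree = mine_tree(metric_example_db, MiningConfig(min_vs=1, max_gap=20),
                         keep_instances=False)
        node = tree.find(AB)
        assert node.instances is None
        m = compute_metrics(node, metric_example_db, max_gap=20)
        assert (m.mhs, m.mmd) == (pytest.approx(2.0), pytest.approx(5.0))

    def test_all_hs_one_gives_mhs_one(self):
        db = STIDatabase(
            [Transaction(f"t{i}", (STI("A", 1, 2), STI("B", 4, 5))) for i in range(4)]
        )
        tree = mine_tree(db, MiningConfig(min_vs=4, max_gap=20))
        assert tree.find(AB).metrics.mhs == 1.0


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        MiningConfig(min_vs=0)
    with pytest.raises(ValueError):
        MiningConfig(min_vs=0.5, max_gap=-1)
    with pytest.raises(ValueError):
        MiningConfig(min_vs=0.5, epsilon=-0.1)
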