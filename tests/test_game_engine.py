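import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from crowdgene import (
    Board,
    CVConfig,
    ExpressionDataset,
    bot_select,
    fit_display_tree,
    generate_boards,
    play_game,
    rank_boards_by_difficulty,
    score_hand,
)
from crowdgene.game_engine import (
    GameError,
    GameState,
    generate_balanced_boards,
    read_boards,
    read_game_records,
    write_boards,
    write_game_records,
)

from conftest import make_perfect_gene_ds


def first_available_policy(state, rng):
    return sorted(state.remaining)[0]


# ---------------------------------------------------------------------------
# Wrapper scoring

class TestScoreHand:
    def test_perfect_gene_scores_one(self, fast_cv):
        ds, perfect = make_perfect_gene_ds()
        assert score_hand([perfect], ds, fast_cv) == 1.0

    def test_sklearn_tree_agrees_on_separable_gene(self, fast_cv):
        # independent learner cross-check: a perfectly separating gene is
        # classified without error by any reasonable tree
        ds, perfect = make_perfect_gene_ds()
        X = ds.gene_rows([perfect]).T
        clf = DecisionTreeClassifier(max_depth=3, random_state=0).fit(X, ds.labels)
        assert clf.score(X, ds.labels) == 1.0
        assert score_hand([perfect], ds, fast_cv) == 1.0

    def test_constant_genes_score_near_majority_rate(self, fast_cv):
        n = 30
        ds = ExpressionDataset(
            ["C1", "C2"], [f"s{i}" for i in range(n)],
            np.ones((2, n)), np.array([0, 1] * (n // 2)),
        )
        assert abs(score_hand(["C1", "C2"], ds, fast_cv) - 0.5) <= 0.1

    def test_permutation_invariance(self, planted_ds, fast_cv):
        ds, info = planted_ds
        hand = sorted(info)[:3] + [ds.gene_ids[40]]
        base = score_hand(hand, ds, fast_cv, use_cache=False)
        for perm in itertools.permutations(hand):
            assert score_hand(list(perm), ds, fast_cv, use_cache=False) == base

    def test_score_in_unit_interval(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        rng = np.random.default_rng(0)
        for _ in range(10):
            hand = list(rng.choice(ds.gene_ids, size=3, replace=False))
            assert 0.0 <= score_hand(hand, ds, fast_cv) <= 1.0

    def test_unknown_gene_rejected(self, tiny_ds, fast_cv):
        with pytest.raises(KeyError, match="NOPE"):
            score_hand(["NOPE"], tiny_ds, fast_cv)

    def test_matches_brute_force_depth1_cv_oracle(self):
        # 12-sample fixture, 2 genes, 3-fold stratified CV, depth-1 trees:
        # exhaustively enumerate every threshold split per fold
        values = np.array([
            [1, 2, 2, 3, 4, 5, 5, 6, 7, 8, 8, 9],
            [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8],
        ], dtype=float)
        labels = np.array([0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1])
        ds = ExpressionDataset(["GA", "GB"], [f"s{i}" for i in range(12)],
                               values, labels)
        cv = CVConfig(n_folds=3, tree_max_depth=1, tree_min_leaf=1, seed=7)

        def majority(y):
            ones = int(y.sum())
            return 1 if ones > len(y) - ones else 0

        def gini_split(y_left, y_right):
            out = 0.0
            for part in (y_left, y_right):
                p = part.mean()
                out += len(part) * 2.0 * p * (1.0 - p)
            return out / (len(y_left) + len(y_right))

        X = values.T
        correct = total = 0
        folds = StratifiedKFold(3, shuffle=True, random_state=cv.seed)
        for train_idx, test_idx in folds.split(X, labels):
            Xtr, ytr = X[train_idx], labels[train_idx]
            p = ytr.mean()
            best = (2.0 * p * (1.0 - p), None)  # parent gini, leaf
            for j in range(2):
                xs = np.unique(Xtr[:, j])
                for lo, hi in zip(xs[:-1], xs[1:]):
                    thr = (lo + hi) / 2.0
                    mask = Xtr[:, j] <= thr
                    g = gini_split(ytr[mask], ytr[~mask])
                    if g < best[0] - 1e-12:
                        best = (g, (j, thr, majority(ytr[mask]),
                                    majority(ytr[~mask])))
            Xte, yte = X[test_idx], labels[test_idx]
            if best[1] is None:
                pred = np.full(len(yte), majority(ytr))
            else:
                j, thr, left_cls, right_cls = best[1]
                pred = np.where(Xte[:, j] <= thr, left_cls, right_cls)
            correct += int((pred == yte).sum())
            total += len(yte)
        assert score_hand(["GA", "GB"], ds, cv) == correct / total


class TestDisplayTree:
    def test_perfect_gene_gives_depth_one_pure_tree(self, fast_cv):
        ds, perfect = make_perfect_gene_ds()
        tree = fit_display_tree([perfect], ds, fast_cv)
        root = tree.root
        assert not root.is_leaf and root.left.is_leaf and root.right.is_leaf
        assert root.left.class_counts[1] == 0  # low side pure class 0
        assert root.right.class_counts[0] == 0
        assert "PERFECT" in tree.to_text(tree.feature_names_)
        assert "digraph" in tree.to_dot(tree.feature_names_)

    def test_constant_genes_give_single_majority_leaf(self, fast_cv):
        ds = ExpressionDataset(
            ["C1"], [f"s{i}" for i in range(12)], np.ones((1, 12)),
            np.array([0] * 5 + [1] * 7),
        )
        tree = fit_display_tree(["C1"], ds, fast_cv)
        assert tree.root.is_leaf
        assert tree.root.prediction == 1

    def test_xor_structure_uses_both_genes(self):
        # slightly unbalanced XOR so the greedy first split has gain
        cells = [((0, 0), 0, 4), ((0, 1), 1, 4), ((1, 0), 1, 3), ((1, 1), 0, 4)]
        cols, labels = [], []
        for (a, b), y, count in cells:
            cols += [(a, b)] * count
            labels += [y] * count
        values = np.array(cols, dtype=float).T
        ds = ExpressionDataset(
            ["X1", "X2"], [f"s{i}" for i in range(len(labels))],
            values, np.array(labels),
        )
        cv = CVConfig(n_folds=3, tree_max_depth=2, tree_min_leaf=1)
        tree = fit_display_tree(["X1", "X2"], ds, cv)
        assert tree.internal_features() == {0, 1}
        X = values.T
        assert tree.accuracy(X, np.array(labels)) == 1.0


# ---------------------------------------------------------------------------
# Bot and play

class TestBot:
    def _state_bot_to_move(self, board, human_picks, remaining):
        return GameState(board=board, human_hand=list(human_picks),
                         bot_hand=[], remaining=list(remaining),
                         turn_index=1)

    def test_forced_move(self, fast_cv):
        ds, perfect = make_perfect_gene_ds()
        board = Board(1, ds.gene_ids[:6])
        state = self._state_bot_to_move(board, [ds.gene_ids[6]],
                                        [ds.gene_ids[1]])
        assert bot_select(state, ds, fast_cv, 0) == ds.gene_ids[1]

    def test_bot_takes_perfectly_separating_gene(self, fast_cv):
        ds, perfect = make_perfect_gene_ds()
        board = Board(1, ds.gene_ids)
        state = self._state_bot_to_move(board, [ds.gene_ids[3]],
                                        [g for g in ds.gene_ids
                                         if g not in {perfect, ds.gene_ids[3]}]
                                        + [perfect])
        assert bot_select(state, ds, fast_cv, 0) == perfect

    def test_bot_choice_is_marginally_optimal(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        board = Board(1, ds.gene_ids[:10])
        state = self._state_bot_to_move(board, [ds.gene_ids[0]],
                                        ds.gene_ids[1:10])
        pick = bot_select(state, ds, fast_cv, 3)
        pick_score = score_hand([pick], ds, fast_cv)
        for g in state.remaining:
            assert pick_score >= score_hand([g], ds, fast_cv)

    def test_tie_break_uniform_over_identical_genes(self, fast_cv):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        values = np.vstack([base, base, rng.normal(size=20) * 0.01])
        ds = ExpressionDataset(["TWIN_A", "TWIN_B", "DUD"],
                               [f"s{i}" for i in range(20)],
                               values, np.array([0, 1] * 10))
        board = Board(1, ["TWIN_A", "TWIN_B", "DUD"])
        seen = set()
        for seed in range(100):
            state = self._state_bot_to_move(board, ["DUD"],
                                            ["TWIN_A", "TWIN_B"])
            seen.add(bot_select(state, ds, fast_cv, seed))
        assert seen == {"TWIN_A", "TWIN_B"}

    def test_out_of_turn_rejected(self, tiny_ds, fast_cv):
        board = Board(1, tiny_ds.gene_ids)
        state = GameState(board=board, remaining=list(tiny_ds.gene_ids))
        with pytest.raises(GameError, match="turn"):
            bot_select(state, tiny_ds, fast_cv, 0)


class TestPlayGame:
    def test_conservation_of_cards(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        board = Board(1, ds.gene_ids[:25])
        rec = play_game(board, first_available_policy, ds, fast_cv, seed=1)
        picked = rec.human_selections + rec.bot_selections
        assert len(rec.human_selections) == len(rec.bot_selections) == 5
        assert len(set(picked)) == 10
        assert set(picked) <= set(board.genes)

    def test_determinism(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        board = Board(1, ds.gene_ids[:25])
        a = play_game(board, first_available_policy, ds, fast_cv, seed=9)
        b = play_game(board, first_available_policy, ds, fast_cv, seed=9)
        assert a == b

    def test_informed_human_usually_not_beaten(self, fast_cv):
        # planted genes carry all the signal; the rest are constant, so
        # holding more planted genes decides the game
        rng = np.random.default_rng(21)
        n = 60
        labels = np.array([0, 1] * (n // 2))
        planted = [f"INF{i}" for i in range(5)]
        values = np.zeros((25, n))
        for i in range(5):
            values[i] = rng.normal(0, 1, n) + 2.5 * labels
        genes = planted + [f"C{i:02d}" for i in range(20)]
        ds = ExpressionDataset(genes, [f"s{j}" for j in range(n)],
                               values, labels)
        board = Board(1, genes)

        def informed(state, _rng):
            for g in planted:
                if g in state.remaining:
                    return g
            return sorted(state.remaining)[0]

        wins = 0
        for s in range(20):
            rec = play_game(board, informed, ds, fast_cv, seed=s)
            wins += rec.human_score >= rec.bot_score
        assert wins > 10

    def test_policy_returning_taken_gene_rejected(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        board = Board(1, ds.gene_ids[:25])
        with pytest.raises(GameError, match="not available"):
            play_game(board, lambda s, r: board.genes[0] if s.turn_index < 2
                      else board.genes[0], ds, fast_cv, seed=0)

    def test_record_jsonl_round_trip(self, planted_ds, fast_cv, tmp_path):
        ds, _ = planted_ds
        board = Board(1, ds.gene_ids[:25])
        recs = [play_game(board, first_available_policy, ds, fast_cv, seed=s,
                          player_id=f"p{s}") for s in range(2)]
        path = tmp_path / "games.jsonl"
        write_game_records(recs, path)
        assert read_game_records(path) == recs


# ---------------------------------------------------------------------------
# Boards

class TestBoards:
    def test_shapes_and_distinctness(self, planted_ds):
        ds, _ = planted_ds
        boards = generate_boards(ds, 10, seed=0)
        assert len(boards) == 10
        for b in boards:
            assert len(b.genes) == 25
            assert len(set(b.genes)) == 25

    def test_degenerate_weights_fix_the_board(self, planted_ds):
        ds, _ = planted_ds
        chosen = set(ds.gene_ids[:25])
        weights = {g: (1.0 if g in chosen else 0.0) for g in ds.gene_ids}
        boards = generate_boards(ds, 5, candidate_weighting=weights, seed=1)
        for b in boards:
            assert set(b.genes) == chosen

    def test_uniform_weights_give_uniform_appearances(self):
        rng = np.random.default_rng(0)
        ds = ExpressionDataset(
            [f"g{i}" for i in range(100)], [f"s{j}" for j in range(10)],
            rng.normal(size=(100, 10)), np.array([0, 1] * 5),
        )
        boards = generate_boards(ds, 10_000, seed=5)
        counts = {g: 0 for g in ds.gene_ids}
        for b in boards:
            for g in b.genes:
                counts[g] += 1
        observed = np.array([counts[g] for g in ds.gene_ids])
        assert stats.chisquare(observed).pvalue > 0.001

    def test_too_few_genes_rejected(self, tiny_ds):
        with pytest.raises(GameError):
            generate_boards(tiny_ds, 1)

    def test_balanced_boards_equalise_coverage(self, planted_ds):
        ds, _ = planted_ds
        boards = generate_balanced_boards(ds, 12, seed=3)
        counts = {g: 0 for g in ds.gene_ids}
        for b in boards:
            assert len(set(b.genes)) == 25
            for g in b.genes:
                counts[g] += 1
        values = np.array(list(counts.values()))
        assert values.max() - values.min() <= 1

    def test_difficulty_ranking_orders_and_renumbers(self, planted_ds, fast_cv):
        ds, info = planted_ds
        informative_board = Board(1, sorted(info)
                                  + [g for g in ds.gene_ids
                                     if g not in info][:20])
        noise_board = Board(2, [g for g in ds.gene_ids if g not in info][:25])
        ranked = rank_boards_by_difficulty([noise_board, informative_board],
                                           ds, fast_cv)
        assert [b.board_id for b in ranked] == [1, 2]
        assert set(ranked[0].genes) == set(informative_board.genes)
        assert ranked[0].difficulty_score >= ranked[1].difficulty_score

    def test_difficulty_tie_preserves_original_order(self, planted_ds, fast_cv):
        ds, _ = planted_ds
        genes = ds.gene_ids[:25]
        boards = [Board(i + 1, list(genes)) for i in range(3)]
        ranked = rank_boards_by_difficulty(boards, ds, fast_cv)
        assert [b.board_id for b in ranked] == [1, 2, 3]
        assert all(set(b.genes) == set(genes) for b in ranked)

    def test_board_tsv_round_trip(self, planted_ds, tmp_path):
        ds, _ = planted_ds
        boards = generate_boards(ds, 3, seed=2)
        path = tmp_path / "boards.tsv"
        write_boards(boards, path)
        loaded = read_boards(path)
        assert [b.genes for b in loaded] == [b.genes for b in boards]
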