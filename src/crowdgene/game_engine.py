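"""Boards, turn-based play, wrapper cross-validation scoring, and the bot.

A board is 25 genes; two players (human first) alternate picking cards
until each holds 5. A hand is scored by the cross-validated accuracy of a
decision-tree classifier trained on just those genes — a wrapper feature
set evaluation. The automated opponent plays greedy one-step lookahead on
that wrapper score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .expression_data import ExpressionDataset
from .tree import DecisionTree

BOARD_SIZE = 25
HAND_SIZE = 5


class GameError(ValueError):
    """Illegal board, hand, move, or scoring request."""


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and tree settings for wrapper scoring.

    Accuracy is pooled correct/total across folds (averaged over repeats).
    Fold assignment is a deterministic function of ``seed``.
    """

    n_folds: int = 5
    n_repeats: int = 1
    stratified: bool = True
    tree_max_depth: Optional[int] = 3
    tree_min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise GameError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise GameError("n_repeats must be >= 1")
        if self.tree_min_leaf < 1:
            raise GameError("tree_min_leaf must be >= 1")


@dataclass
class Board:
    """A playing field of exactly 25 distinct genes."""

    board_id: int
    genes: list[str]
    difficulty_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.board_id < 1:
            raise GameError("board_id must be >= 1")
        if len(self.genes) != len(set(self.genes)):
            raise GameError("board genes must be distinct")

    def validate_against(self, ds: ExpressionDataset, size: int = BOARD_SIZE) -> None:
        if len(self.genes) != size:
            raise GameError(f"board must hold exactly {size} genes")
        for g in self.genes:
            ds.gene_index(g)


@dataclass
class GameState:
    """Mid-game snapshot; human moves on even turn indices."""

    board: Board
    human_hand: list[str] = field(default_factory=list)
    bot_hand: list[str] = field(default_factory=list)
    remaining: list[str] = field(default_factory=list)
    turn_index: int = 0
    human_score: float = 0.0
    bot_score: float = 0.0

    @property
    def human_to_move(self) -> bool:
        return self.turn_index % 2 == 0

    def take(self, gene: str, by_human: bool) -> None:
        if by_human != self.human_to_move:
            raise GameError("move out of turn")
        if gene not in self.remaining:
            raise GameError(f"gene {gene!r} is not available on the board")
        self.remaining.remove(gene)
        (self.human_hand if by_human else self.bot_hand).append(gene)
        self.turn_index += 1


@dataclass
class GameRecord:
    """Full trace of one completed game."""

    player_id: str
    board_id: int
    human_selections: list[str]
    bot_selections: list[str]
    human_score: float
    bot_score: float
    human_won: bool
    replay_index: int = 0

    JSONL_KEYS = (
        "player_id", "board_id", "human_selections", "bot_selections",
        "human_score", "bot_score", "human_won", "replay_index",
    )

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in self.JSONL_KEYS})

    @classmethod
    def from_json(cls, line: str) -> "GameRecord":
        d = json.loads(line)
        return cls(**{k: d[k] for k in cls.JSONL_KEYS})


def write_game_records(records: Iterable[GameRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_game_records(path: str | Path) -> list[GameRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(GameRecord.from_json(line))
    return out


def write_boards(boards: Iterable[Board], path: str | Path) -> None:
    """TSV: board_id, difficulty_score (or NA), comma-joined genes."""
    with open(path, "w") as fh:
        fh.write("board_id\tdifficulty_score\tgenes\n")
        for b in boards:
            diff = "NA" if b.difficulty_score is None else f"{b.difficulty_score:.6g}"
            fh.write(f"{b.board_id}\t{diff}\t{','.join(b.genes)}\n")


def read_boards(path: str | Path) -> list[Board]:
    boards = []
    for line in Path(path).read_text().splitlines()[1:]:
        bid, diff, genes = line.split("\t")
        boards.append(Board(
            board_id=int(bid),
            genes=genes.split(","),
            difficulty_score=None if diff == "NA" else float(diff),
        ))
    return boards


# ---------------------------------------------------------------------------
# Wrapper scoring

_score_cache: dict[tuple, float] = {}
_fold_cache: dict[tuple, list] = {}
_fingerprints: dict[int, str] = {}


def _ds_token(ds: ExpressionDataset) -> str:
    # fingerprint() hashes the full matrix; memoise per object identity
    token = _fingerprints.get(id(ds))
    if token is None:
        token = ds.fingerprint()
        _fingerprints[id(ds)] = token
    return token


def clear_score_cache() -> None:
    _score_cache.clear()
    _fold_cache.clear()
    _fingerprints.clear()


def _folds(y: np.ndarray, cv: CVConfig, repeat: int) -> list:
    """Fold (train, test) index pairs; fixed by (labels, cv, repeat)."""
    key = (y.tobytes(), cv, repeat)
    cached = _fold_cache.get(key)
    if cached is not None:
        return cached
    seed = cv.seed + repeat
    if cv.stratified:
        counts = np.bincount(y, minlength=2)
        if cv.n_folds > counts.min():
            raise GameError(
                "n_folds exceeds the smaller class size; stratified CV impossible"
            )
        splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(cv.n_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    _fold_cache[key] = folds
    return folds


def score_hand(
    genes: Sequence[str],
    ds: ExpressionDataset,
    cv: CVConfig,
    use_cache: bool = True,
) -> float:
    """Mean cross-validated accuracy of a tree restricted to ``genes``.

    Deterministic given (genes, ds, cv); invariant to gene order within
    the hand. Scores lie in [0, 1].
    """
    if len(genes) == 0:
        raise GameError("cannot score an empty hand")
    key = None
    if use_cache:
        key = (_ds_token(ds), cv, frozenset(genes))
        hit = _score_cache.get(key)
        if hit is not None:
            return hit
    ordered = sorted(set(genes), key=ds.gene_index)
    X = ds.gene_rows(ordered).T
    y = ds.labels
    if len(np.unique(y)) < 2:
        raise GameError("both classes must be present to score a hand")
    total_correct = 0
    total_n = 0
    for repeat in range(cv.n_repeats):
        for train_idx, test_idx in _folds(y, cv, repeat):
            y_train = y[train_idx]
            if not cv.stratified and len(np.unique(y_train)) < 2:
                raise GameError("a CV training fold contains a single class")
            tree = DecisionTree(cv.tree_max_depth, cv.tree_min_leaf)
            tree.fit(X[train_idx], y_train)
            total_correct += int((tree.predict(X[test_idx]) == y[test_idx]).sum())
            total_n += len(test_idx)
    score = total_correct / total_n
    if use_cache:
        _score_cache[key] = score
    return score


def fit_display_tree(
    genes: Sequence[str], ds: ExpressionDataset, cv: CVConfig
) -> DecisionTree:
    """The simplified tree shown to players: trained on all samples,
    restricted to the hand genes. Export with ``.to_text``/``.to_dot``
    using the returned tree's ``feature_names_`` attribute."""
    if len(genes) == 0:
        raise GameError("cannot fit a tree on an empty hand")
    ordered = sorted(set(genes), key=ds.gene_index)
    X = ds.gene_rows(ordered).T
    if len(np.unique(ds.labels)) < 2:
        raise GameError("both classes must be present")
    tree = DecisionTree(cv.tree_max_depth, cv.tree_min_leaf)
    tree.fit(X, ds.labels)
    tree.feature_names_ = list(ordered)  # type: ignore[attr-defined]
    return tree


# ---------------------------------------------------------------------------
# Play

Policy = Callable[[GameState, np.random.Generator], str]


def random_policy(state: GameState, rng: np.random.Generator) -> str:
    return str(rng.choice(sorted(state.remaining)))


def bot_select(
    state: GameState,
    ds: ExpressionDataset,
    cv: CVConfig,
    rng: np.random.Generator | int,
) -> str:
    """Greedy one-step lookahead: the remaining gene maximising the
    wrapper score of the bot's hand plus that gene; ties broken uniformly
    at random."""
    if state.human_to_move:
        raise GameError("bot_select called on the human's turn")
    if not state.remaining:
        raise GameError("no genes remain on the board")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    candidates = sorted(state.remaining)
    scores = np.array(
        [score_hand(state.bot_hand + [g], ds, cv) for g in candidates]
    )
    best = np.flatnonzero(scores == scores.max())
    return candidates[int(rng.choice(best))]


def play_game(
    board: Board,
    human_policy: Policy,
    ds: ExpressionDataset,
    cv: CVConfig,
    seed: int,
    player_id: str = "human",
    replay_index: int = 0,
    hand_size: int = HAND_SIZE,
    bot_wins_ties: bool = True,
) -> GameRecord:
    """Run one full game: alternating picks, human first, both hands
    scored at the end. Reproducible from ``seed``."""
    board.validate_against(ds, size=len(board.genes))
    rng = np.random.default_rng(seed)
    state = GameState(board=board, remaining=list(board.genes))
    for _ in range(hand_size):
        pick = human_policy(state, rng)
        state.take(pick, by_human=True)
        pick = bot_select(state, ds, cv, rng)
        state.take(pick, by_human=False)
    state.human_score = score_hand(state.human_hand, ds, cv)
    state.bot_score = score_hand(state.bot_hand, ds, cv)
    if bot_wins_ties:
        human_won = state.human_score > state.bot_score
    else:
        human_won = state.human_score >= state.bot_score
    return GameRecord(
        player_id=player_id,
        board_id=board.board_id,
        human_selections=list(state.human_hand),
        bot_selections=list(state.bot_hand),
        human_score=state.human_score,
        bot_score=state.bot_score,
        human_won=human_won,
        replay_index=replay_index,
    )


# ---------------------------------------------------------------------------
# Board generation and difficulty ordering

def generate_boards(
    ds: ExpressionDataset,
    n_boards: int,
    candidate_weighting: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    board_size: int = BOARD_SIZE,
) -> list[Board]:
    """Semirandom boards: ``board_size`` genes sampled without replacement,
    weighted by ``candidate_weighting`` (uniform if absent)."""
    if ds.n_genes < board_size:
        raise GameError(f"dataset has fewer than {board_size} genes")
    rng = np.random.default_rng(seed)
    genes = np.array(ds.gene_ids)
    if candidate_weighting is None:
        p = None
    else:
        w = np.array([float(candidate_weighting.get(g, 0.0)) for g in genes])
        if (w < 0).any():
            raise GameError("candidate weights must be nonnegative")
        if np.count_nonzero(w) < board_size:
            raise GameError("fewer positively weighted genes than the board size")
        p = w / w.sum()
    boards = []
    for i in range(n_boards):
        chosen = rng.choice(genes, size=board_size, replace=False, p=p)
        boards.append(Board(board_id=i + 1, genes=[str(g) for g in chosen]))
    return boards


def generate_balanced_boards(
    ds: ExpressionDataset,
    n_boards: int,
    seed: int = 0,
    board_size: int = BOARD_SIZE,
) -> list[Board]:
    """Semirandom boards balancing gene coverage: each board takes the
    currently least-covered genes with random tie-breaking, so appearance
    counts across the pool stay within one of each other. This mirrors a
    composition strategy aiming at broad and deep coverage of the pool."""
    if ds.n_genes < board_size:
        raise GameError(f"dataset has fewer than {board_size} genes")
    rng = np.random.default_rng(seed)
    genes = list(ds.gene_ids)
    coverage = {g: 0 for g in genes}
    boards = []
    for i in range(n_boards):
        keys = {g: rng.random() for g in genes}
        chosen = sorted(genes, key=lambda g: (coverage[g], keys[g]))[:board_size]
        for g in chosen:
            coverage[g] += 1
        boards.append(Board(board_id=i + 1, genes=list(chosen)))
    return boards


def rank_boards_by_difficulty(
    boards: Sequence[Board], ds: ExpressionDataset, cv: CVConfig
) -> list[Board]:
    """Score each full board with the wrapper and renumber 1..n in
    decreasing predictive power (most predictive = board 1, the easiest).
    Ties keep the original board_id order."""
    scored = []
    for b in boards:
        s = score_hand(b.genes, ds, cv)
        scored.append((b, s))
    scored.sort(key=lambda pair: (-pair[1], pair[0].board_id))
    out = []
    for new_id, (b, s) in enumerate(scored, start=1):
        out.append(Board(board_id=new_id, genes=list(b.genes), difficulty_score=s))
    return out
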