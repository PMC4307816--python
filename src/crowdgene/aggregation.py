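"""Vote aggregation: per-gene tallies, the selection-frequency statistic,
and empirical one-tailed P values from simulated random play.

For every gene g the crowd's games yield an occurrence count O(g) — the
number of counted games whose board contained g — and a selection count
S(g) — the number of those games in which the human picked g. The
aggregation statistic is the selection frequency

    F(g) = S(g) / O(g),

and its significance is the one-tailed probability of observing S or more
selections in O games under fully random play, estimated empirically from
a Monte-Carlo null. Only each player's first finished game per board is
counted (the first-five-cards filter), which stops replays from biasing
the tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .crowd_sim import PlayerProfile, assign_cohort
from .expression_data import ExpressionDataset
from .game_engine import (
    Board,
    CVConfig,
    GameRecord,
    GameState,
    bot_select,
    random_policy,
)


class AggregationError(ValueError):
    pass


@dataclass
class GeneTally:
    """Occurrences O, human selections S, frequency F = S/O for one gene."""

    gene: str
    O: int
    S: int
    p_value: Optional[float] = None

    @property
    def F(self) -> float:
        if self.O == 0:
            raise AggregationError(f"F undefined for gene {self.gene} with O=0")
        return self.S / self.O


@dataclass
class GeneTallyTable:
    """Tallies plus the cohort bookkeeping the ranking step reports."""

    tallies: list[GeneTally]
    n_games: int
    n_players: int
    cohort: str = "all"

    def __iter__(self):
        return iter(self.tallies)

    def __len__(self) -> int:
        return len(self.tallies)


CohortFilter = str | Callable[[PlayerProfile], bool]


def tally_games(
    records: Sequence[GameRecord],
    profiles: Sequence[PlayerProfile],
    boards: Mapping[int, Board] | Sequence[Board],
    cohort: CohortFilter = "all",
) -> GeneTallyTable:
    """Count O and S per gene over first finished games of one cohort.

    Only records with replay_index == 0 contribute. Every gene on the
    board of a counted game gains one occurrence; every human-selected
    gene gains one selection, so sum(S) = hand_size x games and
    sum(O) = board_size x games.
    """
    if not isinstance(boards, Mapping):
        boards = {b.board_id: b for b in boards}
    cohort_of = {p.player_id: assign_cohort(p) for p in profiles}
    if callable(cohort):
        by_profile = {p.player_id: cohort(p) for p in profiles}
        keep = lambda pid: by_profile[pid]
        name = "custom"
    elif cohort == "all":
        keep = lambda pid: True
        name = "all"
    else:
        keep = lambda pid: cohort_of[pid] == cohort
        name = cohort
    occurrences: dict[str, int] = {}
    selections: dict[str, int] = {}
    n_games = 0
    contributing: set[str] = set()
    for rec in records:
        if rec.player_id not in cohort_of:
            raise AggregationError(f"record references unknown player {rec.player_id!r}")
        if rec.replay_index != 0 or not keep(rec.player_id):
            continue
        board = boards[rec.board_id]
        n_games += 1
        contributing.add(rec.player_id)
        for g in board.genes:
            occurrences[g] = occurrences.get(g, 0) + 1
        for g in rec.human_selections:
            selections[g] = selections.get(g, 0) + 1
    tallies = [
        GeneTally(g, occurrences[g], selections.get(g, 0))
        for g in sorted(occurrences)
    ]
    return GeneTallyTable(tallies, n_games, len(contributing), name)


# ---------------------------------------------------------------------------
# Monte-Carlo null

@dataclass
class NullTable:
    """Per-O empirical distributions of S under random human play.

    hist[O] is an integer array of length O+1 whose entries count, over
    n_iter simulated replicates, how many replicates produced each value
    of S. Modes: 'symmetric_random' (both players pick uniformly, so a
    tracked gene lands in the human hand with probability
    hand_size/board_size per game) or 'vs_bot' (random human against the
    greedy opponent, played out in full on a reference dataset).
    """

    mode: str
    n_iter: int
    seed: int
    board_size: int = 25
    hand_size: int = 5
    hist: dict[int, np.ndarray] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode} n_iter={self.n_iter} seed={self.seed} "
                     f"board_size={self.board_size} hand_size={self.hand_size}\n")
            fh.write("O\tS\tcount\n")
            for O in sorted(self.hist):
                for S, c in enumerate(self.hist[O]):
                    if c:
                        fh.write(f"{O}\t{S}\t{int(c)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NullTable":
        lines = Path(path).read_text().splitlines()
        meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        table = cls(
            mode=meta["mode"], n_iter=int(meta["n_iter"]), seed=int(meta["seed"]),
            board_size=int(meta["board_size"]), hand_size=int(meta["hand_size"]),
        )
        for line in lines[2:]:
            O, S, c = (int(x) for x in line.split("\t"))
            table.hist.setdefault(O, np.zeros(O + 1, dtype=np.int64))[S] = c
        return table


def _simulate_vs_bot_probability(
    ds: ExpressionDataset, cv: CVConfig, board_size: int, hand_size: int,
    n_games: int, rng: np.random.Generator,
) -> np.ndarray:
    """Per-game outcomes (tracked gene human-selected?) for n_games fresh
    random boards containing a tracked gene, random human vs greedy bot."""
    genes = np.array(ds.gene_ids)
    outcomes = np.zeros(n_games, dtype=bool)
    for i in range(n_games):
        tracked = str(rng.choice(genes))
        others = [g for g in ds.gene_ids if g != tracked]
        fill = rng.choice(others, size=board_size - 1, replace=False)
        board = Board(board_id=1, genes=[tracked] + [str(g) for g in fill])
        state = GameState(board=board, remaining=list(board.genes))
        for _ in range(hand_size):
            state.take(random_policy(state, rng), by_human=True)
            state.take(bot_select(state, ds, cv, rng), by_human=False)
        outcomes[i] = tracked in state.human_hand
    return outcomes


def simulate_null(
    O_values: Iterable[int],
    game_shape: tuple[int, int] = (25, 5),
    mode: str = "symmetric_random",
    n_iter: int = 10_000,
    seed: int = 0,
    ds: Optional[ExpressionDataset] = None,
    cv: Optional[CVConfig] = None,
) -> NullTable:
    """Empirical null of S given O under random human play.

    For each O, each of ``n_iter`` replicates simulates O independent
    games and counts how many times the tracked gene was human-selected.
    In symmetric_random mode the tracked gene's membership in the human
    hand is a uniform hand_size-of-board_size event per game; in vs_bot
    mode each game is played out in full against the greedy opponent on
    ``ds`` (much slower; outcomes remain iid Bernoulli across games).
    """
    if n_iter < 1:
        raise AggregationError("n_iter must be >= 1")
    board_size, hand_size = game_shape
    rng = np.random.default_rng(seed)
    table = NullTable(mode=mode, n_iter=n_iter, seed=seed,
                      board_size=board_size, hand_size=hand_size)
    O_values = sorted(set(int(O) for O in O_values))
    if mode == "symmetric_random":
        p = hand_size / board_size
        for O in O_values:
            # each uniform draw is one simulated random game
            S = (rng.random((n_iter, O)) < p).sum(axis=1)
            table.hist[O] = np.bincount(S, minlength=O + 1).astype(np.int64)
    elif mode == "vs_bot":
        if ds is None or cv is None:
            raise AggregationError("vs_bot mode requires a dataset and CVConfig")
        for O in O_values:
            outcomes = _simulate_vs_bot_probability(
                ds, cv, board_size, hand_size, n_iter * O, rng
            ).reshape(n_iter, O)
            S = outcomes.sum(axis=1)
            table.hist[O] = np.bincount(S, minlength=O + 1).astype(np.int64)
    else:
        raise AggregationError(f"unknown null mode {mode!r}")
    return table


def empirical_p(S: int, O: int, null: NullTable) -> float:
    """Floored one-tailed empirical P: max(r, 1)/n_iter where r counts null
    replicates with S_null >= S. The smallest reportable value is
    1/n_iter; S = 0 always gives 1."""
    if O not in null.hist:
        raise AggregationError(f"O={O} not present in the null table")
    if not 0 <= S <= O:
        raise AggregationError("S must lie in [0, O]")
    r = int(null.hist[O][S:].sum())
    return max(r, 1) / null.n_iter


def exact_binomial_p(S: int, O: int, p_select: float) -> float:
    """Closed-form upper-tail P(X >= S), X ~ Binomial(O, p_select): the
    analytic counterpart of the symmetric-random null."""
    if not 0 <= p_select <= 1:
        raise AggregationError("p_select must lie in [0,1]")
    if not 0 <= S <= O:
        raise AggregationError("S must lie in [0, O]")
    return float(stats.binom.sf(S - 1, O, p_select))


# ---------------------------------------------------------------------------
# Ranking

@dataclass
class RankedGeneSet:
    """Genes passing the significance threshold, in rank order."""

    cohort: str
    alpha: float
    genes: list[GeneTally]
    n_games: int
    n_players: int

    def gene_symbols(self) -> list[str]:
        return [t.gene for t in self.genes]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tO\tS\tF\tp_value\trank\n")
            for rank, t in enumerate(self.genes, start=1):
                fh.write(f"{t.gene}\t{t.O}\t{t.S}\t{t.F:.6g}\t"
                         f"{t.p_value:.6g}\t{rank}\n")


def rank_and_threshold(
    table: GeneTallyTable, null: NullTable, alpha: float = 0.001
) -> RankedGeneSet:
    """Attach empirical P values, sort by (P asc, F desc, O desc, gene),
    and retain genes with P <= alpha."""
    if not table.tallies:
        raise AggregationError("tallies must be nonempty")
    scored = []
    for t in table.tallies:
        scored.append(GeneTally(t.gene, t.O, t.S, empirical_p(t.S, t.O, null)))
    scored.sort(key=lambda t: (t.p_value, -t.F, -t.O, t.gene))
    kept = [t for t in scored if t.p_value <= alpha]
    return RankedGeneSet(table.cohort, alpha, kept, table.n_games, table.n_players)
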