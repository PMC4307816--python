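"""Simulated player crowds under the game's board-lifecycle rules.

Players carry registration-survey answers from which analysis cohorts are
derived: 'expert' (PhD or MD plus self-declared cancer knowledge),
'inexperienced' (no advanced degree, no cancer knowledge, not a
biologist), and 'other'. Each synthetic agent selects genes with
probability proportional to exp(beta * relevance), so beta = 0 is uniform
random play and large beta approaches greedy play on the latent relevance
score.

Lifecycle rules: any open board may be chosen; a board closes once it has
been completed by the closure-threshold number of distinct players
(default 11); a player who wins a board never plays it again, while a
loser may replay it; games per player follow a truncated discrete power
law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .expression_data import ExpressionDataset
from .game_engine import Board, CVConfig, GameRecord, GameState, Policy, play_game

logger = logging.getLogger(__name__)

DEGREES = ("none", "undergraduate", "graduate", "phd", "md")
COHORTS = ("expert", "inexperienced", "other")


@dataclass
class PlayerProfile:
    """Registration survey answers plus the latent knowledge weight."""

    player_id: str
    degree: str = "none"
    is_biologist: Optional[bool] = None
    knows_cancer: Optional[bool] = None
    knowledge_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.degree not in DEGREES:
            raise ValueError(f"unknown degree {self.degree!r}")
        if self.knowledge_weight < 0:
            raise ValueError("knowledge_weight must be nonnegative")


def assign_cohort(profile: PlayerProfile) -> str:
    """Map survey answers to a cohort; missing answers never qualify for
    'expert' or 'inexperienced'."""
    if profile.degree in ("phd", "md") and profile.knows_cancer is True:
        return "expert"
    if (
        profile.degree in ("none", "undergraduate")
        and profile.knows_cancer is False
        and profile.is_biologist is False
    ):
        return "inexperienced"
    return "other"


def make_policy(
    profile: PlayerProfile, relevance: Mapping[str, float]
) -> Policy:
    """Softmax selection over the remaining board genes.

    P(pick g) ∝ exp(beta * relevance(g)); genes absent from the relevance
    map score 0. beta = 0 reduces to uniform random play.
    """
    beta = profile.knowledge_weight

    def policy(state: GameState, rng: np.random.Generator) -> str:
        genes = sorted(state.remaining)
        logits = np.array([beta * relevance.get(g, 0.0) for g in genes])
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        return genes[int(rng.choice(len(genes), p=probs))]

    return policy


@dataclass
class CrowdSpec:
    """Composition and behaviour of a synthetic crowd.

    games_exponent/games_cap define the truncated Zipf distribution of
    games per player. relevance is the latent per-gene score driving
    knowledgeable agents; beta_by_cohort maps each cohort to its softmax
    sharpness. missing_rate is the fraction of 'other'-cohort players
    with unanswered survey questions.
    """

    n_players: int
    cohort_mix: Mapping[str, float] = field(
        default_factory=lambda: {"expert": 0.1, "inexperienced": 0.5, "other": 0.4}
    )
    games_exponent: float = 1.8
    games_cap: int = 718
    relevance: Mapping[str, float] = field(default_factory=dict)
    beta_by_cohort: Mapping[str, float] = field(
        default_factory=lambda: {"expert": 5.0, "inexperienced": 0.0, "other": 1.0}
    )
    missing_rate: float = 0.054
    replay_prob: float = 0.3
    closure_threshold: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        total = sum(self.cohort_mix.get(c, 0.0) for c in COHORTS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cohort_mix must sum to 1")
        if self.games_cap < 1 or self.games_exponent <= 0:
            raise ValueError("invalid games-per-player distribution")
        if self.closure_threshold < 1:
            raise ValueError("closure_threshold must be >= 1")


def sample_games_per_player(
    n: int, exponent: float, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated Zipf draw: P(k) ∝ k^-exponent on 1..cap."""
    k = np.arange(1, cap + 1, dtype=float)
    pmf = k ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, cap + 1), size=n, p=pmf)


def _profile_for_cohort(
    player_id: str, cohort: str, beta: float, missing_rate: float,
    rng: np.random.Generator,
) -> PlayerProfile:
    if cohort == "expert":
        profile = PlayerProfile(
            player_id, degree=str(rng.choice(["phd", "md"])),
            is_biologist=bool(rng.random() < 0.8), knows_cancer=True,
            knowledge_weight=beta,
        )
    elif cohort == "inexperienced":
        profile = PlayerProfile(
            player_id, degree=str(rng.choice(["none", "undergraduate"])),
            is_biologist=False, knows_cancer=False, knowledge_weight=beta,
        )
    else:
        # graduate degree keeps the player 'other' regardless of the
        # remaining answers, so missingness cannot flip the cohort
        missing = rng.random() < missing_rate
        profile = PlayerProfile(
            player_id, degree="graduate",
            is_biologist=None if missing else bool(rng.random() < 0.5),
            knows_cancer=None if missing else bool(rng.random() < 0.5),
            knowledge_weight=beta,
        )
    assert assign_cohort(profile) == cohort
    return profile


def generate_players(crowd: CrowdSpec, rng: np.random.Generator) -> list[PlayerProfile]:
    mix = np.array([crowd.cohort_mix.get(c, 0.0) for c in COHORTS])
    cohorts = rng.choice(COHORTS, size=crowd.n_players, p=mix)
    players = []
    for i, cohort in enumerate(cohorts):
        beta = float(crowd.beta_by_cohort.get(str(cohort), 0.0))
        players.append(
            _profile_for_cohort(f"P{i + 1:05d}", str(cohort), beta,
                                crowd.missing_rate, rng)
        )
    return players


@dataclass
class RoundState:
    """Board lifecycle bookkeeping for one simulated round."""

    boards: dict[int, Board]
    completions: dict[int, set[str]] = field(default_factory=dict)
    closed: set[int] = field(default_factory=set)

    def open_boards(self) -> list[int]:
        return [bid for bid in sorted(self.boards) if bid not in self.closed]

    def record_completion(self, board_id: int, player_id: str,
                          threshold: int) -> None:
        done = self.completions.setdefault(board_id, set())
        done.add(player_id)
        if len(done) >= threshold:
            self.closed.add(board_id)


def simulate_crowd(
    boards: Sequence[Board],
    ds: ExpressionDataset,
    crowd: CrowdSpec,
    cv: CVConfig,
    hand_size: int = 5,
) -> tuple[list[GameRecord], list[PlayerProfile]]:
    """Play a crowd of heterogeneous agents through the board lifecycle.

    Players take turns round-robin, each consuming one game of their
    power-law budget per pass. Board choice is uniform over open boards
    the player has not yet won, except that a loser replays the same
    board with probability ``replay_prob`` while it stays open. The
    simulation stops cleanly when budgets are exhausted or no playable
    board remains.
    """
    if not boards:
        raise ValueError("boards must be nonempty")
    rng = np.random.default_rng(crowd.seed)
    players = generate_players(crowd, rng)
    policies = {p.player_id: make_policy(p, crowd.relevance) for p in players}
    budgets = dict(zip(
        [p.player_id for p in players],
        sample_games_per_player(len(players), crowd.games_exponent,
                                crowd.games_cap, rng),
    ))
    state = RoundState(boards={b.board_id: b for b in boards})
    won: set[tuple[str, int]] = set()
    replay_counts: dict[tuple[str, int], int] = {}
    pending_replay: dict[str, int] = {}
    records: list[GameRecord] = []

    active = [p.player_id for p in players]
    while active:
        still_active = []
        for pid in active:
            if budgets[pid] <= 0:
                continue
            board_id = pending_replay.pop(pid, None)
            if board_id is not None and (
                board_id in state.closed or (pid, board_id) in won
            ):
                board_id = None
            if board_id is None:
                options = [b for b in state.open_boards() if (pid, b) not in won]
                if not options:
                    logger.info("player %s has no open boards left", pid)
                    budgets[pid] = 0
                    continue
                board_id = int(rng.choice(options))
            board = state.boards[board_id]
            replay_index = replay_counts.get((pid, board_id), 0)
            rec = play_game(
                board, policies[pid], ds, cv,
                seed=int(rng.integers(0, 2**31 - 1)),
                player_id=pid, replay_index=replay_index,
                hand_size=hand_size,
            )
            records.append(rec)
            replay_counts[(pid, board_id)] = replay_index + 1
            budgets[pid] -= 1
            state.record_completion(board_id, pid, crowd.closure_threshold)
            if rec.human_won:
                won.add((pid, board_id))
            elif (
                board_id not in state.closed
                and rng.random() < crowd.replay_prob
            ):
                pending_replay[pid] = board_id
            if budgets[pid] > 0:
                still_active.append(pid)
        if not state.open_boards():
            logger.info("all boards closed; simulation stops")
            break
        active = still_active
    return records, players


def write_profiles(
    players: Iterable[PlayerProfile], path: str | Path
) -> None:
    """TSV: player_id, degree, is_biologist, knows_cancer, cohort
    (missing answers written as NA)."""

    def fmt(v: Optional[bool]) -> str:
        return "NA" if v is None else str(v).lower()

    with open(path, "w") as fh:
        fh.write("player_id\tdegree\tis_biologist\tknows_cancer\tcohort\n")
        for p in players:
            fh.write(
                f"{p.player_id}\t{p.degree}\t{fmt(p.is_biologist)}\t"
                f"{fmt(p.knows_cancer)}\t{assign_cohort(p)}\n"
            )


def read_profiles(path: str | Path) -> list[PlayerProfile]:
    def parse(v: str) -> Optional[bool]:
        return None if v == "NA" else v == "true"

    players = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        pid, degree, bio, cancer, _cohort = line.split("\t")
        players.append(PlayerProfile(pid, degree, parse(bio), parse(cancer)))
    return players
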