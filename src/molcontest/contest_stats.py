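"""Per-entry statistic panels, per-challenge medals and the Olympic tally.

The contest winner is declared per challenge: gold goes to the contestant(s)
with the lowest (tie-averaged) rank of the correct candidate among all
contestants for that challenge, so a winner exists even when nobody ranked
the correct candidate first. Joint positions are possible in case of ties.
The overall winner is the participant with the most gold medals (Olympic
tally; silver then bronze break ties).

Interpretation statistics per entry: Top-X counts, mean/median rank,
relative ranking positions, rank quantiles, and two aggregate point schemes:

* **Formula 1 Score** — rounded ranks 1..10 earn 25, 18, 15, 12, 10, 8, 6,
  4, 2, 1 points, summed over challenges;
* **Medal Score** — rounded rank 1 earns 5 points, rank 2 earns 3, rank 3
  earns 1 (not to be confused with the per-challenge gold-medal tally).

Non-integer ranks are rounded up before any of these (rank 1.5 counts as 2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .contest_model import ChallengeSpec, RankResult

__all__ = [
    "EntrySummary",
    "F1_WEIGHTS",
    "MEDAL_POINTS",
    "formula1_score",
    "medal_score",
    "summarize_entry",
    "assign_medals",
    "build_medal_board",
    "medal_counts",
    "olympic_tally",
    "best_per_participant",
    "filter_leaveout",
    "write_summary_table",
    "write_medal_board",
]

#: Motorsport-style points for rounded ranks 1..10.
F1_WEIGHTS = {r: w for r, w in zip(range(1, 11), (25, 18, 15, 12, 10, 8, 6, 4, 2, 1))}

#: Medal Score points for rounded ranks 1..3 (gold/silver/bronze).
MEDAL_POINTS = {1: 5, 2: 3, 3: 1}

_QUANTILE_LEVELS = {"Q10": 0.10, "Q25": 0.25, "Q50": 0.50, "Q75": 0.75, "Q90": 0.90}


def _rounded(ranks: Iterable[RankResult]) -> list[Optional[int]]:
    return [r.rounded_rank for r in ranks]


def formula1_score(ranks: Iterable[RankResult]) -> int:
    """Sum of F1 points over challenges; missing and rank > 10 contribute 0."""
    return sum(F1_WEIGHTS.get(r, 0) for r in _rounded(ranks) if r is not None)


def medal_score(ranks: Iterable[RankResult]) -> int:
    """5/3/1 points for rounded ranks 1/2/3, summed over challenges."""
    return sum(MEDAL_POINTS.get(r, 0) for r in _rounded(ranks) if r is not None)


@dataclass
class EntrySummary:
    """The full statistic panel of one entry over a contest."""

    entry_name: str
    n_challenges: int
    n_ranked: int          # challenges with a non-missing rank
    top1: int
    top3: int
    top10: int
    top1_pos: int
    top1_neg: int
    mean_rank: float
    median_rank: float
    mean_rrp: float
    median_rrp: float
    formula1: int
    medal_score: int
    quantiles: dict[str, float]
    gold: int = 0
    silver: int = 0
    bronze: int = 0
    missing_as_candidate_count: bool = False

    def __post_init__(self) -> None:
        if not self.top1 <= self.top3 <= self.top10 <= self.n_ranked:
            raise ValueError("Top-X counts must be nested within ranked challenges")
        if self.top1 != self.top1_pos + self.top1_neg:
            raise ValueError("top1 must equal top1_pos + top1_neg")


def summarize_entry(
    entry_name: str,
    ranks: Mapping[str, RankResult],
    modes: Mapping[str, str],
    *,
    missing_as_candidate_count: bool = False,
) -> EntrySummary:
    """Compute the Top-X / mean / median / RRP / quantile / F1 / Medal panel.

    Top-X counts use rounded (ceilinged) ranks. Mean, median and quantiles
    are computed over the *average* ranks of non-missing challenges; the
    sensitivity mode ``missing_as_candidate_count`` instead substitutes the
    collapsed candidate count for missing challenges (the heat-map
    convention) before averaging. RRP statistics always exclude missing
    challenges. Raises on an empty rank set.
    """
    if not ranks:
        raise ValueError("empty rank set")
    results = list(ranks.values())
    present = [r for r in results if not r.is_missing]

    if missing_as_candidate_count:
        rank_values = [
            r.average_rank if not r.is_missing else float(r.n_candidates_collapsed)
            for r in results
            if not r.is_missing or r.n_candidates_collapsed >= 1
        ]
    else:
        rank_values = [r.average_rank for r in present]
    rank_arr = np.asarray(rank_values, dtype=float)
    rrp_arr = np.asarray([r.rrp for r in present], dtype=float)

    top1 = sum(1 for r in present if r.rounded_rank == 1)
    top1_pos = sum(
        1 for cid, r in ranks.items()
        if not r.is_missing and r.rounded_rank == 1 and modes.get(cid) == "positive"
    )
    quantiles = {
        name: float(np.quantile(rank_arr, q)) if rank_arr.size else float("nan")
        for name, q in _QUANTILE_LEVELS.items()
    }
    return EntrySummary(
        entry_name=entry_name,
        n_challenges=len(results),
        n_ranked=len(present),
        top1=top1,
        top3=sum(1 for r in present if r.rounded_rank <= 3),
        top10=sum(1 for r in present if r.rounded_rank <= 10),
        top1_pos=top1_pos,
        top1_neg=top1 - top1_pos,
        mean_rank=float(rank_arr.mean()) if rank_arr.size else float("nan"),
        median_rank=float(np.median(rank_arr)) if rank_arr.size else float("nan"),
        mean_rrp=float(rrp_arr.mean()) if rrp_arr.size else float("nan"),
        median_rrp=float(np.median(rrp_arr)) if rrp_arr.size else float("nan"),
        formula1=formula1_score(results),
        medal_score=medal_score(results),
        quantiles=quantiles,
        missing_as_candidate_count=missing_as_candidate_count,
    )


# ---------------------------------------------------------------------------
# Medals
# ---------------------------------------------------------------------------

_MEDAL_BY_POSITION = {1: "gold", 2: "silver", 3: "bronze"}


def assign_medals(
    challenge_ranks: Mapping[str, Optional[RankResult]],
    *,
    scheme: str = "competition",
) -> dict[str, str]:
    """Assign gold/silver/bronze for one challenge across entries.

    Missing ranks are treated as worst; a challenge where every entry is
    missing awards no medals. All entries tied at the minimum average rank
    receive gold jointly. With the default ``"competition"`` scheme the
    position after k joint medals skips k-1 places (two joint golds leave no
    silver); ``"dense"`` instead awards the next distinct rank the next
    medal.
    """
    if scheme not in ("competition", "dense"):
        raise ValueError(f"unknown medal scheme: {scheme!r}")
    effective: dict[str, float] = {}
    for entry, result in challenge_ranks.items():
        if result is None or result.is_missing:
            effective[entry] = float("inf")
        else:
            effective[entry] = result.average_rank
    medals = {entry: "none" for entry in challenge_ranks}
    if all(v == float("inf") for v in effective.values()):
        return medals
    distinct = sorted(set(effective.values()))
    position = 1
    for level, value in enumerate(distinct, start=1):
        holders = [e for e, v in effective.items() if v == value]
        pos = level if scheme == "dense" else position
        if pos > 3:
            break
        for entry in holders:
            medals[entry] = _MEDAL_BY_POSITION[pos]
        position += len(holders)
    return medals


def build_medal_board(
    ranks_by_entry: Mapping[str, Mapping[str, RankResult]],
    *,
    scheme: str = "competition",
) -> dict[str, dict[str, str]]:
    """Medal assignment for every challenge: challenge_id -> entry -> medal."""
    challenge_ids = sorted({cid for ranks in ranks_by_entry.values() for cid in ranks})
    board: dict[str, dict[str, str]] = {}
    for cid in challenge_ids:
        per_challenge = {e: ranks_by_entry[e].get(cid) for e in ranks_by_entry}
        board[cid] = assign_medals(per_challenge, scheme=scheme)
    return board


def medal_counts(board: Mapping[str, Mapping[str, str]]) -> dict[str, tuple[int, int, int]]:
    """Per-entry (gold, silver, bronze) counts over the whole board."""
    counts: dict[str, list[int]] = {}
    for row in board.values():
        for entry, medal in row.items():
            counts.setdefault(entry, [0, 0, 0])
            if medal == "gold":
                counts[entry][0] += 1
            elif medal == "silver":
                counts[entry][1] += 1
            elif medal == "bronze":
                counts[entry][2] += 1
    return {e: tuple(c) for e, c in counts.items()}


def olympic_tally(board: Mapping[str, Mapping[str, str]]) -> list[tuple[str, int, int, int]]:
    """Standings (entry, gold, silver, bronze) ordered by gold, silver, bronze."""
    counts = medal_counts(board)
    return sorted(
        ((e, g, s, b) for e, (g, s, b) in counts.items()),
        key=lambda row: (-row[1], -row[2], -row[3], row[0]),
    )


def best_per_participant(
    standings: Sequence[tuple[str, int, int, int]],
    participant_of: Mapping[str, str],
) -> list[tuple[str, str, int, int, int]]:
    """Select the best overall performing entry per participant.

    The winner declaration considers one entry per participant: the one
    placed highest in the Olympic standings. Returns (participant, entry,
    gold, silver, bronze) rows in standings order.
    """
    seen: set[str] = set()
    best: list[tuple[str, str, int, int, int]] = []
    for entry, g, s, b in standings:
        participant = participant_of.get(entry, entry)
        if participant in seen:
            continue
        seen.add(participant)
        best.append((participant, entry, g, s, b))
    return best


# ---------------------------------------------------------------------------
# Challenge-subset analyses
# ---------------------------------------------------------------------------

@dataclass
class LeaveoutResult:
    challenge_ids: list[str]
    n_positive: int
    n_negative: int


def filter_leaveout(
    challenges: Iterable[ChallengeSpec],
    training_key_lists: Iterable[Iterable[str]],
) -> LeaveoutResult:
    """Challenges whose solution skeleton is absent from *every* training set.

    This is the global leave-out analysis: with participants' training-set
    skeleton lists provided, only challenges no contestant could have seen in
    training are retained, with per-ion-mode counts reported. With no
    training lists all challenges are retained.
    """
    seen: set[str] = set()
    for key_list in training_key_lists:
        seen.update(key_list)
    kept = [c for c in challenges if c.solution_skeleton not in seen]
    return LeaveoutResult(
        challenge_ids=[c.challenge_id for c in kept],
        n_positive=sum(1 for c in kept if c.ion_mode == "positive"),
        n_negative=sum(1 for c in kept if c.ion_mode == "negative"),
    )


# ---------------------------------------------------------------------------
# Table writers
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = [
    "entry", "n_challenges", "n_ranked", "top1", "top3", "top10",
    "top1_pos", "top1_neg", "mean_rank", "median_rank", "mean_rrp",
    "median_rrp", "gold", "silver", "bronze", "formula1", "medal_score",
    "Q10", "Q25", "Q50", "Q75", "Q90",
]


def write_summary_table(summaries: Sequence[EntrySummary], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUMMARY_COLUMNS)
        for s in summaries:
            writer.writerow([
                s.entry_name, s.n_challenges, s.n_ranked, s.top1, s.top3,
                s.top10, s.top1_pos, s.top1_neg, repr(s.mean_rank),
                repr(s.median_rank), repr(s.mean_rrp), repr(s.median_rrp),
                s.gold, s.silver, s.bronze, s.formula1, s.medal_score,
                *(repr(s.quantiles[q]) for q in ("Q10", "Q25", "Q50", "Q75", "Q90")),
            ])


def write_medal_board(board: Mapping[str, Mapping[str, str]], path) -> None:
    """Write the challenge x entry medal board as CSV."""
    path = Path(path)
    entries = sorted({e for row in board.values() for e in row})
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["challenge_id", *entries])
        for cid in sorted(board):
            writer.writerow([cid, *(board[cid].get(e, "none") for e in entries)])
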