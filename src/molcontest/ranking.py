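"""Stereoisomer collapse and tie-averaged ranking of the correct candidate.

Submissions are filtered to remove duplicate stereoisomers using the first
block of the InChIKey, retaining the highest-scoring isomer. The rank of the
correct candidate is then its position when candidates are ordered by
descending score, with the *average* rank taken over all candidates sharing
its score. Non-integer ranks are rounded up to the higher rank when used for
Top-X / Formula 1 / medal scoring (a two-way tie at the top yields average
rank 1.5, counted as rank 2).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .contest_model import RankResult, SubmissionEntry

__all__ = [
    "CollapsedSubmission",
    "collapse_stereo",
    "rank_correct",
    "rrp",
    "tie_averaged_ranks",
    "evaluate_entry",
    "write_rank_table",
    "read_rank_table",
    "MISSING_RANK_RESULT_FIELDS",
]


@dataclass
class CollapsedSubmission:
    """Per-challenge scores keyed by skeleton (first InChIKey block).

    After stereo collapse each skeleton appears once, carrying the maximum
    score over its submitted stereoisomers.
    """

    challenge_id: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.scores.items() if not v >= 0]
        if bad:
            raise ValueError(f"negative or NaN scores for keys: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.scores)


def collapse_stereo(entry: SubmissionEntry, *, strict_keys: bool = False) -> CollapsedSubmission:
    """Collapse stereoisomer duplicates, retaining the highest-scoring isomer.

    Candidates are grouped by skeleton key; where the skeleton could not be
    derived (raw InChI/SMILES with no converter), the verbatim structure
    string is the grouping key, unless ``strict_keys`` is set, in which case
    such candidates raise ``ValueError``.
    """
    scores: dict[str, float] = {}
    for cand in entry.scored_candidates:
        key = cand.skeleton
        if key is None:
            if strict_keys:
                raise ValueError(
                    f"{entry.challenge_id}: no skeleton key for {cand.structure!r}"
                )
            key = cand.structure
        if key not in scores or cand.score > scores[key]:
            scores[key] = cand.score
    return CollapsedSubmission(entry.challenge_id, scores)


def tie_averaged_ranks(scores: Mapping[str, float], epsilon: float = 0.0) -> dict[str, float]:
    """Tie-averaged rank (1 = best) of every candidate, higher score = better.

    For a candidate with B strictly better scores and t candidates tied with
    it (itself included), the rank is ``B + (t + 1) / 2`` — the mean position
    over all orderings of the tied block. ``epsilon`` widens tie detection to
    ``|s_i - s_j| <= epsilon`` for tools that emit effectively-equal floats;
    the default 0 means exact equality of parsed values.
    """
    values = list(scores.values())
    ranks: dict[str, float] = {}
    for key, s in scores.items():
        better = sum(1 for v in values if v > s + epsilon)
        tied = sum(1 for v in values if abs(v - s) <= epsilon)
        ranks[key] = better + (tied + 1) / 2
    return ranks


def rank_correct(
    collapsed: CollapsedSubmission,
    solution_skeleton: str,
    *,
    epsilon: float = 0.0,
    allowed_skeletons: Optional[set] = None,
) -> RankResult:
    """Rank of the correct candidate in a stereo-collapsed submission.

    Returns a fully-missing :class:`RankResult` when the solution skeleton is
    absent (or the submission is empty) — missingness is explicit and only
    substituted at reporting or medal time, never silently imputed.

    Parameters
    ----------
    epsilon:
        Tie tolerance on scores (default 0 = exact equality).
    allowed_skeletons:
        Optional strict mode: restrict ranking to the official candidate
        list, raising if the submission contains skeletons outside it.
        By default submitted candidates absent from the official list are
        kept in the ranking.
    """
    scores = collapsed.scores
    if allowed_skeletons is not None:
        unknown = set(scores) - set(allowed_skeletons)
        if unknown:
            raise ValueError(
                f"{collapsed.challenge_id}: {len(unknown)} submitted skeletons "
                f"not in the candidate list (strict mode), e.g. {sorted(unknown)[:3]}"
            )
    tc = len(scores)
    if solution_skeleton not in scores:
        return RankResult(collapsed.challenge_id, None, None, tc, None)
    s0 = scores[solution_skeleton]
    better = sum(1 for v in scores.values() if v > s0 + epsilon)
    tied = sum(1 for v in scores.values() if abs(v - s0) <= epsilon)
    average = better + (tied + 1) / 2
    return RankResult(
        challenge_id=collapsed.challenge_id,
        average_rank=average,
        rounded_rank=math.ceil(average),
        n_candidates_collapsed=tc,
        rrp=rrp(average, tc),
    )


def rrp(rank: float, tc: int) -> float:
    """Relative ranking position in [0, 1]; 1 = best possible, 0 = worst.

    ``(TC - rank) / (TC - 1)``, making results comparable across candidate
    lists of different sizes; a single-candidate list scores 1.0.
    """
    if not 1 <= rank <= tc:
        raise ValueError(f"rank {rank} outside [1, {tc}]")
    if tc == 1:
        return 1.0
    return (tc - rank) / (tc - 1)


def evaluate_entry(
    submissions: Mapping[str, SubmissionEntry],
    solution_skeletons: Mapping[str, str],
    *,
    epsilon: float = 0.0,
) -> dict[str, RankResult]:
    """Collapse and rank one entry across all challenges of a contest.

    Every challenge in *solution_skeletons* gets a RankResult; challenges
    with no submission yield a fully-missing result with 0 candidates.
    """
    results: dict[str, RankResult] = {}
    for cid, skeleton in solution_skeletons.items():
        sub = submissions.get(cid)
        if sub is None or sub.is_empty:
            results[cid] = RankResult(cid, None, None, 0, None)
        else:
            results[cid] = rank_correct(collapse_stereo(sub), skeleton, epsilon=epsilon)
    return results


MISSING_RANK_RESULT_FIELDS = ("average_rank", "rounded_rank", "rrp")

_RANK_TABLE_COLUMNS = [
    "challenge_id", "entry", "average_rank", "rounded_rank",
    "n_candidates", "rrp", "missing_flag",
]


def write_rank_table(ranks_by_entry: Mapping[str, Mapping[str, RankResult]], path) -> None:
    """Write the per-challenge rank table CSV (one row per entry x challenge)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RANK_TABLE_COLUMNS)
        for entry_name in sorted(ranks_by_entry):
            for cid in sorted(ranks_by_entry[entry_name]):
                r = ranks_by_entry[entry_name][cid]
                writer.writerow([
                    cid, entry_name,
                    "" if r.average_rank is None else repr(r.average_rank),
                    "" if r.rounded_rank is None else r.rounded_rank,
                    r.n_candidates_collapsed,
                    "" if r.rrp is None else repr(r.rrp),
                    int(r.is_missing),
                ])


def read_rank_table(path) -> dict[str, dict[str, RankResult]]:
    """Read back a rank table written by :func:`write_rank_table`."""
    path = Path(path)
    out: dict[str, dict[str, RankResult]] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            missing = row["missing_flag"] == "1"
            result = RankResult(
                challenge_id=row["challenge_id"],
                average_rank=None if missing else float(row["average_rank"]),
                rounded_rank=None if missing else int(row["rounded_rank"]),
                n_candidates_collapsed=int(row["n_candidates"]),
                rrp=None if missing else float(row["rrp"]),
            )
            out.setdefault(row["entry"], {})[row["challenge_id"]] = result
    return out
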