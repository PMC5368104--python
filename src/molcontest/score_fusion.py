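"""Consensus score fusion and metadata scorers.

Heterogeneous candidate scores (different fragmenters, spectral-library
similarity, metadata evidence) are made commensurable by per-challenge
max-normalization, then combined as a weighted sum over the union of
candidates; a candidate missing from one component receives a configurable
missing value (default 0, penalized but not excluded). The combined scores
are non-negative with higher = better, so fused submissions re-enter the
standard evaluation unchanged.

Metadata scorers turn non-spectral evidence into submission-shaped score
maps:

* reference count (identity mapping — heavily referenced compounds first);
* lowest database identifier (older entries are better known; scored 1/id);
* database presence (+10 points per database containing the candidate);
* retention-time agreement against a linear descriptor→RT calibration fit
  on training (descriptor, RT) pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .contest_model import CandidateRecord
from .ranking import CollapsedSubmission, rank_correct
from .contest_stats import F1_WEIGHTS

logger = logging.getLogger("molcontest")

__all__ = [
    "FusionConfig",
    "MetadataRecord",
    "metadata_from_candidates",
    "normalize_scores",
    "combine",
    "refs_score",
    "lowest_id_score",
    "db_presence_score",
    "RTModel",
    "fit_rt_model",
    "rt_score",
    "fit_weights",
]


@dataclass
class FusionConfig:
    """Weighted combination of named score sources.

    ``components`` pairs each score-source name with a non-negative weight;
    equal weights give the plain consensus. ``normalization`` is applied per
    component and challenge before weighting: ``"max_per_challenge"``
    (default; divide by the component's maximum score in that challenge) or
    ``"none"``. Candidates absent from a component contribute
    ``missing_value``.
    """

    components: list[tuple[str, float]]
    normalization: str = "max_per_challenge"
    missing_value: float = 0.0

    def __post_init__(self) -> None:
        if self.normalization not in ("max_per_challenge", "none"):
            raise ValueError(f"unknown normalization: {self.normalization!r}")
        weights = [w for _, w in self.components]
        if any(not np.isfinite(w) or w < 0 for w in weights):
            raise ValueError("weights must be finite and non-negative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one component weight must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "components": [[n, w] for n, w in self.components],
            "normalization": self.normalization,
            "missing_value": self.missing_value,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "FusionConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            components=[(n, float(w)) for n, w in raw["components"]],
            normalization=raw.get("normalization", "max_per_challenge"),
            missing_value=float(raw.get("missing_value", 0.0)),
        )


def normalize_scores(collapsed: CollapsedSubmission) -> CollapsedSubmission:
    """Divide every score by the per-challenge maximum, mapping into [0, 1].

    Order-preserving; an all-zero (or empty) score map is returned unchanged.
    """
    if not collapsed.scores:
        return CollapsedSubmission(collapsed.challenge_id, {})
    top = max(collapsed.scores.values())
    if top == 0:
        return CollapsedSubmission(collapsed.challenge_id, dict(collapsed.scores))
    return CollapsedSubmission(
        collapsed.challenge_id,
        {k: v / top for k, v in collapsed.scores.items()},
    )


def combine(
    components: Mapping[str, CollapsedSubmission],
    cfg: FusionConfig,
) -> CollapsedSubmission:
    """Weighted consensus of several collapsed submissions for one challenge.

    The candidate universe is the union of all components' skeleton keys.
    Each component is normalized per *cfg*, a missing candidate contributes
    ``cfg.missing_value``, and contributions are summed with the configured
    weights. All inputs must refer to the same challenge.
    """
    wanted = [name for name, _ in cfg.components]
    missing_components = [n for n in wanted if n not in components]
    if missing_components:
        raise KeyError(f"components not provided: {missing_components}")
    challenge_ids = {components[n].challenge_id for n in wanted}
    if len(challenge_ids) > 1:
        raise ValueError(f"components refer to different challenges: {challenge_ids}")
    (challenge_id,) = challenge_ids

    normalized = {}
    for name in wanted:
        sub = components[name]
        normalized[name] = (
            normalize_scores(sub).scores
            if cfg.normalization == "max_per_challenge" else sub.scores
        )
    universe = set().union(*normalized.values()) if normalized else set()
    fused = {
        key: sum(
            w * normalized[name].get(key, cfg.missing_value)
            for name, w in cfg.components
        )
        for key in universe
    }
    return CollapsedSubmission(challenge_id, fused)


# ---------------------------------------------------------------------------
# Metadata scorers
# ---------------------------------------------------------------------------

class MetadataRecord(NamedTuple):
    reference_count: Optional[int]
    identifier: Optional[int]
    db_presence: frozenset[str]
    descriptor: Optional[float]


def metadata_from_candidates(
    candidates: Iterable[CandidateRecord],
) -> dict[str, MetadataRecord]:
    """Build a skeleton-keyed metadata table from candidate records.

    Stereoisomer duplicates collapse onto one skeleton; the first row wins
    for scalar fields and database presence is unioned.
    """
    table: dict[str, MetadataRecord] = {}
    for rec in candidates:
        key = rec.skeleton_key
        if key in table:
            prev = table[key]
            table[key] = prev._replace(db_presence=prev.db_presence | rec.db_presence)
        else:
            table[key] = MetadataRecord(
                rec.reference_count, rec.identifier, rec.db_presence, rec.descriptor
            )
    return table


def refs_score(
    meta: Mapping[str, MetadataRecord],
    skeletons: Iterable[str],
    challenge_id: str = "",
) -> CollapsedSubmission:
    """Score candidates by literature reference count (identity mapping)."""
    scores: dict[str, float] = {}
    for key in skeletons:
        record = meta.get(key)
        if record is None or record.reference_count is None:
            logger.warning("refs_score: no reference count for %s, scored 0", key)
            scores[key] = 0.0
        else:
            scores[key] = float(record.reference_count)
    return CollapsedSubmission(challenge_id, scores)


def lowest_id_score(
    meta: Mapping[str, MetadataRecord],
    skeletons: Iterable[str],
    challenge_id: str = "",
) -> CollapsedSubmission:
    """Score candidates by database identifier, lowest id = best entry.

    The reciprocal 1/id satisfies the non-negative / higher-is-better score
    contract; any strictly decreasing transform induces the same ranking.
    """
    scores: dict[str, float] = {}
    for key in skeletons:
        record = meta.get(key)
        if record is None or record.identifier is None or record.identifier <= 0:
            raise ValueError(f"lowest_id_score: no positive identifier for {key}")
        scores[key] = 1.0 / record.identifier
    return CollapsedSubmission(challenge_id, scores)


def db_presence_score(
    meta: Mapping[str, MetadataRecord],
    skeletons: Iterable[str],
    databases: Sequence[str],
    challenge_id: str = "",
) -> CollapsedSubmission:
    """10 points per listed database that contains the candidate.

    Designed for additive combination with a fragmenter score (a candidate
    present in one database adds 10 to its fragmenter score).
    """
    wanted = set(databases)
    scores: dict[str, float] = {}
    for key in skeletons:
        record = meta.get(key)
        presence = record.db_presence if record is not None else frozenset()
        scores[key] = 10.0 * len(presence & wanted)
    return CollapsedSubmission(challenge_id, scores)


@dataclass
class RTModel:
    """Linear retention-time calibration RT = slope * descriptor + intercept."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    n_training: int

    def predict(self, descriptor: float) -> float:
        return self.slope * descriptor + self.intercept


def fit_rt_model(training_pairs: Sequence[tuple[float, float]]) -> RTModel:
    """Least-squares fit of the descriptor→RT line on training pairs.

    Requires at least 3 pairs and non-degenerate descriptor variance.
    """
    if len(training_pairs) < 3:
        raise ValueError("need at least 3 training (descriptor, RT) pairs")
    x = np.asarray([p[0] for p in training_pairs], dtype=float)
    y = np.asarray([p[1] for p in training_pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate descriptor variance in training pairs")
    fit = stats.linregress(x, y)
    return RTModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr_slope=float(fit.stderr),
        stderr_intercept=float(fit.intercept_stderr),
        n_training=len(training_pairs),
    )


def rt_score(
    model: RTModel,
    challenge_rt: float,
    candidate_descriptors: Mapping[str, float],
    *,
    window: float = 2.0,
    challenge_id: str = "",
) -> CollapsedSubmission:
    """Retention-time agreement score in [0, 1].

    Each candidate's RT is predicted from its hydrophobicity descriptor
    through the fitted calibration line; the score is
    ``max(0, 1 - |challenge_rt - predicted| / window)`` with *window* in
    minutes (default 2). A perfect prediction scores 1; deviations at or
    beyond the window score 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    scores = {
        key: max(0.0, 1.0 - abs(challenge_rt - model.predict(desc)) / window)
        for key, desc in candidate_descriptors.items()
    }
    return CollapsedSubmission(challenge_id, scores)


# ---------------------------------------------------------------------------
# Weight fitting
# ---------------------------------------------------------------------------

def _simplex_grid(n_components: int, resolution: int) -> list[tuple[float, ...]]:
    """All non-negative weight vectors summing to 1 with steps 1/resolution."""
    grid = []
    for cuts in combinations_with_replacement(range(n_components), resolution):
        counts = [0] * n_components
        for c in cuts:
            counts[c] += 1
        grid.append(tuple(c / resolution for c in counts))
    return grid


def fit_weights(
    components_by_challenge: Mapping[str, Mapping[str, CollapsedSubmission]],
    solutions: Mapping[str, str],
    *,
    resolution: int = 5,
    normalization: str = "max_per_challenge",
    missing_value: float = 0.0,
) -> tuple[FusionConfig, int, int]:
    """Grid-search fusion weights on training challenges with known solutions.

    Enumerates the weight simplex at steps of ``1/resolution`` and selects
    the weight vector maximizing the Top-1 count over the training
    challenges, breaking ties by Formula 1 score (then by enumeration
    order). Returns ``(best_config, top1, formula1)`` achieved on training.
    """
    names = sorted(components_by_challenge)
    if not names:
        raise ValueError("no components given")
    if resolution < 1:
        raise ValueError("empty weight grid (resolution < 1)")
    challenge_ids = sorted(solutions)

    best: Optional[tuple[int, int, FusionConfig]] = None
    for weights in _simplex_grid(len(names), resolution):
        if not any(w > 0 for w in weights):
            continue
        cfg = FusionConfig(
            components=list(zip(names, weights)),
            normalization=normalization,
            missing_value=missing_value,
        )
        top1 = 0
        f1 = 0
        for cid in challenge_ids:
            per_component = {
                n: components_by_challenge[n][cid]
                for n in names if cid in components_by_challenge[n]
            }
            if len(per_component) != len(names):
                continue
            result = rank_correct(combine(per_component, cfg), solutions[cid])
            if result.rounded_rank is not None:
                if result.rounded_rank == 1:
                    top1 += 1
                f1 += F1_WEIGHTS.get(result.rounded_rank, 0)
        if best is None or (top1, f1) > (best[0], best[1]):
            best = (top1, f1, cfg)
    assert best is not None
    return best[2], best[0], best[1]
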