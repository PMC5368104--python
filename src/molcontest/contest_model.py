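"""Domain types and file I/O for contest evaluation.

The contest exchanges four kinds of plain-text artifacts:

* **submissions** — per-challenge, tab-separated files with two columns:
  a structure representation (standard InChI, SMILES or InChIKey) and a
  non-negative score, higher meaning a better candidate;
* **candidate lists** — CSV files, one row per candidate structure with a
  database identifier, an InChIKey and optional metadata columns;
* **solutions** — a CSV mapping each challenge to its correct InChIKey,
  ion mode and retention time;
* **rank/summary tables** — CSV outputs of the evaluation.

Stereoisomers cannot be distinguished by the analytical methods the contest
evaluates, so all identity comparisons operate on the *skeleton key*: the
first 14-character block of the InChIKey, which is constant across
stereoisomers.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

logger = logging.getLogger("molcontest")

__all__ = [
    "ValidationError",
    "CandidateRecord",
    "ChallengeSpec",
    "ScoredCandidate",
    "SubmissionEntry",
    "RankResult",
    "SolutionRecord",
    "extract_skeleton",
    "is_inchikey",
    "read_submission",
    "write_submission",
    "read_candidates",
    "write_candidates",
    "read_solutions",
    "write_solutions",
    "DEFAULT_COLUMN_MAP",
    "SUBMISSION_FILENAME_PATTERN",
]

#: Default filename pattern for per-challenge submission files.
SUBMISSION_FILENAME_PATTERN = "{entry}-challenge-{challenge_id}.txt"

#: Default candidate-CSV column dialect. Keys are logical field names, values
#: are the column headers expected in the file. Override any subset via the
#: ``column_map`` argument of :func:`read_candidates`.
DEFAULT_COLUMN_MAP = {
    "identifier": "identifier",
    "inchikey": "inchikey",
    "mass": "mass",
    "refcount": "refcount",
    "logp": "logp",
    "databases": "databases",
}

_SKELETON_RE = re.compile(r"^[A-Z]{14}$")
_FULL_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class ValidationError(ValueError):
    """Raised when an input file violates the contest format rules."""


def is_inchikey(text: str) -> bool:
    """Return True if *text* is a full 27-char InChIKey or a bare first block."""
    text = text.removeprefix("InChIKey=")
    return bool(_FULL_KEY_RE.match(text) or _SKELETON_RE.match(text))


def extract_skeleton(structure_key: str) -> str:
    """Return the 14-character first InChIKey block (the stereo-free skeleton).

    Accepts a full 27-character InChIKey (hyphens after positions 14 and 25),
    optionally prefixed with ``InChIKey=``, or a bare 14-character block,
    which is returned unchanged.

    Raises
    ------
    ValidationError
        If the input has any other shape.
    """
    key = structure_key.strip().removeprefix("InChIKey=")
    if _SKELETON_RE.match(key):
        return key
    if _FULL_KEY_RE.match(key):
        return key[:14]
    raise ValidationError(f"not an InChIKey or first block: {structure_key!r}")


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate structure from a challenge's candidate list.

    Parameters
    ----------
    identifier:
        Positive integer database id. Lower ids tend to belong to older,
        better-known database entries.
    structure_key:
        Full 27-character InChIKey.
    monoisotopic_mass:
        Monoisotopic mass in Da; None when the list carries no mass column.
    reference_count:
        Literature/database reference count (optional metadata).
    db_presence:
        Names of the compound databases that contain this candidate.
    descriptor:
        Unitless hydrophobicity descriptor (e.g. logP) for RT prediction.
    """

    identifier: int
    structure_key: str
    monoisotopic_mass: Optional[float] = None
    reference_count: Optional[int] = None
    db_presence: frozenset[str] = frozenset()
    descriptor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.identifier <= 0:
            raise ValidationError(f"identifier must be positive: {self.identifier}")
        if not _FULL_KEY_RE.match(self.structure_key):
            raise ValidationError(f"invalid InChIKey: {self.structure_key!r}")
        if self.monoisotopic_mass is not None and not self.monoisotopic_mass > 0:
            raise ValidationError("monoisotopic_mass must be > 0")
        if self.reference_count is not None and self.reference_count < 0:
            raise ValidationError("reference_count must be non-negative")

    @property
    def skeleton_key(self) -> str:
        return self.structure_key[:14]


_MODE_PRECURSOR = {"positive": "[M+H]+", "negative": "[M-H]-"}


@dataclass
class ChallengeSpec:
    """One contest challenge: solution, ion mode, RT and candidate list."""

    challenge_id: str
    ion_mode: str
    solution_key: str
    retention_time: Optional[float] = None
    precursor_type: Optional[str] = None
    candidates: list[CandidateRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ion_mode not in ("positive", "negative"):
            raise ValidationError(f"unknown ion mode: {self.ion_mode!r}")
        if self.precursor_type is None:
            self.precursor_type = _MODE_PRECURSOR[self.ion_mode]
        elif self.precursor_type != _MODE_PRECURSOR[self.ion_mode]:
            raise ValidationError(
                f"precursor type {self.precursor_type!r} inconsistent with "
                f"{self.ion_mode} mode"
            )

    @property
    def solution_skeleton(self) -> str:
        return extract_skeleton(self.solution_key)

    def verify_solution_present(self) -> None:
        """Check the correct solution's skeleton occurs among the candidates."""
        skeletons = {c.skeleton_key for c in self.candidates}
        if self.solution_skeleton not in skeletons:
            raise ValidationError(
                f"{self.challenge_id}: solution skeleton "
                f"{self.solution_skeleton} absent from candidate list"
            )


class ScoredCandidate(NamedTuple):
    """One (structure, score) line of a submission file.

    ``structure`` is kept verbatim; ``skeleton`` is the derived first
    InChIKey block, or None when the structure is not an InChIKey and no
    converter was supplied.
    """

    structure: str
    score: float
    skeleton: Optional[str]


@dataclass
class SubmissionEntry:
    """One participant entry's scored candidates for one challenge.

    An empty ``scored_candidates`` list is valid and flags a challenge the
    participant did not submit (there is no requirement to submit entries
    for all challenges).
    """

    participant: str
    entry_name: str
    challenge_id: str
    scored_candidates: list[ScoredCandidate] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.scored_candidates


@dataclass(frozen=True)
class RankResult:
    """Tie-averaged rank of the correct candidate in one challenge.

    ``average_rank``/``rounded_rank``/``rrp`` are jointly None (MISSING) when
    the correct solution was absent from the submission or the challenge was
    not submitted at all.
    """

    challenge_id: str
    average_rank: Optional[float]
    rounded_rank: Optional[int]
    n_candidates_collapsed: int
    rrp: Optional[float]

    def __post_init__(self) -> None:
        missing = (self.average_rank is None, self.rounded_rank is None, self.rrp is None)
        if any(missing) != all(missing):
            raise ValueError("rank fields must be jointly missing or present")
        if self.average_rank is not None:
            if self.average_rank < 1:
                raise ValueError("average_rank must be >= 1")
            if self.average_rank > self.n_candidates_collapsed:
                raise ValueError("average_rank exceeds candidate count")

    @property
    def is_missing(self) -> bool:
        return self.average_rank is None


class SolutionRecord(NamedTuple):
    challenge_id: str
    inchikey: str
    ion_mode: str
    retention_time: Optional[float]

    @property
    def skeleton(self) -> str:
        return extract_skeleton(self.inchikey)


# ---------------------------------------------------------------------------
# Submission I/O
# ---------------------------------------------------------------------------

def read_submission(
    path,
    *,
    participant: str = "",
    entry_name: str = "",
    challenge_id: str = "",
    structure_format: str = "inchikey",
    key_converter: Optional[Callable[[str], str]] = None,
) -> SubmissionEntry:
    """Parse a two-column tab-separated submission file.

    Column 1 holds the structure (verbatim), column 2 a non-negative score.
    An empty file yields an entry with no scored candidates (a valid
    "no submission" for that challenge).

    Parameters
    ----------
    structure_format:
        ``"inchikey"`` (default) requires every structure to be an InChIKey
        or first block and derives the skeleton key from it. ``"raw"`` keeps
        structures verbatim (InChI/SMILES submissions); the skeleton is then
        derived through *key_converter* if given, otherwise left as None and
        the verbatim string acts as the identity key downstream.
    key_converter:
        Optional callable mapping a structure string to a full InChIKey
        (e.g. an adapter around a chemistry toolkit). Evaluation itself never
        requires a chemistry engine.

    Raises
    ------
    ValidationError
        On a negative or unparsable score, a malformed line, or (in
        ``"inchikey"`` mode) a malformed structure key — always naming the
        offending line number.
    """
    if structure_format not in ("inchikey", "raw"):
        raise ValueError(f"unknown structure_format: {structure_format!r}")
    path = Path(path)
    scored: list[ScoredCandidate] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected two tab-separated columns, "
                    f"got {len(parts)}"
                )
            structure, score_text = parts[0].strip(), parts[1].strip()
            try:
                score = float(score_text)
            except ValueError:
                raise ValidationError(
                    f"{path.name}:{lineno}: score {score_text!r} is not a number"
                ) from None
            if not score >= 0:  # also rejects NaN
                raise ValidationError(
                    f"{path.name}:{lineno}: score must be non-negative, got {score_text}"
                )
            skeleton: Optional[str] = None
            if structure_format == "inchikey":
                try:
                    skeleton = extract_skeleton(structure)
                except ValidationError as exc:
                    raise ValidationError(f"{path.name}:{lineno}: {exc}") from None
            elif key_converter is not None:
                skeleton = extract_skeleton(key_converter(structure))
            elif is_inchikey(structure):
                skeleton = extract_skeleton(structure)
            scored.append(ScoredCandidate(structure, score, skeleton))
    entry = SubmissionEntry(participant, entry_name, challenge_id, scored)
    if entry.is_empty:
        logger.info("%s: empty submission file (no candidates submitted)", path.name)
    return entry


def write_submission(entry: SubmissionEntry, path) -> None:
    """Write a submission back to the two-column tab-separated format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for cand in entry.scored_candidates:
            fh.write(f"{cand.structure}\t{cand.score!r}\n")


# ---------------------------------------------------------------------------
# Candidate-list I/O
# ---------------------------------------------------------------------------

def _parse_db_presence(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(name.strip() for name in cell.split(";") if name.strip())


def read_candidates(path, column_map: Optional[dict] = None) -> list[CandidateRecord]:
    """Read a candidate-list CSV into :class:`CandidateRecord` objects.

    Rows whose structure key fails InChIKey validation are dropped and
    counted in a log message; rows repeating an already-seen identifier are
    collapsed to the first occurrence with a warning. Optional metadata
    columns (mass, refcount, logp, databases) are populated when mapped and
    present; the ``databases`` column is a semicolon-separated set of
    database names.

    Raises
    ------
    ValidationError
        If a mapped *required* column (identifier, inchikey) is missing.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    records: list[CandidateRecord] = []
    seen_ids: set[int] = set()
    n_dropped = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in ("identifier", "inchikey"):
            if cmap[logical] not in header:
                raise ValidationError(
                    f"{path.name}: required column {cmap[logical]!r} "
                    f"(mapped from {logical!r}) not in header {header}"
                )
        has = {k: cmap[k] in header for k in cmap}
        for row in reader:
            key = (row[cmap["inchikey"]] or "").strip().removeprefix("InChIKey=")
            if not _FULL_KEY_RE.match(key):
                n_dropped += 1
                continue
            identifier = int(row[cmap["identifier"]])
            if identifier in seen_ids:
                logger.warning(
                    "%s: duplicate identifier %d collapsed to first occurrence",
                    path.name, identifier,
                )
                continue
            seen_ids.add(identifier)

            def _opt(field_name, cast):
                if not has[field_name]:
                    return None
                cell = (row[cmap[field_name]] or "").strip()
                return cast(cell) if cell else None

            records.append(
                CandidateRecord(
                    identifier=identifier,
                    structure_key=key,
                    monoisotopic_mass=_opt("mass", float),
                    reference_count=_opt("refcount", lambda c: int(float(c))),
                    db_presence=_parse_db_presence(row[cmap["databases"]])
                    if has["databases"] else frozenset(),
                    descriptor=_opt("logp", float),
                )
            )
    if n_dropped:
        logger.info("%s: dropped %d rows with invalid structure keys", path.name, n_dropped)
    return records


def write_candidates(records: Sequence[CandidateRecord], path,
                     column_map: Optional[dict] = None) -> None:
    """Write candidate records to CSV using the (possibly overridden) dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    fields = [cmap[k] for k in ("identifier", "inchikey", "mass", "refcount",
                                "logp", "databases")]
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for rec in records:
            writer.writerow([
                rec.identifier,
                rec.structure_key,
                "" if rec.monoisotopic_mass is None else repr(rec.monoisotopic_mass),
                "" if rec.reference_count is None else rec.reference_count,
                "" if rec.descriptor is None else repr(rec.descriptor),
                ";".join(sorted(rec.db_presence)),
            ])


# ---------------------------------------------------------------------------
# Solution-table I/O
# ---------------------------------------------------------------------------

def read_solutions(path) -> dict[str, SolutionRecord]:
    """Read the solutions CSV (challenge_id, inchikey, mode, rt_min)."""
    path = Path(path)
    solutions: dict[str, SolutionRecord] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            cid = row["challenge_id"].strip()
            rt = row.get("rt_min", "")
            solutions[cid] = SolutionRecord(
                challenge_id=cid,
                inchikey=row["inchikey"].strip(),
                ion_mode=row["mode"].strip(),
                retention_time=float(rt) if rt not in ("", None) else None,
            )
    return solutions


def write_solutions(solutions: Iterable[SolutionRecord], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["challenge_id", "inchikey", "mode", "rt_min"])
        for sol in solutions:
            writer.writerow([
                sol.challenge_id, sol.inchikey, sol.ion_mode,
                "" if sol.retention_time is None else repr(sol.retention_time),
            ])
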