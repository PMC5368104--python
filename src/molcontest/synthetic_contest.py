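"""Synthetic contest generator.

Produces complete, self-contained contests — challenges with candidate
lists, solutions, metadata, method submissions and library spectra — with
the statistical structure the evaluation machinery assumes, so every stage
is testable without any download:

* challenge composition mirrors the real contest scale: 208 challenges,
  127 positive / 81 negative mode, lognormal candidate-list sizes with a
  mean near 1100 candidates;
* candidate lists contain stereoisomer duplicates (same first InChIKey
  block, different full key) at a configurable rate;
* metadata is skewed the way compound databases are: heavy-tailed (Pareto)
  reference counts with a multiplicative boost on the true compound, low
  database identifiers for true compounds, and a linear descriptor→RT
  relationship with Gaussian noise;
* method submissions follow a one-parameter quality model: the true
  candidate's score quantile is Beta(α, 1) — α = 1 is an uninformative
  method (uniform rank), larger α is better — with optional score
  quantization (ties), per-challenge coverage, and top-k truncation that can
  drop the correct answer.

InChIKeys are syntactically valid but chemically meaningless, and are
collision-free within a contest by construction (a base-26 counter is
embedded in each key). One seed fans out to independent per-stage generator
streams, so contest, submissions and spectra are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .contest_model import (
    CandidateRecord,
    ChallengeSpec,
    ScoredCandidate,
    SolutionRecord,
    SubmissionEntry,
    read_candidates,
    read_solutions,
    write_candidates,
    write_solutions,
    write_submission,
    SUBMISSION_FILENAME_PATTERN,
)
from .spectra import Spectrum, write_mgf

__all__ = [
    "SyntheticContestConfig",
    "MethodProfile",
    "SpectrumNoise",
    "Contest",
    "generate_contest",
    "generate_submissions",
    "generate_library_spectra",
    "write_contest",
    "read_contest",
    "write_submission_set",
]

_PROTON_MASS = 1.007276

_LETTERS = np.array(list(string.ascii_uppercase))


@dataclass
class SyntheticContestConfig:
    """Generative parameters for a synthetic contest.

    Defaults reproduce the real contest's composition: 208 challenges of
    which 127 are positive mode, and lognormal candidate counts
    (log-mean 6.5, log-sd 1.0, mean ≈ 1100 candidates per challenge).
    ``stereo_dup_rate`` is the expected number of extra stereoisomer rows per
    skeleton. ``ref_boost`` multiplies the true compound's Pareto-distributed
    reference count; true compounds draw identifiers from the low range
    ``[1, true_id_max]`` while decoys draw from ``(true_id_max, id_max]``.
    Retention times follow ``RT = rt_slope * descriptor + rt_intercept +
    N(0, rt_noise_sd)`` (minutes).
    """

    n_challenges: int = 208
    frac_positive: float = 127 / 208
    candidate_count_dist: tuple[float, float] = (6.5, 1.0)
    stereo_dup_rate: float = 0.15
    ref_pareto_shape: float = 1.0
    ref_scale: float = 10.0
    ref_boost: float = 100.0
    db_names: tuple[str, ...] = ("HMDB", "ChEBI", "FooDB", "DrugBank", "PlantDB")
    db_prob_true: float = 0.8
    db_prob_decoy: float = 0.2
    descriptor_mean: float = 2.0
    descriptor_sd: float = 1.5
    rt_slope: float = 1.5
    rt_intercept: float = 2.0
    rt_noise_sd: float = 0.3
    n_rt_training: int = 312
    true_id_max: int = 100_000
    id_max: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_challenges < 1:
            raise ValueError("n_challenges must be >= 1")
        if not 0 <= self.frac_positive <= 1:
            raise ValueError("frac_positive must be in [0, 1]")
        if self.candidate_count_dist[1] < 0 or self.stereo_dup_rate < 0:
            raise ValueError("distribution parameters must be non-negative")
        if self.ref_pareto_shape <= 0 or self.ref_scale <= 0:
            raise ValueError("reference-count distribution must be positive")


@dataclass
class MethodProfile:
    """Generative stand-in for one participant method.

    ``quality`` is α in the Beta(α, 1) model of the true candidate's score
    quantile: larger α concentrates the quantile near 1, i.e. the correct
    candidate tends to the top. ``tie_prob`` is the per-challenge probability
    that scores are quantized to two decimals (injecting ties);
    ``coverage`` the probability a challenge is submitted at all;
    ``top_k_truncation`` keeps only the k best-scoring candidate rows,
    possibly dropping the correct answer.
    """

    name: str
    quality: float
    tie_prob: float = 0.0
    coverage: float = 1.0
    top_k_truncation: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quality <= 0:
            raise ValueError("quality (alpha) must be > 0")
        if not 0 <= self.tie_prob <= 1 or not 0 <= self.coverage <= 1:
            raise ValueError("tie_prob and coverage must be in [0, 1]")
        if self.top_k_truncation is not None and self.top_k_truncation < 1:
            raise ValueError("top_k_truncation must be >= 1")


@dataclass
class SpectrumNoise:
    """Noise model for query spectra relative to their library reference:
    Gaussian m/z jitter on the ppm scale and lognormal intensity noise."""

    mz_ppm_sd: float = 5.0
    intensity_cv: float = 0.2


@dataclass
class Contest:
    """A generated contest: challenges (with candidates and metadata),
    retention-time training pairs, and the generating config."""

    config: SyntheticContestConfig
    challenges: list[ChallengeSpec]
    rt_training: list[tuple[float, float]] = field(default_factory=list)

    @property
    def solution_skeletons(self) -> dict[str, str]:
        return {c.challenge_id: c.solution_skeleton for c in self.challenges}

    @property
    def modes(self) -> dict[str, str]:
        return {c.challenge_id: c.ion_mode for c in self.challenges}

    @property
    def solutions(self) -> dict[str, SolutionRecord]:
        return {
            c.challenge_id: SolutionRecord(
                c.challenge_id, c.solution_key, c.ion_mode, c.retention_time
            )
            for c in self.challenges
        }

    @property
    def candidate_counts(self) -> dict[str, int]:
        """Collapsed (unique-skeleton) candidate count per challenge."""
        return {
            c.challenge_id: len({r.skeleton_key for r in c.candidates})
            for c in self.challenges
        }


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage stream fanned out from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _base26(index: int, width: int) -> str:
    chars = []
    for _ in range(width):
        index, rem = divmod(index, 26)
        chars.append(string.ascii_uppercase[rem])
    return "".join(reversed(chars))


class _KeyFactory:
    """Fake but syntactically valid InChIKeys, collision-free by construction:
    a running counter is base-26-encoded into the tail of the first block."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._counter = 0

    def new_skeleton(self) -> str:
        prefix = "".join(self._rng.choice(_LETTERS, size=8))
        skeleton = prefix + _base26(self._counter, 6)
        self._counter += 1
        return skeleton

    @staticmethod
    def full_key(skeleton: str, variant: int) -> str:
        # second block encodes the stereo-variant index; flag/version chars
        # fixed to the standard-InChIKey convention
        return f"{skeleton}-{_base26(variant, 8)}SA-N"


def _unique_ints(rng: np.random.Generator, n: int, low: int, high: int,
                 exclude: set[int]) -> list[int]:
    out: list[int] = []
    taken = set(exclude)
    while len(out) < n:
        draw = int(rng.integers(low, high + 1))
        if draw not in taken:
            taken.add(draw)
            out.append(draw)
    return out


def generate_contest(cfg: SyntheticContestConfig) -> Contest:
    """Generate a full contest deterministically from ``cfg.seed``.

    Each challenge receives a unique solution skeleton that is guaranteed to
    appear in its candidate list, metadata columns as described on
    :class:`SyntheticContestConfig`, and a retention time generated from the
    true compound's descriptor through the linear RT model. Also generates
    ``cfg.n_rt_training`` training (descriptor, RT) pairs from the same
    model.
    """
    rng = _rng(cfg.seed, 0)
    keys = _KeyFactory(rng)
    n = cfg.n_challenges
    n_pos = int(round(cfg.frac_positive * n))
    modes = np.array(["positive"] * n_pos + ["negative"] * (n - n_pos))
    rng.shuffle(modes)

    log_mean, log_sd = cfg.candidate_count_dist
    counts = np.maximum(1, np.round(rng.lognormal(log_mean, log_sd, size=n))).astype(int)

    challenges: list[ChallengeSpec] = []
    used_ids: set[int] = set()
    width = len(str(n))
    for idx in range(n):
        cid = f"challenge-{idx + 1:0{width}d}"
        tc = int(counts[idx])
        skeletons = [keys.new_skeleton() for _ in range(tc)]  # index 0 = solution
        solution_skeleton = skeletons[0]

        extra = rng.poisson(cfg.stereo_dup_rate, size=tc)
        n_rows_per_skel = 1 + extra
        n_rows = int(n_rows_per_skel.sum())

        true_ids = _unique_ints(rng, int(n_rows_per_skel[0]), 1, cfg.true_id_max, used_ids)
        decoy_ids = _unique_ints(rng, n_rows - len(true_ids),
                                 cfg.true_id_max + 1, cfg.id_max, used_ids)
        used_ids.update(true_ids)
        used_ids.update(decoy_ids)

        refcounts = np.maximum(
            1, np.round(cfg.ref_scale * (1.0 + rng.pareto(cfg.ref_pareto_shape, size=tc)))
        ).astype(int)
        refcounts[0] = int(round(refcounts[0] * cfg.ref_boost))
        descriptors = rng.normal(cfg.descriptor_mean, cfg.descriptor_sd, size=tc)

        solution_mass = float(rng.uniform(100.0, 500.0))
        masses = solution_mass * (1.0 + rng.uniform(-5e-6, 5e-6, size=tc))
        masses[0] = solution_mass

        presence_p = np.full(tc, cfg.db_prob_decoy)
        presence_p[0] = cfg.db_prob_true
        presence = rng.random((tc, len(cfg.db_names))) < presence_p[:, None]

        records: list[CandidateRecord] = []
        decoy_iter = iter(decoy_ids)
        for k in range(tc):
            dbs = frozenset(
                name for d, name in enumerate(cfg.db_names) if presence[k, d]
            )
            ids_k = true_ids if k == 0 else [next(decoy_iter) for _ in range(int(n_rows_per_skel[k]))]
            for variant, identifier in enumerate(ids_k):
                records.append(CandidateRecord(
                    identifier=identifier,
                    structure_key=_KeyFactory.full_key(skeletons[k], variant),
                    monoisotopic_mass=float(masses[k]),
                    reference_count=int(refcounts[k]),
                    db_presence=dbs,
                    descriptor=float(descriptors[k]),
                ))

        rt = cfg.rt_slope * descriptors[0] + cfg.rt_intercept + rng.normal(0, cfg.rt_noise_sd)
        challenge = ChallengeSpec(
            challenge_id=cid,
            ion_mode=str(modes[idx]),
            solution_key=_KeyFactory.full_key(solution_skeleton, 0),
            retention_time=float(rt),
            candidates=records,
        )
        challenge.verify_solution_present()
        challenges.append(challenge)

    train_desc = rng.normal(cfg.descriptor_mean, cfg.descriptor_sd, size=cfg.n_rt_training)
    train_rt = (cfg.rt_slope * train_desc + cfg.rt_intercept
                + rng.normal(0, cfg.rt_noise_sd, size=cfg.n_rt_training))
    rt_training = list(zip(train_desc.tolist(), train_rt.tolist()))
    return Contest(config=cfg, challenges=challenges, rt_training=rt_training)


def generate_submissions(
    contest: Contest,
    profiles: Sequence[MethodProfile],
    seed: int,
) -> dict[str, dict[str, SubmissionEntry]]:
    """Simulate participant submissions for every method profile.

    Per covered challenge, the true skeleton's score is drawn from
    Beta(α, 1) and each decoy skeleton's score from Uniform(0, 1), so the
    true candidate's score quantile is Beta(α, 1) by construction; all
    stereoisomer rows of a skeleton share its score (methods cannot
    distinguish stereoisomers). With probability ``tie_prob`` the challenge's
    scores are quantized to two decimals, creating ties. ``top_k_truncation``
    keeps only the k highest-scoring rows. Returns
    ``{entry_name: {challenge_id: SubmissionEntry}}``; uncovered challenges
    are simply absent.
    """
    rng = _rng(seed, 1)
    out: dict[str, dict[str, SubmissionEntry]] = {}
    for profile in profiles:
        per_challenge: dict[str, SubmissionEntry] = {}
        for challenge in contest.challenges:
            if rng.random() >= profile.coverage:
                continue
            skeletons: list[str] = []
            seen: set[str] = set()
            for rec in challenge.candidates:
                if rec.skeleton_key not in seen:
                    seen.add(rec.skeleton_key)
                    skeletons.append(rec.skeleton_key)
            solution = challenge.solution_skeleton
            scores = dict(zip(skeletons, rng.uniform(size=len(skeletons)).tolist()))
            scores[solution] = float(rng.beta(profile.quality, 1.0))
            if rng.random() < profile.tie_prob:
                scores = {s: round(v, 2) for s, v in scores.items()}
            rows = [
                ScoredCandidate(rec.structure_key, scores[rec.skeleton_key],
                                rec.skeleton_key)
                for rec in challenge.candidates
            ]
            if profile.top_k_truncation is not None:
                rows.sort(key=lambda r: -r.score)
                rows = rows[: profile.top_k_truncation]
            per_challenge[challenge.challenge_id] = SubmissionEntry(
                participant=profile.name,
                entry_name=profile.name,
                challenge_id=challenge.challenge_id,
                scored_candidates=rows,
            )
        out[profile.name] = per_challenge
    return out


def generate_library_spectra(
    contest: Contest,
    seed: int,
    noise: Optional[SpectrumNoise] = None,
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Per solution, a reference library spectrum and a noisy query variant.

    The reference has 5–30 random peaks below the precursor m/z (solution
    mass plus/minus a proton by ion mode) and carries the solution's skeleton
    key; the query jitters every m/z by Gaussian ppm-scale noise and every
    intensity by lognormal noise. Returns ``(library, queries)``.
    """
    if noise is None:
        noise = SpectrumNoise()
    rng = _rng(seed, 2)
    library: list[Spectrum] = []
    queries: list[Spectrum] = []
    for challenge in contest.challenges:
        mass = challenge.candidates[0].monoisotopic_mass or 300.0
        sign = 1.0 if challenge.ion_mode == "positive" else -1.0
        precursor = mass + sign * _PROTON_MASS
        n_peaks = int(rng.integers(5, 31))
        mz = np.sort(rng.uniform(50.0, precursor, size=n_peaks))
        intensity = rng.exponential(1.0, size=n_peaks)
        intensity *= float(rng.uniform(1e5, 1e7)) / intensity.max()
        library.append(Spectrum(
            mz=mz,
            intensity=intensity,
            precursor_mz=precursor,
            ion_mode=challenge.ion_mode,
            spectrum_id=f"lib-{challenge.challenge_id}",
            structure_key=challenge.solution_skeleton,
        ))
        q_mz = mz * (1.0 + rng.normal(0.0, noise.mz_ppm_sd, size=n_peaks) * 1e-6)
        q_int = intensity * np.exp(rng.normal(0.0, noise.intensity_cv, size=n_peaks))
        queries.append(Spectrum(
            mz=np.sort(q_mz),
            intensity=q_int[np.argsort(q_mz)],
            precursor_mz=precursor,
            ion_mode=challenge.ion_mode,
            spectrum_id=challenge.challenge_id,
        ))
    return library, queries


# ---------------------------------------------------------------------------
# On-disk contest layout
# ---------------------------------------------------------------------------

def write_contest(contest: Contest, outdir) -> None:
    """Write a contest in the standard exchange formats.

    Layout: ``solutions.csv``, ``candidates/<challenge_id>.csv``,
    ``rt_training.csv`` and ``manifest.json`` (config + seed) under *outdir*.
    """
    outdir = Path(outdir)
    (outdir / "candidates").mkdir(parents=True, exist_ok=True)
    write_solutions(contest.solutions.values(), outdir / "solutions.csv")
    for challenge in contest.challenges:
        write_candidates(challenge.candidates,
                         outdir / "candidates" / f"{challenge.challenge_id}.csv")
    with (outdir / "rt_training.csv").open("w", encoding="utf-8") as fh:
        fh.write("descriptor,rt_min\n")
        for desc, rt in contest.rt_training:
            fh.write(f"{desc!r},{rt!r}\n")
    manifest = {"config": dataclasses.asdict(contest.config),
                "seed": contest.config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_contest(outdir) -> Contest:
    """Read back a contest written by :func:`write_contest`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    raw_cfg = manifest["config"]
    raw_cfg["candidate_count_dist"] = tuple(raw_cfg["candidate_count_dist"])
    raw_cfg["db_names"] = tuple(raw_cfg["db_names"])
    cfg = SyntheticContestConfig(**raw_cfg)
    solutions = read_solutions(outdir / "solutions.csv")
    challenges = []
    for cid, sol in sorted(solutions.items()):
        candidates = read_candidates(outdir / "candidates" / f"{cid}.csv")
        challenges.append(ChallengeSpec(
            challenge_id=cid,
            ion_mode=sol.ion_mode,
            solution_key=sol.inchikey,
            retention_time=sol.retention_time,
            candidates=candidates,
        ))
    rt_training = []
    rt_path = outdir / "rt_training.csv"
    if rt_path.exists():
        for line in rt_path.read_text().splitlines()[1:]:
            desc, rt = line.split(",")
            rt_training.append((float(desc), float(rt)))
    return Contest(config=cfg, challenges=challenges, rt_training=rt_training)


def write_submission_set(
    submissions: dict[str, dict[str, SubmissionEntry]],
    outdir,
    pattern: str = SUBMISSION_FILENAME_PATTERN,
) -> None:
    """Write submissions as ``<outdir>/<entry>/<entry>-challenge-<id>.txt``."""
    outdir = Path(outdir)
    for entry_name, per_challenge in submissions.items():
        entry_dir = outdir / entry_name
        entry_dir.mkdir(parents=True, exist_ok=True)
        for cid, entry in per_challenge.items():
            short_id = cid.removeprefix("challenge-")
            filename = pattern.format(entry=entry_name, challenge_id=short_id)
            write_submission(entry, entry_dir / filename)


def write_spectra_set(spectra: Sequence[Spectrum], outdir, stem: str = "spectra") -> None:
    """Write spectra as one MGF plus a spectrum-id → skeleton key CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mgf(spectra, outdir / f"{stem}.mgf")
    with (outdir / f"{stem}_keys.csv").open("w", encoding="utf-8") as fh:
        fh.write("spectrum_id,skeleton_key\n")
        for s in spectra:
            fh.write(f"{s.spectrum_id},{s.structure_key or ''}\n")
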