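import numpy as np
import pytest

from molcontest import (
    MethodProfile,
    SubmissionEntry,
    ScoredCandidate,
    SyntheticContestConfig,
    generate_contest,
)


_DIGITS_TO_LETTERS = str.maketrans("0123456789", "ABCDEFGHIJ")


def make_key(skeleton: str, second: str = "UHFFFAOYSA", last: str = "N") -> str:
    """Pad a short uppercase stem into a syntactically valid InChIKey."""
    stem = skeleton.upper().translate(_DIGITS_TO_LETTERS)
    return f"{stem.ljust(14, 'Q')[:14]}-{second}-{last}"


def make_entry(scores: dict[str, float], challenge_id: str = "challenge-1",
               name: str = "method") -> SubmissionEntry:
    """Submission whose candidates are full keys derived from skeleton stems."""
    return SubmissionEntry(
        participant=name,
        entry_name=name,
        challenge_id=challenge_id,
        scored_candidates=[
            ScoredCandidate(make_key(stem), score, make_key(stem)[:14])
            for stem, score in scores.items()
        ],
    )


@pytest.fixture(scope="session")
def small_contest():
    """A compact deterministic contest shared by read-only tests."""
    cfg = SyntheticContestConfig(
        n_challenges=24, candidate_count_dist=(3.0, 0.5), seed=42
    )
    return generate_contest(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def default_profiles():
    return [
        MethodProfile("strong", quality=4.0),
        MethodProfile("medium", quality=2.0),
        MethodProfile("weak", quality=1.0),
    ]
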