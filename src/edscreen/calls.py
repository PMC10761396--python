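"""Activity-call vocabulary shared by every stage of the screen.

Every judgement about a chemical — an in vitro assay result, an in silico
model prediction, a ToxCast-style reference classification, an overall
weight-of-evidence conclusion — is expressed as one :class:`ActivityCall`.
The vocabulary is deliberately small: two positive grades (``positive`` and
``weak_positive``, distinct for display but equivalent for voting), a
``negative``, an ``inconclusive`` for judgements that were made but did not
resolve, ``out_of_domain`` for models that declined to predict a chemical
outside their applicability domain, and ``not_evaluated`` for cells that
were never attempted.
"""

from __future__ import annotations

import enum
import math


class ActivityCall(str, enum.Enum):
    """Ordinal categorical activity state for a chemical/endpoint judgement."""

    POSITIVE = "positive"
    WEAK_POSITIVE = "weak_positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"
    OUT_OF_DOMAIN = "out_of_domain"
    NOT_EVALUATED = "not_evaluated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Calls that count as a positive for voting and scoring purposes.
POSITIVE_FAMILY = frozenset({ActivityCall.POSITIVE, ActivityCall.WEAK_POSITIVE})

#: Calls that carry a usable sign (a "distinct" call in efficiency terms).
DISTINCT_CALLS = POSITIVE_FAMILY | {ActivityCall.NEGATIVE}


def parse_call(token: str) -> ActivityCall:
    """Parse a call token from a delimited file; raise on unknown tokens."""
    try:
        return ActivityCall(token.strip().lower())
    except ValueError:
        raise ValueError(f"unrecognised activity-call token: {token!r}") from None


def is_distinct(call: ActivityCall) -> bool:
    """True when the call carries a usable sign (positive family or negative)."""
    return call in DISTINCT_CALLS


def call_sign(call: ActivityCall) -> int | None:
    """+1 for the positive family, -1 for negative, None otherwise."""
    if call in POSITIVE_FAMILY:
        return 1
    if call is ActivityCall.NEGATIVE:
        return -1
    return None


def flip_call(call: ActivityCall) -> ActivityCall:
    """Swap the sign of a distinct call; non-distinct calls pass through.

    ``weak_positive`` flips to ``negative``; ``negative`` flips to
    ``positive`` (the weak grade has no negative counterpart).
    """
    if call in POSITIVE_FAMILY:
        return ActivityCall.NEGATIVE
    if call is ActivityCall.NEGATIVE:
        return ActivityCall.POSITIVE
    return call


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1).

    Percent cells throughout the screen use this convention: 87.5 -> 88,
    62.5 -> 63, 85.7 -> 86.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.floor(x + 0.5))
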