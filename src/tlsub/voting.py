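"""Multi-source majority voting.

A single source-domain transfer can be thrown off by accidental structure in
that one domain.  The pipeline therefore trains one classifier per labeled
source domain (by default five, at clonal proportions 5%-30%) and combines
their per-call predictions with a strict majority vote: a label wins only
with strictly more than half of all votes, otherwise the call is *rejected*
(possible only for even vote counts in the binary case).

The winner is found with the Boyer-Moore majority-vote linear scan followed
by a verification count, which is exactly the strict-majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Final, Sequence

import numpy as np

from tlsub.errors import ConfigurationError, DimensionError

#: Sentinel outcome when no label reaches a strict majority.
REJECT: Final[str] = "reject"

#: Default number of source domains combined by the vote.  Odd counts are
#: recommended: a strict binary majority then always exists and no call is
#: ever rejected.  The canonical choice is the five fixed-proportion panels
#: in the 5%-30% range that do not share the target's proportion.
DEFAULT_N_DOMAINS: Final[int] = 5

#: Policies for resolving rejected (tied) calls.
REJECT_POLICIES: Final[tuple[str, ...]] = ("keep", "drop", "flag")


@dataclass
class VoteTable:
    """Binary predictions of each source-domain classifier for each call."""

    votes: np.ndarray  # (m calls, a domains), entries in {0, 1}
    domain_tags: Sequence[float | str]

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.ndim != 2 or self.votes.shape[1] < 1:
            raise DimensionError("votes must be (m, a) with a >= 1")
        if not np.isin(self.votes, (0, 1)).all():
            raise ConfigurationError("votes must be binary")
        if len(self.domain_tags) != self.votes.shape[1]:
            raise DimensionError("domain_tags length must equal the vote columns")


def majority_vote(votes_for_call: Sequence[int] | np.ndarray) -> int | str:
    """Strict-majority winner of one call's votes, or :data:`REJECT`.

    Boyer-Moore linear scan to find the only possible majority candidate,
    then a verification pass checking it holds strictly more than half of
    all votes.
    """
    votes = list(votes_for_call)
    if len(votes) == 0:
        raise ConfigurationError("empty vote vector")
    candidate, count = votes[0], 0
    for v in votes:
        if count == 0:
            candidate = v
        count += 1 if v == candidate else -1
    if sum(v == candidate for v in votes) * 2 > len(votes):
        return int(candidate)
    return REJECT


def aggregate(
    table: VoteTable, reject_policy: str = "flag"
) -> tuple[np.ndarray, np.ndarray]:
    """Apply :func:`majority_vote` per call and resolve rejected rows.

    Returns ``(final_labels, ambiguous_flags)``.  Rejected rows are flagged
    under every policy; the policy decides their label: ``keep`` and
    ``flag`` retain the call (label 1, ``flag`` additionally marking it for
    FILTER annotation downstream), ``drop`` removes it (label 0).
    """
    if reject_policy not in REJECT_POLICIES:
        raise ConfigurationError(f"reject_policy must be one of {REJECT_POLICIES}")
    m = table.votes.shape[0]
    labels = np.zeros(m, dtype=int)
    flags = np.zeros(m, dtype=bool)
    for i in range(m):
        outcome = majority_vote(table.votes[i])
        if outcome == REJECT:
            flags[i] = True
            labels[i] = 0 if reject_policy == "drop" else 1
        else:
            labels[i] = outcome
    return labels, flags
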