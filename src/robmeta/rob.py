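"""Domain-level risk-of-bias judgments and their aggregation to overall ratings.

Non-randomized studies of interventions are judged on a four-level ordinal
scale (low < moderate < serious < critical) across seven chronologically
organized bias domains: confounding and participant selection
(pre-intervention), measurement of the intervention (at intervention), and
departures from the intended intervention, missing data, outcome measurement,
and selective reporting of results (post-intervention).

The overall study rating follows the domain-based rule: a study is *low* only
when every domain is low; *moderate* when all domains are low or moderate with
at least one moderate; *serious* when at least one domain is serious but none
critical; and *critical* when any domain is critical.  Reviewers additionally
hold discretion to treat concerns in multiple domains as additive — several
moderate judgments may justify an overall *serious* rating, and several serious
judgments an overall *critical* one.  That discretion is formalized here as a
configurable :class:`EscalationPolicy` counting domains at exactly the
triggering level.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class RoBLevel(enum.IntEnum):
    """Ordinal risk-of-bias judgment level, totally ordered."""

    low = 0
    moderate = 1
    serious = 2
    critical = 3

    @classmethod
    def parse(cls, value: "RoBLevel | str | int") -> "RoBLevel":
        if isinstance(value, RoBLevel):
            return value
        if isinstance(value, str):
            try:
                return cls[value.strip().lower()]
            except KeyError:
                raise ValueError(f"unknown risk-of-bias level: {value!r}") from None
        return cls(value)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The seven bias domains in chronological order (pre-intervention,
#: at intervention, post-intervention).
DOMAINS: tuple[str, ...] = (
    "confounding",
    "selection",
    "measurement_intervention",
    "departures",
    "missing_data",
    "measurement_outcome",
    "reported_result",
)


class IncompleteProfileError(ValueError):
    """A study profile is missing one or more of the seven domains."""


@dataclass(frozen=True)
class RoBProfile:
    """One study's seven domain judgments plus an optional consensus overall.

    ``overall`` holds a published consensus rating when the profile was read
    from a table; derived ratings come from :func:`aggregate_overall` and are
    never written back into the profile.
    """

    study_id: str
    domains: Mapping[str, RoBLevel]
    overall: RoBLevel | None = None

    def __post_init__(self) -> None:
        parsed = {k: RoBLevel.parse(v) for k, v in dict(self.domains).items()}
        missing = [d for d in DOMAINS if d not in parsed]
        extra = [d for d in parsed if d not in DOMAINS]
        if missing or extra:
            raise IncompleteProfileError(
                f"profile for {self.study_id!r}: missing domains {missing}, "
                f"unexpected domains {extra}"
            )
        # normalize to chronological domain order
        object.__setattr__(self, "domains", {d: parsed[d] for d in DOMAINS})
        if self.overall is not None:
            object.__setattr__(self, "overall", RoBLevel.parse(self.overall))

    def levels(self) -> tuple[RoBLevel, ...]:
        return tuple(self.domains[d] for d in DOMAINS)


@dataclass(frozen=True)
class EscalationPolicy:
    """Formalization of the multi-domain escalation discretion.

    ``moderate_to_serious_threshold`` moderate-domain judgments escalate an
    otherwise-moderate overall to serious; likewise for serious → critical.
    A single domain never escalates, so thresholds must be at least 2.  The
    default of 3 reproduces every published consensus overall in the two
    re-analyzed reviews (studies with two moderates stay moderate, studies
    with three or four become serious).
    """

    moderate_to_serious_threshold: int = 3
    serious_to_critical_threshold: int = 3
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.moderate_to_serious_threshold < 2 or self.serious_to_critical_threshold < 2:
            raise ValueError("escalation thresholds must be >= 2")


DEFAULT_POLICY = EscalationPolicy()


def aggregate_overall(
    profile: RoBProfile, policy: EscalationPolicy = DEFAULT_POLICY
) -> RoBLevel:
    """Derive a study's overall rating from its seven domain judgments.

    Base rule: the overall equals the maximum domain level (all-low gives low;
    otherwise at least one domain sits at the maximum).  With escalation
    enabled, a moderate base with at least ``moderate_to_serious_threshold``
    moderate domains becomes serious, and a serious base with at least
    ``serious_to_critical_threshold`` serious domains becomes critical.
    Escalation is applied once; a moderate base never cascades to critical.
    """
    levels = profile.levels()
    base = max(levels)
    if not policy.enabled:
        return base
    counts = Counter(levels)
    if base == RoBLevel.moderate and counts[RoBLevel.moderate] >= policy.moderate_to_serious_threshold:
        return RoBLevel.serious
    if base == RoBLevel.serious and counts[RoBLevel.serious] >= policy.serious_to_critical_threshold:
        return RoBLevel.critical
    return base


@dataclass
class Classification:
    """Derived overall ratings, with concordance against any consensus values."""

    derived: dict[str, RoBLevel]
    consensus: dict[str, RoBLevel] = field(default_factory=dict)

    @property
    def disagreements(self) -> dict[str, tuple[RoBLevel, RoBLevel]]:
        """study_id -> (derived, consensus) where the two differ."""
        return {
            sid: (self.derived[sid], cons)
            for sid, cons in self.consensus.items()
            if self.derived[sid] != cons
        }

    @property
    def concordant(self) -> bool:
        return not self.disagreements

    def __getitem__(self, study_id: str) -> RoBLevel:
        return self.derived[study_id]

    def __len__(self) -> int:
        return len(self.derived)

    def items(self):
        return self.derived.items()


def classify_studies(
    profiles: Iterable[RoBProfile], policy: EscalationPolicy = DEFAULT_POLICY
) -> Classification:
    """Apply :func:`aggregate_overall` to each profile.

    Consensus overall values present on the input profiles are retained so the
    result can report agreement between the algorithmic rule and the published
    judgment.
    """
    derived: dict[str, RoBLevel] = {}
    consensus: dict[str, RoBLevel] = {}
    for p in profiles:
        derived[p.study_id] = aggregate_overall(p, policy)
        if p.overall is not None:
            consensus[p.study_id] = p.overall
    return Classification(derived=derived, consensus=consensus)


def count_by_level(classification: Classification | Mapping[str, RoBLevel]) -> dict[RoBLevel, int]:
    """Tally studies per overall level; all four levels always appear."""
    items = classification.derived if isinstance(classification, Classification) else classification
    counts = {level: 0 for level in RoBLevel}
    for lvl in items.values():
        counts[RoBLevel.parse(lvl)] += 1
    return counts
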