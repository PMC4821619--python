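"""Risk-of-bias-stratified sensitivity re-analysis.

A scenario names the maximum acceptable overall risk-of-bias level; studies
rated above it are excluded and the meta-analysis re-run.  Two standard
scenarios mirror common practice: *Analysis A* drops studies with serious or
critical overall RoB (retaining low and moderate), and *Analysis B*
additionally drops moderate studies (retaining only low).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .data import EffectSet
from .pooling import PooledResult, SubgroupResult, pool_by_subgroup
from .rob import Classification, RoBLevel


class UnclassifiedStudyError(KeyError):
    """A study in the effect set has no overall risk-of-bias classification."""


@dataclass(frozen=True)
class Scenario:
    """An exclusion rule: retain studies rated at or below ``max_level``."""

    name: str
    max_level: RoBLevel

    @classmethod
    def analysis_A(cls) -> "Scenario":
        """Exclude serious and critical overall RoB."""
        return cls(name="analysis_A", max_level=RoBLevel.moderate)

    @classmethod
    def analysis_B(cls) -> "Scenario":
        """Exclude moderate, serious and critical overall RoB."""
        return cls(name="analysis_B", max_level=RoBLevel.low)

    @classmethod
    def custom(cls, max_level: RoBLevel | str) -> "Scenario":
        return cls(name="custom", max_level=RoBLevel.parse(max_level))


def _overalls(classification: Classification | Mapping[str, RoBLevel]) -> Mapping[str, RoBLevel]:
    if isinstance(classification, Classification):
        return classification.derived
    return classification


def filter_by_rob(
    effect_set: EffectSet,
    classification: Classification | Mapping[str, RoBLevel],
    max_level: RoBLevel | str,
) -> EffectSet:
    """Retain exactly the effects whose study is rated at or below max_level.

    Order is preserved.  Every study in the set must be classified.
    """
    levels = _overalls(classification)
    max_level = RoBLevel.parse(max_level)
    missing = [sid for sid in effect_set.study_ids if sid not in levels]
    if missing:
        raise UnclassifiedStudyError(
            f"no risk-of-bias classification for: {sorted(set(missing))}"
        )
    keep = {sid for sid in effect_set.study_ids if levels[sid] <= max_level}
    return effect_set.restrict(keep)


@dataclass(frozen=True)
class SensitivityReport:
    """Paired original/post-exclusion syntheses for one effect set.

    ``no_change`` is judged at two-decimal display precision (estimate and
    both CI bounds identical before and after); ``delta_log`` carries the
    full-precision difference.  ``significance_change`` tracks whether the
    95% CI excluding the null was gained, lost or unchanged by the exclusion.
    """

    label: str
    scenario: Scenario
    original: SubgroupResult
    post: SubgroupResult | None
    excluded: tuple[tuple[str, RoBLevel], ...]
    n_original: int
    n_post: int

    @property
    def delta_log(self) -> float | None:
        if self.post is None:
            return None
        return self.post.overall.pooled_log - self.original.overall.pooled_log

    @property
    def no_change(self) -> bool:
        if self.post is None:
            return False
        a, b = self.original.overall, self.post.overall
        return a.display() == b.display()

    @property
    def significance_change(self) -> str:
        if self.post is None:
            return "not_estimable"
        before, after = self.original.overall.significant, self.post.overall.significant
        if before == after:
            return "unchanged"
        return "gained" if after else "lost"

    def to_dict(self) -> dict:
        def pr(r: PooledResult) -> dict:
            return {
                "k": r.k, "estimate": r.estimate, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "tau2": r.tau2, "i2": r.i2, "Q": r.Q,
            }

        return {
            "label": self.label,
            "scenario": self.scenario.name,
            "max_level": self.scenario.max_level.name,
            "n_original": self.n_original,
            "n_post": self.n_post,
            "excluded": [(sid, lvl.name) for sid, lvl in self.excluded],
            "original": pr(self.original.overall),
            "post": pr(self.post.overall) if self.post is not None else None,
            "delta_log": self.delta_log,
            "no_change": self.no_change,
            "significance_change": self.significance_change,
        }


def run_sensitivity(
    effect_set: EffectSet,
    classification: Classification | Mapping[str, RoBLevel],
    scenario: Scenario,
) -> SensitivityReport:
    """Pool before and after excluding studies above the scenario's level."""
    levels = _overalls(classification)
    filtered = filter_by_rob(effect_set, classification, scenario.max_level)
    kept = set(filtered.study_ids)
    excluded = tuple(
        (sid, levels[sid])
        for sid in dict.fromkeys(effect_set.study_ids)  # unique, order kept
        if sid not in kept
    )
    original = pool_by_subgroup(effect_set)
    post = pool_by_subgroup(filtered) if len(filtered) > 0 else None
    return SensitivityReport(
        label=effect_set.label,
        scenario=scenario,
        original=original,
        post=post,
        excluded=excluded,
        n_original=len(effect_set),
        n_post=len(filtered),
    )


def heterogeneity_trace(
    effect_sets: EffectSet | Mapping[str, EffectSet],
    classification: Classification | Mapping[str, RoBLevel],
    scenarios: Iterable[Scenario],
) -> pd.DataFrame:
    """I^2 of the overall synthesis per effect set per exclusion scenario.

    Accepts a single EffectSet or a mapping label -> EffectSet; the returned
    frame has one row per (label, scenario) with k, Q and I^2.
    """
    if isinstance(effect_sets, EffectSet):
        effect_sets = {effect_sets.label: effect_sets}
    rows = []
    for label, es in effect_sets.items():
        for sc in scenarios:
            filtered = filter_by_rob(es, classification, sc.max_level)
            if len(filtered) == 0:
                rows.append({"label": label, "scenario": sc.name, "k": 0,
                             "Q": float("nan"), "i2": float("nan")})
                continue
            pooled = pool_by_subgroup(filtered).overall
            rows.append({"label": label, "scenario": sc.name, "k": pooled.k,
                         "Q": pooled.Q, "i2": pooled.i2})
    return pd.DataFrame(rows, columns=["label", "scenario", "k", "Q", "i2"])
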