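"""Study-level effect data: containers, validation, CSV/JSON I/O, fixtures.

Each record is one study's relative-risk estimate (odds ratio, hazard ratio,
rate ratio, incidence rate ratio or relative risk — pooled interchangeably on
the log scale, the measure label retained for reporting) for one outcome and
exposure, with its printed 95% confidence interval.  Estimates are stored
exactly as published, at two decimals; they are never re-derived from
participant counts.

Packaged fixtures encode the component-study tables of two published
systematic reviews of adverse cardiovascular drug effects:

``tzd_effects``
    31 estimates from 16 non-randomized studies of rosiglitazone versus
    pioglitazone (myocardial infarction, heart failure, overall mortality).
``cox2_effects``
    66 estimates from 20 studies of COX-2 inhibitors and nonselective NSAIDs
    versus non-use, across 8 drug exposure groups.  (A 21st study appears in
    the corresponding risk-of-bias table but published no per-drug estimate.)
``tzd_rob`` / ``cox2_rob``
    The consensus seven-domain risk-of-bias judgments for the 16 and 21
    component studies, with the published overall ratings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .rob import DOMAINS, RoBLevel, RoBProfile

DESIGNS = ("cohort", "case_control")
MEASURES = ("OR", "HR", "RR", "IRR", "ReR")

EFFECT_COLUMNS = (
    "study_id",
    "design",
    "measure",
    "outcome",
    "exposure",
    "estimate",
    "ci_low",
    "ci_high",
)
OPTIONAL_EFFECT_COLUMNS = ("ci_level", "adjusted")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates the effect-record invariants; the message names it."""


class DuplicateStudyError(ValueError):
    """Two rows share (study_id, outcome, exposure)."""


@dataclass(frozen=True)
class StudyEffect:
    """One study × outcome × exposure relative-risk estimate with its CI.

    The invariant ``ci_low <= estimate <= ci_high`` is enforced with a
    tolerance of one unit in the second decimal, since published values are
    independently rounded.
    """

    study_id: str
    design: str
    measure: str
    outcome: str
    exposure: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    adjusted: bool = True

    _ROUNDING_TOL = 0.01

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValidationError(
                f"{self.study_id}: design must be one of {DESIGNS}, got {self.design!r}"
            )
        if self.measure not in MEASURES:
            raise ValidationError(
                f"{self.study_id}: measure must be one of {MEASURES}, got {self.measure!r}"
            )
        for name in ("estimate", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{self.study_id}: {name} must be finite and > 0, got {v!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(
                f"{self.study_id}: ci_level must lie strictly in (0, 1), got {self.ci_level}"
            )
        tol = self._ROUNDING_TOL
        if not (self.ci_low <= self.estimate + tol and self.estimate <= self.ci_high + tol):
            raise ValidationError(
                f"{self.study_id}: estimate {self.estimate} outside CI "
                f"({self.ci_low}, {self.ci_high})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.study_id, self.outcome, self.exposure)


@dataclass
class EffectSet:
    """An ordered collection of study effects — the unit of pooling.

    ``rob`` optionally maps study_id to a full seven-domain
    :class:`~robmeta.rob.RoBProfile` for the joined risk-of-bias table.
    """

    label: str
    effects: list[StudyEffect] = field(default_factory=list)
    rob: dict[str, RoBProfile] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.effects:
            if e.key in seen:
                raise DuplicateStudyError(
                    f"duplicate (study_id, outcome, exposure): {e.key}"
                )
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.effects)

    def __iter__(self) -> Iterator[StudyEffect]:
        return iter(self.effects)

    @property
    def study_ids(self) -> list[str]:
        return [e.study_id for e in self.effects]

    def select(self, outcome: str | None = None, exposure: str | None = None,
               design: str | None = None) -> "EffectSet":
        """Subset by outcome, exposure and/or design; order preserved."""
        kept = [
            e
            for e in self.effects
            if (outcome is None or e.outcome == outcome)
            and (exposure is None or e.exposure == exposure)
            and (design is None or e.design == design)
        ]
        parts = [p for p in (outcome, exposure, design) if p is not None]
        label = "/".join([self.label, *parts]) if parts else self.label
        rob = None
        if self.rob is not None:
            ids = {e.study_id for e in kept}
            rob = {sid: p for sid, p in self.rob.items() if sid in ids}
        return EffectSet(label=label, effects=kept, rob=rob)

    def restrict(self, study_ids: Iterable[str]) -> "EffectSet":
        ids = set(study_ids)
        return replace(
            self,
            effects=[e for e in self.effects if e.study_id in ids],
            rob=None if self.rob is None else {s: p for s, p in self.rob.items() if s in ids},
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    **{c: getattr(e, c) for c in EFFECT_COLUMNS},
                    "ci_level": e.ci_level,
                    "adjusted": e.adjusted,
                }
                for e in self.effects
            ],
            columns=list(EFFECT_COLUMNS) + list(OPTIONAL_EFFECT_COLUMNS),
        )


def _effects_from_dataframe(df: pd.DataFrame, label: str) -> EffectSet:
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    effects: list[StudyEffect] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            effects.append(
                StudyEffect(
                    study_id=str(row["study_id"]),
                    design=str(row["design"]),
                    measure=str(row["measure"]),
                    outcome=str(row["outcome"]),
                    exposure=str(row["exposure"]),
                    estimate=float(row["estimate"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    ci_level=float(row["ci_level"]) if "ci_level" in df.columns else 0.95,
                    adjusted=_parse_bool(row["adjusted"]) if "adjusted" in df.columns else True,
                )
            )
        except ValidationError as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValidationError("; ".join(errors))
    return EffectSet(label=label, effects=effects)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def read_effects_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> EffectSet:
    """Read a UTF-8 comma-separated effects table into a validated EffectSet.

    ``schema`` optionally maps the canonical column names to the names used in
    the file.  Rows violating the record invariants are rejected with their
    row numbers; duplicated (study_id, outcome, exposure) keys raise
    :class:`DuplicateStudyError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"study_id": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return _effects_from_dataframe(df, label=path.stem)


def write_effects_csv(effect_set: EffectSet, path: str | Path) -> None:
    df = effect_set.to_dataframe()
    df["adjusted"] = df["adjusted"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def effects_to_json(effect_set: EffectSet, path: str | Path | None = None) -> str:
    payload = {
        "label": effect_set.label,
        "effects": effect_set.to_dataframe().to_dict(orient="records"),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Risk-of-bias tables


def read_rob_csv(path: str | Path) -> list[RoBProfile]:
    """Read a rob.csv (study_id + seven domain columns [+ overall])."""
    df = pd.read_csv(Path(path), dtype=str)
    missing = [c for c in ("study_id", *DOMAINS) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    profiles = []
    for _, row in df.iterrows():
        overall = row["overall"] if "overall" in df.columns and pd.notna(row["overall"]) else None
        profiles.append(
            RoBProfile(
                study_id=str(row["study_id"]),
                domains={d: RoBLevel.parse(row[d]) for d in DOMAINS},
                overall=RoBLevel.parse(overall) if overall is not None else None,
            )
        )
    return profiles


def write_rob_csv(profiles: Sequence[RoBProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"study_id": p.study_id, **{d: p.domains[d].name for d in DOMAINS}}
        row["overall"] = p.overall.name if p.overall is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def rob_to_json(profiles: Sequence[RoBProfile], path: str | Path | None = None) -> str:
    payload = [
        {
            "study_id": p.study_id,
            "domains": {d: p.domains[d].name for d in DOMAINS},
            "overall": p.overall.name if p.overall is not None else None,
        }
        for p in profiles
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Packaged fixtures

FIXTURES = ("tzd_effects", "cox2_effects", "tzd_rob", "cox2_rob")


def _fixture_path(name: str):
    return resources.files("robmeta.fixtures").joinpath(f"{name}.csv")


def load_fixture(name: str) -> EffectSet | list[RoBProfile]:
    """Load a packaged table; effect fixtures return an EffectSet with its
    risk-of-bias profiles joined, rob fixtures a list of RoBProfile."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    with resources.as_file(_fixture_path(name)) as path:
        if name.endswith("_rob"):
            return read_rob_csv(path)
        effect_set = read_effects_csv(path)
    effect_set.label = name.removesuffix("_effects")
    rob_name = name.replace("_effects", "_rob")
    profiles = load_fixture(rob_name)
    effect_set.rob = {p.study_id: p for p in profiles}
    return effect_set
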