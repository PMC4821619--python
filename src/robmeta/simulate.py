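"""Seeded generators for synthetic study-level data.

The effect generator draws study-specific true log relative risks
theta_i ~ Normal(mu + bias[level_i], tau2) — the standard additive
random-effects structure, with an optional risk-of-bias-dependent shift that
models high-RoB studies systematically exaggerating (or attenuating) the
effect — then observed log effects y_i ~ Normal(theta_i, se_i^2) with
per-study standard errors drawn uniformly from a range spanning those seen in
published pharmacoepidemiological tables.  Confidence limits are reconstructed
as exp(y_i +/- z se_i), so generated records are exactly the shape the
pooling pipeline consumes, and the generating truth is retained alongside.

All generators take an explicit seed and use a single local NumPy generator;
no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .agreement import RatingPair
from .data import EffectSet, StudyEffect
from .pooling import z_quantile
from .rob import DOMAINS, RoBLevel, RoBProfile

#: Overall-level distribution matching the mix observed across the 37
#: component studies of the two re-analyzed reviews (8 low, 18 moderate,
#: 9 serious, 2 critical).
DEFAULT_LEVEL_PROBS: dict[RoBLevel, float] = {
    RoBLevel.low: 8 / 37,
    RoBLevel.moderate: 18 / 37,
    RoBLevel.serious: 9 / 37,
    RoBLevel.critical: 2 / 37,
}


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class MetaSimConfig:
    """Configuration for :func:`simulate_effect_set`.

    mu is the true log relative risk; tau2 the between-study variance on the
    log scale; se_range the uniform support of per-study standard errors
    (default 0.05–0.35, spanning the published fixtures); design_prob the
    probability a study is a cohort (about half the published studies are);
    bias_shift an additive log-scale bias per overall risk-of-bias level
    (zero by default); level_probs the distribution of overall levels.
    """

    mu: float
    tau2: float
    k: int
    se_range: tuple[float, float] = (0.05, 0.35)
    design_prob: float = 0.5
    bias_shift: Mapping[RoBLevel, float] = field(
        default_factory=lambda: {level: 0.0 for level in RoBLevel}
    )
    level_probs: Mapping[RoBLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PROBS)
    )
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ConfigError("tau2 must be >= 0")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ConfigError("se_range must be positive with lo <= hi")
        if not 0.0 <= self.design_prob <= 1.0:
            raise ConfigError("design_prob must be in [0, 1]")
        probs = [self.level_probs.get(level, 0.0) for level in RoBLevel]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("level_probs must be a distribution over the four levels")


@dataclass(frozen=True)
class SimTruth:
    """The generating parameters retained next to a simulated EffectSet."""

    mu: float
    tau2: float
    levels: Mapping[str, RoBLevel]
    theta: Mapping[str, float]


@dataclass(frozen=True)
class SimulatedEffects:
    effect_set: EffectSet
    truth: SimTruth


def simulate_effect_set(cfg: MetaSimConfig) -> SimulatedEffects:
    """Generate a seeded EffectSet with known truth.

    Per study: overall level ~ level_probs; theta_i ~ N(mu + bias[level],
    tau2); se_i ~ U(se_range); y_i ~ N(theta_i, se_i^2); the stored record is
    exp(y_i) with CI exp(y_i +/- z se_i) and a design drawn by design_prob.
    """
    rng = np.random.default_rng(cfg.seed)
    z = z_quantile(cfg.ci_level)
    level_values = list(RoBLevel)
    probs = np.array([cfg.level_probs.get(lv, 0.0) for lv in level_values])
    effects: list[StudyEffect] = []
    levels: dict[str, RoBLevel] = {}
    thetas: dict[str, float] = {}
    for i in range(cfg.k):
        sid = f"study_{i + 1:04d}"
        level = level_values[rng.choice(len(level_values), p=probs)]
        shift = cfg.bias_shift.get(level, 0.0)
        theta = cfg.mu + shift + math.sqrt(cfg.tau2) * rng.standard_normal()
        se = rng.uniform(*cfg.se_range)
        y = theta + se * rng.standard_normal()
        effects.append(
            StudyEffect(
                study_id=sid,
                design="cohort" if rng.random() < cfg.design_prob else "case_control",
                measure="RR",
                outcome="simulated",
                exposure="simulated",
                estimate=math.exp(y),
                ci_low=math.exp(y - z * se),
                ci_high=math.exp(y + z * se),
                ci_level=cfg.ci_level,
            )
        )
        levels[sid] = level
        thetas[sid] = theta
    es = EffectSet(label="simulated", effects=effects)
    return SimulatedEffects(
        effect_set=es,
        truth=SimTruth(mu=cfg.mu, tau2=cfg.tau2, levels=levels, theta=thetas),
    )


@dataclass(frozen=True)
class RaterSimConfig:
    """Configuration for :func:`simulate_rating_pairs`.

    With probability ``agreement_boost`` the two raters are forced to agree
    on a draw from the marginal; otherwise they rate independently from the
    same marginal.  agreement_boost = 0 is the chance-agreement null
    (kappa = 0 in expectation); agreement_boost = 1 gives perfect agreement.
    """

    n: int
    marginal: Sequence[float]
    agreement_boost: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        m = np.asarray(self.marginal, dtype=float)
        if (m < 0).any() or abs(m.sum() - 1.0) > 1e-9:
            raise ConfigError("marginal must be a probability distribution")
        if not 0.0 <= self.agreement_boost <= 1.0:
            raise ConfigError("agreement_boost must be in [0, 1]")


def simulate_rating_pairs(
    cfg: RaterSimConfig, categories: Sequence | None = None
) -> list[RatingPair]:
    """Generate seeded two-rater ordinal ratings with tunable agreement."""
    rng = np.random.default_rng(cfg.seed)
    m = np.asarray(cfg.marginal, dtype=float)
    if categories is None:
        categories = list(range(len(m)))
    if len(categories) != len(m):
        raise ConfigError("categories and marginal must have the same length")
    pairs = []
    for i in range(cfg.n):
        a = categories[rng.choice(len(m), p=m)]
        if rng.random() < cfg.agreement_boost:
            b = a
        else:
            b = categories[rng.choice(len(m), p=m)]
        pairs.append(RatingPair(unit_id=f"unit_{i + 1:05d}", rater1=a, rater2=b))
    return pairs


def simulate_rob_profiles(
    n: int,
    domain_level_probs: Mapping[str, Sequence[float]] | Sequence[float],
    seed: int = 0,
) -> list[RoBProfile]:
    """Generate seeded seven-domain judgment profiles.

    ``domain_level_probs`` is either one distribution over the four levels
    (applied to every domain) or a mapping domain -> distribution.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(domain_level_probs, Mapping):
        domain_level_probs = {d: domain_level_probs for d in DOMAINS}
    dists = {}
    for d in DOMAINS:
        if d not in domain_level_probs:
            raise ConfigError(f"missing distribution for domain {d!r}")
        p = np.asarray(domain_level_probs[d], dtype=float)
        if len(p) != len(RoBLevel) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"domain {d!r}: need a distribution over the four levels")
        dists[d] = p
    levels = list(RoBLevel)
    return [
        RoBProfile(
            study_id=f"study_{i + 1:04d}",
            domains={d: levels[rng.choice(len(levels), p=dists[d])] for d in DOMAINS},
        )
        for i in range(n)
    ]
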