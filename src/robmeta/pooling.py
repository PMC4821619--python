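"""Generic inverse-variance pooling of log relative risks.

Study effects y_i = ln(RR_i), with standard errors back-calculated from the
published confidence limits, se_i = (ln U_i - ln L_i) / (2 z), are combined
with weights w_i = 1/se_i^2 (fixed effect) or w*_i = 1/(se_i^2 + tau^2)
(random effects).  The between-study variance tau^2 uses the DerSimonian-Laird
moment estimator

    tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)),

where Q = sum w_i (y_i - mu_FE)^2 is Cochran's heterogeneity statistic under
the fixed-effect weights.  Heterogeneity is summarized as
I^2 = 100 * max(0, (Q - df) / Q).  Confidence intervals are z-based
(exp(mu +/- z * se)), matching the convention of the standard meta-analysis
software for which these routines are a drop-in; no small-sample (t or
Hartung-Knapp) adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import EffectSet, StudyEffect


class EmptySetError(ValueError):
    """Pooling requires at least one effect."""


class ZeroWidthCIError(ValueError):
    """A degenerate confidence interval leaves the standard error undefined."""


def z_quantile(ci_level: float) -> float:
    """Two-sided standard-normal quantile for a CI level (1.959964 at 95%)."""
    return float(stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0))


@dataclass(frozen=True)
class LogEffect:
    """A study effect on the natural-log scale with its standard error."""

    study_id: str
    y: float
    se: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.study_id}: se must be finite and > 0, got {self.se}")


def to_log_effect(effect: StudyEffect) -> LogEffect:
    """Back-calculate the log effect and its SE from the published CI.

    y = ln(estimate); se = (ln ci_high - ln ci_low) / (2 z) with z the
    standard-normal quantile at the effect's CI level.
    """
    if effect.ci_high <= effect.ci_low:
        raise ZeroWidthCIError(
            f"{effect.study_id}: CI ({effect.ci_low}, {effect.ci_high}) has "
            "non-positive width; standard error undefined"
        )
    z = z_quantile(effect.ci_level)
    se = (math.log(effect.ci_high) - math.log(effect.ci_low)) / (2.0 * z)
    return LogEffect(study_id=effect.study_id, y=math.log(effect.estimate), se=se)


@dataclass(frozen=True)
class PooledResult:
    """A pooled synthesis on the log scale with heterogeneity diagnostics.

    ``estimate``/``ci_low``/``ci_high`` are the exponentiated pooled effect
    and its z-based confidence limits; ``weights`` are normalized to sum to 1.
    ``Q``, ``tau2`` and ``i2`` always derive from the fixed-effect weights,
    whatever model produced the pooled estimate.
    """

    k: int
    pooled_log: float
    se_pooled: float
    estimate: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    tau2: float
    i2: float
    weights: Mapping[str, float]
    method: str = "dl"
    ci_level: float = 0.95

    def display(self, digits: int = 2) -> str:
        """Estimate and CI rounded for reporting, e.g. ``1.16 (1.07-1.24)``."""
        f = f"{{:.{digits}f}}"
        return f"{f.format(self.estimate)} ({f.format(self.ci_low)}-{f.format(self.ci_high)})"

    @property
    def significant(self) -> bool:
        """Whether the CI excludes the null relative risk of 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def _as_arrays(effects: Sequence[LogEffect]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(effects) == 0:
        raise EmptySetError("cannot pool an empty collection of effects")
    y = np.array([e.y for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    ids = [e.study_id for e in effects]
    return y, se, ids


def cochran_q(effects: Sequence[LogEffect]) -> float:
    """Cochran's Q under fixed-effect inverse-variance weights."""
    y, se, _ = _as_arrays(effects)
    w = 1.0 / se**2
    mu = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - mu) ** 2))


def i_squared(Q: float, df: int) -> float:
    """I^2 = 100 * max(0, (Q - df)/Q), in percent; 0 when Q = 0."""
    if df < 0:
        raise ValueError(f"df must be >= 0, got {df}")
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    if Q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (Q - df) / Q)


def dl_tau2(effects: Sequence[LogEffect]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    Truncated at zero.  With fewer than two studies the estimate is
    degenerate; 0 is returned with a warning.
    """
    y, se, _ = _as_arrays(effects)
    k = len(y)
    if k < 2:
        warnings.warn(
            "between-study variance is not estimable from fewer than 2 studies; "
            "returning 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    w = 1.0 / se**2
    sw = float(np.sum(w))
    Q = cochran_q(effects)
    denom = sw - float(np.sum(w**2)) / sw
    return max(0.0, (Q - (k - 1)) / denom)


def _pool(effects: Sequence[LogEffect], tau2: float, method: str,
          ci_level: float) -> PooledResult:
    y, se, ids = _as_arrays(effects)
    k = len(y)
    w_star = 1.0 / (se**2 + tau2)
    sw = float(np.sum(w_star))
    pooled_log = float(np.sum(w_star * y) / sw)
    se_pooled = sw**-0.5
    z = z_quantile(ci_level)
    Q = cochran_q(effects) if k > 1 else 0.0
    df = k - 1
    return PooledResult(
        k=k,
        pooled_log=pooled_log,
        se_pooled=se_pooled,
        estimate=math.exp(pooled_log),
        ci_low=math.exp(pooled_log - z * se_pooled),
        ci_high=math.exp(pooled_log + z * se_pooled),
        Q=Q,
        df=df,
        tau2=tau2,
        i2=i_squared(Q, df) if k > 1 else 0.0,
        weights=dict(zip(ids, (w_star / sw).tolist())),
        method=method,
        ci_level=ci_level,
    )


def fixed_effect_pool(effects: Sequence[LogEffect], ci_level: float = 0.95) -> PooledResult:
    """Inverse-variance fixed-effect synthesis (tau^2 = 0 by definition)."""
    return _pool(effects, tau2=0.0, method="fe", ci_level=ci_level)


def random_effects_pool(effects: Sequence[LogEffect], ci_level: float = 0.95) -> PooledResult:
    """DerSimonian-Laird random-effects synthesis.

    With a single study, or when tau^2 truncates to zero, the result
    coincides with the fixed-effect pool.
    """
    y, se, _ = _as_arrays(effects)
    if len(y) < 2:
        tau2 = 0.0
    else:
        tau2 = dl_tau2(effects)
    return _pool(effects, tau2=tau2, method="dl", ci_level=ci_level)


def pool_effect_set(effect_set: EffectSet, model: str = "re",
                    ci_level: float = 0.95) -> PooledResult:
    """Convert an EffectSet to log effects and pool it."""
    logs = [to_log_effect(e) for e in effect_set]
    if model == "re":
        return random_effects_pool(logs, ci_level=ci_level)
    if model == "fe":
        return fixed_effect_pool(logs, ci_level=ci_level)
    raise ValueError(f"model must be 're' or 'fe', got {model!r}")


@dataclass(frozen=True)
class SubgroupResult:
    """Design-stratified syntheses plus a single overall synthesis.

    Each stratum is pooled with its own tau^2; the overall column is one
    synthesis of all studies with one tau^2 (not a combination of the
    subgroup results), so its CI can be narrower than either stratum's.
    Strata with no studies are omitted from ``per_group``.
    """

    per_group: Mapping[str, PooledResult]
    overall: PooledResult
    label: str = ""

    def __post_init__(self) -> None:
        total = sum(r.k for r in self.per_group.values())
        if total != self.overall.k:
            raise ValueError(f"subgroup k's sum to {total} != overall k {self.overall.k}")


def pool_by_subgroup(effect_set: EffectSet, model: str = "re",
                     ci_level: float = 0.95) -> SubgroupResult:
    """Pool within each design stratum and once across the union."""
    per_group = {}
    for design in ("cohort", "case_control"):
        sub = effect_set.select(design=design)
        if len(sub) > 0:
            per_group[design] = pool_effect_set(sub, model=model, ci_level=ci_level)
    overall = pool_effect_set(effect_set, model=model, ci_level=ci_level)
    return SubgroupResult(per_group=per_group, overall=overall, label=effect_set.label)
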