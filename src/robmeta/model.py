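"""Model-style front end: a MetaAnalysis fitted to study-level data.

The class wraps the functional pooling layer in the fit/results idiom: build a
:class:`MetaAnalysis` from an :class:`~robmeta.data.EffectSet` or a DataFrame,
call :meth:`~MetaAnalysis.fit`, and receive a :class:`MetaAnalysisResults`
carrying the pooled estimate, its confidence interval, heterogeneity
diagnostics, per-study weights, design-stratified syntheses, and ``summary()``
/ ``plot_forest()`` presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import EffectSet, _effects_from_dataframe
from .pooling import (
    LogEffect,
    PooledResult,
    SubgroupResult,
    pool_by_subgroup,
    pool_effect_set,
    to_log_effect,
)


class MetaAnalysis:
    """Generic inverse-variance meta-analysis of relative-risk estimates.

    Parameters
    ----------
    effect_set
        The studies to pool (one outcome/exposure; use
        :meth:`EffectSet.select` first if the set mixes several).
    """

    def __init__(self, effect_set: EffectSet):
        self.effect_set = effect_set
        self.log_effects: list[LogEffect] = [to_log_effect(e) for e in effect_set]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "effects") -> "MetaAnalysis":
        """Build from a DataFrame with the standard effects columns."""
        return cls(_effects_from_dataframe(df, label=label))

    @property
    def k(self) -> int:
        return len(self.effect_set)

    def fit(self, method: str = "dl", by_design: bool = True,
            ci_level: float = 0.95) -> "MetaAnalysisResults":
        """Pool the studies.

        method 'dl' is DerSimonian-Laird random effects; 'fe' the
        inverse-variance fixed-effect model.  With ``by_design`` the cohort
        and case-control strata are additionally pooled separately (each with
        its own between-study variance).
        """
        model = {"dl": "re", "re": "re", "fe": "fe"}.get(method)
        if model is None:
            raise ValueError(f"method must be 'dl' or 'fe', got {method!r}")
        subgroups = None
        if by_design:
            subgroups = pool_by_subgroup(self.effect_set, model=model, ci_level=ci_level)
            pooled = subgroups.overall
        else:
            pooled = pool_effect_set(self.effect_set, model=model, ci_level=ci_level)
        return MetaAnalysisResults(model=self, pooled=pooled, subgroups=subgroups)


@dataclass
class MetaAnalysisResults:
    """Results of a fitted meta-analysis."""

    model: MetaAnalysis
    pooled: PooledResult
    subgroups: SubgroupResult | None = None

    @property
    def estimate(self) -> float:
        return self.pooled.estimate

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.pooled.ci_low, self.pooled.ci_high)

    def study_table(self) -> pd.DataFrame:
        """Per-study log effects, SEs and normalized pooling weights."""
        rows = []
        for e, le in zip(self.model.effect_set, self.model.log_effects):
            rows.append(
                {
                    "study_id": e.study_id,
                    "design": e.design,
                    "measure": e.measure,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "y": le.y,
                    "se": le.se,
                    "weight": self.pooled.weights[e.study_id],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.pooled
        method = "random effects (DerSimonian-Laird)" if p.method == "dl" else "fixed effect"
        lines = [
            f"Meta-analysis: {self.model.effect_set.label}",
            f"  model: {method}, generic inverse variance, log scale",
            f"  studies: {p.k}",
            f"  pooled estimate: {p.display()}  "
            f"[log {p.pooled_log:.4f} (SE {p.se_pooled:.4f})]",
            f"  heterogeneity: Q = {p.Q:.2f} (df = {p.df}), "
            f"tau2 = {p.tau2:.4f}, I2 = {p.i2:.0f}%",
        ]
        if self.subgroups is not None and len(self.subgroups.per_group) > 1:
            for name, r in self.subgroups.per_group.items():
                lines.append(f"  {name:>14}: k = {r.k:2d}  {r.display()}  I2 = {r.i2:.0f}%")
        return "\n".join(lines)

    def plot_forest(self, ax=None, digits: int = 2):
        """Forest plot: per-study estimates and CIs with the pooled diamond."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * (self.pooled.k + 2) + 1))
        table = self.study_table()
        ypos = range(len(table), 0, -1)
        for y, (_, row) in zip(ypos, table.iterrows()):
            ax.plot([row.ci_low, row.ci_high], [y, y], color="0.3", lw=1)
            ax.plot(row.estimate, y, "s", color="0.3",
                    markersize=4 + 10 * row.weight)
        p = self.pooled
        ax.plot([p.ci_low, p.ci_high], [0, 0], color="k", lw=2)
        ax.plot(p.estimate, 0, "D", color="k", markersize=7)
        ax.axvline(1.0, color="0.7", ls="--", lw=1)
        ax.set_xscale("log")
        ax.set_yticks(list(ypos) + [0])
        ax.set_yticklabels(list(table.study_id) + [f"Pooled {p.display(digits)}"])
        ax.set_xlabel("relative risk (log scale)")
        ax.set_title(self.model.effect_set.label)
        return ax

    def text_forest(self, width: int = 40) -> str:
        """Monospace forest plot for terminal output."""
        import math

        table = self.study_table()
        lows = list(table.ci_low) + [self.pooled.ci_low]
        highs = list(table.ci_high) + [self.pooled.ci_high]
        lo, hi = math.log(min(lows)), math.log(max(highs))
        span = hi - lo or 1.0

        def bar(l, e, h, char="-", mark="o"):
            cells = [" "] * width
            i0 = int((math.log(l) - lo) / span * (width - 1))
            i1 = int((math.log(h) - lo) / span * (width - 1))
            im = int((math.log(e) - lo) / span * (width - 1))
            for i in range(i0, i1 + 1):
                cells[i] = char
            cells[im] = mark
            return "".join(cells)

        name_w = max(len(s) for s in table.study_id) + 2
        lines = []
        for _, r in table.iterrows():
            lines.append(
                f"{r.study_id:<{name_w}}|{bar(r.ci_low, r.estimate, r.ci_high)}| "
                f"{r.estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            )
        p = self.pooled
        lines.append(
            f"{'POOLED':<{name_w}}|{bar(p.ci_low, p.estimate, p.ci_high, '=', '#')}| "
            f"{p.display()}"
        )
        return "\n".join(lines)
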