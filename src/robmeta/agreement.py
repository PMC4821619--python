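"""Two-rater agreement on ordinal ratings: Cohen's kappa with linear weights.

Weights follow the agreement convention, w[i][j] = 1 - |i-j|/(k-1): full
credit on the diagonal, partial credit for near-misses, none at the extreme
corners.  (The complementary disagreement convention yields the identical
kappa.)  The contingency table is always built over the full declared
category set — unobserved levels keep their zero rows and columns, which
affects the chance-expected agreement and is therefore an explicit choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .rob import RoBLevel

#: Default category set: the four ordinal risk-of-bias levels.
ROB_CATEGORIES: tuple[RoBLevel, ...] = tuple(RoBLevel)


class CategoryError(ValueError):
    """A rating falls outside the declared category set."""


class UndefinedKappaError(ZeroDivisionError):
    """Expected agreement is 1 (both raters constant on one category);
    kappa is undefined — distinct from kappa = 1."""


@dataclass(frozen=True)
class RatingPair:
    """One unit's ratings by two raters, both from the same ordered set."""

    unit_id: str
    rater1: object
    rater2: object


@dataclass(frozen=True)
class AgreementResult:
    """Weighted-kappa agreement between two raters.

    kappa = (observed - expected) / (1 - expected), with observed and
    expected the weighted proportions of agreement under the empirical joint
    distribution and under independence of the two raters' marginals.
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int
    k: int
    contingency: np.ndarray
    categories: tuple
    kappa_ci: tuple[float, float] | None = None

    def summary(self) -> str:
        lines = [
            "Weighted kappa (linear weights)",
            f"  units: {self.n}   categories: {self.k}",
            f"  observed agreement: {self.observed_agreement:.4f}",
            f"  expected agreement: {self.expected_agreement:.4f}",
            f"  kappa: {self.kappa:.4f}",
        ]
        if self.kappa_ci is not None:
            lines.append(f"  95% bootstrap CI: ({self.kappa_ci[0]:.4f}, {self.kappa_ci[1]:.4f})")
        return "\n".join(lines)


def linear_weights(k: int) -> np.ndarray:
    """The k x k linear agreement-weight matrix, w[i][j] = 1 - |i-j|/(k-1)."""
    if k < 2:
        raise ValueError(f"need at least 2 categories, got {k}")
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def contingency_table(
    pairs: Sequence[RatingPair], categories: Sequence
) -> np.ndarray:
    """k x k count matrix (rater1 rows, rater2 columns) over the full
    declared category set; zero rows/columns are retained."""
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)), dtype=int)
    for p in pairs:
        try:
            i, j = index[p.rater1], index[p.rater2]
        except KeyError as exc:
            raise CategoryError(
                f"unit {p.unit_id!r}: rating {exc.args[0]!r} not in declared "
                f"categories {tuple(categories)}"
            ) from None
        table[i, j] += 1
    return table


def _kappa_from_table(table: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    n = table.sum()
    p = table / n
    observed = float(np.sum(weights * p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = float(np.sum(weights * np.outer(row, col)))
    if expected >= 1.0 - 1e-12:
        raise UndefinedKappaError(
            "expected agreement is 1 (both raters constant); kappa undefined"
        )
    kappa = (observed - expected) / (1.0 - expected)
    return kappa, observed, expected


def weighted_kappa(
    pairs: Sequence[RatingPair],
    categories: Sequence = ROB_CATEGORIES,
    n_boot: int = 0,
    seed: int | None = None,
) -> AgreementResult:
    """Linearly weighted Cohen's kappa for two raters on ordinal categories.

    With ``n_boot`` > 0, a seeded nonparametric bootstrap (resampling units)
    supplies a percentile 95% CI for kappa; no CI is computed by default.
    """
    pairs = list(pairs)
    if len(pairs) == 0:
        raise ValueError("need at least one rating pair")
    categories = tuple(categories)
    table = contingency_table(pairs, categories)
    weights = linear_weights(len(categories))
    kappa, observed, expected = _kappa_from_table(table, weights)
    kappa_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(pairs)
        draws = []
        for _ in range(n_boot):
            resampled = [pairs[i] for i in rng.integers(0, n, size=n)]
            t = contingency_table(resampled, categories)
            try:
                kb, _, _ = _kappa_from_table(t, weights)
            except UndefinedKappaError:
                continue
            draws.append(kb)
        if draws:
            kappa_ci = (
                float(np.percentile(draws, 2.5)),
                float(np.percentile(draws, 97.5)),
            )
    return AgreementResult(
        kappa=kappa,
        observed_agreement=observed,
        expected_agreement=expected,
        n=len(pairs),
        k=len(categories),
        contingency=table,
        categories=categories,
        kappa_ci=kappa_ci,
    )


def pairs_from_records(
    records: Iterable[tuple[str, object, object]]
) -> list[RatingPair]:
    return [RatingPair(unit_id=str(u), rater1=a, rater2=b) for u, a, b in records]
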