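"""Latex yield-potential correlation and regeneration-ability analysis.

Latex yield is measured as total solid content (TSC, grams dry weight) and
adjusted by trunk circumference (TSC/C, g/cm) to remove the bias of tapping
cut length.  Per-snoRNA expression across an F1 population is screened
against TSC/C with Spearman rank correlation; a snoRNA is called
yield-correlated when rho > 0 and rho^2 > 0.2 (both strict).

Regeneration ability is read from continuous-tapping time courses (30-min
intervals): TSC drops sharply over the first tappings and plateaus by 3 h,
so the TSC at the first timepoint >= 180 min is taken as the latex
regeneration ability of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequences_io import SequenceError, logger


@dataclass(frozen=True)
class YieldRecord:
    tree_id: str
    tsc: float
    circumference: float

    def __post_init__(self) -> None:
        if self.tsc < 0:
            raise SequenceError("TSC must be non-negative")
        if self.circumference <= 0:
            raise SequenceError("trunk circumference must be positive")

    @property
    def tsc_c(self) -> float:
        return self.tsc / self.circumference


@dataclass(frozen=True)
class CorrelationResult:
    snorna_id: str
    rho: float
    n: int
    yield_correlated: bool

    @property
    def rho_sq(self) -> float:
        return self.rho ** 2


@dataclass(frozen=True)
class TappingSeries:
    """Ordered (time in minutes, TSC) readings at a fixed interval."""

    tree_id: str
    times: tuple[float, ...]
    tsc: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.tsc):
            raise SequenceError("times and TSC readings differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise SequenceError("tapping times must be strictly increasing")
        if any(v < 0 for v in self.tsc):
            raise SequenceError("TSC readings must be non-negative")


def adjust_tsc(records: list[YieldRecord]) -> pd.DataFrame:
    """Per-tree table with the TSC/C yield-potential column filled."""
    return pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "tsc": r.tsc,
                "circumference": r.circumference,
                "tsc_c": r.tsc_c,
            }
            for r in records
        ]
    )


def spearman_rho(x, y) -> float:
    """Spearman coefficient: Pearson correlation of average ranks.

    Constant input is an error state (the coefficient is undefined), never
    a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SequenceError("x and y must have equal length")
    if x.size < 3:
        raise SequenceError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SequenceError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def classify_yield_correlated(rho: float, min_rho_sq: float = 0.2) -> bool:
    """Positively yield-correlated: rho > 0 and rho^2 > ``min_rho_sq``."""
    return rho > 0 and rho * rho > min_rho_sq


def correlate_expression(
    expression: pd.DataFrame, tsc_c: pd.Series, min_rho_sq: float = 0.2
) -> list[CorrelationResult]:
    """Per-snoRNA Spearman correlation against TSC/C.

    ``expression``: rows = snoRNA ids, columns = tree ids; ``tsc_c`` indexed
    by tree id.  Results are sorted by rho descending.
    """
    missing = set(expression.columns) ^ set(tsc_c.index)
    if missing:
        raise SequenceError(f"tree id mismatch between tables: {sorted(missing)}")
    y = tsc_c.loc[list(expression.columns)].to_numpy(float)
    out = []
    for sno_id, row in expression.iterrows():
        rho = spearman_rho(row.to_numpy(float), y)
        out.append(
            CorrelationResult(
                snorna_id=str(sno_id),
                rho=rho,
                n=len(y),
                yield_correlated=classify_yield_correlated(rho, min_rho_sq),
            )
        )
    out.sort(key=lambda r: (-r.rho, r.snorna_id))
    return out


def regeneration_ability(
    series: TappingSeries,
    stable_time_min: float = 180.0,
    plateau_cv_warn: float = 0.25,
) -> float:
    """TSC at the first timepoint >= ``stable_time_min`` (the 3-h reading).

    Appending post-plateau readings does not change the value.  A warning is
    logged when the readings from that point on vary more than
    ``plateau_cv_warn`` (coefficient of variation), i.e. the series has not
    actually stabilized.
    """
    idx = next(
        (i for i, t in enumerate(series.times) if t >= stable_time_min), None
    )
    if idx is None:
        raise SequenceError(
            f"series {series.tree_id!r} does not reach {stable_time_min} min"
        )
    tail = np.asarray(series.tsc[idx:], dtype=float)
    mean = tail.mean()
    if mean > 0 and tail.std() / mean > plateau_cv_warn:
        logger.warning(
            "tree %s: post-%g-min readings vary (CV=%.2f); plateau doubtful",
            series.tree_id,
            stable_time_min,
            tail.std() / mean,
        )
    return float(series.tsc[idx])


def correlate_regeneration(
    expression: pd.DataFrame,
    abilities: pd.Series,
    min_rho_sq: float = 0.2,
) -> list[CorrelationResult]:
    """Per-snoRNA Spearman correlation of expression with the 3-h
    regeneration ability, sorted by rho descending (reporting order)."""
    return correlate_expression(expression, abilities, min_rho_sq)


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snorna_id": r.snorna_id,
                "rho": r.rho,
                "rho_sq": r.rho_sq,
                "n": r.n,
                "yield_correlated": r.yield_correlated,
            }
            for r in results
        ]
    )
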