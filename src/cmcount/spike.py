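"""Spike-in recovery regression and limit-of-detection estimation.

Cell-line spiking experiments (known numbers of cultured melanoma cells
added per mL of healthy blood, then enriched and counted) are summarized
two ways: an ordinary least-squares regression of recovered on spiked
counts with 95% t-intervals (full recovery means a slope CI containing 1),
and an operational limit of detection — the smallest spike level whose
recovered counts exceed the maximum healthy-donor background in at least
95% of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: sentinel returned when no tested level clears the background criterion
ABOVE_MAX_TESTED = math.inf


@dataclass(frozen=True)
class RecoveryFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    n: int


def _as_frame(experiments) -> pd.DataFrame:
    df = pd.DataFrame(experiments)
    if not {"spiked", "recovered"} <= set(df.columns):
        raise ValueError("experiments need 'spiked' and 'recovered' columns")
    if (df["spiked"] < 0).any() or (df["recovered"] < 0).any():
        raise ValueError("spiked and recovered counts must be >= 0")
    return df


def recovery_regression(experiments) -> RecoveryFit:
    """OLS of recovered on spiked cells with two-sided 95% t-intervals.

    Requires at least three distinct spike levels.  A perfect-fit series
    (zero residual variance) yields degenerate zero-width intervals.
    """
    df = _as_frame(experiments)
    levels = df["spiked"].unique()
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct spike levels for regression, got {len(levels)}"
        )
    x = sm.add_constant(df["spiked"].astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(df["recovered"].astype(float), x).fit()
        ci = np.asarray(fit.conf_int(alpha=0.05))
    ci = np.nan_to_num(ci, nan=0.0)
    if fit.ssr <= 1e-12:  # exact line: degenerate CIs collapse to the point
        ci = np.column_stack([fit.params, fit.params])
    return RecoveryFit(
        slope=float(fit.params.iloc[1]),
        intercept=float(fit.params.iloc[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 1.0,
        n=len(df),
    )


def limit_of_detection(
    experiments, background, min_exceedance: float = 0.95
) -> float:
    """Smallest spike level reliably distinguishable from healthy background.

    A level qualifies when its recovered counts strictly exceed
    ``max(background)`` in at least ``min_exceedance`` of replicates (ties
    with the background count therefore resolve conservatively upward).
    Returns :data:`ABOVE_MAX_TESTED` (inf) when no level qualifies; the
    zero-spike level never qualifies.
    """
    df = _as_frame(experiments)
    background = np.asarray(background)
    if background.size == 0:
        raise ValueError("background counts must be non-empty")
    if not 0 < min_exceedance <= 1:
        raise ValueError("min_exceedance must be in (0, 1]")
    cutoff = float(background.max())
    for level in sorted(df["spiked"].unique()):
        if level <= 0:
            continue
        rec = df.loc[df["spiked"] == level, "recovered"]
        if (rec > cutoff).mean() >= min_exceedance:
            return float(level)
    return ABOVE_MAX_TESTED
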