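"""Per-mL CMC concentration, Poisson counting error and separation bookkeeping.

A cytospin slide carries a fixed deposit (typically 50,000 cells) sampled
from the enriched fraction, so the slide count extrapolates to a
concentration via the ratio of the fraction's total cell number to the
slide deposit, divided by the blood volume processed.  The only sampling
error attributed to a slide count of n rare cells is Poisson: CV% = 100/sqrt(n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

FRACTIONS = ("Feed", "Eluate", "Retentate")


@dataclass(frozen=True)
class SampleRecord:
    """Bookkeeping for one blood sample fraction."""

    sample_id: str
    fraction: str = "Eluate"
    total_cells_in_fraction: float = 2_500_000
    cells_per_slide: float = 50_000
    blood_volume_ml: float = 10.0

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.total_cells_in_fraction <= 0 or self.cells_per_slide <= 0:
            raise ValueError("cell counts must be > 0")
        if self.blood_volume_ml <= 0:
            raise ValueError("blood_volume_ml must be > 0")


@dataclass(frozen=True)
class SlideCount:
    """Four-class tally of one counted slide plus debris/border bookkeeping."""

    n_cmc_slide: int
    n_leuko_slide: int
    n_dual: int = 0
    n_null: int = 0
    n_debris: int = 0
    n_border: int = 0

    def __post_init__(self):
        for name in ("n_cmc_slide", "n_leuko_slide", "n_dual", "n_null",
                     "n_debris", "n_border"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cv_percent(self) -> float | None:
        """Poisson CV% of the CMC tally (None when the tally is 0)."""
        if self.n_cmc_slide < 1:
            return None
        return poisson_cv(self.n_cmc_slide)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return float(round(x, sig - 1 - int(math.floor(math.log10(abs(x))))))


def poisson_cv(n: int, sig: int | None = 2) -> float:
    """Poisson coefficient of variation, percent, for a slide count of n.

    CV% = 100/sqrt(n), rounded to 2 significant figures for reporting
    (pass ``sig=None`` for the unrounded value).
    """
    if n < 1:
        raise ValueError(f"Poisson CV is undefined for a slide count of {n}")
    cv = 100.0 / math.sqrt(n)
    return cv if sig is None else round_sig(cv, sig)


def per_ml(n_cmc_slide: int, sample: SampleRecord) -> float:
    """Extrapolate a slide CMC count to CMCs per mL of whole blood.

    nCMC/mL = n_slide * (total cells in fraction / cells per slide) / blood mL,
    i.e. the slide samples ``cells_per_slide / total_cells`` of the fraction.
    Reported values are conventionally rounded to the nearest integer.
    """
    if n_cmc_slide < 0:
        raise ValueError("n_cmc_slide must be >= 0")
    if sample.cells_per_slide > sample.total_cells_in_fraction:
        warnings.warn(
            f"sample {sample.sample_id}: cells_per_slide "
            f"({sample.cells_per_slide:g}) exceeds the fraction total "
            f"({sample.total_cells_in_fraction:g}); slide oversampled",
            stacklevel=2,
        )
    scale = sample.total_cells_in_fraction / sample.cells_per_slide
    return n_cmc_slide * scale / sample.blood_volume_ml


@dataclass(frozen=True)
class MassBalance:
    recovery: float
    passed: bool
    tolerance: float


def mass_balance(feed: float, eluate: float, retentate: float,
                 tol: float = 0.15) -> MassBalance:
    """Self-consistency check of the separation: do the fractions add up?

    recovery = (eluate + retentate) / feed; passes when |1 - recovery| <= tol.
    """
    if feed <= 0:
        raise ValueError("feed count must be > 0")
    if eluate < 0 or retentate < 0:
        raise ValueError("fraction counts must be >= 0")
    recovery = (eluate + retentate) / feed
    return MassBalance(recovery=recovery, passed=abs(1.0 - recovery) <= tol,
                       tolerance=tol)


def depletion_rate(feed_leuko: float, eluate_leuko: float) -> float:
    """Leukocyte depletion achieved by the separator: 1 - eluate/feed."""
    if feed_leuko <= 0:
        raise ValueError("feed_leuko must be > 0")
    if eluate_leuko > feed_leuko:
        raise ValueError(
            f"eluate leukocytes ({eluate_leuko:g}) exceed feed ({feed_leuko:g})"
        )
    if eluate_leuko < 0:
        raise ValueError("eluate_leuko must be >= 0")
    return 1.0 - eluate_leuko / feed_leuko
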