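"""Cohort statistics for CMC enumeration studies.

Implements the small-cohort analyses appropriate to an 11-patient
enumeration study: median/range summaries, an exact two-sided Mann-Whitney
test (by convolution of the rank-sum distribution conditional on observed
ties), a univariate Cox proportional-hazards fit of overall survival on
log-transformed CMC counts (Newton-Raphson on the partial likelihood,
Breslow or Efron ties), the log-rank test on a dichotomized count, Spearman
correlation, and qPCR delta-delta-Ct fold enrichment of melanoma miRs in
the CMC-enriched Eluate relative to the Feed (U6-normalized).

A packaged fixture, :func:`load_cohort`, carries the published 11-patient
metastatic melanoma table (survival months, censoring flags, per-slide and
per-mL counts, BRAF status, marker used).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

_EXACT_MAX_N = 25


def load_cohort() -> pd.DataFrame:
    """The packaged 11-patient metastatic-melanoma cohort table."""
    with resources.files("cmcount.data").joinpath("melanoma_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    df["alive_at_analysis"] = df["alive_at_analysis"].astype(bool)
    return df


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Median and range of per-mL counts plus categorical breakdowns."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    counts = records["n_cmc_ml"].astype(float)
    out = {
        "n": int(len(records)),
        "median_cmc_ml": float(counts.median()),
        "min_cmc_ml": float(counts.min()),
        "max_cmc_ml": float(counts.max()),
    }
    for col in ("sex", "site", "braf_status", "marker"):
        if col in records.columns:
            out[f"by_{col}"] = records[col].value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# Exact Mann-Whitney


def _rank_sum_distribution(double_ranks: np.ndarray, k: int) -> dict[int, int]:
    """Counts of subsets of size k by doubled-midrank sum (exact, ties OK).

    Dynamic programme over items; doubling midranks makes them integers so
    the distribution is exact and conditional on the observed tie pattern.
    """
    max_sum = int(double_ranks.sum())
    # table[j, s] = number of size-j subsets with doubled-rank sum s
    table = np.zeros((k + 1, max_sum + 1), dtype=object)
    table[0, 0] = 1
    for dr in double_ranks:
        dr = int(dr)
        for j in range(k, 0, -1):
            table[j, dr:] = table[j, dr:] + table[j - 1, : max_sum + 1 - dr]
    return {s: int(c) for s, c in enumerate(table[k]) if c}


def mann_whitney_exact(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact for combined n <= 25.

    Exact mode enumerates the permutation distribution of the rank sum
    conditional on observed ties via convolution; larger samples fall back
    to the normal approximation with tie correction.  Returns (U of group
    a, two-sided p = 2 * min(tail probability, 0.5)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b > _EXACT_MAX_N:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(u_a), float(res.pvalue)

    double_ranks = np.rint(2 * ranks).astype(int)
    dist = _rank_sum_distribution(double_ranks, n_a)
    total = sum(dist.values())
    obs = int(round(2 * r_a))
    p_le = sum(c for s, c in dist.items() if s <= obs) / total
    p_ge = sum(c for s, c in dist.items() if s >= obs) / total
    p = 2.0 * min(p_le, p_ge, 0.5)
    return float(u_a), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)


@dataclass(frozen=True)
class CoxResult:
    beta: float
    se: float
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    ties: str
    n: int
    n_events: int
    n_iter: int


def _cox_score_info(beta, times, events, x, ties):
    """Score and information of the partial likelihood at beta."""
    order = np.argsort(-times, kind="stable")  # descending time
    t_s, e_s, x_s = times[order], events[order], x[order]
    ebx = np.exp(beta * x_s)
    # cumulative risk-set sums: everything with time >= t
    s0 = np.cumsum(ebx)
    s1 = np.cumsum(x_s * ebx)
    s2 = np.cumsum(x_s**2 * ebx)
    score = 0.0
    info = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        dead = [k for k in range(i, j) if e_s[k]]
        if dead:
            # risk set = all with time >= t_s[i] = indices 0..j-1
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            d = len(dead)
            xd = x_s[dead]
            if ties == "breslow":
                score += xd.sum() - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            else:  # efron
                ebx_d = ebx[dead]
                D0, D1, D2 = ebx_d.sum(), (xd * ebx_d).sum(), (xd**2 * ebx_d).sum()
                for m in range(d):
                    f = m / d
                    a0 = S0 - f * D0
                    a1 = S1 - f * D1
                    a2 = S2 - f * D2
                    score += -a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                score += xd.sum()
        i = j
    return score, info


def cox_ph_single(times, events, covariate, ties: str = "breslow") -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson on the partial likelihood.

    ``events`` is 1/True for deaths, 0/False for censored.  Returns the log
    hazard ratio, its standard error, HR = exp(beta) with a 95% Wald CI, and
    the two-sided Wald p-value.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if times.shape != events.shape or times.shape != x.shape:
        raise ValueError("times, events and covariate must have equal length")
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events: the partial likelihood is uninformative")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: the hazard ratio is unidentifiable")

    beta = 0.0
    for it in range(1, 101):
        score, info = _cox_score_info(beta, times, events, x, ties)
        if info <= 1e-12 or abs(beta) > 50:
            raise RuntimeError(
                "partial likelihood appears monotone (no finite hazard-ratio "
                f"estimate); last beta={beta:.6g}"
            )
        step = score / info
        beta += step
        if abs(step) < 1e-10:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in 100 iterations (last beta={beta:.6g})"
        )
    _, info = _cox_score_info(beta, times, events, x, ties)
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        beta=float(beta),
        se=float(se),
        hazard_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p=float(p),
        ties=ties,
        n=len(times),
        n_events=n_events,
        n_iter=it,
    )


def cox_log_count(records: pd.DataFrame, base: str = "ln",
                  ties: str = "breslow") -> CoxResult:
    """Cox fit of survival on log-transformed per-mL counts.

    ``base`` selects the covariate transform: ``"ln"`` (HR per e-fold of
    count, the reporting default) or ``"log10"`` (HR per decade).
    """
    counts = records["n_cmc_ml"].astype(float).to_numpy()
    if (counts <= 0).any():
        raise ValueError("per-mL counts must be > 0 for a log transform")
    if base == "ln":
        cov = np.log(counts)
    elif base == "log10":
        cov = np.log10(counts)
    else:
        raise ValueError(f"base must be 'ln' or 'log10', got {base!r}")
    return cox_ph_single(
        records["survival_months"].to_numpy(),
        ~records["alive_at_analysis"].to_numpy(),
        cov,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Log-rank, Spearman, miR fold change


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test (1 df): returns (chi-square, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group).astype(bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    if not events.any():
        raise ValueError("no events: log-rank statistic is undefined")
    from lifelines.statistics import logrank_test

    res = logrank_test(times[group], times[~group],
                       event_observed_A=events[group],
                       event_observed_B=events[~group])
    return float(res.test_statistic), float(res.p_value)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation is undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class MirMeasurement:
    """Paired qPCR Ct values for one miR in Feed and Eluate (U6-normalized)."""

    mir_id: str
    ct_target_feed: float
    ct_ref_feed: float
    ct_target_eluate: float
    ct_ref_eluate: float

    def __post_init__(self):
        for name in ("ct_target_feed", "ct_ref_feed",
                     "ct_target_eluate", "ct_ref_eluate"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite Ct, got {v}")


def mir_fold_change(m: MirMeasurement) -> float:
    """Fold enrichment of a miR in the Eluate relative to the Feed.

    Standard delta-delta-Ct: 2^-((Ct_tgt,E - Ct_ref,E) - (Ct_tgt,F - Ct_ref,F)).
    """
    ddct = (m.ct_target_eluate - m.ct_ref_eluate) - (m.ct_target_feed - m.ct_ref_feed)
    return float(2.0 ** (-ddct))
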