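"""Per-pair association statistics for binary disease indicators.

All quantities derive from the 2x2 contingency table of a disease pair over
the subjects non-missing for both diseases (pairwise deletion):

* phi coefficient — Pearson correlation specialised to binary variables;
  undefined (returned as NaN, never silently 0) when any table margin is zero.
* co-occurrence relative risk ``RR = (Cij * N) / (Pi * Pj)`` — the joint count
  relative to its expectation under independence given the margins, with a
  delta-method log-normal 95% CI.
* pair test — chi-square without continuity correction when every expected
  cell count is at least 5 (so the identity ``X^2 = N * phi^2`` holds),
  otherwise Fisher's exact two-sided test.
* Clopper–Pearson exact binomial prevalence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable

__all__ = [
    "TwoByTwo",
    "PairStats",
    "pair_counts",
    "phi_coefficient",
    "relative_risk",
    "pair_test",
    "prevalence_ci",
    "filter_diseases",
    "pair_stats",
    "pairwise_table",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Joint presence/absence counts for a disease pair.

    ``n11`` subjects with both, ``n10`` with i only, ``n01`` with j only,
    ``n00`` with neither — all among subjects non-missing for both diseases.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def pi(self) -> int:
        """Subjects with disease i (row margin)."""
        return self.n11 + self.n10

    @property
    def pj(self) -> int:
        """Subjects with disease j (column margin)."""
        return self.n11 + self.n01

    @property
    def cij(self) -> int:
        """Subjects with both diseases."""
        return self.n11

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]])


@dataclass
class PairStats:
    disease_i: str
    disease_j: str
    counts: TwoByTwo
    phi: float
    rr: float
    rr_ci: tuple[float, float]
    p_value: float
    test_used: str


def pair_counts(cohort: CohortTable, i: str, j: str) -> TwoByTwo:
    """2x2 table for diseases (i, j); subjects missing either are excluded."""
    if i == j:
        raise ValueError(f"pair_counts requires two distinct diseases, got {i!r} twice")
    x = cohort.diseases[i].to_numpy(dtype=float)
    y = cohort.diseases[j].to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return TwoByTwo(n11, n10, n01, n00)


def phi_coefficient(t: TwoByTwo) -> float:
    """phi = (n11 n00 - n10 n01) / sqrt(Pi (N-Pi) Pj (N-Pj)); NaN on zero margin.

    Identical to the Pearson correlation of the expanded 0/1 vectors.
    """
    pi, pj, n = t.pi, t.pj, t.n
    denom = pi * (n - pi) * pj * (n - pj)
    if denom == 0:
        return float("nan")
    return (t.n11 * t.n00 - t.n10 * t.n01) / np.sqrt(denom)


def relative_risk(t: TwoByTwo, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Co-occurrence relative risk ``(Cij * N) / (Pi * Pj)`` with a CI.

    NaN when either margin is zero (undefined); 0 with an uninformative CI
    when the diseases never co-occur.  The CI is a log-normal interval whose
    variance comes from the delta method under multinomial sampling of the
    four cells (plug-in proportions).
    """
    pi, pj, n = t.pi, t.pj, t.n
    if pi == 0 or pj == 0:
        return float("nan"), (float("nan"), float("nan"))
    rr = (t.n11 * n) / (pi * pj)
    if t.n11 == 0:
        return 0.0, (0.0, float("nan"))
    # gradient of log RR = log a + log N - log(a+b) - log(a+c) w.r.t. counts
    g = np.array([
        1.0 / t.n11 - 1.0 / pi - 1.0 / pj,
        -1.0 / pi,
        -1.0 / pj,
        0.0,
    ])
    p = np.array([t.n11, t.n10, t.n01, t.n00]) / n
    var_log = float(n * (np.sum(g * g * p) - np.sum(g * p) ** 2))
    se = np.sqrt(max(var_log, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(rr), (float(rr * np.exp(-z * se)), float(rr * np.exp(z * se)))


def pair_test(t: TwoByTwo) -> tuple[float, str]:
    """Two-sided association p-value with the conventional test selection.

    Chi-square (no continuity correction, preserving ``X^2 = N phi^2``) when
    all four expected cell counts are >= 5; Fisher's exact test otherwise.
    """
    pi, pj, n = t.pi, t.pj, t.n
    expected_min = min(
        pi * pj, pi * (n - pj), (n - pi) * pj, (n - pi) * (n - pj)
    ) / n
    table = t.as_array()
    if expected_min >= 5.0:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p), "chi-square"
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(p), "fisher"


def prevalence_ci(
    x: int, n: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Exact (Clopper–Pearson) binomial interval: (point, lower, upper)."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError("require 0 <= x <= n and n >= 1")
    lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return x / n, lo, hi


def filter_diseases(
    strata: Sequence[CohortTable], threshold: float = 0.035
) -> list[str]:
    """Diseases whose prevalence reaches ``threshold`` in at least one stratum.

    Prevalence uses each disease's non-missing denominator within the stratum;
    the comparison is inclusive (>=) and input ordering is preserved.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    names = strata[0].disease_names
    for s in strata[1:]:
        if s.disease_names != names:
            raise ValueError("all strata must share the same disease list")
    retained = []
    for d in names:
        for s in strata:
            col = s.diseases[d].to_numpy(dtype=float)
            denom = np.sum(~np.isnan(col))
            if denom > 0 and np.nansum(col) / denom >= threshold:
                retained.append(d)
                break
    return retained


def pair_stats(cohort: CohortTable, i: str, j: str) -> PairStats:
    """All pooled-sample statistics for one disease pair."""
    t = pair_counts(cohort, i, j)
    rr, ci = relative_risk(t)
    p, test = pair_test(t)
    return PairStats(i, j, t, phi_coefficient(t), rr, ci, p, test)


def pairwise_table(cohort: CohortTable, diseases: Sequence[str] | None = None):
    """Long-format DataFrame of pooled pair statistics for all disease pairs."""
    import pandas as pd

    diseases = list(diseases) if diseases is not None else cohort.disease_names
    rows = []
    for a in range(len(diseases)):
        for b in range(a + 1, len(diseases)):
            s = pair_stats(cohort, diseases[a], diseases[b])
            rows.append({
                "disease_i": s.disease_i,
                "disease_j": s.disease_j,
                "n11": s.counts.n11,
                "n10": s.counts.n10,
                "n01": s.counts.n01,
                "n00": s.counts.n00,
                "phi": s.phi,
                "rr": s.rr,
                "rr_lo": s.rr_ci[0],
                "rr_hi": s.rr_ci[1],
                "p": s.p_value,
                "test": s.test_used,
            })
    return pd.DataFrame(rows)
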