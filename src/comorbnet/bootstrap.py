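"""Bootstrap comorbidity-network engine.

The study design resamples a fixed number of subjects with replacement within
each phenotype stratum (800 for the chronic-bronchitis strata, 400 for the
exacerbation strata — close to the smallest group of each pair, equalising
subgroup size), recomputes every pairwise phi, relative risk, test p-value and
disease prevalence on each resample, and summarises pairs by their mean phi.

Edges are declared significant when the 2.5th percentile of a pair's phi
distribution is strictly positive; network density is the mean of mean phi
over *all* retained pairs; node connectivity aggregates a disease's incident
mean phi (mean by default, sum as sensitivity mode).

Resamples where a pair's 2x2 table has a zero margin yield an undefined phi;
such draws are dropped from that pair's distribution (zero-filling would bias
means toward zero) and the count of defined draws is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .util import stream

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_pairs",
    "significant_edges",
    "network_density",
    "node_connectivity",
    "connectivity_overlap",
    "OverlapReport",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling protocol.

    ``resample_size=None`` means resamples as large as the stratum itself (the
    standard bootstrap); the study pipeline overrides it per trait (800 CB,
    400 Ex).  ``compute_pair_tests=False`` skips the per-resample chi-square /
    Fisher p-values (the one expensive step) for runs that only need phi.
    """

    n_resamples: int = 10_000
    resample_size: int | None = None
    percentile: float = 0.025
    seed: int = 0
    compute_pair_tests: bool = True

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.resample_size is not None and self.resample_size < 2:
            raise ValueError("resample_size must be >= 2")
        if not (0.0 < self.percentile < 0.5):
            raise ValueError("percentile must lie in (0, 0.5)")


@dataclass
class BootstrapResult:
    """Per-pair bootstrap distributions and their summaries for one stratum."""

    disease_names: list[str]
    pairs: list[tuple[str, str]]
    mean_phi: np.ndarray
    phi_p_lo: np.ndarray
    phi_p_hi: np.ndarray
    n_defined: np.ndarray
    mean_rr: np.ndarray
    mean_p: np.ndarray | None
    mean_prevalence: np.ndarray
    phi_draws: np.ndarray
    connectivity_draws: np.ndarray
    config: BootstrapConfig
    stratum_label: str = "all"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_index(self, i: str, j: str) -> int:
        try:
            return self.pairs.index((i, j))
        except ValueError:
            return self.pairs.index((j, i))

    def per_pair(self) -> dict[tuple[str, str], dict[str, float]]:
        """Summary mapping matching the per-pair export contract."""
        out = {}
        for k, pair in enumerate(self.pairs):
            out[pair] = {
                "mean_phi": float(self.mean_phi[k]),
                "phi_p025": float(self.phi_p_lo[k]),
                "phi_p975": float(self.phi_p_hi[k]),
                "n_defined": int(self.n_defined[k]),
                "mean_rr": float(self.mean_rr[k]),
                "mean_p": float(self.mean_p[k]) if self.mean_p is not None else None,
            }
        return out

    def to_jsonable(self) -> dict:
        """Summaries (not per-draw matrices) as plain JSON-safe types."""
        def clean(x):
            return None if x is None or (isinstance(x, float) and np.isnan(x)) else x

        return {
            "stratum": self.stratum_label,
            "config": {
                "n_resamples": self.config.n_resamples,
                "resample_size": self.config.resample_size,
                "percentile": self.config.percentile,
                "seed": self.config.seed,
            },
            "diseases": list(self.disease_names),
            "mean_prevalence": [clean(float(v)) for v in self.mean_prevalence],
            "pairs": [
                {
                    "i": i,
                    "j": j,
                    **{k2: clean(v) for k2, v in summ.items()},
                }
                for (i, j), summ in self.per_pair().items()
            ],
        }


def _pairwise_matrices(x0: np.ndarray, mask: np.ndarray):
    """All 2x2 tables of one (re)sample at once.

    ``x0`` is the 0/1 matrix with missing set to 0, ``mask`` marks observed
    cells.  Returns (n_pair, n11, pi, pj) as K x K matrices over pairwise
    complete subjects.
    """
    m = mask.astype(np.float64)
    n_pair = m.T @ m
    n11 = x0.T @ x0
    pi = x0.T @ m  # pi[a, b] = subjects with disease a among complete (a, b)
    return n_pair, n11, pi, pi.T


def _phi_matrix(n_pair, n11, pi, pj):
    n10 = pi - n11
    n01 = pj - n11
    n00 = n_pair - pi - pj + n11
    den = pi * (n_pair - pi) * pj * (n_pair - pj)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, (n11 * n00 - n10 * n01) / np.sqrt(den), np.nan)
    return phi


_FISHER_CACHE: dict[tuple[int, int, int, int], float] = {}


def _fisher_p(n11: int, n10: int, n01: int, n00: int) -> float:
    key = (n11, n10, n01, n00)
    p = _FISHER_CACHE.get(key)
    if p is None:
        p = float(stats.fisher_exact([[n11, n10], [n01, n00]])[1])
        if len(_FISHER_CACHE) > 2_000_000:  # pragma: no cover - memory guard
            _FISHER_CACHE.clear()
        _FISHER_CACHE[key] = p
    return p


def _p_matrix(n_pair, n11, pi, pj, phi, iu):
    """Per-pair two-sided p-values for one resample (upper triangle only)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        e_min = np.minimum(
            np.minimum(pi * pj, pi * (n_pair - pj)),
            np.minimum((n_pair - pi) * pj, (n_pair - pi) * (n_pair - pj)),
        ) / n_pair
    chi_ok = (e_min >= 5.0) & np.isfinite(phi)
    p = np.full_like(phi, np.nan)
    stat = n_pair * phi * phi  # X^2 = N phi^2 (no continuity correction)
    p[chi_ok] = stats.chi2.sf(stat[chi_ok], 1)
    rows, cols = iu
    for a, b in zip(rows, cols):
        if not chi_ok[a, b]:
            t11 = int(n11[a, b])
            t10 = int(pi[a, b] - n11[a, b])
            t01 = int(pj[a, b] - n11[a, b])
            t00 = int(n_pair[a, b] - pi[a, b] - pj[a, b] + n11[a, b])
            p[a, b] = _fisher_p(t11, t10, t01, t00)
    return p


def bootstrap_pairs(
    cohort: CohortTable,
    diseases: Sequence[str] | None = None,
    config: BootstrapConfig | None = None,
    stratum_label: str = "all",
) -> BootstrapResult:
    """Run the resampling engine on one stratum.

    Fully reproducible from ``config.seed`` and ``stratum_label`` (each
    labelled run consumes its own random stream).
    """
    config = config or BootstrapConfig()
    diseases = list(diseases) if diseases is not None else cohort.disease_names
    unknown = set(diseases) - set(cohort.disease_names)
    if unknown:
        raise ValueError(f"diseases not in cohort: {sorted(unknown)}")
    if cohort.n_subjects < 2:
        raise ValueError("stratum must contain at least 2 subjects")
    values = cohort.diseases[diseases].to_numpy(dtype=np.float64)
    return _bootstrap_matrix(values, diseases, config, stratum_label)


def _bootstrap_matrix(
    values: np.ndarray,
    diseases: Sequence[str],
    config: BootstrapConfig,
    stratum_label: str,
) -> BootstrapResult:
    n, k = values.shape
    m = config.resample_size if config.resample_size is not None else n
    b = config.n_resamples
    mask_full = ~np.isnan(values)
    x_full = np.where(mask_full, values, 0.0)
    iu = np.triu_indices(k, 1)
    n_pairs = len(iu[0])
    rng = stream(config.seed, stratum_label)

    phi_draws = np.empty((b, n_pairs))
    rr_draws = np.empty((b, n_pairs))
    p_draws = np.empty((b, n_pairs)) if config.compute_pair_tests else None
    prev_acc = np.zeros(k)
    prev_cnt = np.zeros(k)
    conn_draws = np.empty((b, k))

    for t in range(b):
        idx = rng.integers(0, n, size=m)
        x0 = x_full[idx]
        mask = mask_full[idx]
        n_pair, n11, pi, pj = _pairwise_matrices(x0, mask)
        phi = _phi_matrix(n_pair, n11, pi, pj)
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = np.where((pi > 0) & (pj > 0), n11 * n_pair / (pi * pj), np.nan)
            denom = mask.sum(axis=0)
            prev = np.where(denom > 0, x0.sum(axis=0) / denom, np.nan)
        ok = ~np.isnan(prev)
        prev_acc[ok] += prev[ok]
        prev_cnt[ok] += 1
        phi_draws[t] = phi[iu]
        rr_draws[t] = rr[iu]
        if p_draws is not None:
            p_draws[t] = _p_matrix(n_pair, n11, pi, pj, phi, iu)[iu]
        phi_sym = phi.copy()
        np.fill_diagonal(phi_sym, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            conn_draws[t] = np.nanmean(phi_sym, axis=1)

    n_defined = np.sum(~np.isnan(phi_draws), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_phi = np.nanmean(phi_draws, axis=0)
        mean_rr = np.nanmean(rr_draws, axis=0)
        mean_p = np.nanmean(p_draws, axis=0) if p_draws is not None else None
    q_lo = np.full(n_pairs, np.nan)
    q_hi = np.full(n_pairs, np.nan)
    for idx_p in range(n_pairs):
        vals = phi_draws[:, idx_p]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            q_lo[idx_p] = np.percentile(vals, 100 * config.percentile, method="linear")
            q_hi[idx_p] = np.percentile(vals, 100 * (1 - config.percentile), method="linear")
    undefined = int(np.sum(n_defined == 0))
    if undefined:
        logger.warning(
            "stratum %s: %d pair(s) had no defined phi draw", stratum_label, undefined
        )
    with np.errstate(invalid="ignore"):
        mean_prev = np.where(prev_cnt > 0, prev_acc / prev_cnt, np.nan)

    pairs = [(diseases[a], diseases[b2]) for a, b2 in zip(*iu)]
    return BootstrapResult(
        disease_names=list(diseases),
        pairs=pairs,
        mean_phi=mean_phi,
        phi_p_lo=q_lo,
        phi_p_hi=q_hi,
        n_defined=n_defined,
        mean_rr=mean_rr,
        mean_p=mean_p,
        mean_prevalence=mean_prev,
        phi_draws=phi_draws,
        connectivity_draws=conn_draws,
        config=config,
        stratum_label=stratum_label,
    )


def significant_edges(result: BootstrapResult) -> set[tuple[str, str]]:
    """Pairs whose lower phi percentile (over defined draws) is strictly > 0."""
    if int(np.sum(result.n_defined > 0)) == 0:
        raise ValueError("no pair has any defined phi draw")
    keep = (result.n_defined > 0) & (result.phi_p_lo > 0.0)
    return {result.pairs[k] for k in np.flatnonzero(keep)}


def network_density(result: BootstrapResult) -> float:
    """Mean of mean phi over all retained pairs (significant or not)."""
    defined = ~np.isnan(result.mean_phi)
    if not defined.any():
        raise ValueError("network density undefined: all pairs undefined")
    dropped = int((~defined).sum())
    if dropped:
        logger.warning(
            "network_density(%s): %d undefined pair(s) excluded",
            result.stratum_label, dropped,
        )
    return float(np.mean(result.mean_phi[defined]))


def node_connectivity(result: BootstrapResult, mode: str = "mean") -> dict[str, float]:
    """Aggregate of each disease's incident mean phi (mean or sum mode).

    Undefined incident pairs are excluded; a node with no defined incident
    pair gets NaN.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    k = len(result.disease_names)
    mat = np.full((k, k), np.nan)
    idx = {d: i for i, d in enumerate(result.disease_names)}
    for (a, b), v in zip(result.pairs, result.mean_phi):
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = v
    agg = np.nansum if mode == "sum" else np.nanmean
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for d, i in idx.items():
            row = mat[i]
            out[d] = float(agg(row)) if np.any(~np.isnan(row)) else float("nan")
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Bootstrap percentile intervals of one node's connectivity in two strata."""

    node: str
    label_a: str
    label_b: str
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    overlap: bool


def connectivity_overlap(
    result_a: BootstrapResult, result_b: BootstrapResult, node: str
) -> OverlapReport:
    """Compare a node's per-resample connectivity distribution across strata.

    Reports each stratum's (percentile, 1-percentile) interval of the node's
    per-resample connectivity and whether the two intervals overlap —
    non-overlapping intervals indicate a clear between-stratum difference in
    how connected the disease is.
    """
    intervals = []
    for res in (result_a, result_b):
        if node not in res.disease_names:
            raise ValueError(f"node {node!r} absent from stratum {res.stratum_label!r}")
        i = res.disease_names.index(node)
        draws = res.connectivity_draws[:, i]
        draws = draws[~np.isnan(draws)]
        if draws.size == 0:
            raise ValueError(f"node {node!r} has no defined connectivity draws")
        pct = res.config.percentile
        intervals.append((
            float(np.percentile(draws, 100 * pct, method="linear")),
            float(np.percentile(draws, 100 * (1 - pct), method="linear")),
        ))
    (lo_a, hi_a), (lo_b, hi_b) = intervals
    overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
    return OverlapReport(
        node=node,
        label_a=result_a.stratum_label,
        label_b=result_b.stratum_label,
        interval_a=intervals[0],
        interval_b=intervals[1],
        overlap=overlap,
    )
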