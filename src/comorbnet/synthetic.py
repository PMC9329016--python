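"""Synthetic binary comorbidity cohorts with planted prevalences and phi structure.

Correlated binary disease indicators are produced by latent multivariate
Gaussian thresholding (Emrich & Piedmonte): each disease is the indicator
``Z_d > Phi^-1(1 - p_d)`` of a standard normal vector ``Z`` with a latent
correlation matrix solved, pair by pair, so that the binary phi coefficient of
each pair hits its target exactly in expectation.  The pair-level solve
inverts the bivariate-normal orthant probability; the full latent matrix is
projected to the nearest positive semi-definite matrix when the pairwise
targets are not jointly attainable.

Phenotype strata (chronic bronchitis CB+/CB-, prior severe exacerbation
Ex+/Ex-) may carry their own phi targets: each joint stratum is generated from
its own latent matrix and the strata are concatenated, so stratified network
analyses see genuinely different planted association structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import CohortTable
from .util import stream

__all__ = [
    "SyntheticSpec",
    "StratumSpec",
    "phi_feasible_bounds",
    "solve_latent_correlation",
    "bvn_cdf",
    "nearest_psd_correlation",
    "generate_cohort",
    "make_study_spec",
    "STUDY_DISEASES",
    "STUDY_PREVALENCES",
    "STUDY_MISSING_RATES",
    "STUDY_TRAIT_DENSITIES",
]

#: joint phenotype stratum labels: CB sign then Ex sign
STRATA = ("cb-ex-", "cb-ex+", "cb+ex-", "cb+ex+")


# ---------------------------------------------------------------------------
# bivariate normal orthant machinery


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Closed form via Owen's T function; comonotone/countermonotone limits are
    handled exactly.
    """
    if rho >= 1.0 - 1e-15:
        return float(stats.norm.cdf(min(h, k)))
    if rho <= -1.0 + 1e-15:
        return float(max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0))
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    # nudge exact zeros off the removable singularity of the T-function form
    if h == 0.0:
        h = 1e-13
    if k == 0.0:
        k = 1e-13
    r = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * r)
    ak = (h - rho * k) / (k * r)
    delta = 0.0 if h * k > 0 else 0.5
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - delta
    )
    return float(min(1.0, max(0.0, val)))


def _orthant_upper(zi: float, zj: float, rho: float) -> float:
    """P(Z1 > zi, Z2 > zj) under correlation rho."""
    return bvn_cdf(-zi, -zj, rho)


def phi_feasible_bounds(p_i: float, p_j: float) -> tuple[float, float]:
    """Attainable phi range for binary margins (p_i, p_j).

    The joint success probability C is bounded by the Frechet-Hoeffding limits
    ``max(0, p_i + p_j - 1) <= C <= min(p_i, p_j)``; mapping both ends through
    ``phi = (C - p_i p_j) / sqrt(p_i q_i p_j q_j)`` gives the interval.
    """
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise ValueError("margins must lie strictly inside (0, 1)")
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    c_min = max(0.0, p_i + p_j - 1.0)
    c_max = min(p_i, p_j)
    return ((c_min - p_i * p_j) / denom, (c_max - p_i * p_j) / denom)


def solve_latent_correlation(
    p_i: float, p_j: float, target_phi: float, *, tol: float = 1e-8
) -> float:
    """Latent Gaussian correlation reproducing ``target_phi`` after thresholding.

    Solves ``P(Z1 > z_i, Z2 > z_j; rho) = p_i p_j + phi * sqrt(p_i q_i p_j q_j)``
    for rho, with ``z = Phi^-1(1 - p)``, by bracketed root finding on the
    orthant probability (monotone increasing in rho) to absolute tolerance
    ``tol``.
    """
    lo, hi = phi_feasible_bounds(p_i, p_j)
    if not (lo <= target_phi <= hi):
        raise ValueError(
            f"target phi {target_phi:.6g} infeasible for margins "
            f"({p_i:.4g}, {p_j:.4g}); attainable interval is "
            f"[{lo:.6g}, {hi:.6g}]"
        )
    if abs(target_phi) < 1e-14:
        return 0.0
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    c_target = p_i * p_j + target_phi * denom
    zi = stats.norm.ppf(1.0 - p_i)
    zj = stats.norm.ppf(1.0 - p_j)

    def f(rho: float) -> float:
        return _orthant_upper(zi, zj, rho) - c_target

    eps = 1e-12
    f_lo, f_hi = f(-1.0 + eps), f(1.0 - eps)
    if f_lo >= 0.0:
        return -1.0
    if f_hi <= 0.0:
        return 1.0
    rho = optimize.brentq(f, -1.0 + eps, 1.0 - eps, xtol=1e-13, rtol=8.9e-16)
    if abs(f(rho)) > tol:  # pragma: no cover - brentq converges far tighter
        raise RuntimeError("orthant-probability root finding failed to converge")
    return float(rho)


def nearest_psd_correlation(
    r: np.ndarray, *, max_perturbation: float = 0.05
) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping followed by re-scaling to a unit diagonal.  Errors if
    the most negative eigenvalue exceeds ``max_perturbation`` in magnitude;
    warns when any projection is applied at all.
    """
    w, v = np.linalg.eigh(r)
    if w.min() >= -1e-10:
        return r
    if -w.min() > max_perturbation:
        raise ValueError(
            f"latent correlation matrix is far from PSD "
            f"(min eigenvalue {w.min():.4g}); pairwise phi targets are "
            "jointly unattainable"
        )
    warnings.warn(
        f"latent matrix projected to nearest PSD (min eigenvalue {w.min():.3g})",
        stacklevel=2,
    )
    w_clipped = np.clip(w, 1e-8, None)
    fixed = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# specification


@dataclass
class StratumSpec:
    """Per-stratum override: phi target (and optionally prevalences)."""

    target_phi: np.ndarray
    prevalences: np.ndarray | None = None


@dataclass
class SyntheticSpec:
    """Targets for one synthetic cohort.

    ``ex_given_cb`` gives P(Ex+ | CB-) and P(Ex+ | CB+); when omitted the two
    phenotype flags are independent with marginal ``ex_fraction``.
    ``stratum_overrides`` maps joint-stratum labels (``cb-ex-`` ... ``cb+ex+``)
    to their own targets; unlisted strata use the base targets.
    """

    n_subjects: int
    disease_names: list[str]
    prevalences: np.ndarray
    target_phi: np.ndarray
    cb_fraction: float
    ex_fraction: float
    seed: int
    missing_rate: np.ndarray | None = None
    stratum_overrides: dict[str, StratumSpec] = field(default_factory=dict)
    ex_given_cb: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        self.target_phi = np.asarray(self.target_phi, dtype=float)
        k = len(self.disease_names)
        if self.prevalences.shape != (k,):
            raise ValueError("prevalences length must match disease_names")
        if np.any(self.prevalences <= 0.0) or np.any(self.prevalences >= 1.0):
            raise ValueError("prevalences must lie strictly inside (0, 1)")
        if self.missing_rate is None:
            self.missing_rate = np.zeros(k)
        self.missing_rate = np.asarray(self.missing_rate, dtype=float)
        if np.any(self.missing_rate < 0.0) or np.any(self.missing_rate >= 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for label, phi, prev in self._stratum_targets():
            _check_phi_matrix(phi, prev, label)

    def _stratum_targets(self):
        """(label, target_phi, prevalences) for each joint stratum."""
        for label in STRATA:
            ov = self.stratum_overrides.get(label)
            phi = self.target_phi if ov is None else np.asarray(ov.target_phi, float)
            prev = self.prevalences
            if ov is not None and ov.prevalences is not None:
                prev = np.asarray(ov.prevalences, float)
            yield label, phi, prev


def _check_phi_matrix(phi: np.ndarray, prev: np.ndarray, label: str) -> None:
    k = len(prev)
    if phi.shape != (k, k):
        raise ValueError(f"{label}: target_phi must be {k}x{k}")
    if not np.allclose(phi, phi.T):
        raise ValueError(f"{label}: target_phi must be symmetric")
    if not np.allclose(np.diag(phi), 1.0):
        raise ValueError(f"{label}: target_phi diagonal must be exactly 1")
    for i in range(k):
        for j in range(i + 1, k):
            lo, hi = phi_feasible_bounds(prev[i], prev[j])
            if not (lo - 1e-12 <= phi[i, j] <= hi + 1e-12):
                raise ValueError(
                    f"{label}: phi[{i},{j}]={phi[i, j]:.4g} outside Frechet "
                    f"bounds [{lo:.4g}, {hi:.4g}] for margins "
                    f"({prev[i]:.4g}, {prev[j]:.4g})"
                )


# ---------------------------------------------------------------------------
# generation

_LATENT_CACHE: dict[bytes, np.ndarray] = {}


def _latent_matrix(prev: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Latent correlation matrix for one stratum, memoised across seeds."""
    key = prev.tobytes() + phi.tobytes()
    cached = _LATENT_CACHE.get(key)
    if cached is not None:
        return cached
    k = len(prev)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = solve_latent_correlation(prev[i], prev[j], phi[i, j])
    r = nearest_psd_correlation(r)
    if len(_LATENT_CACHE) > 64:
        _LATENT_CACHE.clear()
    _LATENT_CACHE[key] = r
    return r


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a seeded cohort realising the spec's targets.

    Reproducible: the seed fully determines flags, disease matrix and
    missingness mask.  Each joint phenotype stratum uses its own independent
    random stream, so adding or editing one stratum's targets never perturbs
    another's draws.
    """
    n, k = spec.n_subjects, len(spec.disease_names)
    rng_flags = stream(spec.seed, "phenotype")
    cb = (rng_flags.random(n) < spec.cb_fraction).astype(float)
    if spec.ex_given_cb is None:
        p_ex = np.full(n, spec.ex_fraction)
    else:
        p_ex = np.where(cb == 1.0, spec.ex_given_cb[1], spec.ex_given_cb[0])
    ex = (rng_flags.random(n) < p_ex).astype(float)

    mat = np.empty((n, k))
    for label, phi, prev in spec._stratum_targets():
        rows = np.flatnonzero((cb == float("+" in label[:3])) & (ex == float(label.endswith("+"))))
        if len(rows) == 0:
            continue
        latent = _latent_matrix(prev, phi)
        chol = np.linalg.cholesky(latent + 1e-12 * np.eye(k))
        z = stream(spec.seed, label).standard_normal((len(rows), k)) @ chol.T
        mat[rows] = (z > stats.norm.ppf(1.0 - prev)).astype(float)

    if np.any(spec.missing_rate > 0):
        miss = stream(spec.seed, "missing").random((n, k)) < spec.missing_rate
        mat[miss] = np.nan

    subjects = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    return CohortTable(subjects, cb, ex, pd.DataFrame(mat, columns=list(spec.disease_names)))


# ---------------------------------------------------------------------------
# study-like default specification

#: 16 candidate diseases of a multicentre Spanish COPD cohort, with overall
#: prevalences computed over non-missing subjects.  PYI is the pack-year
#: index dichotomised at 50; osteoporosis and underweight fall below the 3.5%
#: retention threshold.
STUDY_DISEASES = [
    "AHT", "obesity", "DLP", "PYI", "T2DM", "AF", "SAHS", "HF",
    "IHD", "MD", "PAD", "CVA", "Np", "CKD", "osteoporosis", "underweight",
]

STUDY_PREVALENCES = np.array([
    0.510, 0.359, 0.570, 0.398, 0.194, 0.136, 0.134, 0.127,
    0.116, 0.106, 0.103, 0.063, 0.063, 0.055, 0.020, 0.024,
])

#: fraction of the cohort in which each variable was not measured (some sites
#: did not record some variables)
STUDY_MISSING_RATES = np.array([
    502 / 1726, 26 / 1726, 1009 / 1726, 87 / 1726, 0.0, 0.0, 0.0, 0.0,
    0.0, 0.0, 0.0, 0.0, 0.0, 1 / 1726, 0.0, 26 / 1726,
])

#: target network densities (mean pairwise phi) per phenotype stratum
STUDY_TRAIT_DENSITIES = {"cb-": 0.098, "cb+": 0.050, "ex-": 0.082, "ex+": 0.072}

STUDY_N = 1726
STUDY_CB_FRACTION = 0.52
STUDY_EX_FRACTION = 0.242
#: P(Ex+ | CB-), P(Ex+ | CB+); their CB-weighted mean equals 0.242
STUDY_EX_GIVEN_CB = (0.227, 0.256)


def _solve_joint_stratum_phi(
    densities: Mapping[str, float],
    cb_fraction: float,
    ex_given_cb: tuple[float, float],
) -> dict[str, float]:
    """Constant per-joint-stratum phi matching the four trait-level densities.

    Each trait-level network pools two joint strata, and with equal margins a
    pooled phi is the mixture-weighted mean of the stratum phis; the four
    target densities give four linear equations in the four joint-stratum
    values.  The system is rank-3 (both trait pairs average to the same
    overall density), so the least-squares solution is used; with the study
    targets the residual per stratum is below 0.005.
    """
    p_cb = cb_fraction
    e0, e1 = ex_given_cb
    p_ex = (1 - p_cb) * e0 + p_cb * e1
    # unknowns ordered as STRATA: cb-ex-, cb-ex+, cb+ex-, cb+ex+
    a = np.array([
        [1 - e0, e0, 0, 0],                                    # cb-
        [0, 0, 1 - e1, e1],                                    # cb+
        [(1 - p_cb) * (1 - e0) / (1 - p_ex), 0, p_cb * (1 - e1) / (1 - p_ex), 0],  # ex-
        [0, (1 - p_cb) * e0 / p_ex, 0, p_cb * e1 / p_ex],      # ex+
    ])
    d = np.array([densities["cb-"], densities["cb+"], densities["ex-"], densities["ex+"]])
    x, *_ = np.linalg.lstsq(a, d, rcond=None)
    return dict(zip(STRATA, x))


def _constant_phi_matrix(k: int, value: float) -> np.ndarray:
    m = np.full((k, k), value)
    np.fill_diagonal(m, 1.0)
    return m


def make_study_spec(seed: int) -> SyntheticSpec:
    """Spec emulating the study conditions: 16 diseases, n = 1726, CB+ 52%,
    Ex+ 24.2%, per-variable missingness, and per-stratum constant phi planted
    so the four phenotype networks hit the reported densities."""
    k = len(STUDY_DISEASES)
    stratum_phi = _solve_joint_stratum_phi(
        STUDY_TRAIT_DENSITIES, STUDY_CB_FRACTION, STUDY_EX_GIVEN_CB
    )
    overrides = {
        label: StratumSpec(target_phi=_constant_phi_matrix(k, v))
        for label, v in stratum_phi.items()
    }
    overall = float(np.mean(list(stratum_phi.values())))
    return SyntheticSpec(
        n_subjects=STUDY_N,
        disease_names=list(STUDY_DISEASES),
        prevalences=STUDY_PREVALENCES.copy(),
        target_phi=_constant_phi_matrix(k, overall),
        cb_fraction=STUDY_CB_FRACTION,
        ex_fraction=STUDY_EX_FRACTION,
        ex_given_cb=STUDY_EX_GIVEN_CB,
        missing_rate=STUDY_MISSING_RATES.copy(),
        stratum_overrides=overrides,
        seed=seed,
    )
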