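"""Latent-Gaussian generator: feasibility bounds, orthant solver, recovery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from comorbnet.estimator import PairwiseAssociation
from comorbnet.synthetic import (
    STRATA,
    STUDY_DISEASES,
    StratumSpec,
    SyntheticSpec,
    bvn_cdf,
    generate_cohort,
    make_study_spec,
    nearest_psd_correlation,
    phi_feasible_bounds,
    solve_latent_correlation,
)
from conftest import constant_phi_spec


def phi_from_joint(c, pi, pj):
    return (c - pi * pj) / np.sqrt(pi * (1 - pi) * pj * (1 - pj))


class TestPhiFeasibleBounds:
    def test_symmetric_half_margins_attain_full_range(self):
        lo, hi = phi_feasible_bounds(0.5, 0.5)
        assert lo == pytest.approx(-1.0) and hi == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.1, 0.35, 0.8])
    def test_equal_margins_allow_perfect_positive(self, p):
        assert phi_feasible_bounds(p, p)[1] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pi,pj", [(0.1, 0.5), (0.3, 0.7), (0.05, 0.9), (0.6, 0.8)]
    )
    def test_bounds_match_exhaustive_grid_over_joints(self, pi, pj):
        # brute force: sweep the one free parameter of a 2x2 joint with the
        # given margins and record the attainable phi range
        c_grid = np.linspace(max(0.0, pi + pj - 1.0), min(pi, pj), 20001)
        phis = phi_from_joint(c_grid, pi, pj)
        lo, hi = phi_feasible_bounds(pi, pj)
        assert lo == pytest.approx(phis.min(), abs=1e-9)
        assert hi == pytest.approx(phis.max(), abs=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            phi_feasible_bounds(0.0, 0.5)


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.95, -0.5, 0.0, 0.3, 0.8])
    @pytest.mark.parametrize("h,k", [(-1.2, 0.4), (0.0, 0.7), (0.5, 0.5), (-2.0, -1.0)])
    def test_matches_scipy_integration(self, h, k, rho):
        oracle = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([h, k])
        assert bvn_cdf(h, k, rho) == pytest.approx(float(oracle), abs=2e-7)

    def test_comonotone_limit(self):
        assert bvn_cdf(0.3, 1.1, 1.0) == pytest.approx(stats.norm.cdf(0.3))

    def test_double_zero_closed_form(self):
        assert bvn_cdf(0.0, 0.0, 0.5) == pytest.approx(0.25 + np.arcsin(0.5) / (2 * np.pi))


class TestSolveLatentCorrelation:
    def test_zero_phi_maps_to_zero_rho(self):
        assert solve_latent_correlation(0.3, 0.6, 0.0) == 0.0

    def test_median_threshold_closed_form(self):
        # at p_i = p_j = 1/2, rho = 1/2 gives joint probability
        # 1/4 + arcsin(1/2)/(2 pi) = 1/3, hence phi = 1/3
        assert solve_latent_correlation(0.5, 0.5, 1.0 / 3.0) == pytest.approx(
            0.5, abs=1e-7
        )

    def test_comonotone_limit(self):
        hi = phi_feasible_bounds(0.4, 0.4)[1]
        assert solve_latent_correlation(0.4, 0.4, hi) == pytest.approx(1.0)

    def test_infeasible_target_reports_interval(self):
        with pytest.raises(ValueError, match="attainable interval"):
            solve_latent_correlation(0.1, 0.9, 0.9)

    @pytest.mark.parametrize("pi", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("pj", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("frac", [-0.5, 0.25, 0.75])
    def test_solution_reproduces_target_through_independent_integration(
        self, pi, pj, frac
    ):
        lo, hi = phi_feasible_bounds(pi, pj)
        phi = frac * (hi if frac > 0 else -lo)
        rho = solve_latent_correlation(pi, pj, phi)
        zi, zj = stats.norm.ppf(1 - pi), stats.norm.ppf(1 - pj)
        # oracle: scipy's numerical bivariate-normal integration
        joint = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf(
            [-zi, -zj]
        )
        c_target = pi * pj + phi * np.sqrt(pi * (1 - pi) * pj * (1 - pj))
        assert float(joint) == pytest.approx(c_target, abs=1e-6)


class TestNearestPsd:
    def test_psd_matrix_untouched(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert nearest_psd_correlation(r) is r

    def test_mild_violation_projected_with_warning(self):
        r = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, -0.7], [0.7, -0.7, 1.0]])
        w = np.linalg.eigvalsh(r)
        assert w.min() < 0  # genuinely indefinite input
        with pytest.warns(UserWarning, match="projected"):
            fixed = nearest_psd_correlation(r, max_perturbation=1.0)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)

    def test_strong_violation_rejected(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(ValueError, match="unattainable"):
            nearest_psd_correlation(r, max_perturbation=0.05)


class TestGenerateCohort:
    def test_same_seed_reproduces_identical_cohort(self):
        spec = constant_phi_spec(400, [0.3, 0.2, 0.5], 0.1, seed=11,
                                 missing_rate=[0.1, 0.0, 0.2])
        a, b = generate_cohort(spec), generate_cohort(spec)
        np.testing.assert_array_equal(a.diseases.to_numpy(), b.diseases.to_numpy())
        np.testing.assert_array_equal(a.cb, b.cb)

    def test_different_seed_differs(self):
        a = generate_cohort(constant_phi_spec(400, [0.3, 0.2, 0.5], 0.1, seed=1))
        b = generate_cohort(constant_phi_spec(400, [0.3, 0.2, 0.5], 0.1, seed=2))
        assert not np.array_equal(a.diseases.to_numpy(), b.diseases.to_numpy())

    def test_prevalences_recovered_within_binomial_band(self):
        p = np.array([0.05, 0.2, 0.4, 0.6])
        cohort = generate_cohort(constant_phi_spec(50_000, p, 0.1, seed=3))
        emp = cohort.diseases.to_numpy().mean(axis=0)
        band = 4 * np.sqrt(p * (1 - p) / 50_000)
        assert np.all(np.abs(emp - p) < band)

    def test_independence_target_gives_near_zero_phi(self):
        cohort = generate_cohort(
            constant_phi_spec(50_000, [0.2, 0.4, 0.3, 0.5], 0.0, seed=4)
        )
        pa = PairwiseAssociation().fit(cohort.diseases)
        off = pa.phi_[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.02)

    def test_planted_phi_recovered(self):
        cohort = generate_cohort(constant_phi_spec(50_000, [0.4, 0.4], 0.3, seed=5))
        pa = PairwiseAssociation().fit(cohort.diseases)
        assert pa.phi_[0, 1] == pytest.approx(0.3, abs=0.02)

    def test_phi_recovery_mean_absolute_error_across_seeds(self):
        errs = []
        for seed in range(20):
            cohort = generate_cohort(
                constant_phi_spec(50_000, [0.15, 0.35, 0.5], 0.2, seed=seed)
            )
            pa = PairwiseAssociation().fit(cohort.diseases)
            errs.extend(abs(pa.phi_[i, j] - 0.2) for i, j in [(0, 1), (0, 2), (1, 2)])
        assert np.mean(errs) < 0.02

    def test_missingness_rate_applied_per_disease(self):
        spec = constant_phi_spec(20_000, [0.3, 0.3], 0.0, seed=6,
                                 missing_rate=[0.25, 0.0])
        cohort = generate_cohort(spec)
        miss = np.isnan(cohort.diseases.to_numpy()).mean(axis=0)
        assert miss[0] == pytest.approx(0.25, abs=0.02)
        assert miss[1] == 0.0

    def test_stratum_overrides_plant_different_structure(self):
        base = constant_phi_spec(30_000, [0.3, 0.3], 0.0, seed=7)
        phi_hi = np.array([[1.0, 0.3], [0.3, 1.0]])
        spec = SyntheticSpec(
            n_subjects=30_000,
            disease_names=base.disease_names,
            prevalences=base.prevalences,
            target_phi=base.target_phi,
            cb_fraction=0.5,
            ex_fraction=0.25,
            seed=7,
            stratum_overrides={
                "cb+ex-": StratumSpec(target_phi=phi_hi),
                "cb+ex+": StratumSpec(target_phi=phi_hi),
            },
        )
        cohort = generate_cohort(spec)
        pos = cohort.diseases.to_numpy()[cohort.cb == 1]
        neg = cohort.diseases.to_numpy()[cohort.cb == 0]
        phi_pos = np.corrcoef(pos.T)[0, 1]
        phi_neg = np.corrcoef(neg.T)[0, 1]
        assert phi_pos == pytest.approx(0.3, abs=0.03)
        assert phi_neg == pytest.approx(0.0, abs=0.03)


class TestSpecValidation:
    def test_infeasible_pair_target_rejected(self):
        with pytest.raises(ValueError, match="Frechet"):
            constant_phi_spec(100, [0.05, 0.95], 0.8, seed=0)

    def test_prevalence_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            constant_phi_spec(100, [0.0, 0.5], 0.1, seed=0)

    def test_asymmetric_phi_rejected(self):
        spec_phi = np.array([[1.0, 0.2], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            SyntheticSpec(
                n_subjects=10, disease_names=["a", "b"],
                prevalences=np.array([0.4, 0.4]), target_phi=spec_phi,
                cb_fraction=0.5, ex_fraction=0.2, seed=0,
            )


class TestStudySpec:
    def test_dimensions_and_fractions(self):
        spec = make_study_spec(0)
        assert len(spec.disease_names) == 16
        assert spec.n_subjects == 1726
        assert spec.cb_fraction == 0.52
        assert spec.ex_fraction == 0.242
        assert set(spec.stratum_overrides) == set(STRATA)

    def test_conditional_exacerbation_rates_consistent_with_marginal(self):
        spec = make_study_spec(0)
        e0, e1 = spec.ex_given_cb
        # conditional rates are printed to 3 decimals, so agreement holds to
        # rounding precision only
        marginal = (1 - spec.cb_fraction) * e0 + spec.cb_fraction * e1
        assert marginal == pytest.approx(spec.ex_fraction, abs=5e-4)

    def test_planted_stratum_phi_reproduces_trait_densities(self):
        # mixture algebra: pooling joint strata with the stratum weights must
        # return the four trait-level density targets up to the (rank-3)
        # least-squares residual
        spec = make_study_spec(0)
        phis = {
            lbl: spec.stratum_overrides[lbl].target_phi[0, 1] for lbl in STRATA
        }
        e0, e1 = spec.ex_given_cb
        cb_neg = (1 - e0) * phis["cb-ex-"] + e0 * phis["cb-ex+"]
        cb_pos = (1 - e1) * phis["cb+ex-"] + e1 * phis["cb+ex+"]
        assert cb_neg == pytest.approx(0.098, abs=0.005)
        assert cb_pos == pytest.approx(0.050, abs=0.005)

    def test_generated_cohort_matches_headline_prevalences(self):
        cohort = generate_cohort(make_study_spec(12))
        vals = cohort.diseases.to_numpy()
        idx = {d: i for i, d in enumerate(STUDY_DISEASES)}
        af = np.nanmean(vals[:, idx["AF"]])
        aht = np.nanmean(vals[:, idx["AHT"]])
        assert af == pytest.approx(0.136, abs=0.03)
        assert aht == pytest.approx(0.510, abs=0.05)
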