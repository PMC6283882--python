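import numpy as np
import pandas as pd
import pytest

from aabnet.msfa import marginal_covariance
from aabnet.networks import correlation_matrix
from aabnet.simulate import (
    GroundTruth,
    PerturbationSpec,
    StandardCurve,
    apply_perturbation,
    default_scenario,
    elisa_observe,
    generate_cohort,
    generate_params,
)


def two_analyte_truth(lam=1.0, psi=1.0, transform="identity", p=6):
    """Single common factor loading on the first two of p analytes."""
    Lam = np.zeros((p, 1))
    Lam[0, 0] = Lam[1, 0] = lam
    return GroundTruth(
        analytes=[f"A{i}" for i in range(p)],
        groups=["HD", "D"],
        Lambda={g: Lam.copy() for g in ["HD", "D"]},
        Phi={g: np.zeros((p, 0)) for g in ["HD", "D"]},
        Psi={g: np.full(p, psi) for g in ["HD", "D"]},
        mu={g: np.zeros(p) for g in ["HD", "D"]},
        transform=transform,
        seed=5,
        sex_shift=0.0,
        age_shift=0.0,
    )


class TestGenerateParams:
    def test_same_seed_identical(self):
        a = generate_params(10, 2, 1, 3, seed=4)
        b = generate_params(10, 2, 1, 3, seed=4)
        np.testing.assert_array_equal(a.Lambda, b.Lambda)
        for Pa, Pb in zip(a.Phi, b.Phi):
            np.testing.assert_array_equal(Pa, Pb)

    def test_no_factors_gives_diagonal_covariance(self):
        params = generate_params(5, 0, 0, 2, seed=1)
        sigma = marginal_covariance(params, 0)
        np.testing.assert_allclose(sigma, np.diag(np.diag(sigma)))

    def test_sparsity_zero_fraction(self):
        params = generate_params(10, 2, 0, 1, sparsity=0.5, seed=9)
        frac = np.mean(params.Lambda == 0)
        assert 0.3 <= frac <= 0.7  # Binomial(20, 0.5) within generous bounds

    def test_infeasible_dimensions(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_params(3, 2, 1, 2)


class TestGenerateCohort:
    def test_pairwise_pearson_closed_form(self):
        # lam=1, psi=1: population correlation lam^2/(lam^2+psi) = 0.5
        truth = two_analyte_truth(lam=1.0, psi=1.0)
        table = generate_cohort(truth, {"HD": 2000, "D": 0}, seed=21)
        r = table.values[["A0", "A1"]].corr().iloc[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_comonotone_spearman_near_one(self):
        truth = two_analyte_truth(lam=1.0, psi=1e-6, transform="exponential")
        table = generate_cohort(truth, {"HD": 400, "D": 0}, seed=3)
        corr = correlation_matrix(table.select_groups(["HD"]))
        assert corr.values.loc["A0", "A1"] > 0.999

    def test_zero_size_group_absent(self):
        truth = two_analyte_truth()
        table = generate_cohort(truth, {"HD": 10, "D": 0}, seed=1)
        assert set(table.meta["group"]) == {"HD"}

    def test_exponential_transform_positive(self, scenario_cohort):
        assert (scenario_cohort.values.to_numpy() > 0).all()

    def test_seed_determinism(self, scenario_truth):
        a = generate_cohort(scenario_truth, {"HD": 30, "SSc": 20}, seed=77)
        b = generate_cohort(scenario_truth, {"HD": 30, "SSc": 20}, seed=77)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_sample_covariance_converges_to_model(self):
        params = generate_params(8, 2, 1, 1, sparsity=0.2, seed=14)
        truth = GroundTruth(
            analytes=[f"A{i}" for i in range(8)],
            groups=["HD"],
            Lambda={"HD": params.Lambda},
            Phi={"HD": params.Phi[0]},
            Psi={"HD": params.Psi[0]},
            mu={"HD": params.mu[0]},
            transform="identity",
            seed=6,
            sex_shift=0.0,
            age_shift=0.0,
        )
        table = generate_cohort(truth, {"HD": 5000}, seed=6)
        S = np.cov(table.values.to_numpy(), rowvar=False)
        sigma = truth.covariance("HD")
        rel = np.linalg.norm(S - sigma) / np.linalg.norm(sigma)
        assert rel < 0.10


class TestPerturbations:
    def test_break_pair_population_correlations(self):
        truth = two_analyte_truth(lam=2.0, psi=1.0)  # corr = 4/5 = 0.8
        spec = PerturbationSpec("D", "break_pair", ("A0", "A1"), 0.0)
        perturbed = apply_perturbation(truth, spec)
        assert perturbed.correlation("D").loc["A0", "A1"] < 0.2
        assert perturbed.correlation("HD").loc["A0", "A1"] > 0.6

    def test_break_pair_preserves_marginal_variance(self):
        truth = two_analyte_truth(lam=2.0, psi=1.0)
        perturbed = apply_perturbation(
            truth, PerturbationSpec("D", "break_pair", ("A0", "A1"), 0.0)
        )
        np.testing.assert_allclose(
            np.diag(perturbed.covariance("D")), np.diag(truth.covariance("D"))
        )

    def test_scale_spread_zero_magnitude_identity(self):
        truth = two_analyte_truth()
        perturbed = apply_perturbation(
            truth, PerturbationSpec("D", "scale_spread", ("A0",), 0.0)
        )
        np.testing.assert_allclose(perturbed.covariance("D"), truth.covariance("D"))

    def test_shift_mean_only_named_analyte(self):
        truth = two_analyte_truth()
        perturbed = apply_perturbation(
            truth, PerturbationSpec("D", "shift_mean", ("A2",), 1.5)
        )
        delta = perturbed.mu["D"] - truth.mu["D"]
        assert delta[2] != 0
        assert np.all(delta[np.arange(6) != 2] == 0)
        np.testing.assert_allclose(perturbed.covariance("D"), truth.covariance("D"))

    def test_reference_group_untouched(self):
        truth = two_analyte_truth()
        perturbed = apply_perturbation(
            truth, PerturbationSpec("D", "break_pair", ("A0", "A1"), 0.0)
        )
        np.testing.assert_array_equal(perturbed.Lambda["HD"], truth.Lambda["HD"])

    def test_locality_unnamed_analytes_unchanged(self):
        truth = default_scenario(seed=0)
        base = default_scenario(seed=0)
        spec = PerturbationSpec("OC", "scale_spread", ("ADRB1",), 2.0)
        perturbed = apply_perturbation(truth, spec)
        others = [a for a in truth.analytes if a != "ADRB1"]
        pd.testing.assert_frame_equal(
            perturbed.correlation("OC").loc[others, others],
            base.correlation("OC").loc[others, others],
        )

    def test_unknown_analyte_rejected(self):
        truth = two_analyte_truth()
        with pytest.raises(ValueError, match="unknown analyte"):
            apply_perturbation(truth, PerturbationSpec("D", "shift_mean", ("Z9",), 1.0))


class TestStandardCurve:
    def test_exact_recovery_at_standards(self):
        curve = StandardCurve(noise_sd=0.0)
        conc = np.array([[2.5, 5.0, 10.0, 20.0, 40.0]])
        observed, below = elisa_observe(conc, curve, seed=0)
        np.testing.assert_allclose(observed, conc, rtol=1e-12)
        assert not below.any()

    def test_recovery_between_standards(self):
        curve = StandardCurve(noise_sd=0.0)
        conc = np.array([[3.3, 7.7, 13.0, 31.4]])
        observed, _ = elisa_observe(conc, curve, seed=0)
        np.testing.assert_allclose(observed, conc, rtol=1e-9)

    def test_below_range_flagged(self):
        curve = StandardCurve(noise_sd=0.0)
        observed, below = elisa_observe(np.array([[1.0, 10.0]]), curve, seed=0)
        assert below[0, 0] and not below[0, 1]

    def test_noise_requires_seed_reproducibility(self):
        curve = StandardCurve(noise_sd=0.1)
        conc = np.full((5, 3), 12.0)
        a, _ = elisa_observe(conc, curve, seed=9)
        b, _ = elisa_observe(conc, curve, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_monotonicity_validation(self):
        with pytest.raises(ValueError):
            StandardCurve(concentrations=(2.5, 2.5, 10, 20, 40))
        with pytest.raises(ValueError):
            StandardCurve(responses=(0.5, 0.4, 0.6, 0.7, 0.8))


class TestDefaultScenario:
    def test_planted_family_structure(self, scenario_truth):
        corr = scenario_truth.correlation("HD")
        assert corr.loc["AGTR1", "EDNRA"] > 0.6
        assert corr.loc["CXCR3", "CXCR4"] > 0.6
        assert abs(corr.loc["AGTR1", "CXCR3"]) < 1e-12

    def test_ssc_break_pair_and_hd_intact(self, scenario_truth):
        assert scenario_truth.correlation("SSc").loc["F2R", "F2RL1"] < 0.2
        assert scenario_truth.correlation("HD").loc["F2R", "F2RL1"] > 0.6
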