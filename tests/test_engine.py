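"""Correction engine: chi-square scoring, composition estimation, searches."""

import numpy as np
import pytest
from scipy import stats

from bamorc import (
    ClassKey,
    assigned_correction,
    chi_square_statistic,
    class_probabilities,
    estimate_composition,
    grid_search_correction,
    sequence_composition,
    weighted_residual,
)
from bamorc.classes import COMPOSITION_INDEX, N_COMPOSITION
from bamorc.errors import (
    InsufficientDataError,
    SingularMatrixError,
    ValidationError,
)
from bamorc.overlap import OverlapPrior, identity_prior
from bamorc.simulate import (
    SyntheticSpec,
    generate_assigned_table,
    generate_dataset,
    random_sequence,
    random_ss,
)
from bamorc.types import AssignedShiftTable, CarbonPair, CarbonPairDataset


class TestChiSquareStatistic:
    def test_zero_at_mean(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        pair = CarbonPair(m.mu_ca, m.mu_cb, ordered=True)
        assert chi_square_statistic(pair, m, np.eye(2)) == pytest.approx(0.0)

    def test_identity_sigma(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        pair = CarbonPair(m.mu_ca + 1.0, m.mu_cb, ordered=True)
        assert chi_square_statistic(pair, m, np.eye(2)) == pytest.approx(1.0)

    def test_hand_inversion(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        pair = CarbonPair(m.mu_ca + 1.0, m.mu_cb + 1.0, ordered=True)
        sigma = np.array([[4.0, 2.0], [2.0, 4.0]])
        assert chi_square_statistic(pair, m, sigma) == pytest.approx(1.0 / 3.0)

    def test_singular_sigma(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        pair = CarbonPair(m.mu_ca, m.mu_cb, ordered=True)
        with pytest.raises(SingularMatrixError):
            chi_square_statistic(pair, m, np.ones((2, 2)))


class TestClassProbabilities:
    def test_unit_probability_at_class_mean(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        p = class_probabilities(CarbonPair(m.mu_ca, m.mu_cb), reference_models)
        i = COMPOSITION_INDEX[("A", "H")]
        assert p[i] == pytest.approx(1.0)
        assert np.argmax(p) == i

    def test_order_invariance(self, reference_models):
        a = class_probabilities(CarbonPair(56.2, 30.1), reference_models)
        b = class_probabilities(CarbonPair(30.1, 56.2), reference_models)
        assert a == pytest.approx(b)

    def test_survival_oracle(self):
        """exp(-chi/2) equals the integrated chi-square(2 df) upper tail."""
        chis = np.linspace(0.0, 40.0, 401)
        assert np.max(np.abs(np.exp(-chis / 2) - stats.chi2.sf(chis, df=2))) < 1e-10

    def test_chi_two_maps_to_exp_minus_one(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        sd = m.sd_ca
        # displace along Calpha so that chi* = 2 under the B (diagonal) matrix
        from bamorc.statistics import assemble_covariance_matrix
        from bamorc.engine import chi_square_statistic as chi

        pair = CarbonPair(m.mu_ca + sd * np.sqrt(2), m.mu_cb, ordered=True)
        sigma = assemble_covariance_matrix(reference_models, ClassKey("A", "H"), "B")
        c = chi(pair, m, sigma)
        assert c == pytest.approx(2.0)
        assert np.exp(-c / 2) == pytest.approx(np.exp(-1.0))


class TestSequenceComposition:
    def test_single_class(self):
        y = sequence_composition("AAAA", "HHHH")
        assert y[COMPOSITION_INDEX[("A", "H")]] == 1.0
        assert y.sum() == pytest.approx(1.0)

    def test_glycine_dropped_and_renormalized(self):
        y = sequence_composition("AG", "HH")
        assert y[COMPOSITION_INDEX[("A", "H")]] == 1.0

    def test_even_split(self):
        y = sequence_composition("AC", "HE")
        assert y[COMPOSITION_INDEX[("A", "H")]] == 0.5
        assert y[COMPOSITION_INDEX[("C", "E")]] == 0.5

    @pytest.mark.parametrize("seq,ss", [("AB", "HH"), ("AA", "H"), ("AA", "HX")])
    def test_validation(self, seq, ss):
        with pytest.raises(ValidationError):
            sequence_composition(seq, ss)


class TestWeightedResidual:
    def test_zero_at_exact_match(self):
        prior = identity_prior(2)
        y = np.array([0.6, 0.4])
        assert weighted_residual(y, y, prior) == 0.0

    def test_hand_sums(self):
        omega = np.eye(2)
        y_est = np.array([0.6, 0.4])
        y_seq = np.array([0.5, 0.5])
        p1 = OverlapPrior(omega=omega, weights=np.array([1.0, 1.0]))
        assert weighted_residual(y_est, y_seq, p1) == pytest.approx(0.2)
        p2 = OverlapPrior(omega=omega, weights=np.array([0.5, 1.0]))
        assert weighted_residual(y_est, y_seq, p2) == pytest.approx(0.15)


class TestEstimateComposition:
    def test_normalized_57_entries(self, reference_models):
        ds, _ = generate_dataset(
            SyntheticSpec(
                sequence=random_sequence(50, 1),
                ss_string=random_ss(50, 2),
                seed=3,
                model_source=reference_models,
            )
        )
        y = estimate_composition(ds, reference_models)
        assert y.shape == (N_COMPOSITION,)
        assert y.sum() == pytest.approx(1.0)
        assert np.all(y >= 0)

    def test_dominance_at_class_mean(self, reference_models):
        m = reference_models[ClassKey("A", "H")]
        pairs = [CarbonPair(m.mu_ca, m.mu_cb) for _ in range(200)]
        ds = CarbonPairDataset(pairs=pairs, sequence="A" * 200, ss_string="H" * 200)
        y = estimate_composition(ds, reference_models)
        assert np.argmax(y) == COMPOSITION_INDEX[("A", "H")]

    def test_self_consistency_with_prior(self, reference_models, overlap_prior):
        """A large dataset of composition Y estimates to ~ Y . Omega."""
        seq = random_sequence(5000, 4)
        ss = random_ss(5000, 5)
        ds, _ = generate_dataset(
            SyntheticSpec(
                sequence=seq, ss_string=ss, seed=6, model_source=reference_models
            )
        )
        y = estimate_composition(ds, reference_models)
        target = sequence_composition(seq, ss) @ overlap_prior.omega
        assert np.max(np.abs(y - target)) < 0.02

    def test_empty_dataset(self, reference_models):
        ds = CarbonPairDataset(pairs=[], sequence="AA", ss_string="HH")
        with pytest.raises(InsufficientDataError):
            estimate_composition(ds, reference_models)


class TestGridSearchCorrection:
    def test_residual_curve_has_100_points(self, reference_models, overlap_prior):
        ds, _ = generate_dataset(
            SyntheticSpec(
                sequence=random_sequence(60, 7),
                ss_string=random_ss(60, 8),
                true_offset=1.0,
                seed=9,
                model_source=reference_models,
            )
        )
        res = grid_search_correction(ds, reference_models, overlap_prior)
        assert len(res.residual_curve) == 100
        assert abs(res.m2 - res.m1) <= 1.0 + 10.0 / 49.0
        round2 = res.residual_curve[50:]
        assert res.final_residual == pytest.approx(min(r for _, r in round2))

    def test_equivariance(self, reference_models, overlap_prior):
        spec = SyntheticSpec(
            sequence=random_sequence(80, 10),
            ss_string=random_ss(80, 11),
            true_offset=0.5,
            seed=12,
            model_source=reference_models,
        )
        ds, _ = generate_dataset(spec)
        shifted = CarbonPairDataset(
            pairs=[CarbonPair(p.shift_a + 1.0, p.shift_b + 1.0) for p in ds.pairs],
            sequence=ds.sequence,
            ss_string=ds.ss_string,
        )
        r0 = grid_search_correction(ds, reference_models, overlap_prior)
        r1 = grid_search_correction(shifted, reference_models, overlap_prior)
        # one round-2 step (2/49) plus round-1 aliasing (10/49 grid)
        assert r1.m2 - r0.m2 == pytest.approx(1.0, abs=2.0 / 49.0 + 10.0 / 49.0 / 2)

    def test_deterministic(self, reference_models, overlap_prior):
        ds, _ = generate_dataset(
            SyntheticSpec(
                sequence=random_sequence(60, 13),
                ss_string=random_ss(60, 14),
                true_offset=-2.0,
                seed=15,
                model_source=reference_models,
            )
        )
        a = grid_search_correction(ds, reference_models, overlap_prior)
        b = grid_search_correction(ds, reference_models, overlap_prior)
        assert a.m2 == b.m2 and a.residual_curve == b.residual_curve

    def test_empty_dataset(self, reference_models):
        ds = CarbonPairDataset(pairs=[], sequence="AA", ss_string="HH")
        with pytest.raises(InsufficientDataError):
            grid_search_correction(ds, reference_models)

    def test_low_completeness_warns(self, reference_models):
        ds, _ = generate_dataset(
            SyntheticSpec(
                sequence=random_sequence(100, 16),
                ss_string=random_ss(100, 17),
                missing_fraction=0.7,
                seed=18,
                model_source=reference_models,
            )
        )
        with pytest.warns(UserWarning, match="complete"):
            grid_search_correction(ds, reference_models)


class TestAssignedCorrection:
    def test_recovery(self, reference_models):
        """Known assignments pin the offset to a few hundredths of a ppm."""
        tab, _ = generate_assigned_table(
            SyntheticSpec(
                sequence=random_sequence(2000, 70),
                ss_string=random_ss(2000, 71),
                true_offset=1.5,
                seed=72,
                model_source=reference_models,
            )
        )
        res = assigned_correction(tab, reference_models, seed=0)
        assert res.m2 == pytest.approx(1.5, abs=0.05)
        assert res.method == "de"

    def test_objective_shape(self, reference_models):
        from bamorc.engine import _assigned_objective_factory

        tab, _ = generate_assigned_table(
            SyntheticSpec(
                sequence=random_sequence(150, 73),
                ss_string=random_ss(150, 74),
                true_offset=0.8,
                seed=75,
                model_source=reference_models,
            )
        )
        obj = _assigned_objective_factory(tab, reference_models)
        assert obj(0.8) < obj(2.8)
        assert obj(0.8) < obj(-1.2)

    def test_empty_table(self, reference_models):
        with pytest.raises(InsufficientDataError):
            assigned_correction(AssignedShiftTable(rows=[]), reference_models)

    def test_deterministic(self, reference_models):
        tab, _ = generate_assigned_table(
            SyntheticSpec(
                sequence=random_sequence(100, 76),
                ss_string=random_ss(100, 77),
                true_offset=-0.7,
                seed=78,
                model_source=reference_models,
            )
        )
        a = assigned_correction(tab, reference_models, seed=5)
        b = assigned_correction(tab, reference_models, seed=5)
        assert a.m2 == b.m2
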