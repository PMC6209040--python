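"""Class statistics, cysteine splitting, Q statistic and covariance refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamorc import (
    ClassKey,
    assemble_covariance_matrix,
    compute_class_statistics,
    fit_model_set,
    refine_covariance_selection,
    rmsd_q_statistic,
    split_cysteine_states,
)
from bamorc.classes import ALL_MODEL_KEYS, BIVARIATE_KEYS
from bamorc.errors import (
    DegenerateClusterError,
    InsufficientDataError,
    MissingClassError,
    NoBivariateModelError,
    UndefinedQError,
)
from bamorc.reference_models import build_reference_models
from bamorc.simulate import generate_corpus
from bamorc.statistics import make_entry_quality
from bamorc.types import BivariateClassModel, ModelSet, ShiftRecord


def _rec(ca, cb, aa="A", ss="H", entry="X", idx=0, state="unknown"):
    return ShiftRecord(
        entry_id=entry,
        residue_index=idx,
        amino_acid=aa,
        secondary_structure=ss,
        ca_shift=ca,
        cb_shift=cb,
        cys_state=state,
    )


class TestComputeClassStatistics:
    def test_hand_example(self):
        records = [_rec(70.0, 30.0), _rec(72.0, 32.0)]
        m = compute_class_statistics(records, ClassKey("A", "H"))
        assert m.mu_ca == pytest.approx(71.0)
        assert m.mu_cb == pytest.approx(31.0)
        assert m.sd_ca == pytest.approx(np.sqrt(2), abs=1e-4)
        assert m.sd_cb == pytest.approx(np.sqrt(2), abs=1e-4)
        assert m.cov == pytest.approx(2.0)

    def test_zero_variance(self):
        records = [_rec(50.0, 30.0, idx=i) for i in range(3)]
        m = compute_class_statistics(records, ClassKey("A", "H"))
        assert m.sd_ca == 0.0 and m.sd_cb == 0.0 and m.cov == 0.0

    def test_monte_carlo_recovery(self):
        """At n=50,000 sample statistics match generating parameters to 2%."""
        rng = np.random.default_rng(5)
        mu, sds, r = (58.0, 33.0), (1.2, 1.5), -0.4
        cov = r * sds[0] * sds[1]
        draws = rng.multivariate_normal(
            mu, [[sds[0] ** 2, cov], [cov, sds[1] ** 2]], size=50_000
        )
        records = [_rec(ca, cb, idx=i) for i, (ca, cb) in enumerate(draws)]
        m = compute_class_statistics(records, ClassKey("A", "H"))
        assert m.mu_ca == pytest.approx(mu[0], rel=0.02)
        assert m.mu_cb == pytest.approx(mu[1], rel=0.02)
        assert m.sd_ca == pytest.approx(sds[0], rel=0.02)
        assert m.sd_cb == pytest.approx(sds[1], rel=0.02)
        assert m.cov == pytest.approx(cov, rel=0.02)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError, match="A-H"):
            compute_class_statistics([_rec(70.0, 30.0)], ClassKey("A", "H"))

    def test_glycine_univariate(self):
        records = [
            ShiftRecord("X", i, "G", "C", 44.0 + i) for i in range(4)
        ]
        m = compute_class_statistics(records, ClassKey("G", "C"))
        assert m.mu_cb is None and m.cov is None
        assert m.mu_ca == pytest.approx(45.5)


class TestAssembleCovarianceMatrix:
    @pytest.fixture()
    def toy_models(self):
        """One residue type with distinct per-SS statistics."""
        models = dict(build_reference_models().models)
        stats = {"H": (2.0, 1.0, 1.0), "E": (2.0, 1.0, 1.5), "C": (2.0, 1.0, 2.0)}
        for ss, (sa, sb, cov) in stats.items():
            key = ClassKey("A", ss)
            models[key] = BivariateClassModel(
                key=key, mu_ca=55.0, mu_cb=19.0, sd_ca=sa, sd_cb=sb, cov=cov, n=100
            )
        return ModelSet(variant="E", models=models)

    def test_variant_a_pooled_diagonal(self, toy_models):
        sigma = assemble_covariance_matrix(toy_models, ClassKey("A", "H"), "A")
        assert sigma == pytest.approx(np.diag([4.0, 1.0]))

    def test_variant_d_mean_covariance(self, toy_models):
        sigma = assemble_covariance_matrix(toy_models, ClassKey("A", "H"), "D")
        assert sigma[0, 1] == pytest.approx(1.5)
        assert sigma[1, 0] == pytest.approx(1.5)

    def test_variant_e_identity_mapping(self, reference_models):
        key = ClassKey("A", "H")
        m = reference_models[key]
        sigma = assemble_covariance_matrix(reference_models, key, "E")
        assert sigma == pytest.approx(
            np.array([[m.sd_ca**2, m.cov], [m.cov, m.sd_cb**2]])
        )

    def test_glycine_rejected(self, reference_models):
        with pytest.raises(NoBivariateModelError):
            assemble_covariance_matrix(reference_models, ClassKey("G", "H"), "E")

    @pytest.mark.parametrize("variant", ["A", "B", "C", "D", "E"])
    def test_symmetric_positive_semidefinite(self, reference_models, variant):
        for key in BIVARIATE_KEYS:
            sigma = assemble_covariance_matrix(reference_models, key, variant)
            assert sigma[0, 1] == sigma[1, 0]
            assert np.all(np.linalg.eigvalsh(sigma) >= -1e-12)


class TestSplitCysteineStates:
    def _cloud(self, center, n, seed, ss="H"):
        rng = np.random.default_rng(seed)
        pts = rng.normal(center, 1.0, size=(n, 2))
        return [
            _rec(ca, cb, aa="C", ss=ss, idx=i + seed * 1000)
            for i, (ca, cb) in enumerate(pts)
        ]

    def test_labels_by_generating_centroid(self):
        ox = self._cloud((55.5, 41.0), 200, seed=1)
        red = self._cloud((59.5, 28.0), 200, seed=2)
        labelled = split_cysteine_states(ox + red)
        by_idx = {r.residue_index: r.cys_state for r in labelled}
        assert all(by_idx[r.residue_index] == "oxidized" for r in ox)
        assert all(by_idx[r.residue_index] == "reduced" for r in red)

    def test_degenerate_cluster(self):
        identical = [_rec(58.0, 28.0, aa="C", idx=i) for i in range(5)]
        with pytest.raises(DegenerateClusterError):
            split_cysteine_states(identical)

    def test_restart_stability(self):
        records = self._cloud((55.5, 41.0), 200, seed=3) + self._cloud(
            (59.5, 28.0), 200, seed=4
        )
        a = split_cysteine_states(records, random_state=0)
        b = split_cysteine_states(records, random_state=12345)
        assert [r.cys_state for r in a] == [r.cys_state for r in b]


class TestQStatistic:
    @pytest.mark.parametrize(
        "ca,cb,expected",
        [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.3, 0.1, 0.7937005259)],
    )
    def test_values(self, ca, cb, expected):
        assert rmsd_q_statistic(ca, cb) == pytest.approx(expected, abs=1e-5)

    def test_both_zero(self):
        with pytest.raises(UndefinedQError):
            rmsd_q_statistic(0.0, 0.0)

    @given(
        a=st.floats(1e-3, 10.0),
        b=st.floats(1e-3, 10.0),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_scale_invariance(self, a, b, scale):
        q = rmsd_q_statistic(a, b)
        assert 0.0 <= q <= 1.0
        assert rmsd_q_statistic(b, a) == pytest.approx(q)
        assert rmsd_q_statistic(a * scale, b * scale) == pytest.approx(q, abs=1e-9)


def _quality_entries(n_low, n_high, r_low, r_high, seed, n_pairs=30):
    """Entries with controlled Q and controlled deviation correlation."""
    rng = np.random.default_rng(seed)
    entries = []
    for k in range(n_low + n_high):
        low = k < n_low
        r = r_low if low else r_high
        devs = rng.multivariate_normal(
            [0, 0], [[1.0, r], [r, 1.0]], size=n_pairs
        )
        if low:
            rmsd_ca = rng.uniform(0.4, 0.5)
            rmsd_cb = rmsd_ca * (1 + rng.uniform(-0.05, 0.05))
        else:
            rmsd_ca = rng.uniform(0.2, 0.3)
            rmsd_cb = rmsd_ca * rng.uniform(2.5, 3.5)
        entries.append((make_entry_quality(f"E{k}", rmsd_ca, rmsd_cb), devs))
    return entries


class TestRefineCovarianceSelection:
    def test_recovers_generating_cutoff(self):
        entries = _quality_entries(20, 20, r_low=-0.4, r_high=0.0, seed=6, n_pairs=200)
        report = refine_covariance_selection(entries)
        assert 0.25 <= report.q_cutoff <= 0.35
        low_ids = {e[0].entry_id for e in entries if e[0].q <= report.q_cutoff}
        assert set(report.selected_entry_ids) == low_ids
        assert report.p_value < 0.01

    def test_no_signal_selects_all(self):
        entries = _quality_entries(20, 20, r_low=-0.3, r_high=-0.3, seed=7)
        report = refine_covariance_selection(entries)
        # no split produces a convincing contrast; p-value stays large
        assert report.p_value > 0.01

    def test_too_few_entries_selects_all(self):
        entries = _quality_entries(6, 6, r_low=-0.4, r_high=0.0, seed=8)
        report = refine_covariance_selection(entries)
        assert report.p_value == 1.0
        assert len(report.selected_entry_ids) == 12


class TestFitModelSet:
    def test_missing_class_error(self):
        gly_only = [ShiftRecord("X", i, "G", "H", 45.0 + 0.1 * i) for i in range(10)]
        with pytest.raises(MissingClassError):
            fit_model_set(gly_only)

    def test_complete_over_63_keys(self, reference_models):
        records, _ = generate_corpus(reference_models, n_per_class=30, seed=3)
        ms = fit_model_set(records, variant="E")
        assert set(ms.models) == set(ALL_MODEL_KEYS)

    def test_e_revised_beats_e_on_contaminated_corpus(self, reference_models):
        """With half the entries decorrelated, refined covariances sit closer
        to the generating ones than the all-data covariances do."""
        records, qualities = generate_corpus(
            reference_models,
            n_per_class=400,
            seed=13,
            n_entries=40,
            decorrelated_fraction=0.5,
        )
        ms_e = fit_model_set(records, qualities, variant="E")
        ms_rev = fit_model_set(records, qualities, variant="E_revised")
        err_e, err_rev = 0.0, 0.0
        for key in BIVARIATE_KEYS:
            true_cov = reference_models[key].cov
            err_e += abs(ms_e[key].cov - true_cov)
            err_rev += abs(ms_rev[key].cov - true_cov)
        assert err_rev < err_e
        assert ms_rev.selection_report is not None
        # roughly the correlated half of the entries should be retained
        assert 15 <= len(ms_rev.selection_report.selected_entry_ids) <= 25
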