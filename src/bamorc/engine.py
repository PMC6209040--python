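"""Reference-correction engine.

A mis-referenced carbon dimension adds one constant offset to every 13C
shift.  The engine finds that offset by comparing two amino-acid/secondary-
structure composition vectors over the 57 non-glycine classes:

* Y, the composition known from the protein sequence and its secondary
  structure;
* Y'(c), the composition estimated from the spin systems after subtracting a
  candidate correction c: each unordered (Calpha, Cbeta) pair is scored
  against the 60 bivariate class models with the Mahalanobis chi-square
  statistic, converted to an upper-tail chi-square(2 df) probability
  exp(-chi/2), summed per class and normalized.

The residual min_c sum_i w_i |Y'_i(c) - (Y . Omega)_i| — with Omega the
prediction-overlap matrix acting as a Bayesian prior and w its diagonal — is
minimized by a two-round grid search.  The assigned variant knows each pair's
class, scores it against that single model, and minimizes the mean chi-square
by differential evolution.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.optimize import differential_evolution

from .classes import (
    BIVARIATE_KEYS,
    BIVARIATE_INDEX,
    COMPOSITION_INDEX,
    CYS_STATES,
    CYSTEINE,
    GLYCINE,
    MERGE_MATRIX,
    N_COMPOSITION,
    NON_GLY_RESIDUES,
    ClassKey,
    SS_TYPES,
)
from .errors import InsufficientDataError, SingularMatrixError, ValidationError
from .overlap import OverlapPrior, identity_prior
from .statistics import assemble_covariance_matrix
from .types import (
    AssignedShiftTable,
    BivariateClassModel,
    CarbonPair,
    CarbonPairDataset,
    CorrectionResult,
    ModelSet,
)

SEARCH_MIN = -5.0
SEARCH_MAX = 5.0
N_CANDIDATES = 50
ROUND2_HALF_WIDTH = 1.0
COMPLETENESS_WARN = 0.5

DE_BOUNDS = (-10.0, 10.0)
DE_POPSIZE = 40
DE_MAXITER = 50


def chi_square_statistic(
    pair: CarbonPair, model: BivariateClassModel, sigma: np.ndarray
) -> float:
    """Mahalanobis chi-square of an ordered (Calpha, Cbeta) pair vs a model."""
    sigma = np.asarray(sigma, dtype=float)
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
    if abs(det) < 1e-12:
        raise SingularMatrixError(f"singular covariance matrix for class {model.key}")
    d = np.array([pair.shift_a - model.mu_ca, pair.shift_b - model.mu_cb])
    inv = np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[1, 0], sigma[0, 0]]]) / det
    return float(d @ inv @ d)


class _EngineArrays:
    """Vectorized view of a ModelSet: means and inverse covariances (60, ...)."""

    def __init__(self, model_set: ModelSet, variant: Optional[str] = None):
        variant = variant or model_set.variant
        mu = np.empty((len(BIVARIATE_KEYS), 2))
        inv = np.empty((len(BIVARIATE_KEYS), 2, 2))
        for i, key in enumerate(BIVARIATE_KEYS):
            m = model_set[key]
            mu[i] = (m.mu_ca, m.mu_cb)
            sigma = assemble_covariance_matrix(model_set, key, variant)
            det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
            if abs(det) < 1e-12:
                raise SingularMatrixError(f"singular covariance for class {key}")
            inv[i] = (
                np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[0, 1], sigma[0, 0]]])
                / det
            )
        self.mu = mu
        self.inv = inv

    def chi(self, v: np.ndarray) -> np.ndarray:
        """chi-square of ordered pairs v (..., 2) against all 60 models."""
        d = v[..., None, :] - self.mu  # (..., 60, 2)
        a, b, c = self.inv[:, 0, 0], self.inv[:, 0, 1], self.inv[:, 1, 1]
        return d[..., 0] ** 2 * a + 2 * d[..., 0] * d[..., 1] * b + d[..., 1] ** 2 * c

    def prob60(self, v: np.ndarray, ordered: bool = False) -> np.ndarray:
        """Upper-tail chi-square(2) probabilities exp(-chi/2), (..., 60).

        Unordered pairs are evaluated in both orderings; the larger
        probability (smaller chi-square) is kept per model, which makes the
        result invariant under swapping the two shifts.
        """
        chi = self.chi(v)
        if not ordered:
            chi = np.minimum(chi, self.chi(v[..., ::-1]))
        return np.exp(-0.5 * chi)


def _pairs_array(dataset: CarbonPairDataset) -> np.ndarray:
    return np.array([(p.shift_a, p.shift_b) for p in dataset.pairs], dtype=float)


def class_probabilities(pair: CarbonPair, model_set: ModelSet) -> np.ndarray:
    """Unnormalized 57-class probabilities of one carbon pair.

    Each of the 60 bivariate models yields p = P(chi2_2 >= chi*) =
    exp(-chi*/2); the two cysteine-state probabilities of each secondary
    structure are merged by summation into the single cysteine composition
    class.
    """
    arrays = _EngineArrays(model_set)
    v = np.array([pair.shift_a, pair.shift_b])
    p60 = arrays.prob60(v, ordered=pair.ordered)
    return p60 @ MERGE_MATRIX


def sequence_composition(sequence: str, ss_string: str) -> np.ndarray:
    """Normalized 57-class composition Y from sequence + secondary structure.

    Glycine residues carry no beta carbon and are excluded; the remaining
    counts are renormalized.
    """
    if len(sequence) != len(ss_string):
        raise ValidationError("sequence and SS string must have equal length")
    y = np.zeros(N_COMPOSITION)
    for aa, ss in zip(sequence, ss_string):
        if aa == GLYCINE:
            continue
        if aa not in NON_GLY_RESIDUES:
            raise ValidationError(f"unknown residue letter {aa!r}")
        if ss not in SS_TYPES:
            raise ValidationError(f"unknown secondary-structure letter {ss!r}")
        y[COMPOSITION_INDEX[(aa, ss)]] += 1.0
    total = y.sum()
    if total == 0:
        raise ValidationError("sequence contains no non-glycine residues")
    return y / total


def estimate_composition(
    dataset: CarbonPairDataset,
    model_set: ModelSet,
    candidate_correction: float = 0.0,
    _arrays: Optional[_EngineArrays] = None,
) -> np.ndarray:
    """Estimated composition Y' after removing a candidate correction.

    The candidate is subtracted from both carbons of every pair; each pair's
    57-class probability vector is normalized to unit mass, the vectors are
    summed element-wise over the dataset and the result is normalized again.
    Per-pair normalization keeps the estimate consistent with the overlap
    prior: a large dataset of true composition Y then yields Y' -> Y . Omega.
    """
    if not dataset.pairs:
        raise InsufficientDataError("cannot estimate composition of an empty dataset")
    arrays = _arrays or _EngineArrays(model_set)
    v = _pairs_array(dataset) - candidate_correction
    p57 = arrays.prob60(v) @ MERGE_MATRIX
    p57 = p57 / np.maximum(p57.sum(axis=1, keepdims=True), 1e-300)
    y = p57.sum(axis=0)
    return y / y.sum()


def weighted_residual(
    y_est: np.ndarray, y_seq: np.ndarray, prior: OverlapPrior
) -> float:
    """sum_i w_i |y_est_i - (y_seq . Omega)_i| (the optimization residual)."""
    target = y_seq @ prior.omega
    return float(np.sum(prior.weights * np.abs(y_est - target)))


def _argmin_tiebreak(candidates: np.ndarray, residuals: np.ndarray) -> int:
    """Index of the smallest residual; ties go to the smallest |candidate|."""
    return min(
        range(len(candidates)),
        key=lambda i: (residuals[i], abs(candidates[i]), candidates[i]),
    )


def _residuals_at(
    candidates: np.ndarray,
    pairs: np.ndarray,
    arrays: _EngineArrays,
    target: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Vectorized residual evaluation over a 1D grid of candidates."""
    v = pairs[None, :, :] - candidates[:, None, None]  # (K, P, 2)
    p57 = arrays.prob60(v) @ MERGE_MATRIX  # (K, P, 57)
    p57 = p57 / np.maximum(p57.sum(axis=2, keepdims=True), 1e-300)
    y = p57.sum(axis=1)
    y = y / y.sum(axis=1, keepdims=True)
    return np.abs(y - target) @ weights


def grid_search_correction(
    dataset: CarbonPairDataset,
    model_set: ModelSet,
    prior: Optional[OverlapPrior] = None,
    search_min: float = SEARCH_MIN,
    search_max: float = SEARCH_MAX,
    n_candidates: int = N_CANDIDATES,
) -> CorrectionResult:
    """Two-round grid search for the carbon reference correction.

    Round 1 samples ``n_candidates`` (default 50) evenly spaced corrections on
    [search_min, search_max] (default [-5, 5] ppm) and takes the residual
    argmin M1; round 2 samples another 50 on [M1 - 1, M1 + 1] and reports the
    argmin M2 as the final correction.  The corrected shifts are the observed
    values minus M2.  With no prior supplied, the identity overlap matrix and
    unit weights are used (the un-ablated method passes the fitted prior).
    """
    if not dataset.pairs:
        raise InsufficientDataError("cannot run a grid search on an empty dataset")
    if dataset.completeness < COMPLETENESS_WARN:
        warnings.warn(
            f"dataset is only {dataset.completeness:.0%} complete "
            f"(< {COMPLETENESS_WARN:.0%}); the correction may be unreliable",
            stacklevel=2,
        )
    prior = prior or identity_prior()
    arrays = _EngineArrays(model_set)
    pairs = _pairs_array(dataset)
    y_seq = sequence_composition(dataset.sequence, dataset.ss_string)
    target = y_seq @ prior.omega

    round1 = np.linspace(search_min, search_max, n_candidates)
    res1 = _residuals_at(round1, pairs, arrays, target, prior.weights)
    i1 = _argmin_tiebreak(round1, res1)
    m1 = float(round1[i1])

    round2 = np.linspace(m1 - ROUND2_HALF_WIDTH, m1 + ROUND2_HALF_WIDTH, n_candidates)
    res2 = _residuals_at(round2, pairs, arrays, target, prior.weights)
    i2 = _argmin_tiebreak(round2, res2)
    m2 = float(round2[i2])

    curve = [(float(c), float(r)) for c, r in zip(round1, res1)]
    curve += [(float(c), float(r)) for c, r in zip(round2, res2)]
    return CorrectionResult(
        m1=m1,
        m2=m2,
        residual_curve=curve,
        final_residual=float(res2[i2]),
        method="grid",
    )


def _assigned_objective_factory(table: AssignedShiftTable, model_set: ModelSet):
    """Vectorized mean-chi-square objective over the table's assigned rows."""
    rows = table.usable_rows()
    shifts = np.array([(r.ca_shift, r.cb_shift) for r in rows], dtype=float)
    mu_list, inv_list, row_of = [], [], []
    arrays = _EngineArrays(model_set)
    for i, r in enumerate(rows):
        classes = (
            CYS_STATES if r.amino_acid == CYSTEINE else (r.amino_acid,)
        )
        for aa_class in classes:
            j = BIVARIATE_INDEX[ClassKey(aa_class, r.secondary_structure)]
            mu_list.append(arrays.mu[j])
            inv_list.append(arrays.inv[j])
            row_of.append(i)
    mu = np.asarray(mu_list)
    inv = np.asarray(inv_list)
    row_of = np.asarray(row_of)
    a, b, c = inv[:, 0, 0], inv[:, 0, 1], inv[:, 1, 1]
    n_rows = len(rows)

    def objective(correction: float) -> float:
        d = shifts[row_of] - correction - mu
        chi = d[:, 0] ** 2 * a + 2 * d[:, 0] * d[:, 1] * b + d[:, 1] ** 2 * c
        # cysteine rows contribute the smaller of their two state chi-squares
        per_row = np.full(n_rows, np.inf)
        np.minimum.at(per_row, row_of, chi)
        return float(per_row.mean())

    return objective


def assigned_correction(
    table: AssignedShiftTable,
    model_set: ModelSet,
    seed: int = 0,
    bounds: tuple[float, float] = DE_BOUNDS,
    popsize: int = DE_POPSIZE,
    maxiter: int = DE_MAXITER,
) -> CorrectionResult:
    """Assigned-mode correction by differential evolution.

    With known residue types and secondary structure, each row is scored
    against exactly one class model (cysteine: the better of its two state
    models) and the mean chi-square over rows is minimized over a single
    offset applied to both carbons.
    """
    rows = table.usable_rows()
    if len(rows) < 5:
        raise InsufficientDataError(
            f"assigned correction needs >= 5 usable non-glycine rows, got {len(rows)}"
        )
    objective = _assigned_objective_factory(table, model_set)
    result = differential_evolution(
        lambda x: objective(float(x[0])),
        bounds=[bounds],
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=1e-8,
        polish=True,
    )
    m2 = float(result.x[0])
    curve_x = np.linspace(bounds[0], bounds[1], 100)
    curve = [(float(c), objective(float(c))) for c in curve_x]
    return CorrectionResult(
        m1=m2,
        m2=m2,
        residual_curve=curve,
        final_residual=objective(m2),
        method="de",
    )


def apply_correction(dataset: CarbonPairDataset, correction: float) -> CarbonPairDataset:
    """Re-referenced copy of a dataset: every carbon minus the correction."""
    pairs = [
        CarbonPair(p.shift_a - correction, p.shift_b - correction, p.ordered)
        for p in dataset.pairs
    ]
    singles = [s - correction for s in dataset.ca_singles]
    return CarbonPairDataset(
        pairs=pairs,
        sequence=dataset.sequence,
        ss_string=dataset.ss_string,
        ca_singles=singles,
    )
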