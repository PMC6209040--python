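"""Prediction-overlap prior.

The bivariate class models overlap heavily in the (Calpha, Cbeta) plane, so a
composition estimated by probabilistic typing is a smeared version of the
true composition.  The overlap matrix Omega captures that smearing
empirically: row t is the average normalized 57-class probability vector of
corpus records whose true class is t.  Multiplying the sequence composition Y
by Omega "ages" it the same way the classifier ages the data, and the
diagonal of Omega weights each class by how self-identifiable it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .classes import (
    COMPOSITION_CLASSES,
    COMPOSITION_INDEX,
    GLYCINE,
    MERGE_MATRIX,
    N_COMPOSITION,
    ClassKey,
    SS_TYPES,
    composition_label,
)
from .errors import MissingClassError, ValidationError
from .types import ModelSet, ShiftRecord


@dataclass
class OverlapPrior:
    """Row-stochastic overlap matrix Omega plus its diagonal weights.

    ``glycine_block`` optionally carries the 3x3 overlap of the glycine
    (Calpha-only) classes; it is unused unless glycine support is enabled.
    """

    omega: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...] = tuple(
        composition_label(i) for i in range(N_COMPOSITION)
    )
    glycine_block: Optional[np.ndarray] = None

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.omega.shape[0]
        if self.omega.shape != (n, n) or self.weights.shape != (n,):
            raise ValidationError("omega must be square and weights its diagonal size")


def identity_prior(n: int = N_COMPOSITION) -> OverlapPrior:
    """No-prior ablation: identity overlap matrix and unit weights."""
    return OverlapPrior(omega=np.eye(n), weights=np.ones(n))


def compute_overlap_matrix(
    corpus: Sequence[ShiftRecord],
    model_set: ModelSet,
    include_glycine: bool = False,
) -> OverlapPrior:
    """Estimate Omega from corpus records of known true class.

    For every non-glycine record with both shifts, the normalized 57-class
    probability vector is computed and accumulated into the row of the
    record's true (residue, SS) class; rows are averaged and renormalized to
    sum 1.  The weights are the diagonal.  With ``include_glycine`` a separate
    3x3 block is built from glycine Calpha shifts and the three univariate
    glycine models (chi-square with 1 df).
    """
    from .engine import _EngineArrays  # deferred: engine imports this module

    arrays = _EngineArrays(model_set)
    usable = [
        r for r in corpus if r.amino_acid != GLYCINE and r.cb_shift is not None
    ]
    if not usable:
        raise MissingClassError(
            [ClassKey(aa, ss) for aa, ss in COMPOSITION_CLASSES]
        )
    v = np.array([(r.ca_shift, r.cb_shift) for r in usable])
    true_idx = np.array(
        [COMPOSITION_INDEX[(r.amino_acid, r.secondary_structure)] for r in usable]
    )
    p57 = arrays.prob60(v) @ MERGE_MATRIX
    p57 = p57 / p57.sum(axis=1, keepdims=True)

    counts = np.bincount(true_idx, minlength=N_COMPOSITION).astype(float)
    empty = counts == 0
    if np.any(empty):
        raise MissingClassError(
            [
                ClassKey(*COMPOSITION_CLASSES[i])
                for i in np.flatnonzero(empty)
            ]
        )
    omega = np.zeros((N_COMPOSITION, N_COMPOSITION))
    np.add.at(omega, true_idx, p57)
    omega /= counts[:, None]
    omega /= omega.sum(axis=1, keepdims=True)

    glycine_block = None
    if include_glycine:
        glycine_block = _glycine_overlap_block(corpus, model_set)
    return OverlapPrior(
        omega=omega, weights=np.diag(omega).copy(), glycine_block=glycine_block
    )


def _glycine_overlap_block(
    corpus: Sequence[ShiftRecord], model_set: ModelSet
) -> np.ndarray:
    """3x3 overlap of the glycine Calpha-only classes (chi-square, 1 df)."""
    gly = [r for r in corpus if r.amino_acid == GLYCINE]
    if not gly:
        raise MissingClassError([ClassKey(GLYCINE, ss) for ss in SS_TYPES])
    mu = np.array([model_set[ClassKey(GLYCINE, ss)].mu_ca for ss in SS_TYPES])
    sd = np.array([model_set[ClassKey(GLYCINE, ss)].sd_ca for ss in SS_TYPES])
    ca = np.array([r.ca_shift for r in gly])
    chi = ((ca[:, None] - mu) / sd) ** 2
    p = stats.chi2.sf(chi, df=1)
    p = p / np.maximum(p.sum(axis=1, keepdims=True), 1e-300)
    block = np.zeros((3, 3))
    ss_index = {ss: i for i, ss in enumerate(SS_TYPES)}
    idx = np.array([ss_index[r.secondary_structure] for r in gly])
    counts = np.bincount(idx, minlength=3).astype(float)
    if np.any(counts == 0):
        raise MissingClassError(
            [ClassKey(GLYCINE, SS_TYPES[i]) for i in np.flatnonzero(counts == 0)]
        )
    np.add.at(block, idx, p)
    block /= counts[:, None]
    block /= block.sum(axis=1, keepdims=True)
    return block


def classifier_weights(prior: OverlapPrior) -> np.ndarray:
    """The diagonal of Omega, unmodified."""
    return np.diag(prior.omega).copy()


def apply_prior(y: np.ndarray, prior: OverlapPrior) -> np.ndarray:
    """y . Omega; conserves mass for a row-stochastic Omega."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != prior.omega.shape[0]:
        raise ValidationError(
            f"composition length {y.shape[-1]} != overlap dimension "
            f"{prior.omega.shape[0]}"
        )
    return y @ prior.omega
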