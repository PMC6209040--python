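"""Per-class Calpha/Cbeta shift statistics and covariance refinement.

This module turns an assigned-shift corpus into the bank of bivariate
Gaussian class models the correction engine scores against:

1. group records by (amino acid, secondary structure);
2. split cysteine into its two oxidation states by K-means (K=2) on the
   (Calpha, Cbeta) plane, per secondary structure;
3. compute sample means, standard deviations and covariances (n-1
   denominators);
4. optionally refine the covariances by discarding entries whose Calpha and
   Cbeta shifts appear decoupled (e.g. assembled from different spectra),
   using the RMSD-based Q statistic and a correlation-difference scan.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .classes import (
    ALL_MODEL_KEYS,
    CYS_OXIDIZED,
    CYS_REDUCED,
    CYSTEINE,
    ClassKey,
    SS_TYPES,
)
from .errors import (
    DegenerateClusterError,
    InsufficientDataError,
    MissingClassError,
    NoBivariateModelError,
    UndefinedQError,
)
from .types import (
    BivariateClassModel,
    EntryQuality,
    ModelSet,
    SelectionReport,
    ShiftRecord,
    records_to_array,
)

#: Minimum number of entries each side of an admissible Q-cutoff split.
MIN_GROUP_SIZE = 10

#: Minimum shift pairs an entry must contribute to the refinement scan.
MIN_PAIRS_PER_ENTRY = 3


def _matches(record: ShiftRecord, key: ClassKey) -> bool:
    if record.secondary_structure != key.secondary_structure:
        return False
    if key.amino_acid_class in (CYS_OXIDIZED, CYS_REDUCED):
        return record.amino_acid == CYSTEINE and record.model_class == key.amino_acid_class
    return record.amino_acid == key.amino_acid_class


def compute_class_statistics(
    records: Sequence[ShiftRecord], key: ClassKey
) -> BivariateClassModel:
    """Sample mean/sd/covariance of the records matching ``key``.

    All denominators are n-1.  Glycine classes are univariate (Calpha only).
    Raises :class:`InsufficientDataError` below two matching records.
    """
    matching = [r for r in records if _matches(r, key)]
    if len(matching) < 2:
        raise InsufficientDataError(
            f"class {key.amino_acid_class}-{key.secondary_structure}: "
            f"{len(matching)} record(s), need at least 2"
        )
    ca = np.array([r.ca_shift for r in matching], dtype=float)
    if key.is_glycine:
        return BivariateClassModel(
            key=key,
            mu_ca=float(ca.mean()),
            sd_ca=float(ca.std(ddof=1)),
            n=len(matching),
        )
    if any(r.cb_shift is None for r in matching):
        raise InsufficientDataError(
            f"class {key.amino_acid_class}-{key.secondary_structure}: "
            "bivariate statistics require cb_shift on every record"
        )
    cb = np.array([r.cb_shift for r in matching], dtype=float)
    cov = float(np.cov(ca, cb, ddof=1)[0, 1])
    return BivariateClassModel(
        key=key,
        mu_ca=float(ca.mean()),
        mu_cb=float(cb.mean()),
        sd_ca=float(ca.std(ddof=1)),
        sd_cb=float(cb.std(ddof=1)),
        cov=cov,
        n=len(matching),
    )


def assemble_covariance_matrix(
    model_set: ModelSet, key: ClassKey, variant: Optional[str] = None
) -> np.ndarray:
    """2x2 covariance matrix of a non-glycine class under a matrix variant.

    A: pooled variances, no covariance.  B: SS-specific variances, no
    covariance.  C: pooled variances and pooled covariance.  D: SS-specific
    variances, covariance averaged over the three secondary structures.
    E / E_revised: fully SS-specific variances and covariance.
    """
    if key.is_glycine:
        raise NoBivariateModelError("glycine has no bivariate covariance matrix")
    variant = variant or model_set.variant
    m = model_set[key]
    if variant == "A":
        sd_ca, sd_cb, _ = model_set.pooled_stats(key.amino_acid_class)
        return np.diag([sd_ca**2, sd_cb**2])
    if variant == "B":
        return np.diag([m.sd_ca**2, m.sd_cb**2])
    if variant == "C":
        sd_ca, sd_cb, cov = model_set.pooled_stats(key.amino_acid_class)
        return np.array([[sd_ca**2, cov], [cov, sd_cb**2]])
    if variant == "D":
        covs = [
            model_set[ClassKey(key.amino_acid_class, ss)].cov for ss in SS_TYPES
        ]
        mean_cov = float(np.mean(covs))
        return np.array([[m.sd_ca**2, mean_cov], [mean_cov, m.sd_cb**2]])
    if variant in ("E", "E_revised"):
        return np.array([[m.sd_ca**2, m.cov], [m.cov, m.sd_cb**2]])
    raise ValueError(f"unknown variant {variant!r}")


def split_cysteine_states(
    records: Sequence[ShiftRecord],
    n_restarts: int = 10,
    random_state: int = 0,
) -> list[ShiftRecord]:
    """Label cysteine records oxidized/reduced by per-SS K-means (K=2).

    The cluster with the larger mean Cbeta shift is the oxidized
    (disulfide-bonded) form, whose Cbeta sits near 41 ppm versus ~28 ppm for
    the free thiol.  Multiple restarts keep the partition stable for
    well-separated clusters.
    """
    cys = [r for r in records if r.amino_acid == CYSTEINE]
    if any(r.cb_shift is None for r in cys):
        raise InsufficientDataError("cysteine splitting requires cb_shift on every record")
    labelled: list[ShiftRecord] = []
    for ss in SS_TYPES:
        group = [r for r in cys if r.secondary_structure == ss]
        if not group:
            continue
        xy = records_to_array(group)
        if len(np.unique(xy, axis=0)) < 2:
            raise DegenerateClusterError(
                f"cysteine-{ss}: all points identical, cannot split oxidation states"
            )
        km = KMeans(n_clusters=2, n_init=n_restarts, random_state=random_state)
        lab = km.fit_predict(xy)
        mean_cb = [xy[lab == k, 1].mean() for k in (0, 1)]
        oxidized_cluster = int(np.argmax(mean_cb))
        for rec, k in zip(group, lab):
            state = "oxidized" if k == oxidized_cluster else "reduced"
            labelled.append(rec.with_cys_state(state))
    return labelled


def rmsd_q_statistic(rmsd_ca: float, rmsd_cb: float) -> float:
    """Q = ((|rmsd_ca - rmsd_cb|) / (|rmsd_ca| + |rmsd_cb|))^(1/3).

    Q lies in [0, 1]; the cube root pulls the skewed ratio toward normality.
    Small Q means the two nuclei were predicted about equally well, the
    signature of shifts that came from a single experiment.
    """
    if rmsd_ca < 0 or rmsd_cb < 0:
        raise ValueError("RMSD values must be non-negative")
    denom = abs(rmsd_ca) + abs(rmsd_cb)
    if denom == 0:
        raise UndefinedQError("Q undefined: both RMSD values are zero")
    return float((abs(rmsd_ca - rmsd_cb) / denom) ** (1.0 / 3.0))


def make_entry_quality(entry_id: str, rmsd_ca: float, rmsd_cb: float) -> EntryQuality:
    return EntryQuality(
        entry_id=entry_id,
        rmsd_ca=rmsd_ca,
        rmsd_cb=rmsd_cb,
        q=rmsd_q_statistic(rmsd_ca, rmsd_cb),
    )


def _fisher_z_p(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value for equality of two independent correlations."""
    r1 = float(np.clip(r1, -0.999999, 0.999999))
    r2 = float(np.clip(r2, -0.999999, 0.999999))
    if n1 < 4 or n2 < 4:
        return 1.0
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def _pooled_r(devs: Sequence[np.ndarray]) -> tuple[float, int]:
    pooled = np.vstack(devs)
    if len(pooled) < 2:
        return 0.0, len(pooled)
    sd = pooled.std(axis=0)
    if np.any(sd == 0):
        return 0.0, len(pooled)
    return float(np.corrcoef(pooled[:, 0], pooled[:, 1])[0, 1]), len(pooled)


def refine_covariance_selection(
    entries: Sequence[tuple[EntryQuality, np.ndarray]],
) -> SelectionReport:
    """Scan Q cutoffs for the split maximizing the correlation contrast.

    Each element pairs an entry's quality record with its (k, 2) array of
    Calpha/Cbeta deviations from the class means.  Entries are sorted by Q;
    every observed Q value is tried as a cutoff, the low-Q and high-Q groups'
    pooled deviation correlations r1/r2 are compared by a Fisher-z two-sample
    test, and the split with the smallest p-value wins.  Splits leaving fewer
    than ``MIN_GROUP_SIZE`` entries on either side are skipped; with no
    admissible split, every entry is selected and p = 1.
    """
    entries = [e for e in entries if len(e[1]) >= MIN_PAIRS_PER_ENTRY]
    order = sorted(range(len(entries)), key=lambda i: (entries[i][0].q, entries[i][0].entry_id))
    entries = [entries[i] for i in order]
    qs = [e[0].q for e in entries]
    all_ids = [e[0].entry_id for e in entries]

    best: Optional[tuple[float, float, int]] = None  # (p, cutoff, split index)
    best_rs = (0.0, 0.0)
    for i in range(len(entries) - 1):
        if qs[i] == qs[i + 1]:
            continue  # identical Q values cannot be separated
        low, high = entries[: i + 1], entries[i + 1 :]
        if len(low) < MIN_GROUP_SIZE or len(high) < MIN_GROUP_SIZE:
            continue
        r1, n1 = _pooled_r([e[1] for e in low])
        r2, n2 = _pooled_r([e[1] for e in high])
        p = _fisher_z_p(r1, n1, r2, n2)
        cand = (p, qs[i], i)
        if best is None or cand < best:
            best = cand
            best_rs = (r1, r2)
    if best is None:
        r_all, _ = _pooled_r([e[1] for e in entries]) if entries else (0.0, 0)
        return SelectionReport(
            q_cutoff=1.0,
            r_selected=r_all,
            r_rejected=r_all,
            p_value=1.0,
            selected_entry_ids=all_ids,
        )
    p, cutoff, i = best
    return SelectionReport(
        q_cutoff=cutoff,
        r_selected=best_rs[0],
        r_rejected=best_rs[1],
        p_value=p,
        selected_entry_ids=[e[0].entry_id for e in entries[: i + 1]],
    )


def _entry_deviations(
    records: Sequence[ShiftRecord], models: dict[ClassKey, BivariateClassModel]
) -> dict[str, np.ndarray]:
    """Per-entry (k, 2) deviations of bivariate records from their class means."""
    devs: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.amino_acid == "G" or r.cb_shift is None:
            continue
        m = models[ClassKey(r.model_class, r.secondary_structure)]
        devs.setdefault(r.entry_id, []).append(
            (r.ca_shift - m.mu_ca, r.cb_shift - m.mu_cb)
        )
    return {k: np.asarray(v, dtype=float) for k, v in devs.items()}


def fit_model_set(
    corpus: Sequence[ShiftRecord],
    entry_qualities: Optional[Sequence[EntryQuality]] = None,
    variant: str = "E",
) -> ModelSet:
    """Fit the complete 63-key model bank from an assigned-shift corpus.

    Cysteines are split into oxidation states first (K-means, per SS).  For
    the E_revised variant the covariances (only) are recomputed from the
    entries retained by :func:`refine_covariance_selection`; means and
    standard deviations keep the full-corpus values.
    """
    non_cys = [r for r in corpus if r.amino_acid != CYSTEINE]
    cys = split_cysteine_states(corpus) if any(
        r.amino_acid == CYSTEINE for r in corpus
    ) else []
    records = non_cys + cys

    models: dict[ClassKey, BivariateClassModel] = {}
    missing: list[ClassKey] = []
    for key in ALL_MODEL_KEYS:
        try:
            models[key] = compute_class_statistics(records, key)
        except InsufficientDataError:
            missing.append(key)
    if missing:
        raise MissingClassError(missing)

    report = None
    if variant == "E_revised":
        if entry_qualities is None:
            raise ValueError("variant E_revised requires entry_qualities")
        devs = _entry_deviations(records, models)
        qual_by_id = {q.entry_id: q for q in entry_qualities}
        pairs = [
            (qual_by_id[eid], d)
            for eid, d in devs.items()
            if eid in qual_by_id and len(d) >= MIN_PAIRS_PER_ENTRY
        ]
        report = refine_covariance_selection(pairs)
        selected = set(report.selected_entry_ids)
        subset = [r for r in records if r.entry_id in selected]
        for key in list(models):
            if key.is_glycine:
                continue
            try:
                refined = compute_class_statistics(subset, key)
            except InsufficientDataError:
                continue  # class absent from the selected entries: keep full-corpus cov
            m = models[key]
            cov = refined.cov
            bound = m.sd_ca * m.sd_cb
            cov = float(np.clip(cov, -bound, bound))
            models[key] = replace(m, cov=cov)

    return ModelSet(variant=variant, models=models, selection_report=report)
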