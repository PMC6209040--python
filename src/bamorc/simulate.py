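"""Synthetic corpora, spin-system datasets, assigned tables and peak lists.

Everything the method consumes can be simulated from the class models
themselves, giving every module a ground-truthed test bed with no external
download.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classes import (
    BIVARIATE_KEYS,
    CYS_OXIDIZED,
    CYS_REDUCED,
    CYSTEINE,
    GLYCINE,
    GLYCINE_KEYS,
    AA_ORDER,
    ClassKey,
    SS_TYPES,
)
from .errors import ValidationError
from .reference_models import build_reference_models
from .statistics import make_entry_quality
from .types import (
    AssignedRow,
    AssignedShiftTable,
    CarbonPair,
    CarbonPairDataset,
    EntryQuality,
    ModelSet,
    Peak3D,
    ShiftRecord,
)

#: Default per-peak root jitter (typical digital resolutions, ppm).
DEFAULT_H_JITTER = 0.004
DEFAULT_N_JITTER = 0.04

#: Amide root ranges (ppm) and the minimum normalized root spacing enforced.
H_ROOT_RANGE = (7.5, 9.5)
N_ROOT_RANGE = (105.0, 130.0)
MIN_ROOT_SPACING_SDS = 5.0


@dataclass
class SyntheticSpec:
    """Stated world of one synthetic protein dataset."""

    sequence: str
    ss_string: str
    true_offset: float = 0.0
    missing_fraction: float = 0.0
    h_jitter_sd: float = DEFAULT_H_JITTER
    n_jitter_sd: float = DEFAULT_N_JITTER
    seed: int = 0
    model_source: Optional[ModelSet] = None

    def __post_init__(self):
        if len(self.sequence) != len(self.ss_string):
            raise ValidationError("sequence and SS string must have equal length")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must lie in [0, 1)")

    @property
    def models(self) -> ModelSet:
        return self.model_source or build_reference_models()


@dataclass
class DatasetTruth:
    """Ground truth accompanying a generated dataset."""

    true_offset: float
    residue_indices: list[int]            # residues contributing a kept pair
    model_classes: list[str]              # incl. resolved cysteine states
    ss: list[str]


def random_sequence(length: int, seed: int) -> str:
    """Uniform random sequence over the 20 standard residues."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA_ORDER), size=length))


def random_ss(length: int, seed: int) -> str:
    """Secondary-structure string sampled uniformly over H/E/C."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(SS_TYPES), size=length))


def _draw_pair(
    rng: np.random.Generator, model, decorrelated: bool = False
) -> tuple[float, float]:
    mean = [model.mu_ca, model.mu_cb]
    cov = 0.0 if decorrelated else model.cov
    sigma = [[model.sd_ca**2, cov], [cov, model.sd_cb**2]]
    ca, cb = rng.multivariate_normal(mean, sigma)
    return float(ca), float(cb)


def generate_corpus(
    model_set: Optional[ModelSet] = None,
    n_per_class: int = 100,
    seed: int = 0,
    n_entries: int = 40,
    decorrelated_fraction: float = 0.0,
) -> tuple[list[ShiftRecord], list[EntryQuality]]:
    """Draw an assigned-shift corpus from the class models.

    Records are distributed over ``n_entries`` synthetic entries.  A
    ``decorrelated_fraction`` of entries mimics shifts assembled from
    separate spectra: their Calpha/Cbeta draws are independent (covariance
    zero) and their fabricated RMSD pair is lopsided, giving a high Q;
    the remaining entries draw with the full model covariance and carry
    near-equal RMSDs (low Q).
    """
    if n_per_class < 2:
        raise ValidationError("n_per_class must be >= 2")
    model_set = model_set or build_reference_models()
    rng = np.random.default_rng(seed)

    n_decorrelated = int(round(decorrelated_fraction * n_entries))
    flags = np.zeros(n_entries, dtype=bool)
    flags[:n_decorrelated] = True
    rng.shuffle(flags)

    qualities: list[EntryQuality] = []
    for e in range(n_entries):
        if flags[e]:
            rmsd_ca = rng.uniform(0.2, 0.4)
            rmsd_cb = rmsd_ca * rng.uniform(2.5, 3.5)
        else:
            rmsd_ca = rng.uniform(0.3, 0.5)
            rmsd_cb = rmsd_ca * (1.0 + rng.uniform(-0.05, 0.05))
        qualities.append(make_entry_quality(f"E{e:04d}", rmsd_ca, rmsd_cb))

    records: list[ShiftRecord] = []
    counter = 0
    for key in BIVARIATE_KEYS:
        model = model_set[key]
        entry_of = rng.integers(0, n_entries, size=n_per_class)
        for k in range(n_per_class):
            ca, cb = _draw_pair(rng, model, decorrelated=bool(flags[entry_of[k]]))
            if key.amino_acid_class in (CYS_OXIDIZED, CYS_REDUCED):
                aa = CYSTEINE
                state = "oxidized" if key.amino_acid_class == CYS_OXIDIZED else "reduced"
            else:
                aa, state = key.amino_acid_class, "unknown"
            records.append(
                ShiftRecord(
                    entry_id=f"E{entry_of[k]:04d}",
                    residue_index=counter,
                    amino_acid=aa,
                    secondary_structure=key.secondary_structure,
                    ca_shift=ca,
                    cb_shift=cb,
                    cys_state=state,
                )
            )
            counter += 1
    for key in GLYCINE_KEYS:
        model = model_set[key]
        entry_of = rng.integers(0, n_entries, size=n_per_class)
        for k in range(n_per_class):
            ca = float(rng.normal(model.mu_ca, model.sd_ca))
            records.append(
                ShiftRecord(
                    entry_id=f"E{entry_of[k]:04d}",
                    residue_index=counter,
                    amino_acid=GLYCINE,
                    secondary_structure=key.secondary_structure,
                    ca_shift=ca,
                )
            )
            counter += 1
    return records, qualities


def _residue_draws(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-residue model class and carbon draws (offset not yet applied)."""
    models = spec.models
    draws = []
    for i, (aa, ss) in enumerate(zip(spec.sequence, spec.ss_string)):
        if aa == GLYCINE:
            m = models[ClassKey(GLYCINE, ss)]
            ca = float(rng.normal(m.mu_ca, m.sd_ca))
            draws.append((i, GLYCINE, ss, ca, None))
            continue
        if aa == CYSTEINE:
            aa_class = CYS_OXIDIZED if rng.random() < 0.5 else CYS_REDUCED
        else:
            aa_class = aa
        m = models[ClassKey(aa_class, ss)]
        ca, cb = _draw_pair(rng, m)
        draws.append((i, aa_class, ss, ca, cb))
    return draws


def generate_dataset(spec: SyntheticSpec) -> tuple[CarbonPairDataset, DatasetTruth]:
    """Draw a spin-system dataset for one protein.

    Each non-glycine residue yields one unordered (Calpha, Cbeta) pair from
    its class model (cysteine resolves its oxidation state by a fair coin,
    recorded in the truth); the true offset is added to both carbons, and
    ceil(missing_fraction x count) pairs are dropped uniformly at random.
    The offset is applied after all random draws, so datasets differing only
    in ``true_offset`` are shifted copies of each other.
    """
    rng = np.random.default_rng(spec.seed)
    draws = _residue_draws(spec, rng)
    bivariate = [d for d in draws if d[4] is not None]
    swap = rng.random(len(bivariate)) < 0.5

    n_drop = int(np.ceil(spec.missing_fraction * len(bivariate)))
    keep = np.ones(len(bivariate), dtype=bool)
    if n_drop:
        keep[rng.choice(len(bivariate), size=n_drop, replace=False)] = False

    pairs: list[CarbonPair] = []
    truth = DatasetTruth(
        true_offset=spec.true_offset, residue_indices=[], model_classes=[], ss=[]
    )
    for k, (i, aa_class, ss, ca, cb) in enumerate(bivariate):
        if not keep[k]:
            continue
        a, b = (cb, ca) if swap[k] else (ca, cb)
        pairs.append(
            CarbonPair(a + spec.true_offset, b + spec.true_offset, ordered=False)
        )
        truth.residue_indices.append(i)
        truth.model_classes.append(aa_class)
        truth.ss.append(ss)
    singles = [
        d[3] + spec.true_offset for d in draws if d[4] is None
    ]
    dataset = CarbonPairDataset(
        pairs=pairs,
        sequence=spec.sequence,
        ss_string=spec.ss_string,
        ca_singles=singles,
    )
    return dataset, truth


def generate_assigned_table(
    spec: SyntheticSpec,
) -> tuple[AssignedShiftTable, DatasetTruth]:
    """Assigned-shift table with the same generative process as the datasets.

    Residue types and secondary structure are kept (cysteine rows keep only
    the residue letter; the drawn oxidation state lives in the truth), and
    the same dropout rule removes whole residues.
    """
    rng = np.random.default_rng(spec.seed)
    draws = _residue_draws(spec, rng)
    bivariate = [d for d in draws if d[4] is not None]
    n_drop = int(np.ceil(spec.missing_fraction * len(bivariate)))
    keep = np.ones(len(bivariate), dtype=bool)
    if n_drop:
        keep[rng.choice(len(bivariate), size=n_drop, replace=False)] = False

    rows: list[AssignedRow] = []
    truth = DatasetTruth(
        true_offset=spec.true_offset, residue_indices=[], model_classes=[], ss=[]
    )
    for k, (i, aa_class, ss, ca, cb) in enumerate(bivariate):
        if not keep[k]:
            continue
        aa = CYSTEINE if aa_class in (CYS_OXIDIZED, CYS_REDUCED) else aa_class
        rows.append(
            AssignedRow(
                residue_index=i + 1,  # 1-based, NMR-STAR convention
                amino_acid=aa,
                secondary_structure=ss,
                ca_shift=ca + spec.true_offset,
                cb_shift=cb + spec.true_offset,
            )
        )
        truth.residue_indices.append(i)
        truth.model_classes.append(aa_class)
        truth.ss.append(ss)
    for i, aa_class, ss, ca, _ in draws:
        if aa_class == GLYCINE:
            rows.append(
                AssignedRow(
                    residue_index=i + 1,
                    amino_acid=GLYCINE,
                    secondary_structure=ss,
                    ca_shift=ca + spec.true_offset,
                    cb_shift=None,
                )
            )
    return AssignedShiftTable(rows=rows), truth


def _draw_roots(
    n: int, rng: np.random.Generator, h_sd: float, n_sd: float
) -> np.ndarray:
    """Amide roots with rejection to enforce a minimum normalized spacing."""
    roots = np.empty((n, 2))
    count = 0
    while count < n:
        h = rng.uniform(*H_ROOT_RANGE)
        nn = rng.uniform(*N_ROOT_RANGE)
        if count:
            d = np.hypot(
                (roots[:count, 0] - h) / h_sd, (roots[:count, 1] - nn) / n_sd
            )
            if d.min() < MIN_ROOT_SPACING_SDS:
                continue
        roots[count] = (h, nn)
        count += 1
    return roots


@dataclass
class PeakListTruth:
    """Which generated peaks belong to which residue."""

    true_offset: float
    residue_of_peak: dict[int, int]       # line_index -> residue index
    pair_line_indices: list[tuple[int, int]]  # non-glycine peak pairs


def generate_peak_list(spec: SyntheticSpec) -> tuple[list[Peak3D], PeakListTruth]:
    """3D HN(CO)CACB-type peak list with known grouping.

    Every residue gets an amide root; non-glycine residues emit two peaks
    (Calpha and Cbeta) and glycine one, each peak's root jittered
    independently with the spec's sds.  Whole spin systems are dropped by
    ``missing_fraction``.  The returned list is shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    draws = _residue_draws(spec, rng)
    roots = _draw_roots(len(draws), rng, spec.h_jitter_sd, spec.n_jitter_sd)

    n_res = len(draws)
    n_drop = int(np.ceil(spec.missing_fraction * n_res))
    keep = np.ones(n_res, dtype=bool)
    if n_drop:
        keep[rng.choice(n_res, size=n_drop, replace=False)] = False

    raw: list[tuple[int, float, float, float]] = []  # (residue, h, n, c)
    for k, (i, aa_class, ss, ca, cb) in enumerate(draws):
        if not keep[k]:
            continue
        carbons = [ca] if cb is None else [ca, cb]
        for c in carbons:
            h = roots[k, 0] + rng.normal(0, spec.h_jitter_sd)
            nn = roots[k, 1] + rng.normal(0, spec.n_jitter_sd)
            raw.append((i, h, nn, c + spec.true_offset))

    order = rng.permutation(len(raw))
    peaks: list[Peak3D] = []
    residue_of_peak: dict[int, int] = {}
    lines_of_residue: dict[int, list[int]] = {}
    for line, k in enumerate(order):
        res, h, nn, c = raw[k]
        peaks.append(Peak3D(h_shift=h, n_shift=nn, c_shift=c, line_index=line))
        residue_of_peak[line] = res
        lines_of_residue.setdefault(res, []).append(line)
    pair_lines = [
        (lines[0], lines[1])
        for lines in lines_of_residue.values()
        if len(lines) == 2
    ]
    truth = PeakListTruth(
        true_offset=spec.true_offset,
        residue_of_peak=residue_of_peak,
        pair_line_indices=pair_lines,
    )
    return peaks, truth
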