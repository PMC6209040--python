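"""Domain containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .classes import ALL_MODEL_KEYS, CYS_STATES, CYSTEINE, GLYCINE, ClassKey, SS_TYPES
from .errors import ValidationError

VARIANTS = ("A", "B", "C", "D", "E", "E_revised")


@dataclass(frozen=True, slots=True)
class ShiftRecord:
    """One residue's assigned Calpha (and Cbeta) chemical shifts.

    ``cb_shift`` is ``None`` exactly when the residue is glycine or the beta
    carbon was not observed.  ``cys_state`` is meaningful only for cysteine
    ("oxidized", "reduced" or "unknown").
    """

    entry_id: str
    residue_index: int
    amino_acid: str
    secondary_structure: str
    ca_shift: float
    cb_shift: Optional[float] = None
    cys_state: str = "unknown"

    def __post_init__(self):
        if self.secondary_structure not in SS_TYPES:
            raise ValidationError(
                f"secondary structure must be one of {SS_TYPES}, "
                f"got {self.secondary_structure!r}"
            )
        if not 0.0 < self.ca_shift < 200.0:
            raise ValidationError(f"ca_shift {self.ca_shift} outside (0, 200) ppm")
        if self.cb_shift is not None and not 0.0 < self.cb_shift < 200.0:
            raise ValidationError(f"cb_shift {self.cb_shift} outside (0, 200) ppm")
        if self.amino_acid == GLYCINE and self.cb_shift is not None:
            raise ValidationError("glycine records cannot carry a cb_shift")

    @property
    def model_class(self) -> str:
        """Amino-acid model class, resolving cysteine by oxidation state."""
        if self.amino_acid == CYSTEINE:
            if self.cys_state == "oxidized":
                return CYS_STATES[0]
            if self.cys_state == "reduced":
                return CYS_STATES[1]
            raise ValidationError(
                "cysteine record has no oxidation state; run split_cysteine_states"
            )
        return self.amino_acid

    def with_cys_state(self, state: str) -> "ShiftRecord":
        return replace(self, cys_state=state)


@dataclass(frozen=True, slots=True)
class BivariateClassModel:
    """Gaussian parameters of one (amino acid, SS) class.

    Glycine classes are univariate: ``mu_cb``, ``sd_cb`` and ``cov`` are None.
    """

    key: ClassKey
    mu_ca: float
    sd_ca: float
    n: int
    mu_cb: Optional[float] = None
    sd_cb: Optional[float] = None
    cov: Optional[float] = None

    def __post_init__(self):
        if self.sd_ca < 0 or (self.sd_cb is not None and self.sd_cb < 0):
            raise ValidationError("standard deviations must be non-negative")
        if self.cov is not None and self.sd_cb is not None:
            bound = self.sd_ca * self.sd_cb
            if abs(self.cov) > bound + 1e-9:
                raise ValidationError(
                    f"|cov|={abs(self.cov):.4f} exceeds sd_ca*sd_cb={bound:.4f} "
                    f"for class {self.key}"
                )

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_ca, self.mu_cb], dtype=float)


@dataclass
class ModelSet:
    """Complete bank of class models for one covariance-matrix variant."""

    variant: str
    models: dict[ClassKey, BivariateClassModel]
    selection_report: Optional["SelectionReport"] = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")

    def __getitem__(self, key: ClassKey) -> BivariateClassModel:
        return self.models[key]

    @property
    def complete(self) -> bool:
        return all(k in self.models for k in ALL_MODEL_KEYS)

    def pooled_stats(self, amino_acid_class: str) -> tuple[float, float, float]:
        """(sd_ca, sd_cb, cov) pooled across the three secondary structures.

        Pooling averages per-SS variances/covariances weighted by sample count.
        """
        ms = [self.models[ClassKey(amino_acid_class, ss)] for ss in SS_TYPES]
        w = np.array([m.n for m in ms], dtype=float)
        w = w / w.sum()
        var_ca = float(np.dot(w, [m.sd_ca**2 for m in ms]))
        var_cb = float(np.dot(w, [m.sd_cb**2 for m in ms]))
        cov = float(np.dot(w, [m.cov for m in ms]))
        return np.sqrt(var_ca), np.sqrt(var_cb), cov


@dataclass(frozen=True, slots=True)
class EntryQuality:
    """Per-entry Calpha/Cbeta RMSD quality descriptors and the Q statistic."""

    entry_id: str
    rmsd_ca: float
    rmsd_cb: float
    q: float


@dataclass
class SelectionReport:
    """Outcome of the Q-cutoff covariance-refinement scan."""

    q_cutoff: float
    r_selected: float
    r_rejected: float
    p_value: float
    selected_entry_ids: list[str]


@dataclass(frozen=True, slots=True)
class CarbonPair:
    """An unordered (by default) pair of carbon shifts from one spin system."""

    shift_a: float
    shift_b: float
    ordered: bool = False

    def __post_init__(self):
        for s in (self.shift_a, self.shift_b):
            if not 0.0 < s < 200.0:
                raise ValidationError(f"carbon shift {s} outside (0, 200) ppm")


@dataclass
class CarbonPairDataset:
    """Spin-system carbon pairs for one protein plus sequence context.

    ``ca_singles`` carries Calpha-only (glycine-candidate) shifts; they are
    unused unless glycine models are explicitly enabled.
    """

    pairs: list[CarbonPair]
    sequence: str
    ss_string: str
    ca_singles: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.ss_string):
            raise ValidationError(
                f"sequence length {len(self.sequence)} != SS length {len(self.ss_string)}"
            )
        bad = set(self.ss_string) - set(SS_TYPES)
        if bad:
            raise ValidationError(f"SS string contains invalid letters {sorted(bad)}")

    @property
    def n_expected(self) -> int:
        """Number of spin systems expected from the sequence (non-glycine)."""
        return sum(1 for a in self.sequence if a != GLYCINE)

    @property
    def completeness(self) -> float:
        return len(self.pairs) / max(self.n_expected, 1)


@dataclass(frozen=True, slots=True)
class AssignedRow:
    residue_index: int
    amino_acid: str
    secondary_structure: str
    ca_shift: Optional[float]
    cb_shift: Optional[float]


@dataclass
class AssignedShiftTable:
    """Assigned per-residue Calpha/Cbeta shifts with secondary structure."""

    rows: list[AssignedRow]

    def __post_init__(self):
        idx = [r.residue_index for r in self.rows]
        if len(idx) != len(set(idx)):
            raise ValidationError("residue indices in an assigned table must be unique")

    def usable_rows(self) -> list[AssignedRow]:
        """Non-glycine rows carrying both carbon shifts."""
        return [
            r
            for r in self.rows
            if r.amino_acid != GLYCINE
            and r.ca_shift is not None
            and r.cb_shift is not None
        ]


@dataclass
class CorrectionResult:
    """Reference correction estimate and the residual landscape behind it."""

    m1: float
    m2: float
    residual_curve: list[tuple[float, float]]
    final_residual: float
    method: str = "grid"


@dataclass(frozen=True, slots=True)
class Peak3D:
    """One peak of a 3D HN(CO)CACB-type list."""

    h_shift: float
    n_shift: float
    c_shift: float
    intensity: Optional[float] = None
    line_index: int = -1

    @property
    def in_typical_range(self) -> bool:
        return (
            0.0 < self.h_shift < 15.0
            and 90.0 < self.n_shift < 140.0
            and 0.0 < self.c_shift < 100.0
        )


@dataclass(frozen=True, slots=True)
class ToleranceSet:
    tol_h: float
    tol_n: float

    def __post_init__(self):
        if self.tol_h <= 0 or self.tol_n <= 0:
            raise ValidationError("match tolerances must be strictly positive")


@dataclass
class SpinSystemGroup:
    """Peaks sharing one amide (1H, 15N) root; nominally 1 or 2 peaks."""

    peaks: list[Peak3D]
    ambiguous: bool = False

    @property
    def root_h(self) -> float:
        return float(np.mean([p.h_shift for p in self.peaks]))

    @property
    def root_n(self) -> float:
        return float(np.mean([p.n_shift for p in self.peaks]))

    @property
    def carbon_shifts(self) -> list[float]:
        return [p.c_shift for p in self.peaks]


def records_to_array(records: Iterable[ShiftRecord]) -> np.ndarray:
    """(n, 2) array of (ca, cb) shifts; requires cb present on every record."""
    rows = [(r.ca_shift, r.cb_shift) for r in records]
    if any(cb is None for _, cb in rows):
        raise ValidationError("records_to_array requires cb_shift on every record")
    return np.asarray(rows, dtype=float)
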