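"""Built-in reference chemical-shift statistics (the package's default models).

Real deployments derive the class statistics from a large re-referenced
assigned-shift corpus.  Shipping such a corpus is impossible here, so the
package carries a literature-grounded parameter bank instead:

* per-residue random-coil Calpha/Cbeta means (standard tabulated values, ppm),
  with cysteine split into its disulfide-bonded (oxidized, Cbeta ~ 41 ppm) and
  free-thiol (reduced, Cbeta ~ 28 ppm) forms;
* canonical secondary-structure offsets (helix: Calpha +2.6 / Cbeta -0.4;
  sheet: Calpha -1.4 / Cbeta +2.1; coil: 0);
* class standard deviations around 1.1-1.6 ppm, slightly wider outside
  helices;
* Calpha/Cbeta correlations of -0.30 by default; alanine and the two cysteine
  states use the per-SS values reported for those distributions in the
  re-referenced corpus literature.

These parameters are the generating truth for every synthetic experiment in
the package.  They are a stated world, fixed once; they are not fitted to any
evaluation outcome.
"""

from __future__ import annotations

import numpy as np

from .classes import ALL_MODEL_KEYS, CYS_OXIDIZED, CYS_REDUCED, GLYCINE, ClassKey
from .types import BivariateClassModel, ModelSet

#: Random-coil (Calpha, Cbeta) means in ppm; glycine has Calpha only.
RANDOM_COIL: dict[str, tuple[float, float | None]] = {
    "A": (52.5, 19.1),
    CYS_REDUCED: (58.2, 28.0),
    CYS_OXIDIZED: (55.4, 41.1),
    "D": (54.2, 41.1),
    "E": (56.6, 29.9),
    "F": (57.7, 39.6),
    GLYCINE: (45.1, None),
    "H": (55.0, 29.0),
    "I": (61.1, 38.8),
    "K": (56.2, 33.1),
    "L": (55.1, 42.4),
    "M": (55.4, 32.9),
    "N": (53.1, 38.9),
    "P": (63.3, 32.1),
    "Q": (55.7, 29.4),
    "R": (56.0, 30.9),
    "S": (58.3, 63.8),
    "T": (61.8, 69.8),
    "V": (62.2, 32.9),
    "W": (57.5, 29.6),
    "Y": (57.9, 38.8),
}

#: Secondary-structure offsets added to the random-coil means (ppm).
SS_OFFSETS: dict[str, tuple[float, float]] = {
    "H": (2.6, -0.4),
    "E": (-1.4, 2.1),
    "C": (0.0, 0.0),
}

#: Per-SS class standard deviations (sd_ca, sd_cb) in ppm.
SS_SDS: dict[str, tuple[float, float]] = {
    "H": (1.1, 1.3),
    "E": (1.3, 1.5),
    "C": (1.4, 1.6),
}

#: Calpha/Cbeta correlation per (amino-acid class, SS); default -0.30.
SPECIAL_CORRELATIONS: dict[tuple[str, str], float] = {
    ("A", "E"): -0.37,
    ("A", "C"): -0.26,
    ("A", "H"): -0.34,
    (CYS_OXIDIZED, "E"): 0.22,
    (CYS_OXIDIZED, "C"): 0.35,
    (CYS_OXIDIZED, "H"): 0.45,
    (CYS_REDUCED, "E"): -0.31,
    (CYS_REDUCED, "C"): -0.21,
    (CYS_REDUCED, "H"): -0.24,
}

DEFAULT_CORRELATION = -0.30

GLYCINE_SD = 1.3

#: Nominal per-class sample size attached to the built-in models.
REFERENCE_N = 5000


def reference_correlation(amino_acid_class: str, ss: str) -> float:
    return SPECIAL_CORRELATIONS.get((amino_acid_class, ss), DEFAULT_CORRELATION)


def build_reference_models(variant: str = "E") -> ModelSet:
    """Assemble the built-in 63-key ModelSet (60 bivariate + 3 glycine)."""
    models: dict[ClassKey, BivariateClassModel] = {}
    for key in ALL_MODEL_KEYS:
        mu_ca, mu_cb = RANDOM_COIL[key.amino_acid_class]
        d_ca, d_cb = SS_OFFSETS[key.secondary_structure]
        if key.is_glycine:
            models[key] = BivariateClassModel(
                key=key,
                mu_ca=mu_ca + d_ca,
                sd_ca=GLYCINE_SD,
                n=REFERENCE_N,
            )
            continue
        sd_ca, sd_cb = SS_SDS[key.secondary_structure]
        r = reference_correlation(key.amino_acid_class, key.secondary_structure)
        models[key] = BivariateClassModel(
            key=key,
            mu_ca=mu_ca + d_ca,
            mu_cb=mu_cb + d_cb,
            sd_ca=sd_ca,
            sd_cb=sd_cb,
            cov=r * sd_ca * sd_cb,
            n=REFERENCE_N,
        )
    return ModelSet(variant=variant, models=models)


def reference_covariance(key: ClassKey) -> np.ndarray:
    """2x2 generating covariance of one bivariate reference class."""
    m = build_reference_models()[key]
    return np.array([[m.sd_ca**2, m.cov], [m.cov, m.sd_cb**2]])
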