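"""Class spaces for amino-acid / secondary-structure typing.

The method scores unordered (Calpha, Cbeta) shift pairs against a bank of
bivariate Gaussian models, one per amino-acid class and secondary-structure
type.  Two class spaces coexist:

* the *model* space: 20 non-glycine amino-acid classes (18 standard residues
  plus oxidized and reduced cysteine) x 3 secondary structures = 60 bivariate
  models, plus 3 univariate glycine (Calpha-only) models = 63 model keys;
* the *composition* space: 19 non-glycine residue types x 3 secondary
  structures = 57 classes, in which the two cysteine oxidation states are
  merged (a protein sequence does not know the oxidation state).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
GLYCINE: str = "G"
CYSTEINE: str = "C"

#: 19 standard residues that carry a beta carbon, alphabetical one-letter order.
NON_GLY_RESIDUES: tuple[str, ...] = tuple(a for a in AA_ORDER if a != GLYCINE)

SS_TYPES: tuple[str, ...] = ("H", "E", "C")

CYS_OXIDIZED = "Cys_ox"
CYS_REDUCED = "Cys_red"
CYS_STATES: tuple[str, str] = (CYS_OXIDIZED, CYS_REDUCED)

#: 20 bivariate model amino-acid classes (cysteine split by oxidation state).
MODEL_AA_CLASSES: tuple[str, ...] = tuple(
    a for a in NON_GLY_RESIDUES if a != CYSTEINE
) + CYS_STATES


class ClassKey(NamedTuple):
    """(amino-acid class, secondary structure) key of one statistical model."""

    amino_acid_class: str
    secondary_structure: str

    @property
    def is_glycine(self) -> bool:
        return self.amino_acid_class == GLYCINE

    @property
    def residue(self) -> str:
        """One-letter residue type with cysteine states collapsed back to C."""
        if self.amino_acid_class in CYS_STATES:
            return CYSTEINE
        return self.amino_acid_class


#: The 60 bivariate model keys, in a fixed canonical order.
BIVARIATE_KEYS: tuple[ClassKey, ...] = tuple(
    ClassKey(aa, ss) for aa in MODEL_AA_CLASSES for ss in SS_TYPES
)

#: The 3 glycine (Calpha-only) model keys.
GLYCINE_KEYS: tuple[ClassKey, ...] = tuple(ClassKey(GLYCINE, ss) for ss in SS_TYPES)

#: All 63 model keys.
ALL_MODEL_KEYS: tuple[ClassKey, ...] = BIVARIATE_KEYS + GLYCINE_KEYS

#: The 57 composition classes (residue, SS) with cysteine states merged.
COMPOSITION_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (aa, ss) for aa in NON_GLY_RESIDUES for ss in SS_TYPES
)

N_COMPOSITION = len(COMPOSITION_CLASSES)  # 57

COMPOSITION_INDEX: dict[tuple[str, str], int] = {
    c: i for i, c in enumerate(COMPOSITION_CLASSES)
}

#: For each of the 60 bivariate models, the composition-class column it feeds.
MODEL_TO_COMPOSITION: np.ndarray = np.array(
    [COMPOSITION_INDEX[(k.residue, k.secondary_structure)] for k in BIVARIATE_KEYS],
    dtype=np.intp,
)

#: 60 x 57 merge matrix: probabilities of the two cysteine-state models sum
#: into the single cysteine composition class of the same secondary structure.
MERGE_MATRIX: np.ndarray = np.zeros((len(BIVARIATE_KEYS), N_COMPOSITION))
MERGE_MATRIX[np.arange(len(BIVARIATE_KEYS)), MODEL_TO_COMPOSITION] = 1.0

#: Row index of each bivariate model key in the canonical order.
BIVARIATE_INDEX: dict[ClassKey, int] = {k: i for i, k in enumerate(BIVARIATE_KEYS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def composition_label(index: int) -> str:
    aa, ss = COMPOSITION_CLASSES[index]
    return f"{aa}-{ss}"
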