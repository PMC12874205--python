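"""Physical constants, mass tags, and residue scales.

The two modification masses that drive glycopeptide selection are the
TMT sixplex label (fixed on lysine and the peptide N-terminus) and the
fucose+GlcNAc disaccharide left on asparagine after Endo F3 truncation
of a core-fucosylated N-glycan. The TMT mass is recomputed from its
elemental composition rather than hard-coded, so it stays consistent
with the monoisotopic atomic masses shipped with pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

# TMT6plex reporter+balancer label: C8 (13C)4 H20 N (15N) O2
TMT6PLEX_COMPOSITION = "C8C[13]4H20N1N[15]1O2"


def tmt6plex_mass() -> float:
    """Monoisotopic mass of the TMT sixplex label in Da (~229.1629)."""
    return _pmass.calculate_mass(formula=TMT6PLEX_COMPOSITION)


# dHex + HexNAc residue masses: the Endo F3 truncation product on Asn.
FUC_GLCNAC_COMPOSITION = "C14H23N1O9"


def fucosyl_glcnac_mass() -> float:
    """Monoisotopic mass of the fucosyl-GlcNAc tag in Da (~349.1373)."""
    return _pmass.calculate_mass(formula=FUC_GLCNAC_COMPOSITION)


@dataclass(frozen=True)
class SearchConstants:
    """Filtering and scoring constants for glyco-PSM selection.

    ``glyco_tag_mass`` is the configured search value (349.1370 Da); the
    theoretical composition mass 349.1373 also matches within the
    0.01 Da tolerance.
    """

    tmt_mass: float = 229.1629
    glyco_tag_mass: float = 349.1370
    mod_mass_tolerance: float = 0.01
    min_peptide_length_exclusive: int = 7
    fdr_alpha: float = 0.01
    precursor_tol_ppm: float = 10.0
    product_tol_da: float = 0.025
    max_missed_cleavages: int = 2
    max_mods_per_peptide: int = 3
    require_no_proline_plus1: bool = True  # canonical N-X(!=P)-[S/T/C]
    fdr_plus_one: bool = False  # decoy count +1 correction, off by default
    fdr_peptide_level: bool = False  # best-PSM-per-peptide mode

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must be in (0, 1)")
        for name in ("mod_mass_tolerance", "precursor_tol_ppm", "product_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# Kyte-Doolittle hydropathy scale (GRAVY).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_AROMATIC_SET = frozenset("FWY")

# EMBOSS pKa values for isoelectric-point calculation.
EMBOSS_PKA = {
    "n_term": 8.6,
    "c_term": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

N_CHANNELS = 6
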