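"""Dual-wavelength photometry for protein-dye conjugates.

Concentrations follow Beer-Lambert: the dye (a diethylaminocoumarin such as
MDCC) is read at its 430 nm maximum, and the protein at 280 nm after
subtracting the dye's bleed-through at 280 nm (a fixed fraction of A430):

    [protein] = (A280 - A430 * correction) / (eps280 * L)
    [dye]     = A430 / (eps430 * L)
    labeling efficiency = [dye] / [protein] * 100%

Defaults ship the published constants for the TogB scaffold and the MDCC
fluorophore: eps280 = 90,300 M^-1 cm^-1, eps430 = 46,800 M^-1 cm^-1,
correction = 0.164.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhotometryRecord",
    "protein_concentration",
    "dye_concentration",
    "labeling_efficiency",
    "EPS280_TOGB",
    "EPS430_MDCC",
    "MDCC_A280_CORRECTION",
]

EPS280_TOGB = 90_300.0  # M^-1 cm^-1, TogB at 280 nm (ProtParam, primary sequence)
EPS430_MDCC = 46_800.0  # M^-1 cm^-1, MDCC at 430 nm
MDCC_A280_CORRECTION = 0.164  # fraction of A430 that MDCC contributes at 280 nm


@dataclass(frozen=True)
class PhotometryRecord:
    """One dual-wavelength absorbance reading of a labeled protein sample."""

    a280: float
    a430: float
    pathlength_cm: float = 1.0
    eps280_protein: float = EPS280_TOGB
    eps430_dye: float = EPS430_MDCC
    dye_a280_correction: float = MDCC_A280_CORRECTION

    def __post_init__(self):
        if self.a280 < 0 or self.a430 < 0:
            raise ValueError("absorbances must be non-negative")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")
        if self.eps280_protein <= 0 or self.eps430_dye <= 0:
            raise ValueError("extinction coefficients must be positive")
        if not (0 <= self.dye_a280_correction < 1):
            raise ValueError("dye A280 correction must lie in [0, 1)")


def protein_concentration(rec: PhotometryRecord) -> float:
    """Protein concentration in molar, from dye-corrected A280.

    Raises ValueError when the corrected absorbance is negative (the two
    readings are mutually inconsistent).
    """
    corrected = rec.a280 - rec.a430 * rec.dye_a280_correction
    if corrected < 0:
        raise ValueError(
            f"corrected A280 is negative ({corrected:.4g}): A280/A430 readings inconsistent")
    return corrected / (rec.eps280_protein * rec.pathlength_cm)


def dye_concentration(rec: PhotometryRecord) -> float:
    """Dye concentration in molar from A430."""
    return rec.a430 / (rec.eps430_dye * rec.pathlength_cm)


def labeling_efficiency(rec: PhotometryRecord) -> float:
    """Molar dye-to-protein ratio as a percentage.

    Values above 100% are physically suspect (over-labeling or a reading
    error) but are returned as computed; zero protein concentration is a
    hard error.
    """
    protein = protein_concentration(rec)
    if protein == 0:
        raise ValueError("protein concentration is zero; efficiency undefined")
    return dye_concentration(rec) / protein * 100.0
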