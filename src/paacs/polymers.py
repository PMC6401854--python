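"""Built-in polymer parameter sets for the three alpha-amino-acid PAACs.

Each polyamidoamino acid (PAAC) arises from the Michael polyaddition of an
alpha-amino acid across both vinyls of N,N'-methylenebisacrylamide (MBA),
so the repeat-unit molar mass is simply MBA plus the amino acid (simple
addition, no condensation loss).

The amine pKa2 values are anchored at the pH of the chiroptical structuring
transition of each polymer (8.1, 6.8 and 7.3 for the alanine, valine and
leucine polymer respectively), which coincides with amine
half-deprotonation.  The carboxyl pKa1 values and both cooperativity
exponents are synthetic fixture parameters chosen in the range typical of
weak amphoteric polyelectrolytes (pKa1 between 2 and 3; beta below one for
the carboxyl, whose apparent pKa falls with ionization in these polymers,
and above one for the amine, whose apparent pKa rises); they are plausible
defaults for simulation, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ionization import ACID, BASE, IonizableGroup, PolymerSpec

__all__ = [
    "ATOMIC_MASSES",
    "formula_mass",
    "MBA_MASS",
    "repeat_unit_mass",
    "M_L_ALA",
    "M_L_VAL",
    "M_L_LEU",
    "BUILTIN_POLYMERS",
    "CDBands",
    "CD_BANDS",
]

# IUPAC 2021 standard atomic weights, rounded to 3 decimals
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}


def formula_mass(formula: dict[str, int]) -> float:
    """Molar mass (g/mol) of a composition given as {element: count}."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


# N,N'-methylenebisacrylamide C7H10N2O2
MBA_MASS = formula_mass({"C": 7, "H": 10, "N": 2, "O": 2})

_AMINO_ACIDS = {
    "alanine": {"C": 3, "H": 7, "N": 1, "O": 2},
    "valine": {"C": 5, "H": 11, "N": 1, "O": 2},
    "leucine": {"C": 6, "H": 13, "N": 1, "O": 2},
}


def repeat_unit_mass(amino_acid: str) -> float:
    """Repeat-unit molar mass of the PAAC built from ``amino_acid`` + MBA."""
    return MBA_MASS + formula_mass(_AMINO_ACIDS[amino_acid])


M_L_ALA = PolymerSpec(
    name="M-l-Ala",
    repeat_unit_mass=repeat_unit_mass("alanine"),
    acid_group=IonizableGroup(ACID, pka=2.3, beta=0.90),
    base_group=IonizableGroup(BASE, pka=8.1, beta=1.35),
)

M_L_VAL = PolymerSpec(
    name="M-l-Val",
    repeat_unit_mass=repeat_unit_mass("valine"),
    acid_group=IonizableGroup(ACID, pka=2.5, beta=0.90),
    base_group=IonizableGroup(BASE, pka=6.8, beta=1.30),
)

M_L_LEU = PolymerSpec(
    name="M-l-Leu",
    repeat_unit_mass=repeat_unit_mass("leucine"),
    acid_group=IonizableGroup(ACID, pka=2.4, beta=0.90),
    base_group=IonizableGroup(BASE, pka=7.3, beta=1.30),
)

BUILTIN_POLYMERS = {p.name: p for p in (M_L_ALA, M_L_VAL, M_L_LEU)}


@dataclass(frozen=True)
class CDBands:
    """Gaussian band fixture for the synthetic CD generator of one polymer.

    ``pos_center`` is the wavelength of the positive structuring band at
    basic pH (228, 234 and 231 nm for the Ala, Val and Leu polymer); the
    negative band sits at lower wavelength and blue-shifts at acidic pH.
    Widths and amplitudes are generator fixtures, not measured values.
    """

    pos_center: float      # nm
    pos_width: float       # nm (Gaussian sigma)
    pos_amplitude: float   # mdeg M^-1 cm^-1 at full amine deprotonation
    neg_center: float      # nm
    neg_width: float       # nm
    neg_amplitude: float   # mdeg M^-1 cm^-1 (magnitude)
    blue_shift: float      # nm shift of the negative band reached at pH 3


CD_BANDS = {
    "M-l-Ala": CDBands(228.0, 8.0, 5000.0, 210.0, 9.0, 4000.0, 6.0),
    "M-l-Val": CDBands(234.0, 8.0, 7000.0, 213.0, 9.0, 5000.0, 6.0),
    "M-l-Leu": CDBands(231.0, 8.0, 6500.0, 212.0, 9.0, 4800.0, 6.0),
}
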