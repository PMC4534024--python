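"""Peptide mass arithmetic for MALDI-TOF peptide mass fingerprinting.

Monoisotopic and average masses of the 20 standard amino-acid residues are
derived from pinned elemental mass tables rather than hard-coded per residue,
so every downstream mass (tryptic peptides, [M+H]+ ions, b/y fragment
ladders) is bit-reproducible and auditable against the elemental source.

Monoisotopic masses: CODATA 2018 / AME2020 atomic mass evaluation.
Average masses: IUPAC 2021 standard atomic weights (conventional values).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Literal

MassType = Literal["monoisotopic", "average"]

#: element symbol -> (monoisotopic mass, average mass), in Da
ELEMENT_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.008),
    "C": (12.0, 12.011),
    "N": (14.0030740048, 14.007),
    "O": (15.9949146196, 15.999),
    "S": (31.97207100, 32.06),
}

#: residue (post-condensation, i.e. minus water) elemental compositions
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

STANDARD_RESIDUES = frozenset(RESIDUE_COMPOSITIONS)

# CODATA 2018 proton mass in Da
PROTON_MASS = 1.007276466621


def _composition_mass(composition: dict[str, int], mass_type: MassType) -> float:
    idx = 0 if mass_type == "monoisotopic" else 1
    return sum(ELEMENT_MASSES[el][idx] * n for el, n in composition.items())


WATER_MONO = _composition_mass({"H": 2, "O": 1}, "monoisotopic")
WATER_AVG = _composition_mass({"H": 2, "O": 1}, "average")

#: residue -> (monoisotopic, average) residue mass, derived from the tables
RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    aa: (_composition_mass(comp, "monoisotopic"), _composition_mass(comp, "average"))
    for aa, comp in RESIDUE_COMPOSITIONS.items()
}


def water_mass(mass_type: MassType = "monoisotopic") -> float:
    """Mass of one water molecule (the condensation loss per peptide bond)."""
    return WATER_MONO if mass_type == "monoisotopic" else WATER_AVG


def validate_sequence(sequence: str) -> None:
    """Raise ValueError naming the first non-standard residue, if any."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1} in {sequence!r}"
            )


def peptide_composition(sequence: str) -> dict[str, int]:
    """Elemental composition of the neutral (water-terminated) peptide."""
    validate_sequence(sequence)
    comp: Counter[str] = Counter({"H": 2, "O": 1})
    for aa in sequence:
        comp.update(RESIDUE_COMPOSITIONS[aa])
    return dict(comp)


def peptide_mass(
    sequence: str,
    mass_type: MassType = "monoisotopic",
    fixed_modifications: dict[str, float] | None = None,
) -> float:
    """Neutral mass of a peptide in Da.

    Sum of residue masses plus one water. ``fixed_modifications`` maps a
    residue letter to a constant mass offset in Da (e.g. ``{"C": 57.02146}``
    for carbamidomethylation); none are applied by default because the
    digest protocol modelled here reports no alkylation step.
    """
    validate_sequence(sequence)
    idx = 0 if mass_type == "monoisotopic" else 1
    mass = water_mass(mass_type)
    mods = fixed_modifications or {}
    for aa in sequence:
        mass += RESIDUE_MASSES[aa][idx] + mods.get(aa, 0.0)
    return mass


def mz_from_mass(neutral_mass: float, charge: int = 1) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int = 1) -> float:
    """Neutral mass corresponding to an observed m/z at a given charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS


def fragment_ions(
    sequence: str,
    series: Literal["b", "y"],
    charge: int = 1,
    mass_type: MassType = "monoisotopic",
) -> list[float]:
    """m/z values of the b- or y-ion series of a peptide.

    Returns n-1 singly indexed ions for an n-residue peptide: b_i is the
    N-terminal fragment of length i (residue sum + proton), y_j the
    C-terminal fragment of length j (residue sum + water + proton). Only
    charge 1 is used by the pipeline (MALDI produces singly protonated
    ions); higher charges divide in the usual way.
    """
    validate_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("fragment series require a peptide of length >= 2")
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}; expected 'b' or 'y'")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    idx = 0 if mass_type == "monoisotopic" else 1
    n = len(sequence)
    ions = []
    if series == "b":
        acc = 0.0
        for aa in sequence[: n - 1]:
            acc += RESIDUE_MASSES[aa][idx]
            ions.append((acc + charge * PROTON_MASS) / charge)
    else:
        acc = water_mass(mass_type)
        for aa in reversed(sequence[1:]):
            acc += RESIDUE_MASSES[aa][idx]
            ions.append((acc + charge * PROTON_MASS) / charge)
    return ions


@dataclass(frozen=True)
class MassConstants:
    """Snapshot of the physical constants behind all mass arithmetic."""

    water_monoisotopic: float = WATER_MONO
    water_average: float = WATER_AVG
    proton: float = PROTON_MASS


def constants_table() -> dict:
    """Machine-readable dump of all pinned constants, for audit."""
    return {
        "elements": {el: {"monoisotopic": m, "average": a} for el, (m, a) in ELEMENT_MASSES.items()},
        "residues": {
            aa: {
                "composition": RESIDUE_COMPOSITIONS[aa],
                "monoisotopic": RESIDUE_MASSES[aa][0],
                "average": RESIDUE_MASSES[aa][1],
            }
            for aa in sorted(RESIDUE_COMPOSITIONS)
        },
        "water": {"monoisotopic": WATER_MONO, "average": WATER_AVG},
        "proton": PROTON_MASS,
    }


def export_constants(path) -> None:
    """Write the constants table as JSON."""
    with open(path, "w") as fh:
        json.dump(constants_table(), fh, indent=2, sort_keys=True)
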