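"""Bundled per-element parameter tables.

van der Waals radii are Bondi (1964) consensus values in Å. The
Lennard-Jones table holds Tripos-style well depths (kcal/mol) and per-atom
rmin values (Å, the pair-minimum distance contributed by one atom; pairs
combine by Lorentz-Berthelot: arithmetic mean of rmin, geometric mean of
epsilon). Both tables are overridable per call; they are deliberately small
— organic elements plus the sp3-carbon probe used for field calculations.
"""

from __future__ import annotations

# Bondi vdW radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

# (lj_epsilon kcal/mol, lj_rmin Å) — Tripos-like parameters
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.042, 3.00),
    "C": (0.107, 3.40),
    "N": (0.095, 3.10),
    "O": (0.116, 3.04),
    "S": (0.314, 3.60),
    "Cl": (0.314, 3.50),
}

#: sp3 carbon probe defaults: +1 e charge, Tripos-like LJ well.
SP3_CARBON_PROBE = {"charge": 1.0, "lj_epsilon": 0.107, "lj_rmin": 3.40}

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_K = 332.0636


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    """Look up the van der Waals radius (Å) of ``element``.

    Raises ``KeyError`` with the offending symbol if unknown.
    """
    if overrides and element in overrides:
        return float(overrides[element])
    try:
        return VDW_RADII[element]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; "
            "supply an override table"
        ) from None


def lj_params(element: str, overrides: dict[str, tuple[float, float]] | None = None
              ) -> tuple[float, float]:
    """Return ``(epsilon, rmin)`` Lennard-Jones parameters for ``element``."""
    if overrides and element in overrides:
        eps, rmin = overrides[element]
        return float(eps), float(rmin)
    try:
        return LJ_PARAMS[element]
    except KeyError:
        raise KeyError(
            f"no Lennard-Jones parameters for element {element!r}; "
            "supply an override table"
        ) from None
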