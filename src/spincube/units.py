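"""Unit conventions and conversions.

Internal working unit for engine energies is the hartree (atomic unit, a.u.);
reported energies are kJ/mol.  Lengths are Cartesian angstrom throughout.
"""

from __future__ import annotations

HARTREE_TO_KJ_PER_MOL: float = 2625.4996
"""1 hartree in kJ/mol (CODATA-style value; 1e-6 a.u. is then ~2.6 J/mol)."""

BOHR_TO_ANGSTROM: float = 0.52917721092

_TO_KJ = {
    "a.u.": HARTREE_TO_KJ_PER_MOL,
    "au": HARTREE_TO_KJ_PER_MOL,
    "hartree": HARTREE_TO_KJ_PER_MOL,
    "kJ/mol": 1.0,
    "J/mol": 1e-3,
}


def unit_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between a.u. (hartree), kJ/mol and J/mol.

    Parameters
    ----------
    value : float
        Energy in ``from_unit``.
    from_unit, to_unit : str
        One of ``"a.u."`` (aliases ``"au"``, ``"hartree"``), ``"kJ/mol"``,
        ``"J/mol"``.

    Raises
    ------
    ValueError
        If either unit is not recognised.
    """
    try:
        f = _TO_KJ[from_unit]
    except KeyError:
        raise ValueError(f"unknown unit: {from_unit!r}") from None
    try:
        t = _TO_KJ[to_unit]
    except KeyError:
        raise ValueError(f"unknown unit: {to_unit!r}") from None
    return value * (f / t)
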