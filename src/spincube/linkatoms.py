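"""Hydrogen link-atom placement and the electrostatic-embedding point-charge model.

When a covalent bond crosses the QM/MM boundary, the QM region is capped with
a hydrogen link atom (HL) placed on the line between the QM-side atom and the
replaced environment atom (the carbon link atom, CL):

    HL = qm + g * (cl - qm),   0 < g <= 1

with g the ratio of equilibrium X-H to X-CL bond lengths (default 1.09/1.51
for a C-C bond truncated to C-H).  The environment enters the QM Hamiltonian
as an array of partial point charges, one per system-2 atom, except the CL
atoms, which are excluded outright; the excluded charge is NOT redistributed,
so the model total may be non-integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Atom, Partition, Structure

__all__ = [
    "PointChargeModel",
    "place_link_atom",
    "build_point_charge_model",
    "truncate_qm_system",
]


@dataclass
class PointChargeModel:
    """Entries of (position angstrom, charge e, source serial) for system 2."""

    positions: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,)
    source_serials: list[int]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if len(self.source_serials) == 0:
            self.positions = self.positions.reshape(0, 3)
            self.charges = self.charges.reshape(0)
        if self.positions.shape != (len(self.source_serials), 3):
            raise ValueError("positions must be (n, 3) matching source serials")
        if self.charges.shape != (len(self.source_serials),):
            raise ValueError("charges must be (n,) matching source serials")

    def __len__(self) -> int:
        return len(self.source_serials)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def to_text(self) -> str:
        lines = [
            f"{p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f} {q:12.6f} {s:d}"
            for p, q, s in zip(self.positions, self.charges, self.source_serials)
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def empty(cls) -> "PointChargeModel":
        return cls(np.zeros((0, 3)), np.zeros(0), [])


def place_link_atom(qm_pos, cl_pos, scale: float) -> np.ndarray:
    """Position of the hydrogen link atom: qm + scale*(cl - qm).

    Raises on coincident endpoints (no bond direction) or a scale outside
    [0, 1].
    """
    qm = np.asarray(qm_pos, dtype=float)
    cl = np.asarray(cl_pos, dtype=float)
    if not (0.0 <= scale <= 1.0):
        raise ValueError("link-atom scale must be in [0, 1]")
    if np.allclose(qm, cl, rtol=0.0, atol=1e-12):
        raise ValueError("QM and CL positions coincide; bond direction undefined")
    return qm + scale * (cl - qm)


def build_point_charge_model(structure: Structure, partition: Partition) -> PointChargeModel:
    """One point charge per system-2 atom, excluding CL atoms.

    Charges are copied unmodified from the structure's partial charges; the
    excluded CL charge is not redistributed.
    """
    cl = partition.cl_serials
    entries = [
        a
        for a in structure
        if a.serial in partition.system2_serials and a.serial not in cl
    ]
    if not entries:
        return PointChargeModel.empty()
    return PointChargeModel(
        np.array([a.xyz for a in entries]),
        np.array([a.partial_charge for a in entries]),
        [a.serial for a in entries],
    )


def truncate_qm_system(
    structure: Structure,
    partition: Partition,
    hl_serial_start: int | None = None,
) -> Structure:
    """System-1 atoms plus one hydrogen link atom per junction.

    HL atoms carry zero partial charge and fresh serials above the structure
    maximum (or ``hl_serial_start``).  With no junctions the QM subset is
    returned unchanged.
    """
    atoms = [a for a in structure if a.serial in partition.system1_serials]
    next_serial = (
        hl_serial_start
        if hl_serial_start is not None
        else max(structure.serials) + 1
    )
    for j in partition.junctions:
        qm = structure.atom(j.qm_serial)
        cl = structure.atom(j.cl_serial)
        pos = place_link_atom(qm.xyz, cl.xyz, j.scale)
        atoms.append(Atom("H", tuple(pos), 0.0, next_serial, "HL"))
        next_serial += 1
    return Structure(atoms, title=structure.title + " [QM truncated]")
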