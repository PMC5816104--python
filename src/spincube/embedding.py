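"""Subtractive electrostatic-embedding QM/MM energy assembly.

The total energy is assembled from three terms,

    E_QM/MM = E_QM1+ptch2^HL + E_MM12,q1=0^CL - E_MM1,q1=0^HL

where the first term is the QM energy of the hydrogen-capped QM region
embedded in the system-2 point charges (the self-energy of the charges is
excluded — an obligation on the engine contract), the second is the
classical energy of ALL atoms (with CL atoms, QM charges zeroed to avoid
double counting of electrostatics), and the third is the classical energy of
the capped QM region without electrostatics.  Truncation artifacts cancel
between the two classical terms.

The single-level total is then extrapolated to a better functional and basis
set by assuming the functional and basis corrections are additive:

    E_tot = E_QM/MM^SV(P) + E_TPSS^TZVP + E_B3LYP^SV(P) - 2 E_TPSS^SV(P)

Engines are pluggable: any callable taking (structure, point-charge model or
None, BS state or None, level label) and returning an EngineResult.  Level
labels like "TPSS/def2-SV(P)" are opaque tags — no electronic structure is
computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Protocol

import numpy as np

from .geometry import Partition, Structure
from .linkatoms import PointChargeModel, build_point_charge_model, truncate_qm_system
from .spinstates import BSState
from .units import unit_convert  # noqa: F401  (re-exported convenience)

__all__ = [
    "EngineResult",
    "EngineContract",
    "EngineError",
    "EnergyComponents",
    "LevelEnergies",
    "assemble_qmmm_energy",
    "extrapolate_total_energy",
    "run_qmmm",
    "cached_engine",
    "unit_convert",
]


@dataclass
class EngineResult:
    """Per-call engine output: energy (a.u.), optional gradients and spins.

    Gradients are per-atom triples in a.u./angstrom; spin populations are
    per-atom net unpaired-electron counts (Mulliken-style).
    """

    energy: float
    gradients: Optional[np.ndarray] = None
    spin_populations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError("engine energy must be finite")
        if self.gradients is not None:
            self.gradients = np.asarray(self.gradients, dtype=float)
            if self.gradients.ndim != 2 or self.gradients.shape[1] != 3:
                raise ValueError("gradients must be an (n_atoms, 3) array")


class EngineContract(Protocol):
    """A deterministic energy engine (the stand-in for a QM or MM program)."""

    def __call__(
        self,
        structure: Structure,
        charges: Optional[PointChargeModel],
        state: Optional[BSState],
        level: str,
    ) -> EngineResult: ...


class EngineError(RuntimeError):
    """Engine failure, annotated with the energy term being evaluated."""

    def __init__(self, term: str, cause: Exception):
        super().__init__(f"engine failed while evaluating term {term!r}: {cause}")
        self.term = term
        self.cause = cause


@dataclass(frozen=True)
class EnergyComponents:
    """The three subtractive-scheme terms, in hartree."""

    e_qm1_ptch2_hl: float  # QM, capped region in the point-charge field
    e_mm12_q1_0_cl: float  # MM, all atoms, QM charges zeroed
    e_mm1_q1_0_hl: float  # MM, capped region, no electrostatics

    def __post_init__(self) -> None:
        for name in ("e_qm1_ptch2_hl", "e_mm12_q1_0_cl", "e_mm1_q1_0_hl"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"component {name} must be finite")

    def to_text(self) -> str:
        return (
            f"e_qm1_ptch2_hl {self.e_qm1_ptch2_hl!r}\n"
            f"e_mm12_q1_0_cl {self.e_mm12_q1_0_cl!r}\n"
            f"e_mm1_q1_0_hl {self.e_mm1_q1_0_hl!r}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "EnergyComponents":
        vals = {}
        for line in text.strip().splitlines():
            key, value = line.split()
            vals[key] = float(value)
        return cls(**vals)


@dataclass(frozen=True)
class LevelEnergies:
    """The four single-level energies entering the extrapolation, in hartree."""

    e_qmmm_svp: float
    e_tpss_tzvp: float
    e_b3lyp_svp: float
    e_tpss_svp: float

    def __post_init__(self) -> None:
        for name in ("e_qmmm_svp", "e_tpss_tzvp", "e_b3lyp_svp", "e_tpss_svp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"level energy {name} must be finite")


def assemble_qmmm_energy(c: EnergyComponents) -> float:
    """Subtractive total: QM term + full-MM term - capped-region MM term."""
    return c.e_qm1_ptch2_hl + c.e_mm12_q1_0_cl - c.e_mm1_q1_0_hl


def extrapolate_total_energy(l: LevelEnergies) -> float:
    """Additive functional/basis extrapolation (coefficients +1,+1,+1,-2)."""
    return l.e_qmmm_svp + l.e_tpss_tzvp + l.e_b3lyp_svp - 2.0 * l.e_tpss_svp


def cached_engine(engine: EngineContract) -> EngineContract:
    """Memoise an engine on (structure, charge model, state, level).

    Profile assembly calls the same stationary points repeatedly; caching
    guarantees each distinct input is evaluated once.
    """
    cache: dict = {}

    def wrapped(structure, charges, state, level):
        key = (
            structure.content_hash(),
            None
            if charges is None or len(charges) == 0
            else (
                charges.positions.tobytes(),
                charges.charges.tobytes(),
                tuple(charges.source_serials),
            ),
            None if state is None else state.orientations,
            level,
        )
        if key not in cache:
            cache[key] = engine(structure, charges, state, level)
        return cache[key]

    return wrapped


def run_qmmm(
    structure: Structure,
    partition: Partition,
    qm_engine: EngineContract,
    mm_engine: EngineContract,
    state: Optional[BSState] = None,
    level: str = "TPSS/def2-SV(P)",
) -> tuple[float, EnergyComponents]:
    """Evaluate the subtractive QM/MM energy for one structure and partition.

    Orchestrates the capped-region construction, the point-charge model, the
    three engine calls and the final assembly; returns (total energy in
    hartree, the three components) for auditability.

    The "q1 = 0" convention zeroes the partial charges of system-1 atoms in
    the structure handed to the MM engine — atoms are never deleted.  The
    capped region handed to the third term additionally has ALL charges
    zeroed (no electrostatics at all in that term).
    """
    qm_region = truncate_qm_system(structure, partition)
    charges = build_point_charge_model(structure, partition)

    def call(engine, term, struct, chg, st):
        try:
            return engine(struct, chg, st, level)
        except Exception as exc:  # annotate which term failed
            raise EngineError(term, exc) from exc

    r_qm = call(qm_engine, "e_qm1_ptch2_hl", qm_region, charges, state)

    full_q1_0 = structure.with_charges({s: 0.0 for s in partition.system1_serials})
    r_mm_full = call(mm_engine, "e_mm12_q1_0_cl", full_q1_0, None, None)

    qm_region_q0 = qm_region.with_charges({s: 0.0 for s in qm_region.serials})
    r_mm_region = call(mm_engine, "e_mm1_q1_0_hl", qm_region_q0, None, None)

    components = EnergyComponents(
        r_qm.energy, r_mm_full.energy, r_mm_region.energy
    )
    return assemble_qmmm_energy(components), components
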