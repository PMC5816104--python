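"""Ising-approximation exchange Hamiltonian: the synthetic stand-in engine.

Broken-symmetry determinants are collinear, so a Heisenberg exchange
Hamiltonian evaluated on them reduces to the Ising form

    E(sigma) = offset + sum_{i<j} J_ij m_i m_j sigma_i sigma_j

with sigma_i = +/-1 the site orientations, m_i the site spin magnitudes
(unpaired-electron counts) and J_ij pairwise exchange couplings in kJ/mol
(positive J favours anti-alignment of the pair).  The physical picture for a
[4Fe4S]2+ cubane — two ferromagnetically coupled mixed-valence pairs that
couple antiferromagnetically to a singlet — corresponds to the ``two_J``
model: J_intra < 0 within the pairs and J_inter > 0 across them, which makes
the pair-aligned 2-up/2-down states the lowest of the six.

The module generates BS energy tables with known couplings (plus optional
Gaussian noise), recovers couplings by linear least squares, and wraps the
Hamiltonian in toy QM/MM engines (harmonic bonds + Coulomb + spin term) so
the whole embedding and scan machinery is testable without quantum
chemistry.  No couplings are fitted to experimental tables as a scientific
claim; the fit is a synthetic-validation device.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import Structure, bonded, COVALENT_RADII
from .linkatoms import PointChargeModel
from .spinstates import BSEnergyTable, BSState, SiteSpins
from .embedding import EngineResult
from .units import BOHR_TO_ANGSTROM, HARTREE_TO_KJ_PER_MOL

__all__ = [
    "HeisenbergParams",
    "SyntheticTableSpec",
    "ising_energy",
    "generate_bs_table",
    "fit_couplings",
    "FitDiagnostics",
    "toy_mm_engine",
    "toy_spin_engine",
    "double_well_engine",
]

DEFAULT_PAIR_PARTITION: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (2, 3))


@dataclass
class HeisenbergParams:
    """Exchange couplings over site pairs, in kJ/mol.

    ``model="full_6J"``: ``couplings`` maps every in-cluster pair (i<j) to a
    coupling (6 per 4-site cluster).  ``model="two_J"``: only ``j_intra``
    (within the ferromagnetic pairs of ``pair_partition``) and ``j_inter``
    (across pairs) are used.
    """

    model: str = "two_J"
    couplings: dict[tuple[int, int], float] = field(default_factory=dict)
    j_intra: float = -40.0
    j_inter: float = 30.0
    offset: float = 0.0
    pair_partition: tuple[tuple[int, int], ...] = DEFAULT_PAIR_PARTITION

    def __post_init__(self) -> None:
        if self.model not in ("two_J", "full_6J"):
            raise ValueError(f"unknown model {self.model!r}")
        for v in (self.j_intra, self.j_inter, self.offset, *self.couplings.values()):
            if not math.isfinite(v):
                raise ValueError("couplings must be finite")

    def coupling(self, i: int, j: int, n_sites: int) -> float:
        """J for sites i<j; cross-cluster pairs couple as 0 for 8 sites."""
        if i > j:
            i, j = j, i
        if n_sites == 8 and (i < 4) != (j < 4):
            return 0.0
        ci = (i % 4, j % 4) if n_sites == 8 else (i, j)
        if self.model == "full_6J":
            return self.couplings.get((i, j), self.couplings.get(ci, 0.0))
        intra = any(set(ci) == set(p) for p in self.pair_partition)
        return self.j_intra if intra else self.j_inter

    def to_text(self) -> str:
        lines = [f"model {self.model}", f"offset {self.offset!r}"]
        if self.model == "two_J":
            lines += [f"j_intra {self.j_intra!r}", f"j_inter {self.j_inter!r}"]
            lines += [
                "pair_partition " + ";".join(f"{a},{b}" for a, b in self.pair_partition)
            ]
        else:
            lines += [f"J_{i}_{j} {v!r}" for (i, j), v in sorted(self.couplings.items())]
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticTableSpec:
    """Recipe for a synthetic BS energy table."""

    params: HeisenbergParams
    site_spins: SiteSpins
    states: Sequence[BSState]
    noise_sd: float = 0.0
    seed: int = 0
    family: str = "synthetic"
    column: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def ising_energy(state: BSState, params: HeisenbergParams, spins: SiteSpins) -> float:
    """offset + sum_{i<j} J_ij m_i m_j sigma_i sigma_j, in kJ/mol."""
    n = state.n_sites
    if len(spins) != n:
        raise ValueError(
            f"state has {n} sites but {len(spins)} spin magnitudes were given"
        )
    sigma = state.orientations
    m = spins.magnitudes
    e = params.offset
    for i, j in itertools.combinations(range(n), 2):
        J = params.coupling(i, j, n)
        if J != 0.0:
            e += J * m[i] * m[j] * sigma[i] * sigma[j]
    return e


def generate_bs_table(spec: SyntheticTableSpec) -> BSEnergyTable:
    """One row per state; energy = Ising energy + N(0, noise_sd), seeded.

    The generator stream is named per table so the same seed always yields
    the same noise regardless of call order elsewhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0x5C,)))
    noise = (
        rng.normal(0.0, spec.noise_sd, size=len(spec.states))
        if spec.noise_sd > 0
        else np.zeros(len(spec.states))
    )
    rows = [
        (s.label, spec.family, spec.column,
         ising_energy(s, spec.params, spec.site_spins) + float(dz))
        for s, dz in zip(spec.states, noise)
    ]
    return BSEnergyTable(rows)


@dataclass
class FitDiagnostics:
    """Design-matrix diagnostics of a coupling fit."""

    rank: int
    n_parameters: int
    singular_values: np.ndarray
    residual_norm: float
    identifiable_combinations: list[dict[str, float]]
    parameter_names: list[str]

    @property
    def rank_deficient(self) -> bool:
        return self.rank < self.n_parameters


def _design_matrix(
    states: Sequence[BSState],
    spins: SiteSpins,
    model: str,
    pair_partition: tuple[tuple[int, int], ...],
) -> tuple[np.ndarray, list[str]]:
    n = states[0].n_sites
    m = spins.magnitudes
    if model == "two_J":
        names = ["j_intra", "j_inter", "offset"]
        rows = []
        for s in states:
            x_intra = x_inter = 0.0
            for i, j in itertools.combinations(range(n), 2):
                if n == 8 and (i < 4) != (j < 4):
                    continue
                ci = {i % 4, j % 4} if n == 8 else {i, j}
                term = m[i] * m[j] * s.orientations[i] * s.orientations[j]
                if any(ci == set(p) for p in pair_partition):
                    x_intra += term
                else:
                    x_inter += term
            rows.append([x_intra, x_inter, 1.0])
        return np.array(rows), names
    # full_6J: one column per in-cluster pair
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if not (n == 8 and (i < 4) != (j < 4))
    ]
    names = [f"J_{i}_{j}" for i, j in pairs] + ["offset"]
    rows = []
    for s in states:
        row = [
            m[i] * m[j] * s.orientations[i] * s.orientations[j] for i, j in pairs
        ]
        row.append(1.0)
        rows.append(row)
    return np.array(rows), names


def fit_couplings(
    table: BSEnergyTable,
    spins: SiteSpins,
    model: str = "two_J",
    pair_partition: tuple[tuple[int, int], ...] = DEFAULT_PAIR_PARTITION,
) -> tuple[HeisenbergParams, FitDiagnostics]:
    """Least-squares coupling recovery from a BS energy table.

    Solves the linear model E(state) = X(state) . theta for theta =
    (couplings..., offset) by minimum-norm least squares.  The diagnostics
    report the design rank and, for rank-deficient designs, the identifiable
    parameter combinations (right singular vectors with non-negligible
    singular value); the minimum-norm solution still reproduces every table
    energy when the system is consistent.  Missing rows are excluded.
    """
    from .spinstates import parse_label

    entries = [(parse_label(lbl), e) for lbl, _, _, e in table.rows if e is not None]
    if len(entries) < 2:
        raise ValueError("need at least two non-missing rows to fit couplings")
    states = [s for s, _ in entries]
    y = np.array([e for _, e in entries])
    X, names = _design_matrix(states, spins, model, pair_partition)
    n_params = X.shape[1]
    rank = int(np.linalg.matrix_rank(X))
    theta, _, _, sv = np.linalg.lstsq(X, y, rcond=None)
    residual = float(np.linalg.norm(X @ theta - y))
    # identifiable combinations: right singular vectors with sv above cutoff
    _, s_full, vt = np.linalg.svd(X)
    cutoff = (s_full.max() if s_full.size else 0.0) * max(X.shape) * np.finfo(float).eps
    combos = [
        {name: float(c) for name, c in zip(names, vt[k])}
        for k in range(len(s_full))
        if s_full[k] > cutoff
    ]
    diagnostics = FitDiagnostics(
        rank=rank,
        n_parameters=n_params,
        singular_values=s_full,
        residual_norm=residual,
        identifiable_combinations=combos,
        parameter_names=names,
    )
    if model == "two_J":
        params = HeisenbergParams(
            model="two_J",
            j_intra=float(theta[0]),
            j_inter=float(theta[1]),
            offset=float(theta[2]),
            pair_partition=pair_partition,
        )
    else:
        n = states[0].n_sites
        pairs = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if not (n == 8 and (i < 4) != (j < 4))
        ]
        params = HeisenbergParams(
            model="full_6J",
            couplings={p: float(t) for p, t in zip(pairs, theta[:-1])},
            offset=float(theta[-1]),
        )
    return params, diagnostics


# ---------------------------------------------------------------------------
# Toy engines (the DFT/force-field stand-ins)
# ---------------------------------------------------------------------------

_KJ_TO_AU = 1.0 / HARTREE_TO_KJ_PER_MOL


def _bond_list(structure: Structure) -> list[tuple[int, int]]:
    atoms = structure.atoms
    out = []
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            if bonded(atoms[a], atoms[b]):
                out.append((a, b))
    return out


def _harmonic_and_coulomb(
    structure: Structure,
    charges: Optional[PointChargeModel],
    k_bond: float,
    bond_pairs: Optional[Sequence[tuple[int, int]]],
) -> tuple[float, np.ndarray]:
    """Energy (hartree) and gradient (hartree/angstrom) of the toy force field.

    Harmonic bonds k(r - r0)^2 with r0 the covalent-radius sum, Coulomb over
    intra-structure pairs and against the external point charges.  The
    charge-charge self-energy of the external model is never included.
    """
    pos = structure.positions()
    q = np.array([a.partial_charge for a in structure])
    n = len(structure)
    grad = np.zeros((n, 3))
    energy = 0.0

    if bond_pairs is None:
        pairs = _bond_list(structure)
    else:  # explicit serial pairs keep the topology fixed during scans
        index = {s: i for i, s in enumerate(structure.serials)}
        pairs = [(index[a], index[b]) for a, b in bond_pairs if a in index and b in index]

    for i, j in pairs:
        d = pos[i] - pos[j]
        r = float(np.linalg.norm(d))
        r0 = (
            COVALENT_RADII[structure.atoms[i].element.upper()]
            + COVALENT_RADII[structure.atoms[j].element.upper()]
        )
        energy += k_bond * (r - r0) ** 2
        g = 2.0 * k_bond * (r - r0) * d / r
        grad[i] += g
        grad[j] -= g

    # intra-structure Coulomb (atomic units: q in e, r in bohr)
    if np.any(q != 0.0):
        for i in range(n):
            if q[i] == 0.0:
                continue
            for j in range(i + 1, n):
                if q[j] == 0.0:
                    continue
                d = pos[i] - pos[j]
                r = float(np.linalg.norm(d))
                e = q[i] * q[j] * BOHR_TO_ANGSTROM / r
                energy += e
                g = -e * d / r**2
                grad[i] += g
                grad[j] -= g

    # embedding Coulomb against the external charges (their self-energy excluded)
    if charges is not None and len(charges) > 0:
        for i in range(n):
            if q[i] == 0.0:
                continue
            for p, qc in zip(charges.positions, charges.charges):
                if qc == 0.0:
                    continue
                d = pos[i] - p
                r = float(np.linalg.norm(d))
                e = q[i] * qc * BOHR_TO_ANGSTROM / r
                energy += e
                grad[i] += -e * d / r**2
    return energy, grad


def toy_mm_engine(
    k_bond: float = 0.3,
    bond_pairs: Optional[Sequence[tuple[int, int]]] = None,
):
    """Spin-blind toy force field: harmonic bonds + Coulomb.

    ``k_bond`` is in hartree/angstrom^2.  Bonds are auto-detected with the
    covalent-radius cutoff unless an explicit serial-pair list is given
    (which keeps the topology fixed during scans).  Deterministic and
    gradient-capable.
    """

    def engine(structure, charges, state, level):
        energy, grad = _harmonic_and_coulomb(structure, charges, k_bond, bond_pairs)
        return EngineResult(energy, grad)

    return engine


def toy_spin_engine(
    params: HeisenbergParams,
    spins: SiteSpins,
    k_bond: float = 0.3,
    bond_pairs: Optional[Sequence[tuple[int, int]]] = None,
):
    """Toy spin engine: the MM terms plus the Ising energy of the BS state.

    The spin term is evaluated over the structure's Fe atoms in order; a
    state whose length does not match the Fe count raises.  With all
    couplings zero this engine coincides with :func:`toy_mm_engine`.  It also
    reports per-Fe spin populations sigma_i * m_i.
    """

    def engine(structure, charges, state, level):
        energy, grad = _harmonic_and_coulomb(structure, charges, k_bond, bond_pairs)
        pops = None
        if state is not None:
            n_fe = sum(1 for a in structure if a.element.upper() == "FE")
            if n_fe != state.n_sites:
                raise ValueError(
                    f"structure has {n_fe} Fe sites but state has {state.n_sites}"
                )
            energy += ising_energy(state, params, spins) * _KJ_TO_AU
            pops = np.array(
                [s * m for s, m in zip(state.orientations, spins.magnitudes)]
            )
        return EngineResult(energy, grad, pops)

    return engine


def double_well_engine(
    pair: tuple[int, int],
    a: float = 0.05,
    r_center: float = 2.0,
    half_width: float = 0.3,
    k_spectator: float = 0.5,
    anchors: Optional[Mapping[int, np.ndarray]] = None,
):
    """Analytic double-well toy surface for scan-driver validation.

    The scanned pair (two atom serials) feels a quartic in its distance r,

        V(r) = a * ((r - r_center)^2 - half_width^2)^2     [hartree],

    with wells at r_center +/- half_width (V = 0) and a saddle of height
    a * half_width^4 at r = r_center.  Every other atom is tethered
    harmonically (k_spectator, hartree/angstrom^2) to its anchor position
    (captured on first call unless given), so relaxed spectators contribute
    nothing and the relaxed scan profile IS the quartic — giving a
    closed-form check of the constrained-scan maximum.
    """
    captured: dict[int, np.ndarray] = dict(anchors or {})

    def engine(structure, charges, state, level):
        pos = {atm.serial: atm.xyz for atm in structure}
        d = pos[pair[0]] - pos[pair[1]]
        r = float(np.linalg.norm(d))
        u = (r - r_center) ** 2 - half_width**2
        energy = a * u**2
        grad = np.zeros((len(structure), 3))
        index = {s: i for i, s in enumerate(structure.serials)}
        dVdr = 4.0 * a * u * (r - r_center)
        grad[index[pair[0]]] += dVdr * d / r
        grad[index[pair[1]]] -= dVdr * d / r
        for atm in structure:
            if atm.serial in pair:
                continue
            if atm.serial not in captured:
                captured[atm.serial] = atm.xyz.copy()
            dd = atm.xyz - captured[atm.serial]
            energy += k_spectator * float(dd @ dd)
            grad[index[atm.serial]] += 2.0 * k_spectator * dd
        return EngineResult(energy, grad)

    return engine
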