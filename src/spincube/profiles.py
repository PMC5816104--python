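"""Reaction profiles and the constrained-coordinate scan driver.

A reaction profile is an ordered list of labelled stationary points
(RS/TS/IM/PS with subscripts) with energies in kJ/mol relative to a declared
reference point.  Barriers are read as the highest intervening energy above
the starting point of a segment; exothermicities as E(from) - E(to).

The scan driver relaxes the QM region under a single fixed-distance
constraint against any gradient-capable engine, holding system-2 atoms (and
any explicitly frozen serials) fixed — the standard device for mapping a
bond-formation coordinate when no transition-state optimiser is available.
Convergence requires BOTH an energy change below the energy tolerance and a
maximum atomic gradient norm below the gradient tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import Partition, Structure
from .linkatoms import build_point_charge_model, truncate_qm_system
from .embedding import EngineContract
from .units import HARTREE_TO_KJ_PER_MOL

__all__ = [
    "StationaryPoint",
    "ReactionProfile",
    "ScanSpec",
    "ScanPoint",
    "assemble_profile",
    "barrier",
    "exothermicity",
    "compare_mechanisms",
    "constrained_scan",
]


@dataclass(frozen=True)
class StationaryPoint:
    """A labelled point on a reaction profile (energy in kJ/mol, relative)."""

    label: str
    energy: float
    note: str = ""
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"energy of {self.label!r} must be finite")


@dataclass
class ReactionProfile:
    """Ordered stationary points; the reference point has energy 0."""

    points: list[StationaryPoint]
    reference: str

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError("stationary-point labels must be unique")
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} not in profile")
        if abs(self.energy(self.reference)) > 1e-9:
            raise ValueError("reference point must sit at energy 0")

    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def energy(self, label: str) -> float:
        for p in self.points:
            if p.label == label:
                return p.energy
        raise KeyError(f"no stationary point labelled {label!r}")

    def index(self, label: str) -> int:
        return self.labels().index(label)

    def to_tsv(self, path: str | None = None) -> str:
        lines = ["label\tenergy_kJmol\tnote"]
        lines += [f"{p.label}\t{p.energy:g}\t{p.note}" for p in self.points]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, path_or_text: str, reference: str | None = None) -> "ReactionProfile":
        text = path_or_text
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
        points = []
        for line in text.strip().splitlines()[1:]:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            label, energy = parts[0], float(parts[1])
            note = parts[2] if len(parts) > 2 else ""
            points.append(StationaryPoint(label, energy, note))
        if reference is None:
            reference = next(p.label for p in points if p.energy == 0.0)
        return cls(points, reference)


def assemble_profile(
    points: Sequence[tuple[str, float]] | Sequence[tuple[str, float, str]],
    reference: str,
) -> ReactionProfile:
    """Shift absolute energies so the reference point is 0; preserve order."""
    labels = [p[0] for p in points]
    if reference not in labels:
        raise KeyError(f"reference {reference!r} not among the points")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate stationary-point labels")
    ref_energy = next(p[1] for p in points if p[0] == reference)
    out = []
    for p in points:
        note = p[2] if len(p) > 2 else ""
        out.append(StationaryPoint(p[0], p[1] - ref_energy, note))
    return ReactionProfile(out, reference)


def barrier(profile: ReactionProfile, from_label: str, to_label: str) -> float:
    """Highest intervening energy above E(from) on the from->to segment.

    Never negative: a monotonically downhill segment has barrier 0.
    """
    i, j = profile.index(from_label), profile.index(to_label)
    if j <= i:
        raise ValueError(f"{to_label!r} must follow {from_label!r} in the profile")
    e_from = profile.points[i].energy
    peak = max(p.energy for p in profile.points[i : j + 1])
    return max(peak - e_from, 0.0)


def exothermicity(profile: ReactionProfile, from_label: str, to_label: str) -> float:
    """E(from) - E(to); positive when the step is downhill (exothermic)."""
    i, j = profile.index(from_label), profile.index(to_label)
    if j <= i:
        raise ValueError(f"{to_label!r} must follow {from_label!r} in the profile")
    return profile.points[i].energy - profile.points[j].energy


def compare_mechanisms(
    profile_a: ReactionProfile,
    profile_b: ReactionProfile,
    from_labels: tuple[str, str],
    ts_labels: tuple[str, str],
    product_labels: tuple[str, str],
) -> tuple[float, float]:
    """(Delta barrier, Delta product energy) between two mechanisms.

    Delta barrier = barrier_a - barrier_b over each mechanism's from->product
    segment; Delta product = E_product_a - E_product_b.  Positive values mean
    mechanism a has the higher barrier / less stable product.  The TS labels
    must lie on the compared segments (checked).
    """
    for prof, frm, ts, prod in (
        (profile_a, from_labels[0], ts_labels[0], product_labels[0]),
        (profile_b, from_labels[1], ts_labels[1], product_labels[1]),
    ):
        for lbl in (frm, ts, prod):
            prof.energy(lbl)  # raises on missing labels
        if not (prof.index(frm) < prof.index(ts) < prof.index(prod)):
            raise ValueError(f"TS {ts!r} does not lie between {frm!r} and {prod!r}")
    ba = barrier(profile_a, from_labels[0], product_labels[0])
    bb = barrier(profile_b, from_labels[1], product_labels[1])
    dp = profile_a.energy(product_labels[0]) - profile_b.energy(product_labels[1])
    return ba - bb, dp


# ---------------------------------------------------------------------------
# Constrained scan driver
# ---------------------------------------------------------------------------


@dataclass
class ScanSpec:
    """A fixed-distance scan: which pair, which targets, how tight.

    Tolerances follow common geometry-optimisation practice: energy change
    below 1e-6 a.u. between iterations AND maximum Cartesian gradient norm
    below 1e-3 a.u.; both must hold simultaneously.
    """

    pair: tuple[int, int]
    targets: Sequence[float]
    max_steps: int = 200
    energy_tol: float = 1e-6  # a.u.
    gradient_tol: float = 1e-3  # a.u. (max per-atom norm, projected)
    frozen_serials: frozenset[int] = frozenset()
    level: str = "toy"


@dataclass(frozen=True)
class ScanPoint:
    coordinate: float  # angstrom
    energy: float  # hartree
    converged: bool
    gradient_norm: float
    structure: Structure = field(compare=False, repr=False, default=None)


def _set_pair_distance(
    positions: dict[int, np.ndarray], pair: tuple[int, int], target: float
) -> None:
    a, b = pair
    d = positions[b] - positions[a]
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("constrained atoms coincide")
    positions[b] = positions[a] + d * (target / r)


def constrained_scan(
    structure: Structure,
    partition: Partition,
    engine: EngineContract,
    spec: ScanSpec,
    state=None,
) -> list[ScanPoint]:
    """Relaxed energies along a fixed-distance coordinate.

    For each target distance the constrained pair is set to that separation
    and every non-frozen, non-system-2 degree of freedom is relaxed with the
    constraint enforced exactly (an equality-constrained quasi-Newton
    minimisation, equivalent to eliminating the gradient component along the
    constraint).  Each point starts from the previous relaxed geometry.
    Gradients on hydrogen link atoms are not back-projected (system 2 is
    fixed, so junction forces are frozen by construction).

    Raises if the optimiser exhausts ``max_steps`` without meeting both
    stopping criteria; the offending gradient norm is included.
    """
    a, b = spec.pair
    for s in (a, b):
        if s not in partition.system1_serials:
            raise ValueError(f"constrained atom {s} is not in the QM region")
    free = [
        s
        for s in structure.serials
        if s in partition.system1_serials and s not in spec.frozen_serials
    ]
    if a not in free or b not in free:
        raise ValueError("constrained atoms must be free to move")
    charges = build_point_charge_model(structure, partition)
    current = {s: structure.atom(s).xyz.copy() for s in structure.serials}
    n_free = len(free)

    def build(positions: dict[int, np.ndarray]) -> Structure:
        moved = structure.with_positions(
            np.array([positions[s] for s in structure.serials])
        )
        return truncate_qm_system(moved, partition)

    def eval_point(x: np.ndarray):
        positions = dict(current)
        for k, s in enumerate(free):
            positions[s] = x[3 * k : 3 * k + 3]
        qm = build(positions)
        res = engine(qm, charges, state, spec.level)
        grad = np.zeros(3 * n_free)
        if res.gradients is not None:
            gmap = dict(zip(qm.serials, res.gradients))
            for k, s in enumerate(free):
                grad[3 * k : 3 * k + 3] = gmap.get(s, 0.0)
        return res.energy, grad, positions

    results: list[ScanPoint] = []
    ia, ib = free.index(a), free.index(b)
    for target in spec.targets:
        _set_pair_distance(current, spec.pair, float(target))
        x = np.concatenate([current[s] for s in free])

        def c_fun(x):
            d = x[3 * ib : 3 * ib + 3] - x[3 * ia : 3 * ia + 3]
            return float(np.linalg.norm(d)) - float(target)

        def c_jac(x):
            d = x[3 * ib : 3 * ib + 3] - x[3 * ia : 3 * ia + 3]
            r = float(np.linalg.norm(d))
            j = np.zeros_like(x)
            j[3 * ib : 3 * ib + 3] = d / r
            j[3 * ia : 3 * ia + 3] = -d / r
            return j

        def f(x):
            e, g, _ = eval_point(x)
            return e, g

        e_prev = None
        converged = False
        gnorm = float("inf")
        for _ in range(spec.max_steps):
            sol = minimize(
                f,
                x,
                jac=True,
                method="SLSQP",
                constraints=[{"type": "eq", "fun": c_fun, "jac": c_jac}],
                options={"maxiter": 80, "ftol": 1e-14},
            )
            x = sol.x
            e, g, positions = eval_point(x)
            # projected gradient: remove the component along the constraint
            cj = c_jac(x)
            g_proj = g - (g @ cj) / (cj @ cj) * cj
            gnorm = max(
                float(np.linalg.norm(g_proj[3 * k : 3 * k + 3]))
                for k in range(n_free)
            )
            if (
                e_prev is not None
                and abs(e - e_prev) < spec.energy_tol
                and gnorm < spec.gradient_tol
            ):
                converged = True
                break
            e_prev = e
        if not converged:
            raise RuntimeError(
                f"scan point at {target:.3f} A did not converge in "
                f"{spec.max_steps} steps (last max gradient norm {gnorm:.2e} a.u.)"
            )
        current = positions
        relaxed = structure.with_positions(
            np.array([current[s] for s in structure.serials])
        )
        results.append(ScanPoint(float(target), e, converged, gnorm, relaxed))
    return results


def scan_to_tsv(points: Sequence[ScanPoint], path: str | None = None) -> str:
    """Serialise scan output: coordinate, energy in a.u. and kJ/mol, flag."""
    lines = ["coordinate_A\tenergy_au\tenergy_kJmol\tconverged"]
    for p in points:
        lines.append(
            f"{p.coordinate:.4f}\t{p.energy:.10f}\t"
            f"{p.energy * HARTREE_TO_KJ_PER_MOL:.6f}\t{int(p.converged)}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
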