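"""Synthetic inputs: idealised cubanes, a miniature active site, packaged tables.

The geometric generator builds idealised [4Fe4S] cubanes — two concentric,
dual tetrahedra of Fe and S scaled so that all twelve Fe-S contacts equal the
requested distance — with optional ligand stubs (thiolate, water, serinate)
and Gaussian coordinate jitter to emulate the distortion of real clusters.
``make_lip_a_fixture`` assembles a miniature two-cluster active site:
main cluster (3 thiolates + 1 water) and auxiliary cluster (3 thiolates +
1 serinate) 12 angstrom apart, a neutral point-charge environment, and a
QM/MM partition with a junction at every stub CA atom.  It is a miniature:
no claim of electrostatic realism for a full solvated protein is made.

The packaged tables transcribe the reference broken-symmetry energy table
and stationary-point energies this package's analysis operations are
validated against.  Every packaged number carries a mandatory note recording
what it is; loading fails on a checksum mismatch or a missing note.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    Atom,
    ClusterSpec,
    Partition,
    Structure,
    partition_structure,
)
from .profiles import ReactionProfile
from .spinstates import BSEnergyTable

__all__ = [
    "CubaneSpec",
    "FixtureBundle",
    "make_cubane",
    "make_lip_a_fixture",
    "packaged_tables",
    "packaged_scalars",
    "FixtureIntegrityError",
]

STUB_TYPES = ("thiolate", "water", "serinate", "none")

# sha256 of the shipped data files; packaged_tables refuses tampered copies
_CHECKSUMS = {
    "table1.tsv": "c2c84edea9d8ea69aba9e47b9711fa581e44eb57dda3598657432816e8000a0c",
    "profile_first_insertion.tsv": "9acbe081931172327fb711f2e62bf8a49065f1c15fda4cbbf4816c49ec9cea86",
    "profile_second_insertion_mech1.tsv": "2511f46542ecfb9665e48a2d128e2f8db41cb8d2c9fd83571364b5fe6bc72e0a",
    "profile_second_insertion_mech2.tsv": "68765cfe1609016cb053100f38677875b5e5d352f4cfb6ec20ef0d1409a64d1c",
    "profile_rs2_cleavage_unreduced.tsv": "c7064e2ed19a8039bed91cc27a4616d1c8bdb540e9fe248421a28c601ac23fd9",
    "reported_scalars.tsv": "2cd0f919093d020358e113a1bec94ee675c4caee45264c4e5cc26e773113dc68",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture failed its checksum or provenance-note check."""


@dataclass
class CubaneSpec:
    """Recipe for one idealised cubane with ligand stubs."""

    fe_s_distance: float = 2.30
    stubs: tuple[str, str, str, str] = ("thiolate",) * 4
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.fe_s_distance > 0:
            raise ValueError("fe_s_distance must be positive")
        if len(self.stubs) != 4:
            raise ValueError("exactly 4 Fe sites take a stub type")
        for s in self.stubs:
            if s not in STUB_TYPES:
                raise ValueError(f"unknown stub type {s!r}")


@dataclass
class FixtureBundle:
    """A generated miniature active site ready for QM/MM."""

    structure: Structure
    partition: Partition
    clusters: tuple[ClusterSpec, ClusterSpec]
    notes: str = ""
    stub_serials: dict = field(default_factory=dict)


# vertices of the two interpenetrating tetrahedra on the unit cube
_FE_CORNERS = np.array([(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)], dtype=float)
_S_CORNERS = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)], dtype=float)

# synthetic partial charges (e); environment groups are built neutral
_CHARGES = {
    "FE": 0.5,
    "S_sulfide": -0.5,
    "SG": -0.4,
    "CB": 0.1,
    "CA": -0.1,
    "OW": -0.8,
    "HW": 0.4,
    "OG": -0.5,
}


def _stub_atoms(kind: str, fe_pos: np.ndarray, direction: np.ndarray, serial: int):
    """Atoms of one ligand stub along the outward radial direction.

    Returns (atoms, qm_serials, ca_serial or None).  Thiolate/serinate stubs
    end in a CA atom meant for system 2 (the junction partner of CB).
    """
    u = direction / np.linalg.norm(direction)
    atoms: list[Atom] = []
    if kind == "none":
        return atoms, [], None
    if kind == "water":
        o = fe_pos + 2.1 * u
        # H atoms off-axis so they do not collide with anything
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        atoms.append(Atom("O", tuple(o), _CHARGES["OW"], serial, "HOH"))
        atoms.append(Atom("H", tuple(o + 0.76 * u + 0.59 * perp), _CHARGES["HW"], serial + 1, "HOH"))
        atoms.append(Atom("H", tuple(o + 0.76 * u - 0.59 * perp), _CHARGES["HW"], serial + 2, "HOH"))
        return atoms, [a.serial for a in atoms], None
    if kind == "thiolate":
        sg = fe_pos + 2.30 * u
        cb = sg + 1.80 * u
        ca = cb + 1.53 * u
        atoms.append(Atom("S", tuple(sg), _CHARGES["SG"], serial, "CYS"))
        atoms.append(Atom("C", tuple(cb), _CHARGES["CB"], serial + 1, "CYS"))
        atoms.append(Atom("C", tuple(ca), _CHARGES["CA"], serial + 2, "CYS"))
        return atoms, [serial, serial + 1], serial + 2
    if kind == "serinate":
        og = fe_pos + 1.86 * u
        cb = og + 1.43 * u
        ca = cb + 1.53 * u
        atoms.append(Atom("O", tuple(og), _CHARGES["OG"], serial, "SER"))
        atoms.append(Atom("C", tuple(cb), _CHARGES["CB"], serial + 1, "SER"))
        atoms.append(Atom("C", tuple(ca), _CHARGES["CA"], serial + 2, "SER"))
        return atoms, [serial, serial + 1], serial + 2
    raise ValueError(kind)


def make_cubane(
    spec: CubaneSpec,
    seed: int = 0,
    serial_start: int = 1,
) -> tuple[Structure, ClusterSpec, dict]:
    """Build one idealised cubane with stubs.

    Returns (structure, cluster spec, stub bookkeeping).  The core is 8
    atoms — 4 Fe and 4 inorganic S on interpenetrating tetrahedra with all
    12 Fe-S distances equal to ``spec.fe_s_distance`` — followed by the stub
    atoms.  Jitter (if any) is Gaussian per coordinate with the given seed
    and is applied to every atom, so the generated structure is reproducible
    for a fixed seed.
    """
    a = spec.fe_s_distance  # cube edge = nearest Fe-S separation
    centroid = np.asarray(spec.centroid, dtype=float)
    shift = centroid - a * np.array([0.5, 0.5, 0.5])
    fe_pos = _FE_CORNERS * a + shift
    s_pos = _S_CORNERS * a + shift

    serial = serial_start
    atoms: list[Atom] = []
    fe_serials, s_serials = [], []
    for p in fe_pos:
        atoms.append(Atom("FE", tuple(p), _CHARGES["FE"], serial, "SF4"))
        fe_serials.append(serial)
        serial += 1
    for p in s_pos:
        atoms.append(Atom("S", tuple(p), _CHARGES["S_sulfide"], serial, "SF4"))
        s_serials.append(serial)
        serial += 1

    stub_info = {"qm": [], "junctions": [], "by_site": {}}
    for site, (kind, p) in enumerate(zip(spec.stubs, fe_pos)):
        direction = p - centroid
        st_atoms, qm, ca = _stub_atoms(kind, p, direction, serial)
        atoms.extend(st_atoms)
        serial += len(st_atoms)
        stub_info["qm"].extend(qm)
        stub_info["by_site"][site] = [at.serial for at in st_atoms]
        if ca is not None:
            stub_info["junctions"].append((qm[-1], ca))  # CB -> CA

    structure = Structure(atoms, title="idealised [4Fe4S] cubane")
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.normal(0.0, spec.jitter_sd, size=(len(atoms), 3))
        structure = structure.with_positions(structure.positions() + jitter)
    cluster = ClusterSpec(fe_serials, s_serials)
    return structure, cluster, stub_info


def make_lip_a_fixture(
    seed: int = 0,
    n_env_atoms: int = 99,
    separation: float = 12.0,
) -> FixtureBundle:
    """Miniature two-cluster active-site bundle with environment charges.

    Main cluster (Fe1-Fe4): three thiolate stubs and one water; auxiliary
    cluster (Fe5-Fe8): three thiolates and one serinate; centroids
    ``separation`` apart.  The environment is ``n_env_atoms`` point-charge
    atoms (water-like neutral three-atom groups) scattered on a shell around
    the whole assembly, kept clear of the QM region.  System 2 holds the CA
    atoms and the environment; every stub CA is a junction.
    """
    main_spec = CubaneSpec(stubs=("water", "thiolate", "thiolate", "thiolate"))
    aux_spec = CubaneSpec(
        stubs=("serinate", "thiolate", "thiolate", "thiolate"),
        centroid=(separation, 0.0, 0.0),
    )
    main_struct, main_cluster, main_info = make_cubane(main_spec, seed, serial_start=1)
    aux_struct, aux_cluster, aux_info = make_cubane(
        aux_spec, seed, serial_start=max(main_struct.serials) + 1
    )
    aux_cluster.label_offset = 4

    atoms = list(main_struct.atoms) + list(aux_struct.atoms)
    serial = max(a.serial for a in atoms) + 1

    # neutral water-like charge groups on a shell around the assembly centre
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xE7,)))
    centre = np.array([separation / 2.0, 0.0, 0.0])
    qm_positions = np.array([a.xyz for a in atoms])
    n_groups = n_env_atoms // 3
    placed = 0
    while placed < n_groups:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        radius = rng.uniform(11.0, 15.0)
        o = centre + radius * v
        if np.min(np.linalg.norm(qm_positions - o, axis=1)) < 4.0:
            continue
        h1 = o + rng.normal(0, 0.3, 3) + np.array([0.96, 0, 0])
        h2 = o + rng.normal(0, 0.3, 3) + np.array([-0.24, 0.93, 0])
        atoms.append(Atom("O", tuple(o), -0.8, serial, "ENV"))
        atoms.append(Atom("H", tuple(h1), 0.4, serial + 1, "ENV"))
        atoms.append(Atom("H", tuple(h2), 0.4, serial + 2, "ENV"))
        serial += 3
        placed += 1

    structure = Structure(atoms, title="miniature two-cluster active site")
    core = set(main_cluster.fe_serials + main_cluster.sulfide_serials
               + aux_cluster.fe_serials + aux_cluster.sulfide_serials)
    qm_serials = core | set(main_info["qm"]) | set(aux_info["qm"])
    junctions = main_info["junctions"] + aux_info["junctions"]
    partition = partition_structure(structure, qm_serials, junctions)
    return FixtureBundle(
        structure=structure,
        partition=partition,
        clusters=(main_cluster, aux_cluster),
        notes=(
            f"two idealised cubanes {separation:g} A apart; "
            f"{placed * 3} neutral environment charge atoms; "
            f"{len(junctions)} stub junctions"
        ),
        stub_serials={"main": main_info["by_site"], "aux": aux_info["by_site"]},
    )


# ---------------------------------------------------------------------------
# Packaged transcriptions
# ---------------------------------------------------------------------------


def _read_packaged(name: str) -> str:
    ref = resources.files("spincube.data").joinpath(name)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise FixtureIntegrityError(
            f"{name}: checksum mismatch ({digest[:12]}... != {expected[:12]}...)"
        )
    return data.decode("utf-8")


def _require_notes(df: pd.DataFrame, name: str) -> None:
    notes = df["note"].astype(str).str.strip()
    if (notes == "").any() or notes.isna().any():
        raise FixtureIntegrityError(f"{name}: every packaged number needs a note")


def packaged_tables() -> tuple[BSEnergyTable, dict[str, ReactionProfile]]:
    """The shipped BS energy table and stationary-point profiles.

    Checksums are verified and every row must carry a provenance note.
    Profile keys: ``first_insertion``, ``second_insertion_mech1``,
    ``second_insertion_mech2``, ``rs2_cleavage_unreduced``.
    """
    import io

    text = _read_packaged("table1.tsv")
    df = pd.read_csv(io.StringIO(text), sep="\t")
    _require_notes(df, "table1.tsv")
    table = BSEnergyTable.from_tsv(text)

    profiles: dict[str, ReactionProfile] = {}
    for key in (
        "first_insertion",
        "second_insertion_mech1",
        "second_insertion_mech2",
        "rs2_cleavage_unreduced",
    ):
        name = f"profile_{key}.tsv"
        ptext = _read_packaged(name)
        pdf = pd.read_csv(io.StringIO(ptext), sep="\t")
        _require_notes(pdf, name)
        profiles[key] = ReactionProfile.from_tsv(ptext)
    return table, profiles


def packaged_scalars() -> dict[str, dict]:
    """Reported standalone numbers (with notes) used by the analyses."""
    import io

    text = _read_packaged("reported_scalars.tsv")
    df = pd.read_csv(io.StringIO(text), sep="\t")
    _require_notes(df, "reported_scalars.tsv")
    return {
        str(r.name): {"value": float(r.value), "note": str(r.note)}
        for r in df.itertuples(index=False)
    }
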