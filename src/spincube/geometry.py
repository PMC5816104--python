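"""Atoms, structures, QM/MM partitioning and cluster geometry metrics.

Coordinates are Cartesian angstrom throughout; no unit switching happens in
this module.  Atom ordering is preserved from input, and Fe site labels
(Fe1..Fe8) follow the order given in a :class:`ClusterSpec`, never a spatial
sort.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Junction",
    "Partition",
    "ClusterSpec",
    "DistanceTable",
    "COVALENT_RADII",
    "bonded",
    "discover_junctions",
    "partition_structure",
    "fe_ligand_distances",
    "read_pdb",
    "write_xyz",
    "write_pdb",
]

# Covalent radii in angstrom (Cordero et al. consensus values) for the
# elements that occur in Fe/S cluster active sites and their surroundings.
COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "FE": 1.32,
    "NA": 1.66,
    "MG": 1.41,
    "K": 2.03,
    "ZN": 1.22,
}

#: bond-detection cutoff = (r_cov(a) + r_cov(b)) * BOND_SCALE
BOND_SCALE: float = 1.2


def _radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"unrecognised element symbol: {element!r}") from None


@dataclass(frozen=True)
class Atom:
    """A point atom: element, position (angstrom), partial charge (e), serial."""

    element: str
    position: tuple[float, float, float]
    partial_charge: float = 0.0
    serial: int = 0
    residue_tag: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite triple")
        _radius(self.element)  # validates symbol
        object.__setattr__(self, "position", tuple(float(x) for x in pos))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Structure:
    """An ordered collection of atoms with unique serials."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        self._index = {a.serial: i for i, a in enumerate(self.atoms)}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def serials(self) -> list[int]:
        return [a.serial for a in self.atoms]

    def atom(self, serial: int) -> Atom:
        try:
            return self.atoms[self._index[serial]]
        except KeyError:
            raise KeyError(f"serial {serial} not present in structure") from None

    def positions(self, serials: Sequence[int] | None = None) -> np.ndarray:
        if serials is None:
            return np.array([a.xyz for a in self.atoms])
        return np.array([self.atom(s).xyz for s in serials])

    def with_positions(self, new_positions: np.ndarray) -> "Structure":
        """Copy with all atom positions replaced (same order)."""
        new_positions = np.asarray(new_positions, dtype=float)
        if new_positions.shape != (len(self.atoms), 3):
            raise ValueError("position array shape must be (n_atoms, 3)")
        atoms = [
            Atom(a.element, tuple(p), a.partial_charge, a.serial, a.residue_tag)
            for a, p in zip(self.atoms, new_positions)
        ]
        return Structure(atoms, self.title)

    def with_charges(self, charges: Mapping[int, float]) -> "Structure":
        """Copy with the partial charges of the given serials replaced."""
        atoms = [
            Atom(
                a.element,
                a.position,
                float(charges.get(a.serial, a.partial_charge)),
                a.serial,
                a.residue_tag,
            )
            for a in self.atoms
        ]
        return Structure(atoms, self.title)

    def subset(self, serials: Iterable[int], title: str = "") -> "Structure":
        keep = set(serials)
        atoms = [a for a in self.atoms if a.serial in keep]
        missing = keep - {a.serial for a in atoms}
        if missing:
            raise KeyError(f"serials not in structure: {sorted(missing)}")
        return Structure(atoms, title or self.title)

    def content_hash(self) -> int:
        """Order-sensitive hash of elements, serials, positions and charges."""
        items = tuple(
            (a.element, a.serial, tuple(round(x, 9) for x in a.position),
             round(a.partial_charge, 9))
            for a in self.atoms
        )
        return hash(items)


@dataclass(frozen=True)
class Junction:
    """A covalent bond severed at the QM/MM boundary.

    ``qm_serial`` is the QM-side bonded atom, ``cl_serial`` the environment
    (carbon link, CL) atom it bonds to, and ``scale`` the dimensionless
    link-atom placement factor g in HL = qm + g*(cl - qm).
    """

    qm_serial: int
    cl_serial: int
    scale: float = 0.7219  # C-H / C-C equilibrium ratio, 1.09/1.51

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("junction scale must be in (0, 1]")


@dataclass
class Partition:
    """QM-region (system 1) vs fixed environment (system 2) atom assignment."""

    system1_serials: frozenset[int]
    system2_serials: frozenset[int]
    junctions: list[Junction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.system1_serials = frozenset(self.system1_serials)
        self.system2_serials = frozenset(self.system2_serials)
        if self.system1_serials & self.system2_serials:
            raise ValueError("system 1 and system 2 must be disjoint")
        for j in self.junctions:
            if j.qm_serial not in self.system1_serials:
                raise ValueError(f"junction qm atom {j.qm_serial} not in system 1")
            if j.cl_serial not in self.system2_serials:
                raise ValueError(f"junction cl atom {j.cl_serial} not in system 2")

    @property
    def cl_serials(self) -> frozenset[int]:
        return frozenset(j.cl_serial for j in self.junctions)


@dataclass
class ClusterSpec:
    """Site bookkeeping for one [4Fe4S] cubane.

    Fe site labels are assigned by the order of ``fe_serials`` (Fe1..Fe4 for
    the main cluster, Fe5..Fe8 for the auxiliary one), not by any spatial
    criterion.
    """

    fe_serials: list[int]
    sulfide_serials: list[int]
    oxidation_assignment: list[int] = field(default_factory=lambda: [2, 2, 3, 3])
    total_charge: int | None = None
    label_offset: int = 0  # 0 -> Fe1..Fe4, 4 -> Fe5..Fe8

    def __post_init__(self) -> None:
        if len(self.fe_serials) != 4:
            raise ValueError("a cubane has exactly 4 Fe sites")
        if len(self.sulfide_serials) != 4:
            raise ValueError("a cubane has exactly 4 inorganic sulfides")
        if any(q not in (2, 3) for q in self.oxidation_assignment):
            raise ValueError("formal Fe charges must be +2 or +3")
        # core charge: sum(Fe) + 4 * (-2)
        core = sum(self.oxidation_assignment) - 8
        if self.total_charge is None:
            self.total_charge = core
        elif self.total_charge != core:
            raise ValueError(
                f"total_charge {self.total_charge} inconsistent with oxidation "
                f"assignment (expected {core})"
            )

    def fe_labels(self) -> list[str]:
        return [f"Fe{self.label_offset + i + 1}" for i in range(4)]


@dataclass
class DistanceTable:
    """Rows of (Fe site label, ligand atom label, distance in angstrom)."""

    rows: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for site, lig, d in self.rows:
            if not d > 0:
                raise ValueError(f"non-positive distance for {site}-{lig}")

    def to_tsv(self) -> str:
        out = ["fe_site\tligand\tdistance_A"]
        out += [f"{s}\t{l}\t{d:.4f}" for s, l, d in self.rows]
        return "\n".join(out) + "\n"

    def distances(self) -> list[float]:
        return [d for _, _, d in self.rows]


def bonded(a: Atom, b: Atom, scale: float = BOND_SCALE) -> bool:
    """Distance-cutoff bond test: r < (r_cov(a)+r_cov(b)) * scale."""
    cut = (_radius(a.element) + _radius(b.element)) * scale
    return float(np.linalg.norm(a.xyz - b.xyz)) < cut


def discover_junctions(
    structure: Structure,
    qm_serials: Iterable[int],
    scale_factor: float | None = None,
) -> list[tuple[int, int]]:
    """Find (qm_serial, cl_serial) pairs of covalent bonds crossing the boundary.

    Bonds are detected with the covalent-radius-sum cutoff; this is how the
    boundary between a cluster's ligand stubs and the environment is located
    when no explicit junction list is given.
    """
    qm = set(qm_serials)
    pairs: list[tuple[int, int]] = []
    qm_atoms = [a for a in structure if a.serial in qm]
    mm_atoms = [a for a in structure if a.serial not in qm]
    for a in qm_atoms:
        for b in mm_atoms:
            if bonded(a, b):
                pairs.append((a.serial, b.serial))
    return sorted(pairs)


def partition_structure(
    structure: Structure,
    qm_serials: Iterable[int],
    junction_spec: Sequence[tuple[int, int] | tuple[int, int, float] | Junction]
    | str
    | None = None,
) -> Partition:
    """Split a structure into QM region (system 1) and environment (system 2).

    Parameters
    ----------
    structure : Structure
    qm_serials : iterable of int
        Serials of the QM region; must be non-empty and present.
    junction_spec : sequence, "auto", or None
        Declared boundary bonds as ``(qm_serial, cl_serial)`` or
        ``(qm_serial, cl_serial, scale)`` tuples (or ready Junction objects);
        ``"auto"`` discovers them with the covalent-radius bond cutoff; None
        means no junctions.

    Raises
    ------
    KeyError
        A serial is not in the structure.
    ValueError
        Empty QM set, or a declared junction whose endpoints do not bridge the
        two subsystems.
    """
    qm = set(qm_serials)
    if not qm:
        raise ValueError("QM region must be non-empty")
    all_serials = set(structure.serials)
    missing = qm - all_serials
    if missing:
        raise KeyError(f"QM serials not in structure: {sorted(missing)}")
    mm = all_serials - qm

    if junction_spec == "auto":
        junction_spec = discover_junctions(structure, qm)
    junctions: list[Junction] = []
    for spec in junction_spec or []:
        if isinstance(spec, Junction):
            j = spec
        elif len(spec) == 2:
            j = Junction(int(spec[0]), int(spec[1]))
        else:
            j = Junction(int(spec[0]), int(spec[1]), float(spec[2]))
        for s in (j.qm_serial, j.cl_serial):
            if s not in all_serials:
                raise KeyError(f"junction serial {s} not in structure")
        if j.qm_serial not in qm or j.cl_serial not in mm:
            raise ValueError(
                f"junction ({j.qm_serial}, {j.cl_serial}) does not bridge "
                "system 1 and system 2"
            )
        junctions.append(j)
    return Partition(frozenset(qm), frozenset(mm), junctions)


def fe_ligand_distances(
    structure: Structure,
    cluster: ClusterSpec,
    ligand_serials: Iterable[int],
    cutoff: float = 3.0,
) -> DistanceTable:
    """Euclidean Fe-ligand distances, one row per pair within ``cutoff``.

    Ligand atom labels are ``<element><serial>``.  Coincident atoms (distance
    exactly 0) indicate corrupt geometry and raise.
    """
    ligands = list(ligand_serials)
    if not ligands:
        raise ValueError("ligand set must be non-empty")
    rows: list[tuple[str, str, float]] = []
    for label, fe_serial in zip(cluster.fe_labels(), cluster.fe_serials):
        fe = structure.atom(fe_serial)
        for ls in ligands:
            if ls == fe_serial:
                continue
            lig = structure.atom(ls)
            d = float(np.linalg.norm(fe.xyz - lig.xyz))
            if d == 0.0:
                raise ValueError(
                    f"coincident atoms: {fe_serial} and {ls} share a position"
                )
            if d <= cutoff:
                rows.append((label, f"{lig.element}{lig.serial}", d))
    return DistanceTable(rows)


# ---------------------------------------------------------------------------
# File I/O: PDB in (via gemmi), XYZ / PDB out
# ---------------------------------------------------------------------------

def read_pdb(path_or_text: str, charges: Mapping[int, float] | None = None) -> Structure:
    """Read a PDB file (ATOM and HETATM records, e.g. SF4 clusters).

    Alternate locations: for each (residue, atom-name) group the conformer
    with the highest occupancy is kept; ties keep the first.  PDB files carry
    no partial charges; pass ``charges`` (serial -> e) to set them.
    """
    import gemmi

    if "\n" in path_or_text:
        st = gemmi.read_pdb_string(path_or_text)
    else:
        st = gemmi.read_pdb(path_or_text)
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            best: dict[str, "gemmi.Atom"] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in residue:  # preserve file order among the kept ones
                if best.get(at.name) is not at:
                    continue
                el = at.element.name
                q = 0.0 if charges is None else float(charges.get(at.serial, 0.0))
                atoms.append(
                    Atom(
                        el,
                        (at.pos.x, at.pos.y, at.pos.z),
                        q,
                        at.serial,
                        residue.name,
                    )
                )
    return Structure(atoms, title=st.name or "pdb")


def write_xyz(structure: Structure, path: str | None = None) -> str:
    """Serialise to XYZ text; writes to ``path`` when given."""
    buf = io.StringIO()
    buf.write(f"{len(structure)}\n{structure.title}\n")
    for a in structure:
        x, y, z = a.position
        el = a.element.capitalize()
        buf.write(f"{el:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_pdb(structure: Structure, path: str | None = None) -> str:
    """Serialise to PDB text (HETATM records), via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.title or "spincube"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, a in enumerate(structure):
        res = gemmi.Residue()
        res.name = (a.residue_tag or "UNK")[:3]
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H"
        at = gemmi.Atom()
        at.name = a.element.capitalize()
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.serial = a.serial
        at.occ = 1.0
        res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
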