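"""Broken-symmetry (BS) spin-state enumeration and energy-table analysis.

A BS state of a [4Fe4S] cluster assigns each high-spin Fe site a surplus of
spin up (+1) or down (-1); the antiferromagnetic singlet states have two of
each, which can be chosen in C(4,2) = 6 ways per cluster.  States are written
as arrow strings, e.g. ``[↑↑↓↓ ↓↑↑↓]`` for two clusters in the site order
Fe1..Fe8 with a space between clusters.

Two generation routes are provided, mirroring common practice for preparing
BS determinants: the fragment method (assign whole ferromagnetic fragments a
common orientation) and site swapping (permute site orientations within one
cluster).  Both are closed within the plain enumeration.

Energy tables of BS states (relative energies in kJ/mol, possibly with
missing entries for states that could not be converged) are analysed per
"family": the set of states sharing a fixed spin pattern on one cluster while
the other cluster's pattern varies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UP",
    "DOWN",
    "MISSING",
    "BSState",
    "SiteSpins",
    "BSEnergyTable",
    "FamilyStats",
    "parse_label",
    "format_label",
    "enumerate_bs_states",
    "enumerate_two_cluster_singlets",
    "count_unpaired_spins",
    "bs_from_fragments",
    "bs_by_site_swap",
    "analyze_family",
    "estimate_missing_state",
    "spin_population_summary",
    "round_half_up",
]

UP = "↑"  # ↑
DOWN = "↓"  # ↓

#: sentinel for a table cell whose state could not be converged
MISSING = None


@dataclass(frozen=True)
class BSState:
    """A signed spin-orientation assignment over 4 or 8 Fe sites."""

    orientations: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.orientations:
            raise ValueError("a BS state needs at least one site")
        if any(o not in (-1, 1) for o in self.orientations):
            raise ValueError("orientations must be +1 or -1")

    @property
    def label(self) -> str:
        return format_label(self)

    @property
    def n_sites(self) -> int:
        return len(self.orientations)

    def clusters(self) -> list[tuple[int, ...]]:
        """Per-cluster orientation tuples (groups of four for 8 sites)."""
        o = self.orientations
        if len(o) == 8:
            return [o[:4], o[4:]]
        return [o]

    def flipped(self) -> "BSState":
        return BSState(tuple(-o for o in self.orientations))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BSState({self.label!r})"


@dataclass(frozen=True)
class SiteSpins:
    """Per-site spin magnitudes as unpaired-electron counts.

    High-spin Fe(II) has 4 unpaired electrons, Fe(III) 5; a delocalised
    mixed-valence Fe(2.5+) pair is represented as 4.5 per site.
    """

    magnitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not m > 0 for m in self.magnitudes):
            raise ValueError("site spin magnitudes must be positive")

    @classmethod
    def uniform(cls, m: float, n_sites: int) -> "SiteSpins":
        return cls((float(m),) * n_sites)

    def __len__(self) -> int:
        return len(self.magnitudes)


def _parse_arrows(text: str) -> tuple[int, ...]:
    arrows = []
    for ch in text:
        if ch == UP:
            arrows.append(1)
        elif ch == DOWN:
            arrows.append(-1)
        elif ch in "[] \t":
            continue
        else:
            raise ValueError(f"unexpected character {ch!r} in spin label")
    return tuple(arrows)


def parse_label(text: str) -> BSState:
    """Parse an arrow string like ``[↑↑↓↓ ↓↑↑↓]`` into a BSState.

    Brackets are optional; a label must resolve to exactly 4 or 8 arrows.
    """
    arrows = _parse_arrows(text)
    if len(arrows) not in (4, 8):
        raise ValueError(
            f"spin label must have 4 or 8 arrows, got {len(arrows)}: {text!r}"
        )
    return BSState(arrows)


def format_label(state: BSState) -> str:
    """Format as a bracketed arrow string, space-separated between clusters."""
    parts = [
        "".join(UP if o == 1 else DOWN for o in cl) for cl in state.clusters()
    ]
    return "[" + " ".join(parts) + "]"


def enumerate_bs_states(n_sites: int, n_up: int) -> list[BSState]:
    """All distinct assignments of exactly ``n_up`` up-sites, lexicographic.

    Lexicographic order treats +1 (up) < -1 (down) reading left to right, so
    the all-up pattern comes first.  The count is C(n_sites, n_up).
    """
    if n_sites < 0 or n_up < 0:
        raise ValueError("counts must be non-negative")
    if n_up > n_sites:
        raise ValueError("n_up cannot exceed n_sites")
    if n_sites == 0:
        raise ValueError("need at least one site")
    states = []
    from itertools import combinations

    for ups in combinations(range(n_sites), n_up):
        o = tuple(1 if i in ups else -1 for i in range(n_sites))
        states.append(BSState(o))
    return states


def enumerate_two_cluster_singlets() -> list[BSState]:
    """The 36 = 6 x 6 combined states with both clusters spin-balanced."""
    singles = enumerate_bs_states(4, 2)
    return [
        BSState(a.orientations + b.orientations)
        for a in singles
        for b in singles
    ]


def count_unpaired_spins(oxidation_assignments: Sequence[int | Sequence[int]]) -> int:
    """Total unpaired electrons for high-spin Fe sites.

    Accepts a flat list of formal charges (+2 or +3) or a list of per-cluster
    lists.  Each Fe(II) contributes 4 unpaired spins and each Fe(III) 5; two
    clusters of [2Fe(II) 2Fe(III)] give 2 x 2 x (4 + 5) = 36.
    """
    flat: list[int] = []
    for item in oxidation_assignments:
        if isinstance(item, (list, tuple)):
            flat.extend(int(q) for q in item)
        else:
            flat.append(int(item))
    total = 0
    for q in flat:
        if q == 2:
            total += 4
        elif q == 3:
            total += 5
        else:
            raise ValueError(f"unsupported formal Fe charge: {q:+d}")
    return total


def bs_from_fragments(
    fragment_assignment: Mapping[int, object],
    fragment_spins: Mapping[object, int],
) -> BSState:
    """Build a BS state by giving whole fragments a common orientation.

    ``fragment_assignment`` maps site index (0-based) to a fragment key;
    every site of a cluster must be assigned, and every referenced fragment
    must have a spin of +1 or -1.
    """
    n = len(fragment_assignment)
    if sorted(fragment_assignment) != list(range(n)):
        raise ValueError("fragment assignment must cover sites 0..n-1 exactly")
    orientations = []
    for site in range(n):
        frag = fragment_assignment[site]
        try:
            s = fragment_spins[frag]
        except KeyError:
            raise ValueError(f"no spin given for fragment {frag!r}") from None
        if s not in (-1, 1):
            raise ValueError("fragment spins must be +1 or -1")
        orientations.append(s)
    return BSState(tuple(orientations))


def bs_by_site_swap(state: BSState, permutation: Sequence[int]) -> BSState:
    """Permute site orientations; the permutation must act within one cluster.

    ``permutation`` is a full-length site permutation (``new[i] =
    old[permutation[i]]``).  For 8-site states any mapping that mixes the
    first and last four sites raises.
    """
    n = state.n_sites
    if sorted(permutation) != list(range(n)):
        raise ValueError("not a permutation of the site indices")
    if n == 8:
        for i, p in enumerate(permutation):
            if (i < 4) != (p < 4):
                raise ValueError("permutation must not mix the two clusters")
    return BSState(tuple(state.orientations[p] for p in permutation))


# ---------------------------------------------------------------------------
# Energy tables and family statistics
# ---------------------------------------------------------------------------

FAMILIES = ("main_fixed", "aux_fixed")
COLUMNS = ("resting", "reactive")


@dataclass
class BSEnergyTable:
    """Rows of (label, family tag, column tag, relative energy kJ/mol or missing)."""

    rows: list[tuple[str, str, str, float | None]]

    def __post_init__(self) -> None:
        seen = set()
        for label, family, column, energy in self.rows:
            parse_label(label)  # must be parseable
            key = (label, column)
            if key in seen:
                raise ValueError(f"duplicate row for {key}")
            seen.add(key)
            if energy is not None and not math.isfinite(energy):
                raise ValueError(f"non-finite energy for {key}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["label", "family", "column", "energy_kJmol"]
        )

    def to_tsv(self, path: str | None = None) -> str:
        df = self.to_frame()
        text = df.to_csv(sep="\t", index=False, na_rep="NA")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, path_or_text: str) -> "BSEnergyTable":
        import io

        src = io.StringIO(path_or_text) if "\n" in path_or_text else path_or_text
        df = pd.read_csv(src, sep="\t", comment="#")
        rows = [
            (
                str(r.label),
                str(r.family),
                str(r.column),
                None if pd.isna(r.energy_kJmol) else float(r.energy_kJmol),
            )
            for r in df.itertuples()
        ]
        return cls(rows)

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for label, *_ in self.rows:
            seen.setdefault(label)
        return list(seen)


@dataclass(frozen=True)
class FamilyStats:
    """Summary statistics of one state family in a BS energy table."""

    spread: float
    min_state: str
    min_energy: float
    gap_to_second: float
    n_within: int
    n_states: int
    tied: bool = False


def round_half_up(x: float) -> int:
    """Round with halves away from zero (39.5 -> 40), as in prose reporting."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _fixed_pattern(table: BSEnergyTable, family: str) -> tuple[tuple[int, ...], slice]:
    """The arrow pattern a family keeps fixed, and which half it occupies.

    ``main_fixed`` rows share their first-cluster pattern (the main cluster is
    held fixed while the auxiliary one varies); ``aux_fixed`` rows share their
    second-cluster pattern.  The pattern is read off the rows tagged with the
    family, which must agree.
    """
    half = slice(0, 4) if family == "main_fixed" else slice(4, 8)
    patterns = {
        parse_label(label).orientations[half]
        for label, fam, _, _ in table.rows
        if fam == family
    }
    if not patterns:
        raise ValueError(f"no rows tagged with family {family!r}")
    if len(patterns) > 1:
        raise ValueError(f"rows of family {family!r} disagree on the fixed pattern")
    return patterns.pop(), half


def analyze_family(
    table: BSEnergyTable,
    family: str | None,
    column: str,
    tol: float = 2.0,
) -> FamilyStats:
    """Spread, ground state and gap statistics for one family of BS states.

    A family is selected by pattern matching on the label, not by the block a
    row was tagged with: a row whose fixed-cluster half equals the family's
    fixed pattern belongs to the family even if it was entered in the other
    block (the table's shared row counts for both families).  ``family=None``
    pools every non-missing entry in the column.

    Returns max-min spread, the minimum-energy state (ties broken
    lexicographically on the label and reported via ``tied``), the gap from
    the minimum to the second-lowest energy, and the number of states within
    ``tol`` (inclusive) of the minimum.  Missing entries are excluded from
    every statistic.
    """
    if family is None:
        entries = [
            (label, e) for label, _, col, e in table.rows
            if col == column and e is not None
        ]
    else:
        pattern, half = _fixed_pattern(table, family)
        entries = [
            (label, e)
            for label, _, col, e in table.rows
            if col == column
            and e is not None
            and parse_label(label).orientations[half] == pattern
        ]
    if not entries:
        raise ValueError("family has no non-missing entries in this column")
    if len(entries) < 2:
        label, e = entries[0]
        return FamilyStats(0.0, label, e, 0.0, 1, 1)
    energies = np.array([e for _, e in entries])
    emin = float(energies.min())
    emax = float(energies.max())
    at_min = sorted(label for label, e in entries if e == emin)
    second = float(np.sort(energies)[1])
    n_within = int(np.sum(energies <= emin + tol))
    return FamilyStats(
        spread=emax - emin,
        min_state=at_min[0],
        min_energy=emin,
        gap_to_second=second - emin,
        n_within=n_within,
        n_states=len(entries),
        tied=len(at_min) > 1,
    )


def estimate_missing_state(e_reference: float, delta_aux: float) -> float:
    """Additive transfer estimate for an unconverged state's energy.

    Assumes the main-cluster and auxiliary-cluster spin energies add: the
    missing state sits ``delta_aux`` below a reference state that differs
    only in the auxiliary-cluster pattern, so the estimate is
    ``e_reference - delta_aux``.
    """
    if not (math.isfinite(e_reference) and math.isfinite(delta_aux)):
        raise ValueError("inputs must be finite")
    return e_reference - delta_aux


def spin_population_summary(
    populations: Iterable[float],
    low_magnitude_tol: float = 0.1,
) -> list[tuple[int, float, bool]]:
    """Classify per-site spin populations into (sign, magnitude, low flag).

    The sign (+1/-1, or 0 for an exactly vanishing population, which is
    treated as unassigned) recovers the BS orientation of each Fe site; a
    site is flagged low when its magnitude falls below the family median
    magnitude minus ``low_magnitude_tol`` — the signature of an Fe ion whose
    spin density is reduced relative to its peers (or of a zero population).
    """
    values = [float(v) for v in populations]
    if not values:
        raise ValueError("no spin populations given")
    mags = np.abs(values)
    median = float(np.median(mags))
    out = []
    for v in values:
        sign = 0 if v == 0.0 else (1 if v > 0 else -1)
        low = sign == 0 or abs(v) < median - low_magnitude_tol
        out.append((sign, abs(v), low))
    return out
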