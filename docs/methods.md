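# Methods

## Scope and design

spincube implements the computational scaffolding of a broken-symmetry
QM/MM study of a two-cubane iron–sulfur active site at desk scale. The
quantum-chemistry engine is deliberately out of scope: every operation that
would call a DFT or force-field program goes through a pluggable engine
contract — a deterministic callable `(structure, point charges | None,
BS state | None, level label) → (energy, gradients, spin populations)` with
energies in hartree. Level labels such as `"TPSS/def2-SV(P)"` are opaque
tags; nothing electronic is computed from them. The shipped toy engines
(harmonic bonds + Coulomb, optionally + Ising exchange) make the whole
pipeline executable and testable, but results obtained with them
characterise the *machinery*, not the chemistry of any real enzyme.

## Broken-symmetry states and table analysis

A BS state is a ±1 orientation vector over Fe sites; labels are arrow
strings in fixed site order (Fe1–Fe4, then Fe5–Fe8 for two clusters,
space-separated). Site labels always follow the declared cluster order,
never a spatial sort, so renumbering only permutes labels.

Family statistics (`analyze_family`) select rows by *pattern matching on
the label*, not by which table block a row was entered in: the family that
holds the main cluster fixed contains every row whose first-cluster arrows
equal the family's fixed pattern. This matters for the shared row whose
main half matches the main-fixed pattern and whose auxiliary half matches
the aux-fixed pattern — it belongs to both families, and both family
spreads are wrong without it. Missing entries (states whose SCF/geometry
could not be converged) are first-class (`NA` in TSV) and excluded from
every statistic. Ties for the minimum are broken lexicographically on the
label and reported explicitly. Prose-style integer reporting uses half-up
rounding (39.5 → 40).

The additive missing-state estimate assumes main-cluster and
auxiliary-cluster spin-flip energies add: `E(missing) ≈ E(reference) −
ΔE(aux)`. With the packaged inputs this gives 8.9 kJ/mol where the original
analysis reported "roughly 8"; the gap presumably reflects unrounded
internal values, and the two are not forced to agree.

## Link atoms and the point-charge model

The hydrogen link atom sits at `qm + g·(cl − qm)`. The placement factor g
defaults to 0.722 ≈ 1.09/1.51, the ratio of equilibrium C–H to C–C bond
lengths, and is configurable per junction — the linear relation is
standard, but no universal factor exists. The point-charge model contains
one entry per environment atom *except* the CL atoms, whose charge is
dropped outright and **not** redistributed; the model total is therefore
generally non-integral, which is documented behaviour, not an error.
Charge-smearing schemes beyond bare CL exclusion are intentionally not
implemented.

## Energy assembly

The subtractive total is `E_QM1+ptch2^HL + E_MM12,q1=0^CL − E_MM1,q1=0^HL`.
Conventions: "q₁ = 0" is realised by zeroing the partial charges of QM
atoms in the structure handed to the MM engine (atoms are never deleted);
the third term additionally has *all* charges zeroed (no electrostatics).
The exclusion of the point-charge self-energy from the QM term is an
obligation on the engine contract, honoured by the toy engines and asserted
in tests. The MM term follows the assembly literally (full classical energy
of all atoms with q₁ = 0), including any bonded terms spanning the
junction; with identical engines those cancel against the third term. With
identical QM/MM engines and a faithful embedding Coulomb, the assembly
reproduces the plain full-system energy to ≤ 10⁻¹² hartree on random
junction-free fixtures, and on junction-bearing fixtures when charges
vanish — the central cancellation property.

Internal unit is the hartree; reported energies are kJ/mol with
1 hartree = 2625.4996 kJ/mol (so the 10⁻⁶ a.u. convergence threshold is
~2.6 J/mol). Engine calls are memoised on (structure hash, charge-model
hash, state, level) so profile assembly never re-evaluates a point.

## Ising stand-in and coupling recovery

BS determinants are collinear, so the Heisenberg Hamiltonian is evaluated
in the Ising form `E = E₀ + Σ J_ij m_i m_j σ_i σ_j` (positive J favours
anti-alignment); no spin projection is applied, matching the raw-BS-energy
convention. Site magnitudes default to 4.5/2 unpaired-spin equivalents per
mixed-valence site. The `two_J` model fixes the ferromagnetic pair
partition from the fragment assignment used to build the states
(default pairs (Fe1,Fe2)/(Fe3,Fe4)).

Coupling recovery is linear least squares on the pair-product design
matrix. A mathematical caveat discovered during design: over the six
2-up/2-down singlet states the intra-pair and inter-pair sign sums obey
`x_intra + x_inter = −2m²` identically, so the (x_intra, x_inter, 1) design
has rank 2 and the three `two_J` parameters are **not** identifiable from
singlets alone. The fit therefore reports the design rank and the
identifiable combinations (right singular vectors), returns the
minimum-norm solution (which still reproduces every table energy when the
system is consistent), and exact recovery is demonstrated on state sets
extended with the all-up and one 3-up determinant, which restore full rank.
Synthetic-table noise is i.i.d. Gaussian per state with a named generator
stream per table, so a seed fully determines a table. Fits to measured
tables are exploratory diagnostics only and are flagged as such in CLI
output.

## Scans and profiles

The constrained scan enforces a single fixed interatomic distance with an
SLSQP equality constraint and checks convergence on the *projected*
gradient (component along the constraint removed), stopping only when the
energy change < 10⁻⁶ a.u. and the maximum per-atom projected gradient norm
< 10⁻³ a.u. hold simultaneously; non-convergence raises with the last
gradient norm. Environment atoms and explicitly frozen serials never move.
Gradients on hydrogen link atoms are not back-projected onto their QM/CL
parents — with a fixed environment the junction geometry is effectively
frozen, and the validation scans are junction-free.

Profiles are gauge-fixed by subtracting the declared reference energy.
Barrier = max intervening energy − E(from) (never negative); exothermicity
= E(from) − E(to). Mechanism comparison reports (Δbarrier, Δproduct) with
positive values meaning the first mechanism is higher/less stable. The
packaged stationary-point fixtures encode only numbers printed as text in
the source analysis; transition-state rows are explicit points constructed
as reference + barrier, with a note on each row saying so. Two reported
numbers disagree between that analysis' results (34 kJ/mol for the
S3-attack barrier) and its concluding summary (30 kJ/mol); both are
packaged with notes and neither is forced. The two half-reactions are kept
as separate profiles, each with its own reference.

## Synthetic geometry generator

The ideal cubane is realised as two concentric dual tetrahedra (Fe and S on
alternating cube vertices) scaled so all 12 Fe–S contacts equal the target
distance (default 2.30 Å, the centre of the 2.24–2.43 Å range seen in
refined structures); Gaussian jitter emulates the real distortion. Ligand
stubs grow radially: thiolate (S–CB–CA), serinate (O–CB–CA), water (no
junction). The miniature active-site bundle places two cubanes 12 Å apart —
main: 3 thiolates + water; auxiliary: 3 thiolates + serinate — with ~100
environment atoms in neutral water-like charge groups on an 11–15 Å shell
(kept ≥ 4 Å from the QM region), and junctions at every stub CA. What this
emulates: the layout, bookkeeping and electrostatic plumbing of a
two-cluster QM/MM setup. What it does not: a ~15,000-atom solvated protein,
real charge distributions, or DFT-quality geometries — so passing tests
demonstrate correct machinery, not chemical accuracy on real systems.
Partial charges are synthetic round numbers chosen so groups are neutral
and totals are controlled. Coincident atoms anywhere raise (corrupt
geometry) rather than returning zero distances. Bond detection for junction
discovery and the toy force field uses a covalent-radius-sum × 1.2 cutoff.

## Problem sizes and numerical choices

Validation runs use deliberately small problems: 4–10-atom random
structures (100 fixtures) for the cancellation property, 6–16-state
synthetic tables with 200 noise seeds for recovery-error decay, a 34-point
0.02 Å scan grid for the saddle check (the quartic's curvature makes the
grid-discretisation error ~0.2 %, well inside the 2 % check), and
~140-atom active-site bundles. PDB alternate locations keep the highest
occupancy (first on tie); occupancies and charges otherwise pass through
untouched. All randomness flows from a single integer seed through named
generator streams.

## Known limitations

- No transition-state optimisation, no spin projection, no charge
  redistribution at junctions, no protonation assignment, no force-field
  typing.
- The Ising engine is a stand-in: exchange couplings fitted to any real
  table carry no claim about the underlying electronic structure.
- The scan driver handles a single distance constraint; multiple
  simultaneous constraints are out of scope.
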