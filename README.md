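# spincube

Broken-symmetry spin-state analysis and subtractive QM/MM energy assembly
for enzymes with [4Fe4S] cubane clusters, built around the lipoyl-synthase
(LipA) two-cluster active site: a main cluster that binds and cleaves
S-adenosylmethionine and an auxiliary cluster that donates the inserted
sulfur atoms.

Who this is for: computational (bio)inorganic chemists who run
broken-symmetry DFT and QM/MM studies of iron–sulfur enzymes and want the
*bookkeeping* layer — spin-state enumeration, link-atom and point-charge
construction, energy assembly and extrapolation, profile statistics — as
tested, scriptable code, decoupled from any particular quantum-chemistry
engine. The electronic structure itself stays behind a pluggable engine
contract; a toy Ising/force-field engine ships with the package so every
stage runs end to end without external software or data.

## The models

**Broken-symmetry states.** A [4Fe4S]²⁺ cluster holds two high-spin Fe²⁺
(4 unpaired electrons) and two Fe³⁺ (5), i.e. 18 unpaired spins per cluster
and 4 × (4 + 5) = 36 for two. The antiferromagnetic singlet is approximated
by collinear determinants assigning each Fe site spin up or down, two of
each per cluster: C(4,2) = 6 states per cluster, 36 for two clusters,
written as arrow strings like `[↑↑↓↓ ↓↑↑↓]` in site order Fe1…Fe8.
Enumeration, the fragment method, site swapping, label parsing, and the
family statistics (spread, ground state, gap, states-within-tolerance) over
energy tables of such states are all implemented, with missing (unconverged)
entries as first-class values.

**Subtractive electrostatic-embedding QM/MM.** With the QM region capped by
hydrogen link atoms HL (placed at `qm + g·(cl − qm)` along each severed
bond) and the environment represented by point charges (one per atom,
carbon-link CL atoms excluded),

```
E_QM/MM = E_QM1+ptch2^HL + E_MM12,q1=0^CL − E_MM1,q1=0^HL
```

so truncation artifacts cancel between the two classical terms. The
single-level energy is extrapolated to a better functional/basis assuming
additive corrections:

```
E_tot = E_QM/MM^SV(P) + E_TPSS^TZVP + E_B3LYP^SV(P) − 2·E_TPSS^SV(P)
```

**Ising stand-in engine.** On collinear BS determinants a Heisenberg
exchange Hamiltonian reduces to `E = E₀ + Σ_{i<j} J_ij m_i m_j σ_i σ_j`;
the `two_J` variant (ferromagnetic J within two mixed-valence pairs,
antiferromagnetic J across) reproduces the standard physical picture of two
S = 9/2 subclusters coupling to a singlet. The package generates synthetic
BS tables from known couplings (optionally noisy) and recovers couplings by
least squares with full rank diagnostics.

**Reaction profiles and scans.** Stationary-point profiles (RS/TS/IM/PS)
with barrier = highest intervening energy above the segment start,
exothermicity = E(from) − E(to), mechanism comparison, and a
constrained-distance scan driver (SLSQP with the gradient projected off the
constraint; converged when the energy change < 10⁻⁶ a.u. *and* the maximum
gradient norm < 10⁻³ a.u.).

## Worked example

The packaged BS energy table transcribes the relative energies (kJ/mol) of
eleven two-cluster spin states in the resting and reactive states. Pooling
all reactive entries:

```
$ spincube analyze --table src/spincube/data/table1.tsv --column reactive
{
  "family": "pooled",
  "column": "reactive",
  "n_states": 10,
  "spread_kJmol": 46.5,
  "min_state": "↑↑↓↓ ↓↑↑↓",
  "min_energy_kJmol": -9.1,
  "gap_to_second_kJmol": 7.0,
  "n_within_tol": 1,
  "tied": false
}
```

The ground state is `[↑↑↓↓ ↓↑↑↓]` at −9.1 kJ/mol, 7.0 kJ/mol below every
other converged state — the "reactive spin state" used for the mechanism.
On the second-insertion profile, the hydrogen-abstraction step reads:

```
$ spincube profile-stats --profile src/spincube/data/profile_second_insertion_mech1.tsv \
      --from IM1_2 --to IM2_2
barrier_kJmol 71
exothermicity_kJmol 24
```

i.e. a 71 kJ/mol barrier to abstract H8 and a C8-radical intermediate
24 kJ/mol below IM1₂. The same calls are available from Python
(`spincube.analyze_family`, `spincube.barrier`, …).

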