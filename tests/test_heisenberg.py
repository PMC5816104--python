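import itertools

import numpy as np
import pytest

from spincube.geometry import Atom, Structure
from spincube.heisenberg import (
    HeisenbergParams,
    SyntheticTableSpec,
    fit_couplings,
    generate_bs_table,
    ising_energy,
    toy_mm_engine,
    toy_spin_engine,
)
from spincube.linkatoms import PointChargeModel
from spincube.spinstates import BSState, SiteSpins, enumerate_bs_states, parse_label

SPINS4 = SiteSpins.uniform(2.25, 4)  # mixed-valence 4.5 unpaired / 2 per site
TWO_J = HeisenbergParams(model="two_J", j_intra=-35.0, j_inter=22.0, offset=3.0)


def full_rank_states() -> list[BSState]:
    """Singlets plus high-spin and broken-count states: full-rank two_J design."""
    return (
        enumerate_bs_states(4, 2)
        + [BSState((1, 1, 1, 1))]
        + enumerate_bs_states(4, 3)
    )


class TestIsingEnergy:
    def test_zero_couplings_return_offset(self):
        p = HeisenbergParams(model="two_J", j_intra=0.0, j_inter=0.0, offset=7.5)
        for s in enumerate_bs_states(4, 2):
            assert ising_energy(s, p, SPINS4) == pytest.approx(7.5)

    def test_uniform_coupling_on_singlet_states(self):
        # 2 aligned and 4 anti-aligned pairs in any 2-up/2-down state
        J, m = 5.0, 2.0
        p = HeisenbergParams(model="two_J", j_intra=J, j_inter=J, offset=1.0)
        spins = SiteSpins.uniform(m, 4)
        for s in enumerate_bs_states(4, 2):
            assert ising_energy(s, p, spins) == pytest.approx(1.0 + J * m * m * (2 - 4))

    def test_pair_aligned_states_are_lowest_for_afm_inter(self):
        # ferromagnetic pairs (J_intra < 0), antiferromagnetic across (J_inter > 0):
        # brute force over the six singlets finds the pair-aligned states lowest
        energies = {
            s.label: ising_energy(s, TWO_J, SPINS4) for s in enumerate_bs_states(4, 2)
        }
        lowest = sorted(energies, key=energies.get)[:2]
        assert set(lowest) == {"[↑↑↓↓]", "[↓↓↑↑]"}

    def test_global_spin_flip_symmetry(self):
        rng = np.random.default_rng(1)
        couplings = {
            (i, j): float(rng.normal(0, 10))
            for i, j in itertools.combinations(range(4), 2)
        }
        p = HeisenbergParams(model="full_6J", couplings=couplings, offset=-2.0)
        for n_up in range(5):
            for s in enumerate_bs_states(4, n_up):
                assert ising_energy(s, p, SPINS4) == pytest.approx(
                    ising_energy(s.flipped(), p, SPINS4), abs=1e-12
                )

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            ising_energy(parse_label("↑↑↓↓"), TWO_J, SiteSpins.uniform(2.0, 8))


class TestGenerateTable:
    def test_noiseless_table_equals_model(self):
        spec = SyntheticTableSpec(TWO_J, SPINS4, enumerate_bs_states(4, 2))
        table = generate_bs_table(spec)
        for (label, _, _, e), s in zip(table.rows, spec.states):
            assert e == pytest.approx(ising_energy(s, TWO_J, SPINS4), abs=1e-12)

    def test_same_seed_reproduces_table(self):
        spec = dict(
            params=TWO_J, site_spins=SPINS4, states=enumerate_bs_states(4, 2),
            noise_sd=1.5, seed=42,
        )
        t1 = generate_bs_table(SyntheticTableSpec(**spec))
        t2 = generate_bs_table(SyntheticTableSpec(**spec))
        assert t1.rows == t2.rows

    def test_noise_sd_within_chi_square_bounds(self):
        # n=6 draws of N(0,1): sample sd within [0.2, 2.5] with huge margin
        singlets = enumerate_bs_states(4, 2)
        clean = generate_bs_table(SyntheticTableSpec(TWO_J, SPINS4, singlets))
        for seed in range(5):
            noisy = generate_bs_table(
                SyntheticTableSpec(TWO_J, SPINS4, singlets, noise_sd=1.0, seed=seed)
            )
            diff = np.array(
                [a[3] - b[3] for a, b in zip(noisy.rows, clean.rows)]
            )
            assert 0.2 <= np.std(diff, ddof=1) <= 2.5

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTableSpec(TWO_J, SPINS4, enumerate_bs_states(4, 2), noise_sd=-1)

    def test_afm_ground_state_is_pair_aligned_singlet(self):
        # physical picture: two ferromagnetic pairs coupled antiferromagnetically
        table = generate_bs_table(
            SyntheticTableSpec(TWO_J, SPINS4, full_rank_states())
        )
        energies = {l: e for l, _, _, e in table.rows}
        ground = min(energies, key=energies.get)
        assert ground in ("[↑↑↓↓]", "[↓↓↑↑]")


class TestFitCouplings:
    def test_exact_recovery_from_noiseless_full_rank_table(self):
        table = generate_bs_table(SyntheticTableSpec(TWO_J, SPINS4, full_rank_states()))
        params, diag = fit_couplings(table, SPINS4, "two_J")
        assert diag.rank == diag.n_parameters == 3
        assert params.j_intra == pytest.approx(TWO_J.j_intra, abs=1e-10)
        assert params.j_inter == pytest.approx(TWO_J.j_inter, abs=1e-10)
        assert params.offset == pytest.approx(TWO_J.offset, abs=1e-10)
        assert diag.residual_norm < 1e-10

    def test_six_singlets_are_rank_deficient_but_consistent(self):
        # over the six singlets x_intra + x_inter = -2 m^2 identically, so only
        # two of the three two_J parameters are identifiable
        singlets = enumerate_bs_states(4, 2)
        table = generate_bs_table(SyntheticTableSpec(TWO_J, SPINS4, singlets))
        params, diag = fit_couplings(table, SPINS4, "two_J")
        assert diag.rank == 2
        assert diag.rank_deficient
        assert diag.residual_norm < 1e-10
        assert len(diag.identifiable_combinations) == 2
        # the minimum-norm solution still reproduces every table energy
        for (label, _, _, e) in table.rows:
            assert ising_energy(parse_label(label), params, SPINS4) == pytest.approx(
                e, abs=1e-9
            )

    def test_full_6j_on_six_singlets_rank_deficient_min_norm_reproduces(self):
        singlets = enumerate_bs_states(4, 2)
        table = generate_bs_table(SyntheticTableSpec(TWO_J, SPINS4, singlets))
        params, diag = fit_couplings(table, SPINS4, "full_6J")
        assert diag.n_parameters == 7
        assert diag.rank < 7  # singular 6x7 design (rank oracle: singular values)
        sv = diag.singular_values
        assert np.sum(sv > sv.max() * 7 * np.finfo(float).eps) == diag.rank
        for (label, _, _, e) in table.rows:
            assert ising_energy(parse_label(label), params, SPINS4) == pytest.approx(
                e, abs=1e-9
            )

    def test_adding_high_spin_state_raises_rank(self):
        singlets = enumerate_bs_states(4, 2)
        t6 = generate_bs_table(SyntheticTableSpec(TWO_J, SPINS4, singlets))
        t7 = generate_bs_table(
            SyntheticTableSpec(TWO_J, SPINS4, singlets + [BSState((1, 1, 1, 1))])
        )
        _, d6 = fit_couplings(t6, SPINS4, "full_6J")
        _, d7 = fit_couplings(t7, SPINS4, "full_6J")
        assert d7.rank > d6.rank

    def test_too_few_rows_raise(self):
        table = generate_bs_table(
            SyntheticTableSpec(TWO_J, SPINS4, enumerate_bs_states(4, 2)[:1])
        )
        with pytest.raises(ValueError):
            fit_couplings(table, SPINS4, "two_J")

    def test_recovery_error_shrinks_with_added_states(self):
        # mean |error| over 200 seeded noise draws decreases as states are added
        base = (
            enumerate_bs_states(4, 2)
            + [BSState((1, 1, 1, 1))]
            + enumerate_bs_states(4, 3)
            + enumerate_bs_states(4, 1)
            + [BSState((-1, -1, -1, -1))]
        )
        mean_err = {}
        for n_states in (8, 12, 16):
            errs = []
            for seed in range(200):
                t = generate_bs_table(
                    SyntheticTableSpec(
                        TWO_J, SPINS4, base[:n_states], noise_sd=2.0, seed=seed
                    )
                )
                p, _ = fit_couplings(t, SPINS4, "two_J")
                errs.append(
                    abs(p.j_intra - TWO_J.j_intra) + abs(p.j_inter - TWO_J.j_inter)
                )
            mean_err[n_states] = float(np.mean(errs))
        assert mean_err[8] > mean_err[12] > mean_err[16]


def two_atom_structure(r=1.5, q=(0.0, 0.0)):
    return Structure(
        [Atom("C", (0, 0, 0), q[0], 1), Atom("C", (r, 0, 0), q[1], 2)]
    )


class TestToyEngines:
    def test_spin_engine_with_zero_couplings_equals_mm(self, lipa_bundle):
        p0 = HeisenbergParams(model="two_J", j_intra=0.0, j_inter=0.0, offset=0.0)
        qm = toy_spin_engine(p0, SiteSpins.uniform(2.25, 8))
        mm = toy_mm_engine()
        st = lipa_bundle.structure
        state = parse_label("[↑↑↓↓ ↓↑↑↓]")
        assert qm(st, None, state, "x").energy == pytest.approx(
            mm(st, None, None, "x").energy, abs=1e-12
        )

    def test_state_difference_is_geometry_independent(self):
        spins = SiteSpins.uniform(2.25, 4)
        qm = toy_spin_engine(TWO_J, spins)
        s1, s2 = parse_label("↑↑↓↓"), parse_label("↑↓↑↓")
        d_ising = (ising_energy(s1, TWO_J, spins) - ising_energy(s2, TWO_J, spins))
        for scale in (1.0, 1.1):
            atoms = [
                Atom("FE", (scale * 3 * i, 0, 0), 0.0, i + 1) for i in range(4)
            ]
            st = Structure(atoms)
            d = qm(st, None, s1, "x").energy - qm(st, None, s2, "x").energy
            assert d * 2625.4996 == pytest.approx(d_ising, abs=1e-9)

    def test_wrong_state_length_raises(self):
        qm = toy_spin_engine(TWO_J, SiteSpins.uniform(2.25, 8))
        st = Structure([Atom("FE", (3 * i, 0, 0), 0.0, i + 1) for i in range(4)])
        with pytest.raises(ValueError):
            qm(st, None, parse_label("[↑↑↓↓ ↓↑↑↓]"), "x")

    def test_embedding_coulomb_linear_in_external_charges(self):
        st = two_atom_structure(r=5.0, q=(0.3, 0.0))  # no bond at 5 A, one charge
        mm = toy_mm_engine()
        pcm1 = PointChargeModel(np.array([[0.0, 4.0, 0.0]]), np.array([0.5]), [99])
        pcm2 = PointChargeModel(np.array([[0.0, 4.0, 0.0]]), np.array([1.0]), [99])
        e1 = mm(st, pcm1, None, "x").energy
        e2 = mm(st, pcm2, None, "x").energy
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_harmonic_gradient_is_analytic(self):
        st = two_atom_structure(r=1.6)
        mm = toy_mm_engine(k_bond=0.3)
        res = mm(st, None, None, "x")
        # numerical gradient check on atom 2 x-coordinate
        h = 1e-6
        st_p = st.with_positions(np.array([[0, 0, 0], [1.6 + h, 0, 0]]))
        st_m = st.with_positions(np.array([[0, 0, 0], [1.6 - h, 0, 0]]))
        num = (mm(st_p, None, None, "x").energy - mm(st_m, None, None, "x").energy) / (
            2 * h
        )
        assert res.gradients[1, 0] == pytest.approx(num, rel=1e-5)
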