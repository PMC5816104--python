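import itertools
import math

import numpy as np
import pytest

from spincube.spinstates import (
    BSEnergyTable,
    BSState,
    analyze_family,
    bs_by_site_swap,
    bs_from_fragments,
    count_unpaired_spins,
    enumerate_bs_states,
    enumerate_two_cluster_singlets,
    estimate_missing_state,
    format_label,
    parse_label,
    round_half_up,
    spin_population_summary,
)

TABLE1_LABELS = [
    "[↑↓↑↓ ↓↑↓↑]", "[↑↓↑↓ ↑↓↓↑]", "[↑↓↑↓ ↑↑↓↓]", "[↑↓↑↓ ↓↓↑↑]",
    "[↑↓↑↓ ↓↑↑↓]", "[↑↓↑↓ ↑↓↑↓]", "[↓↑↑↓ ↓↑↑↓]", "[↓↓↑↑ ↓↑↑↓]",
    "[↑↑↓↓ ↓↑↑↓]", "[↑↓↓↑ ↓↑↑↓]", "[↓↑↓↑ ↓↑↑↓]",
]


def bitmask_states(n_sites: int, n_up: int) -> set[tuple[int, ...]]:
    """Exhaustive brute-force oracle over all 2^n sign patterns."""
    out = set()
    for mask in range(2**n_sites):
        o = tuple(1 if mask >> i & 1 else -1 for i in range(n_sites))
        if sum(1 for x in o if x == 1) == n_up:
            out.add(o)
    return out


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_sites, n_up, expected",
        [(4, 2, 6), (4, 4, 1), (4, 0, 1), (8, 4, 70)],
    )
    def test_cardinality(self, n_sites, n_up, expected):
        states = enumerate_bs_states(n_sites, n_up)
        assert len(states) == expected
        assert len(set(states)) == expected
        assert expected == math.comb(n_sites, n_up)

    @pytest.mark.parametrize("n_sites", range(1, 11))
    def test_matches_bitmask_oracle(self, n_sites):
        for n_up in range(n_sites + 1):
            got = {s.orientations for s in enumerate_bs_states(n_sites, n_up)}
            assert got == bitmask_states(n_sites, n_up)

    def test_deterministic_lexicographic_order(self):
        states = enumerate_bs_states(4, 2)
        assert [s.label for s in states] == [
            "[↑↑↓↓]", "[↑↓↑↓]", "[↑↓↓↑]", "[↓↑↑↓]", "[↓↑↓↑]", "[↓↓↑↑]",
        ]

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            enumerate_bs_states(4, -1)
        with pytest.raises(ValueError):
            enumerate_bs_states(4, 5)

    def test_two_cluster_singlets(self):
        combined = enumerate_two_cluster_singlets()
        assert len(combined) == 36  # 6 x 6 product
        labels = {s.label for s in combined}
        assert "[↑↑↓↓ ↓↑↑↓]" in labels
        for s in combined:
            for cluster in s.clusters():
                assert sum(cluster) == 0


class TestUnpairedSpins:
    def test_two_mixed_valence_clusters_give_36(self):
        assert count_unpaired_spins([[2, 2, 3, 3], [2, 2, 3, 3]]) == 36

    def test_single_cluster_is_half(self):
        assert count_unpaired_spins([2, 2, 3, 3]) == 18

    def test_all_ferric_cluster(self):
        assert count_unpaired_spins([3, 3, 3, 3]) == 20

    def test_unsupported_charge_raises(self):
        with pytest.raises(ValueError):
            count_unpaired_spins([2, 4, 3, 3])


class TestLabels:
    def test_parse_table_row_label(self):
        s = parse_label("[↑↑↓↓ ↓↑↑↓]")
        assert s.orientations == (1, 1, -1, -1, -1, 1, 1, -1)

    @pytest.mark.parametrize("label", TABLE1_LABELS)
    def test_round_trip_on_all_table_labels(self, label):
        assert format_label(parse_label(label)) == label

    @pytest.mark.parametrize("bad", ["↑↑↑", "↑↑↓↓↓", "[↑↑x↓]", "↑↑↓↓ ↓↑↑"])
    def test_malformed_labels_raise(self, bad):
        with pytest.raises(ValueError):
            parse_label(bad)

    def test_brackets_and_spacing_optional(self):
        assert parse_label("↑↑↓↓↓↑↑↓") == parse_label("[↑↑↓↓ ↓↑↑↓]")


class TestGenerationRoutes:
    def test_fragments_inherit_orientation(self):
        s = bs_from_fragments(
            {0: "A", 1: "A", 2: "B", 3: "B"}, {"A": 1, "B": -1}
        )
        assert s.label == "[↑↑↓↓]"

    def test_pair_bipartitions_generate_all_six_singlets(self):
        # the 3 ways to split 4 sites into two ferromagnetic pairs, x 2 signs,
        # generate exactly the 6 antiferromagnetic singlet states
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        generated = set()
        for up_pair, down_pair in pairings:
            for sign in (1, -1):
                assignment = {site: "U" for site in up_pair}
                assignment.update({site: "D" for site in down_pair})
                generated.add(
                    bs_from_fragments(assignment, {"U": sign, "D": -sign})
                )
        oracle = set(enumerate_bs_states(4, 2))
        assert generated == oracle

    def test_single_fragment_gives_high_spin_not_singlet(self):
        s = bs_from_fragments({i: "all" for i in range(4)}, {"all": 1})
        assert s.label == "[↑↑↑↑]"
        assert sum(s.orientations) != 0  # flagged: not a singlet

    def test_unassigned_site_raises(self):
        with pytest.raises(ValueError):
            bs_from_fragments({0: "A", 1: "A", 3: "A"}, {"A": 1})

    def test_swap_examples(self):
        s = parse_label("↑↓↑↓")
        assert bs_by_site_swap(s, [0, 1, 2, 3]) == s
        assert bs_by_site_swap(s, [2, 1, 0, 3]) == s  # sites 1,3 equal
        assert bs_by_site_swap(s, [1, 0, 2, 3]).label == "[↓↑↑↓]"

    def test_swap_orbit_covers_all_six_states(self):
        start = parse_label("↑↑↓↓")
        orbit = {
            bs_by_site_swap(start, list(p))
            for p in itertools.permutations(range(4))
        }
        assert orbit == set(enumerate_bs_states(4, 2))

    def test_cross_cluster_swap_raises(self):
        s = parse_label("[↑↑↓↓ ↓↑↑↓]")
        perm = [4, 1, 2, 3, 0, 5, 6, 7]  # mixes the clusters
        with pytest.raises(ValueError):
            bs_by_site_swap(s, perm)

    def test_both_routes_closed_under_enumeration(self):
        oracle = {s.orientations for s in enumerate_bs_states(4, 2)}
        for s in enumerate_bs_states(4, 2):
            for p in itertools.permutations(range(4)):
                assert bs_by_site_swap(s, list(p)).orientations in oracle


def make_table(rows):
    return BSEnergyTable(rows)


class TestAnalyzeFamily:
    def test_resting_aux_varied_spread(self, table1):
        stats = analyze_family(table1, "main_fixed", "resting")
        assert stats.spread == pytest.approx(8.6)
        assert round_half_up(stats.spread) == 9
        assert stats.min_energy == pytest.approx(-5.9)

    def test_resting_main_varied_includes_shared_row(self, table1):
        stats = analyze_family(table1, "aux_fixed", "resting")
        # the shared [↑↓↑↓ ↓↑↑↓] row at -5.9 is the family maximum
        assert stats.n_states == 6
        assert stats.spread == pytest.approx(13.4)
        assert stats.n_within == 3  # three states within 2 kJ/mol of the minimum

    def test_reactive_pooled_ground_state_and_gap(self, table1):
        stats = analyze_family(table1, None, "reactive")
        assert parse_label(stats.min_state) == parse_label("[↑↑↓↓ ↓↑↑↓]")
        assert stats.min_energy == pytest.approx(-9.1)
        assert stats.gap_to_second == pytest.approx(7.0)

    def test_missing_rows_are_excluded(self, table1):
        stats = analyze_family(table1, "aux_fixed", "reactive")
        # 5 block rows (one NA, excluded) + the shared row
        assert stats.n_states == 5

    def test_row_order_and_shift_invariance(self, table1):
        base = analyze_family(table1, "aux_fixed", "resting")
        shifted = make_table(
            [
                (l, f, c, None if e is None else e + 123.4)
                for l, f, c, e in reversed(table1.rows)
            ]
        )
        stats = analyze_family(shifted, "aux_fixed", "resting")
        assert stats.spread == pytest.approx(base.spread)
        assert stats.gap_to_second == pytest.approx(base.gap_to_second)
        assert stats.n_within == base.n_within
        assert stats.min_energy == pytest.approx(base.min_energy + 123.4)

    def test_single_entry_family(self):
        t = make_table([("↑↑↓↓", "aux_fixed", "resting", 4.2)])
        stats = analyze_family(t, None, "resting", tol=0.0)
        assert stats.spread == 0.0
        assert stats.n_within == 1

    def test_all_missing_family_raises(self):
        t = make_table([("↑↑↓↓", "main_fixed", "resting", None)])
        with pytest.raises(ValueError):
            analyze_family(t, None, "resting")

    def test_tie_reported_and_broken_lexicographically(self):
        t = make_table(
            [
                ("↑↓↑↓", "f", "c", -1.0),
                ("↑↑↓↓", "f", "c", -1.0),
                ("↓↓↑↑", "f", "c", 0.0),
            ]
        )
        stats = analyze_family(t, None, "c")
        assert stats.tied
        assert stats.min_state == "↑↑↓↓"  # lexicographically first label


class TestEstimateAndPopulations:
    @pytest.mark.parametrize(
        "ref, delta, expected", [(11.0, 2.0, 9.0), (5.5, 0.0, 5.5), (0.0, 0.0, 0.0)]
    )
    def test_additive_transfer_estimate(self, ref, delta, expected):
        assert estimate_missing_state(ref, delta) == pytest.approx(expected)

    def test_low_spin_density_site_is_flagged(self):
        out = spin_population_summary([-3.4, 3.6, 3.7, 3.8], 0.1)
        signs = [s for s, _, _ in out]
        flags = [f for _, _, f in out]
        assert signs == [-1, 1, 1, 1]
        assert flags == [True, False, False, False]

    def test_uniform_populations_unflagged(self):
        out = spin_population_summary([4.0, 4.0, 4.0, 4.0], 0.1)
        assert all(s == 1 and not f for s, _, f in out)

    def test_zero_population_unassigned_and_flagged(self):
        out = spin_population_summary([0.0, 4.0, -4.0, 4.0], 0.1)
        assert out[0][0] == 0 and out[0][2]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            spin_population_summary([])


class TestTableIO:
    def test_tsv_round_trip_with_missing(self, table1):
        text = table1.to_tsv()
        back = BSEnergyTable.from_tsv(text)
        assert back.rows == table1.rows

    def test_duplicate_label_column_rejected(self):
        with pytest.raises(ValueError):
            make_table(
                [("↑↑↓↓", "f", "c", 1.0), ("↑↑↓↓", "g", "c", 2.0)]
            )
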