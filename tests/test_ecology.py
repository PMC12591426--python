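"""Niche overlap, regional interaction networks, NEI and adaptive shifts."""

import numpy as np
import pytest

import ecoevosim as es
from ecoevosim.ecology import (
    COMPETITIVE,
    FACILITATIVE,
    INHIBITORY,
    NicheState,
    RegionalEcologicalNetwork,
    adaptive_shift,
    compute_all_nei,
    compute_nei,
    niche_overlap,
    update_network,
)


def net_of(niches, fitness, noncomp=()):
    """Build a network plus lookup closures from parallel dicts."""
    net = RegionalEcologicalNetwork(0)
    net.nodes = set(niches)
    for s, t, w in noncomp:
        net.noncomp[(s, t)] = w
    return net, (lambda p: niches[p]), (lambda p: fitness[p])


class TestNicheOverlap:
    def test_identical_realized_intervals_overlap_fully(self):
        a = NicheState(10, 0, 4)
        assert niche_overlap(a, NicheState(10, 99, 4)) == 1.0

    def test_disjoint_intervals_do_not_overlap(self):
        assert niche_overlap(NicheState(2, 0, 2), NicheState(12, 0, 2)) == 0.0

    def test_worked_interval_jaccard_example(self):
        # [0,4] vs [2,6]: intersection 2 over union 6
        a = NicheState(2, 0, 2)
        b = NicheState(4, 0, 2)
        assert niche_overlap(a, b) == pytest.approx(1 / 3)

    def test_degenerate_points(self):
        assert niche_overlap(NicheState(5, 0, 0), NicheState(5, 0, 0)) == 1.0
        assert niche_overlap(NicheState(5, 0, 0), NicheState(6, 0, 0)) == 0.0

    def test_symmetry_on_random_states(self, rng):
        for _ in range(200):
            a = NicheState(int(rng.integers(256)), 0, int(rng.integers(20)))
            b = NicheState(int(rng.integers(256)), 0, int(rng.integers(20)))
            assert niche_overlap(a, b) == niche_overlap(b, a)
            assert 0.0 <= niche_overlap(a, b) <= 1.0


class TestUpdateNetwork:
    def test_single_population_has_empty_link_set(self, rng):
        net, niche_of, _f = net_of({1: NicheState(5, 0, 2)}, {1: 0.5})
        update_network(net, niche_of, 1.0, 0.0, rng)
        assert net.links(niche_of) == []

    def test_overlapping_pair_gets_symmetric_competitive_links_only(self, rng):
        niches = {1: NicheState(10, 0, 4), 2: NicheState(10, 0, 4)}
        net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5})
        update_network(net, niche_of, 1.0, 0.0, rng)
        links = net.links(niche_of)
        kinds = {(l.source, l.target): (l.kind, l.weight) for l in links}
        assert kinds == {
            (1, 2): (COMPETITIVE, -1.0),
            (2, 1): (COMPETITIVE, -1.0),
        }
        assert net.noncomp == {}

    def test_allometric_direction_of_forced_noncompetitive_links(self, rng):
        # big organism (n=200) facilitates small one (n=10); the small one
        # inhibits the big one
        niches = {1: NicheState(200, 0, 3), 2: NicheState(10, 0, 3)}
        net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5})
        update_network(net, niche_of, 1.0, 0.0, rng, link_magnitude=0.5)
        assert net.noncomp[(1, 2)] == 0.5    # facilitative
        assert net.noncomp[(2, 1)] == -0.5   # inhibitory

    def test_equal_positions_never_link(self, rng):
        niches = {1: NicheState(10, 0, 0), 2: NicheState(10, 0, 0)}
        net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5})
        # identical points overlap fully -> competitive, no candidates
        update_network(net, niche_of, 1.0, 0.0, rng)
        assert net.noncomp == {}

    def test_link_removed_when_pair_starts_overlapping(self, rng):
        niches = {1: NicheState(0, 0, 2), 2: NicheState(10, 0, 2)}
        net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5},
                                   noncomp=[(1, 2, 0.5)])
        niches[2] = NicheState(2, 0, 2)  # now overlapping
        update_network(net, niche_of, 0.0, 0.0, rng)
        assert net.noncomp == {}

    def test_stochastic_removal_rate(self):
        rng = np.random.default_rng(5)
        removed = 0
        for _ in range(2000):
            niches = {1: NicheState(0, 0, 1), 2: NicheState(10, 0, 1)}
            net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5},
                                       noncomp=[(1, 2, 0.5)])
            update_network(net, niche_of, 0.0, 0.25, rng)
            removed += (1, 2) not in net.noncomp
        assert abs(removed / 2000 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 2000)


class TestNEI:
    def test_isolated_population_has_zero_nei(self, rng):
        net, niche_of, fit_of = net_of({7: NicheState(5, 0, 2)}, {7: 0.9})
        assert compute_nei(net, 7, fit_of, niche_of) == 0.0

    def test_full_overlap_equal_fitness_gives_minus_one(self, rng):
        niches = {1: NicheState(10, 0, 4), 2: NicheState(10, 0, 4)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        assert compute_nei(net, 1, fit_of, niche_of) == pytest.approx(-1.0)
        assert compute_nei(net, 2, fit_of, niche_of) == pytest.approx(-1.0)

    def test_maximally_fitter_party_escapes_competition_cost(self):
        niches = {1: NicheState(10, 0, 4), 2: NicheState(10, 0, 4)}
        net, niche_of, fit_of = net_of(niches, {1: 1.0, 2: 0.0})
        # F = +1 for the fitter party: -1 * (1 - 1) = 0
        assert compute_nei(net, 1, fit_of, niche_of) == pytest.approx(0.0)
        # the weaker party pays double: -1 * (1 + 1) = -2
        assert compute_nei(net, 2, fit_of, niche_of) == pytest.approx(-2.0)

    def test_unknown_focal_rejected(self):
        net, niche_of, fit_of = net_of({1: NicheState(0, 0, 1)}, {1: 0.5})
        with pytest.raises(KeyError):
            compute_nei(net, 99, fit_of, niche_of)

    def test_incoming_noncompetitive_weights_accumulate(self):
        niches = {1: NicheState(0, 0, 1), 2: NicheState(10, 0, 1),
                  3: NicheState(20, 0, 1)}
        net, niche_of, fit_of = net_of(
            niches, {1: 0.5, 2: 0.5, 3: 0.5},
            noncomp=[(2, 1, 0.5), (3, 1, -0.5)],
        )
        assert compute_nei(net, 1, fit_of, niche_of) == pytest.approx(0.0)

    def test_competition_only_nei_is_never_positive(self, rng):
        for _ in range(100):
            niches = {
                i: NicheState(int(rng.integers(30)), 0, int(rng.integers(6)))
                for i in range(6)
            }
            fits = {i: float(rng.random()) for i in range(6)}
            net, niche_of, fit_of = net_of(niches, fits)
            for i in range(6):
                assert compute_nei(net, i, fit_of, niche_of) <= 1e-12

    def test_matches_bruteforce_oracle_on_random_networks(self, rng):
        # oracle: literal sum over cohabitants of -ov*(1-F) plus incoming W
        def clamp(x):
            return max(-1.0, min(1.0, x))

        for _ in range(50):
            n = 10
            niches = {
                i: NicheState(int(rng.integers(40)), 0, int(rng.integers(8)))
                for i in range(n)
            }
            fits = {i: float(rng.random()) for i in range(n)}
            pairs = {}
            for _ in range(8):
                s, t = rng.choice(n, 2, replace=False)
                if niche_overlap(niches[int(s)], niches[int(t)]) == 0.0:
                    pairs[(int(s), int(t))] = 0.5 if rng.random() < 0.5 else -0.5
            noncomp = [(s, t, w) for (s, t), w in pairs.items()]
            net, niche_of, fit_of = net_of(niches, fits, noncomp)
            all_nei = compute_all_nei(net, fit_of, niche_of)
            for a in range(n):
                expected_stored = 0.0
                for i in range(n):
                    if i == a:
                        continue
                    ov = niche_overlap(niches[a], niches[i])
                    if ov > 0:
                        expected_stored += -ov * (1 - clamp(fits[a] - fits[i]))
                for s, t, w in noncomp:
                    if t == a:
                        expected_stored += w
                assert all_nei[a] == pytest.approx(expected_stored)
                assert compute_nei(net, a, fit_of, niche_of) == pytest.approx(
                    expected_stored
                )


class TestAdaptiveShift:
    def test_no_op_above_threshold(self, rng):
        niches = {1: NicheState(10, 10, 2), 2: NicheState(10, 10, 2)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        out = adaptive_shift(1, niches[1], 0.0, net, niche_of, fit_of, -0.5, rng)
        assert out is None

    def test_escape_from_full_overlap_raises_prospective_nei(self, rng):
        niches = {1: NicheState(10, 10, 1), 2: NicheState(10, 10, 1)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        nei = compute_nei(net, 1, fit_of, niche_of)
        assert nei == pytest.approx(-1.0)
        out = adaptive_shift(1, niches[1], nei, net, niche_of, fit_of, -0.5, rng)
        assert out is not None
        assert niche_overlap(out, niches[2]) < 1.0
        assert out.n != 10 or out.r != 1

    def test_shift_magnitude_is_at_most_one_unit(self, rng):
        niches = {1: NicheState(10, 10, 3), 2: NicheState(10, 10, 3)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        for _ in range(50):
            out = adaptive_shift(1, niches[1], -1.0, net, niche_of, fit_of,
                                 -0.5, rng)
            if out is None:
                continue
            assert abs(out.n - 10) <= 1 and abs(out.r - 3) <= 1
            assert out.c == 10  # the optimum never moves

    def test_negative_candidates_excluded(self, rng):
        niches = {1: NicheState(0, 0, 0), 2: NicheState(0, 0, 0)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        for _ in range(50):
            out = adaptive_shift(1, niches[1], -1.0, net, niche_of, fit_of,
                                 -0.5, rng)
            if out is not None:
                assert out.n >= 0 and out.r >= 0

    def test_tied_escapes_chosen_uniformly(self):
        # enumerate the candidate moves and their prospective NEI by hand:
        # for two identical zero-width niches at n=10, the five legal moves
        # (9,0) (9,1) (10,1) (11,0) (11,1) all reach NEI 0 and tie; the
        # tie-break must pick each with frequency ~ 1/5
        rng = np.random.default_rng(17)
        niches = {1: NicheState(10, 10, 0), 2: NicheState(10, 10, 0)}
        net, niche_of, fit_of = net_of(niches, {1: 0.5, 2: 0.5})
        counts = {}
        n_trials = 10_000
        for _ in range(n_trials):
            out = adaptive_shift(1, niches[1], -1.0, net, niche_of, fit_of,
                                 -0.5, rng)
            assert out is not None
            counts[(out.n, out.r)] = counts.get((out.n, out.r), 0) + 1
        assert set(counts) == {(9, 0), (9, 1), (10, 1), (11, 0), (11, 1)}
        se = np.sqrt(0.2 * 0.8 / n_trials)
        for k, c in counts.items():
            assert abs(c / n_trials - 0.2) < 4 * se
        # the two mirror-image n-moves at unchanged r are equally likely
        mirror = counts[(9, 0)] + counts[(11, 0)]
        assert abs(counts[(11, 0)] / mirror - 0.5) < 0.05


class TestEdgeListExport:
    def test_csv_contains_all_links(self, rng):
        niches = {1: NicheState(10, 0, 4), 2: NicheState(10, 0, 4),
                  3: NicheState(100, 0, 1)}
        net, niche_of, _f = net_of(niches, {1: 0.5, 2: 0.5, 3: 0.5},
                                   noncomp=[(3, 1, 0.5)])
        text = net.edge_list_csv(niche_of)
        lines = text.strip().splitlines()
        assert lines[0] == "source,target,kind,weight"
        assert any("competitive" in l for l in lines[1:])
        assert any("facilitative" in l for l in lines[1:])
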