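"""Diplotype-state HMM: emissions, transitions, forward-backward vs exact
path enumeration, imputation, ancestor merging, male X, and mosaics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccmosaic import haprecon as hp
from ccmosaic import simdata
from ccmosaic.simdata import Pedigree

S36 = hp.STATE_SPACE_36


def _mm(positions, chrom="chr1"):
    idx = pd.Index([f"m{i}" for i in range(len(positions))], name="marker")
    return pd.DataFrame({"chromosome": chrom, "position": positions}, index=idx)


def _enumerate_posteriors(calls, positions, alleles, params, space):
    """Independent oracle: exact marginals by summing over all state paths."""
    n = len(calls)
    k = space.n_states
    prior = np.full(k, 1.0 / k)
    emis = hp._emission_matrix(calls, alleles, params.epsilon, space)
    trans = [
        hp.transition_matrix(positions[m] - positions[m - 1], params.rho, space)
        for m in range(1, n)
    ]
    post = np.zeros((n, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=n):
        w = prior[path[0]] * emis[0, path[0]]
        for m in range(1, n):
            w *= trans[m - 1][path[m - 1], path[m]] * emis[m, path[m]]
        total += w
        for m, s in enumerate(path):
            post[m, s] += w
    return post / total


class TestStateSpace:
    def test_canonical_order_and_bijection(self):
        assert S36.n_states == 36
        assert S36.names[:8] == ["AA", "BB", "CC", "DD", "EE", "FF", "GG", "HH"]
        assert S36.names[8:11] == ["AB", "AC", "AD"]
        for k, (i, j) in enumerate(S36.states):
            assert S36.index(i, j) == k and S36.index(j, i) == k


class TestEmission:
    def test_matching_inbred_call(self):
        alleles = np.array(list("AAAAGGGG"))
        assert hp.emission_probability("A", 0, alleles, 0.01) == pytest.approx(0.99)

    def test_n_is_uninformative(self):
        alleles = np.array(list("AAAAGGGG"))
        for s in range(36):
            assert hp.emission_probability("N", s, alleles, 0.01) == 1.0

    def test_normalizes_over_call_vocabulary(self):
        alleles = np.array(list("AGAGAGAG"))
        for s in range(36):
            total = sum(hp.emission_probability(c, s, alleles, 0.01) for c in ("A", "G", "H"))
            assert total == pytest.approx(1.0)

    def test_discordant_pair_expects_h(self):
        alleles = np.array(list("AAAAGGGG"))
        s = S36.index(0, 4)  # A/J with NZO: alleles differ
        assert hp.emission_probability("H", s, alleles, 0.01) == pytest.approx(0.99)


class TestTransitions:
    def test_zero_distance_is_identity(self):
        assert np.allclose(hp.transition_matrix(0.0, 1e-4), np.eye(36))

    @given(st.floats(1.0, 1e7), st.floats(1e-8, 1e-3))
    def test_rows_sum_to_one(self, d, rho):
        m = hp.transition_matrix(d, rho)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert (m >= 0).all()

    def test_long_distance_reaches_pair_stationary(self):
        m = hp.transition_matrix(1e9, 1e-3)
        # oracle: enumerate two independent uniform haplotypes onto pairs
        expected = np.zeros(36)
        for a in range(8):
            for b in range(8):
                expected[S36.index(a, b)] += 1 / 64
        assert np.allclose(m, np.tile(expected, (36, 1)), atol=1e-9)


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self):
        space = hp.DiplotypeStateSpace(3)
        rng = np.random.default_rng(12)
        params = hp.HmmParams(epsilon=0.02, rho=2e-4)
        for trial in range(4):
            n = 4
            positions = np.sort(rng.choice(20_000, size=n, replace=False) + 1)
            alleles = rng.choice(["A", "G"], size=(n, 3))
            while any(len(set(row)) < 2 for row in alleles):
                alleles = rng.choice(["A", "G"], size=(n, 3))
            calls = [str(rng.choice(["A", "G", "H", "N"])) for _ in range(n)]
            track = hp.forward_backward(calls, _mm(positions), alleles, params)
            oracle = _enumerate_posteriors(calls, positions, alleles, params, space)
            assert np.abs(track.probs - oracle).max() < 1e-10

    def test_single_marker_bayes(self):
        alleles = np.array([list("AGGGGGGG")])
        track = hp.forward_backward(["A"], _mm([500]), alleles, hp.HmmParams())
        with_a = [k for k, (i, j) in enumerate(S36.states) if 0 in (i, j)]
        without_a = [k for k in range(36) if k not in with_a]
        assert track.probs[0, with_a].sum() > track.probs[0, without_a].sum()

    def test_all_n_returns_prior(self):
        alleles = np.tile(np.array(list("AAAAGGGG")), (3, 1))
        track = hp.forward_backward(["N", "N", "N"], _mm([10, 20, 30]), alleles, hp.HmmParams())
        assert np.allclose(track.probs, 1 / 36)

    def test_rows_are_distributions(self):
        rng = np.random.default_rng(5)
        n = 30
        alleles = rng.choice(["A", "G"], size=(n, 8))
        calls = list(rng.choice(["A", "G", "H", "N"], size=n))
        track = hp.forward_backward(
            calls, _mm(sorted(rng.choice(100_000, n, replace=False) + 1)), alleles, hp.HmmParams()
        )
        assert np.allclose(track.probs.sum(axis=1), 1.0)
        assert (track.probs >= 0).all()


class TestImputation:
    def _track(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(36), size=3)
        return hp.StateProbabilityTrack(markers=_mm([1000, 2000, 4000]), probs=probs)

    def test_coincident_target_identical(self):
        t = self._track()
        out = hp.impute_probabilities(t, [2000])
        assert np.allclose(out.probs[0], t.probs[1], atol=1e-12)

    def test_midpoint_is_renormalized_mean(self):
        t = self._track()
        out = hp.impute_probabilities(t, [1500])
        mean = (t.probs[0] + t.probs[1]) / 2
        assert np.allclose(out.probs[0], mean / mean.sum(), atol=1e-12)

    def test_outside_range_takes_end_vector(self):
        t = self._track()
        out = hp.impute_probabilities(t, [10, 9999])
        assert np.allclose(out.probs[0], t.probs[0])
        assert np.allclose(out.probs[1], t.probs[-1])

    def test_empty_track_rejected(self):
        t = self._track()
        empty = hp.StateProbabilityTrack(markers=t.markers.iloc[:0], probs=np.zeros((0, 36)))
        with pytest.raises(ValueError):
            hp.impute_probabilities(empty, [100])


class TestMergeAncestors:
    def test_two_founder_redistribution_example(self):
        v1 = np.zeros(36)
        v1[S36.index(0, 0)] = 0.9
        v1[S36.index(0, 1)] = 0.1
        v2 = np.zeros(36)
        v2[S36.index(1, 1)] = 0.8
        v2[S36.index(0, 1)] = 0.2
        merged = hp.merge_ancestors([v1, v2])
        expected = np.zeros(36)
        expected[S36.index(0, 1)] = 1.0
        assert np.allclose(merged, expected)

    def test_single_ancestor_unchanged(self):
        rng = np.random.default_rng(1)
        v = rng.dirichlet(np.ones(36))
        assert np.allclose(hp.merge_ancestors([v]), v)

    def test_concordant_inbred_maxima_no_redistribution(self):
        v = np.zeros(36)
        v[S36.index(0, 0)] = 0.7
        v[S36.index(0, 2)] = 0.3
        merged = hp.merge_ancestors([v, v.copy()])
        assert merged.argmax() == S36.index(0, 0)

    def test_three_way_conflict_support(self):
        vs = []
        for f in (0, 1, 2):
            v = np.zeros(36)
            v[S36.index(f, f)] = 1.0
            vs.append(v)
        merged = hp.merge_ancestors(vs)
        support = {S36.names[k] for k in np.nonzero(merged)[0]}
        assert support == {"AB", "AC", "BC"}

    @given(st.lists(st.floats(0.01, 1.0), min_size=36, max_size=36))
    def test_idempotence(self, raw):
        v = np.array(raw)
        v /= v.sum()
        assert np.allclose(hp.merge_ancestors([v, v]), v, atol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hp.merge_ancestors([])


class TestMaleX:
    def test_expand_uniform_and_point_mass(self):
        out = hp.expand_male_x(np.full(8, 1 / 8))
        assert np.allclose(out[:8], 1 / 8) and np.allclose(out[8:], 0)
        point = np.zeros(8)
        point[3] = 1.0
        assert hp.expand_male_x(point).argmax() == 3

    def test_male_x_track_has_zero_het_mass(self):
        rng = np.random.default_rng(4)
        n = 20
        alleles = rng.choice(["A", "G"], size=(n, 8))
        calls = list(rng.choice(["A", "G"], size=n))
        track = hp.forward_backward(
            calls, _mm(sorted(rng.choice(50_000, n, replace=False) + 1), chrom="chrX"),
            alleles, hp.HmmParams(), chromosome_kind="male_x",
        )
        assert track.probs[:, 8:].max() == 0.0
        assert np.allclose(track.probs.sum(axis=1), 1.0)

    def test_merge_preserves_zero_het_mass_for_male_x_pair(self):
        a = hp.expand_male_x(np.array([0.9, 0.1, 0, 0, 0, 0, 0, 0]))
        b = hp.expand_male_x(np.array([0.85, 0.15, 0, 0, 0, 0, 0, 0]))
        merged = hp.merge_ancestors([a, b])
        assert merged[8:].max() == 0.0


class TestMosaic:
    def test_constant_track_single_segment(self):
        probs = np.zeros((4, 36))
        probs[:, S36.index(2, 5)] = 1.0
        track = hp.StateProbabilityTrack(markers=_mm([100, 300, 700, 900]), probs=probs)
        mosaic = hp.mosaic_from_track(track)
        assert len(mosaic.segments) == 1
        seg = mosaic.segments[0]
        assert (seg.start, seg.end, seg.founders) == (100, 900, (2, 5))

    def test_boundary_at_midpoint(self):
        probs = np.zeros((2, 36))
        probs[0, S36.index(0, 0)] = 1.0
        probs[1, S36.index(1, 1)] = 1.0
        track = hp.StateProbabilityTrack(markers=_mm([1000, 2000]), probs=probs)
        mosaic = hp.mosaic_from_track(track)
        assert mosaic.segments[0].end == 1500
        assert mosaic.segments[1].start == 1501

    def test_low_posterior_flagged_uncertain(self):
        probs = np.full((3, 36), (1 - 0.3) / 35)
        probs[:, 0] = 0.3
        track = hp.StateProbabilityTrack(markers=_mm([10, 20, 30]), probs=probs)
        mosaic = hp.mosaic_from_track(track, min_posterior=0.5)
        assert mosaic.segments[0].uncertain

    def test_recovers_simulated_mosaic(self, dense_panel):
        g = simdata.simulate_cc_strain(dense_panel, Pedigree(tuple(range(8)), 6, seed=42),
                                       crossover_rate_per_bp=1e-5)
        calls = simdata.emit_array_genotypes(g, dense_panel, seed=9)
        track = hp.forward_backward(
            list(calls), dense_panel.markers, dense_panel.marker_alleles,
            hp.HmmParams(epsilon=0.005, rho=2e-5),
        )
        mosaic = hp.mosaic_from_track(track)
        spacing = 1_000_000 / 2000
        truth = simdata.strain_segments(g)["chr1"]
        positions = dense_panel.markers["position"].to_numpy()
        # the recovered mosaic agrees with the true diplotype over almost
        # all of the assayed span; disagreement is confined to narrow
        # bands at segment boundaries, whose placement is limited by the
        # density of markers that discriminate the two flanking states
        # (between a quarter and three quarters of all markers, depending
        # on the state pair), not by the raw marker spacing
        grid = np.arange(positions[0], positions[-1], 500)
        agree = 0
        for pos in grid:
            true_pair = g.diplotype_at("chr1", int(pos))
            rec = mosaic.founder_pair_at(int(pos))
            agree += rec == true_pair
        # this realization has ~70 true boundaries; at 1-2 effective
        # spacings of blur each, up to ~5-6% of the span sits in boundary
        # bands, bounding achievable agreement near 0.94
        assert agree / len(grid) >= 0.93
        # boundaries between adjacent well-resolved segments land within a
        # few effective marker spacings of the truth
        resolvable = [
            (s, e, p) for s, e, p in truth if e - s + 1 >= 5 * spacing
        ]
        recovered_bounds = [seg.start for seg in mosaic.segments[1:]]
        errors = [
            min(abs(s2 - r) for r in recovered_bounds)
            for (s1, e1, p1), (s2, e2, p2) in zip(resolvable, resolvable[1:])
            if e1 + 1 == s2  # truly adjacent, no unresolvable sliver between
        ]
        assert errors and np.mean(errors) <= 4 * spacing
        assert max(errors) <= 15 * spacing

    def test_recovery_rate_on_noisy_genotypes(self, dense_panel):
        g = simdata.simulate_cc_strain(dense_panel, Pedigree(tuple(range(8)), 6, seed=42),
                                       crossover_rate_per_bp=1e-5)
        calls = simdata.emit_array_genotypes(g, dense_panel, error_rate=0.005, seed=9)
        track = hp.forward_backward(
            list(calls), dense_panel.markers, dense_panel.marker_alleles,
            hp.HmmParams(epsilon=0.005, rho=2e-5),
        )
        am = track.probs.argmax(axis=1)
        truth = np.array(
            [
                S36.index(*g.diplotype_at(row["chromosome"], row["position"]))
                for _, row in dense_panel.markers.iterrows()
            ]
        )
        assert (am == truth).mean() >= 0.95
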