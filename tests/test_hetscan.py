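"""Residual-heterozygosity estimation: marker filters, trio evidence,
cluster combining, the genome-fraction estimator, and identity matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccmosaic import hetscan, simdata
from ccmosaic.founders import FOUNDER_IDS
from ccmosaic.genio import GenotypeMatrix
from ccmosaic.simdata import Pedigree


def _marker_map(positions, chrom="chr1"):
    idx = pd.Index([f"m{i}" for i in range(len(positions))], name="marker")
    return pd.DataFrame({"chromosome": chrom, "position": positions}, index=idx)


def _gm(calls_by_sample, positions=None, chrom="chr1"):
    n = len(next(iter(calls_by_sample.values())))
    mm = _marker_map(positions or [100 * (i + 1) for i in range(n)], chrom)
    return GenotypeMatrix(markers=mm, calls=pd.DataFrame(calls_by_sample, index=mm.index))


class TestMarkerSelection:
    def _founder_fixture(self, rows):
        # two replicates per founder; rows: per marker, dict founder -> pair of calls
        samples = {}
        for f in FOUNDER_IDS:
            for rep in (0, 1):
                samples[f"{f}_r{rep}"] = [row[f][rep] for row in rows]
        gm = _gm(samples)
        mapping = {f"{f}_r{rep}": f for f in FOUNDER_IDS for rep in (0, 1)}
        return gm, mapping

    def test_filters_drop_and_retain(self):
        clean = {f: ("A", "A") for f in FOUNDER_IDS[:4]} | {f: ("G", "G") for f in FOUNDER_IDS[4:]}
        triallelic = dict(clean) | {"A/J": ("C", "C")}
        monomorphic = {f: ("A", "A") for f in FOUNDER_IDS}
        with_n = dict(clean) | {"PWK/PhJ": ("N", "N")}
        discordant = dict(clean) | {"WSB/EiJ": ("G", "A")}
        gm, mapping = self._founder_fixture([clean, triallelic, monomorphic, with_n, discordant])
        f1 = _gm({"f1_AxF": ["H", "A", "A", "A", "A"]}, positions=gm.markers["position"].tolist())
        result = hetscan.select_informative_markers(
            gm, mapping, f1, {"f1_AxF": ("A/J", "CAST/EiJ")}
        )
        assert list(result.markers.index) == ["m0"]
        assert result.drop_counts == {
            "biallelic": 1, "informative": 1, "founder_hn": 1,
            "replicate_discordant": 1, "f1_mismatch": 0,
        }
        assert result.founder_alleles.loc["m0", "A/J"] == "A"

    def test_f1_mismatch_filter(self):
        clean = {f: ("A", "A") for f in FOUNDER_IDS[:4]} | {f: ("G", "G") for f in FOUNDER_IDS[4:]}
        gm, mapping = self._founder_fixture([clean])
        f1 = _gm({"f1_AxF": ["A"]})  # A/J x CAST/EiJ must call H
        result = hetscan.select_informative_markers(
            gm, mapping, f1, {"f1_AxF": ("A/J", "CAST/EiJ")}
        )
        assert len(result.markers) == 0
        assert result.drop_counts["f1_mismatch"] == 1

    def test_planted_violations_bookkeeping(self):
        rng = np.random.default_rng(0)
        rows, n_clean = [], 0
        for _ in range(50):
            alleles = rng.choice(["A", "G"], size=8)
            while len(set(alleles)) < 2:
                alleles = rng.choice(["A", "G"], size=8)
            row = {f: (a, a) for f, a in zip(FOUNDER_IDS, alleles)}
            if rng.random() < 0.2:
                row[FOUNDER_IDS[int(rng.integers(8))]] = ("N", "N")
            else:
                n_clean += 1
            rows.append(row)
        gm, mapping = self._founder_fixture(rows)
        result = hetscan.select_informative_markers(gm, mapping)
        assert len(result.markers) == n_clean


class TestTrioEvidence:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (("A", "A", "A"), False),
            (("A", "H", "A"), True),
            (("A", "A", "G"), True),
            (("A", "N", "A"), False),
            (("N", "N", "N"), None),
            (("N", "N", "H"), True),
        ],
    )
    def test_evidence_rule(self, calls, expected):
        assert hetscan.trio_marker_evidence(calls) is expected

    def test_arity_checked(self):
        with pytest.raises(ValueError):
            hetscan.trio_marker_evidence(("A", "A"))


class TestClustering:
    def test_single_run_span(self):
        mm = _marker_map([10, 20, 30, 40, 50])
        ev = pd.Series([False, True, True, True, False], index=mm.index)
        track = hetscan.cluster_evidence(ev, mm)
        assert len(track.clusters) == 1
        c = track.clusters[0]
        assert (c.first_pos, c.last_pos, c.span_bp) == (20, 40, 21)

    def test_no_flags_zero_clusters_zero_fraction(self):
        mm = _marker_map([10, 20, 30])
        ev = pd.Series([False, False, False], index=mm.index)
        track = hetscan.cluster_evidence(ev, mm)
        est = hetscan.estimate_het_fraction(track, mm)
        assert track.clusters == [] and est.fraction == 0.0

    def test_strict_mode_splits_at_single_unflagged_marker(self):
        mm = _marker_map([10, 20, 30, 40, 50])
        ev = pd.Series([True, True, False, True, True], index=mm.index)
        strict = hetscan.cluster_evidence(ev, mm, max_gap_markers=0)
        assert len(strict.clusters) == 2
        bridged = hetscan.cluster_evidence(ev, mm)  # default tolerance bridges
        assert len(bridged.clusters) == 1

    def test_singleton_span_is_mean_spacing(self):
        mm = _marker_map([100, 200, 300, 400, 500])
        ev = pd.Series([False, False, True, False, False], index=mm.index)
        track = hetscan.cluster_evidence(ev, mm, max_gap_markers=0)
        assert track.clusters[0].span_bp == 100

    def test_all_n_markers_leave_denominator(self):
        mm = _marker_map([10, 100, 200, 5000])
        ev = pd.Series([True, True, None, None], index=mm.index)
        track = hetscan.cluster_evidence(ev, mm)
        assert track.assayed_span_bp == 91  # span of assayed markers only

    def test_undefined_estimate_without_assayed_markers(self):
        mm = _marker_map([10, 20])
        ev = pd.Series([None, None], index=mm.index, dtype=object)
        track = hetscan.cluster_evidence(ev, mm)
        with pytest.raises(hetscan.UndefinedEstimateError):
            hetscan.estimate_het_fraction(track, mm)


class TestEstimator:
    def test_fully_inbred_zero_noise_estimates_zero(self, small_panel):
        g = simdata.simulate_cc_strain(small_panel, Pedigree(tuple(range(8)), 200, seed=2))
        calls = [simdata.emit_array_genotypes(g, small_panel, seed=i) for i in range(3)]
        trio = pd.concat(calls, axis=1)
        trio.columns = ["a", "b", "c"]
        est = hetscan.trio_het_estimate(trio, small_panel.markers)
        assert est.fraction == 0.0

    def test_adding_h_call_never_decreases_fraction(self):
        rng = np.random.default_rng(3)
        mm = _marker_map(sorted(rng.choice(100_000, size=60, replace=False) + 1))
        calls = pd.DataFrame(
            rng.choice(["A", "G", "H", "N"], size=(60, 3), p=[0.45, 0.4, 0.1, 0.05]),
            index=mm.index, columns=["a", "b", "c"],
        )
        base = hetscan.trio_het_estimate(calls, mm).fraction
        for m in range(0, 60, 7):
            if calls.iloc[m].eq("N").all():
                continue  # flipping an unassayed marker changes the denominator too
            bumped = calls.copy()
            bumped.iloc[m, 0] = "H"
            assert hetscan.trio_het_estimate(bumped, mm).fraction >= base - 1e-12


class TestConcordance:
    def test_basic_values(self):
        a = pd.Series(["A", "G", "H", "N", "A"], index=[f"m{i}" for i in range(5)])
        b = pd.Series(["A", "G", "H", "A", "N"], index=a.index)
        assert hetscan.concordance(a, a) == 1.0
        assert hetscan.concordance(a, b) == 1.0  # N pairs excluded
        c = pd.Series(["G", "A", "A", "A", "G"], index=a.index)
        assert hetscan.concordance(a, c) == 0.0

    def test_half_matching(self):
        a = pd.Series(list("AAAAAGGGGG"), index=[f"m{i}" for i in range(10)])
        b = pd.Series(list("AAAAAAAAAA"), index=a.index)
        assert hetscan.concordance(a, b) == 0.5

    @given(st.lists(st.tuples(st.sampled_from("AGHN"), st.sampled_from("AGHN")), min_size=1, max_size=30))
    def test_symmetry(self, pairs):
        idx = [f"m{i}" for i in range(len(pairs))]
        a = pd.Series([p[0] for p in pairs], index=idx)
        b = pd.Series([p[1] for p in pairs], index=idx)
        try:
            ab = hetscan.concordance(a, b)
        except hetscan.UndefinedEstimateError:
            with pytest.raises(hetscan.UndefinedEstimateError):
                hetscan.concordance(b, a)
            return
        assert ab == hetscan.concordance(b, a)

    def test_no_comparable_markers_raises(self):
        a = pd.Series(["N", "N"], index=["m0", "m1"])
        with pytest.raises(hetscan.UndefinedEstimateError):
            hetscan.concordance(a, a)


class TestStrainMatching:
    def _reference_panel(self, panel, genomes):
        cols = {
            name: simdata.emit_array_genotypes(g, panel, seed=7_000 + i)
            for i, (name, g) in enumerate(genomes.items())
        }
        return pd.DataFrame(cols)

    def test_noisy_sample_matches_its_strain(self, small_panel):
        genomes = {
            f"S{i}": simdata.simulate_cc_strain(
                small_panel, Pedigree(simdata.random_funnel(np.random.default_rng(i)), 20, seed=i)
            )
            for i in range(5)
        }
        ref = self._reference_panel(small_panel, genomes)
        hits = 0
        for t in range(20):
            target = f"S{t % 5}"
            sample = simdata.emit_array_genotypes(
                genomes[target], small_panel, error_rate=0.01, seed=500 + t
            )
            res = hetscan.match_sample_to_strain(sample, ref)
            hits += res.best == [target]
        assert hits == 20

    def test_tie_reported_not_resolved(self):
        idx = [f"m{i}" for i in range(4)]
        ref = pd.DataFrame({"S1": ["A", "G", "A", "G"], "S2": ["A", "G", "A", "G"]}, index=idx)
        sample = pd.Series(["A", "G", "A", "G"], index=idx)
        res = hetscan.match_sample_to_strain(sample, ref)
        assert sorted(res.best) == ["S1", "S2"]

    def test_unrelated_sample_flagged(self, small_panel):
        genomes = {
            f"S{i}": simdata.simulate_cc_strain(
                small_panel, Pedigree(simdata.random_funnel(np.random.default_rng(i)), 20, seed=i)
            )
            for i in range(5)
        }
        ref = self._reference_panel(small_panel, genomes)
        rng = np.random.default_rng(99)
        sample = pd.Series(
            rng.choice(["A", "C", "G", "T"], size=len(ref)), index=ref.index
        )
        res = hetscan.match_sample_to_strain(sample, ref)
        assert res.flagged

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            hetscan.match_sample_to_strain(pd.Series(dtype=object), pd.DataFrame())
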