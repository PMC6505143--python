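"""End-to-end calibration experiments on synthetic CC data.

Each routine regenerates its inputs from a seed, runs one pipeline stage
at the study's desk-scale conditions, and returns the measured quantity:
forward-backward exactness against path enumeration, ancestor-merge
behavior, implanted-deletion recall and breakpoint accuracy, residual-
heterozygosity estimator error, sib-mating decay calibration, and the
enrichment test's type-I error. The analysis drivers and the acceptance
script report these numbers; the test suite asserts on them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import delscan, haprecon as hp, hetscan, popstats, simdata
from .simdata import Pedigree


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# forward-backward vs exhaustive path enumeration
# ---------------------------------------------------------------------------


def _enumerate_marginals(calls, positions, alleles, params, space):
    """Exact posterior marginals by summing over every state path."""
    n, k = len(calls), space.n_states
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


def forward_backward_enumeration_gap(seed: int = 0, n_trials: int = 10) -> float:
    """Largest absolute difference between forward-backward posteriors and
    exhaustive path enumeration on 3-founder, 4-marker instances."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    space = hp.DiplotypeStateSpace(3)
    params = hp.HmmParams(epsilon=0.02, rho=2e-4)
    worst = 0.0
    for _ in range(n_trials):
        n = 4
        positions = np.sort(rng.choice(20_000, size=n, replace=False) + 1)
        alleles = rng.choice(["A", "G"], size=(n, 3))
        while any(len(set(row)) < 2 for row in alleles):
            alleles = rng.choice(["A", "G"], size=(n, 3))
        calls = [str(rng.choice(["A", "G", "H", "N"])) for _ in range(n)]
        mm = pd.DataFrame(
            {"chromosome": "chr1", "position": positions},
            index=pd.Index([f"m{i}" for i in range(n)], name="marker"),
        )
        track = hp.forward_backward(calls, mm, alleles, params)
        oracle = _enumerate_marginals(calls, positions, alleles, params, space)
        worst = max(worst, float(np.abs(track.probs - oracle).max()))
    return worst


# ---------------------------------------------------------------------------
# ancestor merging
# ---------------------------------------------------------------------------


def merge_rule_checks(seed: int = 0) -> dict:
    """The two-ancestor redistribution worked example and an idempotence
    probe on a random normalized vector."""
    s = hp.STATE_SPACE_36
    v1 = np.zeros(36)
    v1[s.index(0, 0)] = 0.9
    v1[s.index(0, 1)] = 0.1
    v2 = np.zeros(36)
    v2[s.index(1, 1)] = 0.8
    v2[s.index(0, 1)] = 0.2
    merged = hp.merge_ancestors([v1, v2])
    rng = np.random.default_rng(_child_seed(seed, 2))
    v = rng.dirichlet(np.ones(36))
    idem_dev = float(np.abs(hp.merge_ancestors([v, v]) - v).max())
    return {
        "het_state_probability": float(merged[s.index(0, 1)]),
        "off_target_mass": float(merged.sum() - merged[s.index(0, 1)]),
        "idempotence_deviation": idem_dev,
    }


# ---------------------------------------------------------------------------
# implanted-deletion recall
# ---------------------------------------------------------------------------


def deletion_benchmark(
    seed: int = 0,
    n_seeds: int = 10,
    depth: float = 10.0,
    error_rate: float = 0.002,
    sizes=(600, 2_000, 20_000),
) -> dict:
    """Recall and breakpoint accuracy for implanted strain-private
    homozygous deletions on a 100 kb template.

    Truth intervals are leftmost-normalized before comparison, matching
    the caller's micro-homology convention.
    """
    found = total = 0
    worst_bp_error = 0
    false_calls = 0
    for rep in range(n_seeds):
        ref = simdata.random_sequence(100_000, seed=_child_seed(seed, 100 + rep))
        dels = ((15_001, 15_000 + sizes[0]),
                (40_001, 40_000 + sizes[1]),
                (60_001, 60_000 + sizes[2]))
        rs = simdata.simulate_reads(
            ref, 150, depth, error_rate, seed=_child_seed(seed, 200 + rep),
            implanted_deletions=dels,
        )
        calls, _, _ = delscan.scan_for_deletions(ref, rs.reads)
        matched = set()
        for s, e in dels:
            total += 1
            a, b = delscan._leftmost(ref, s - 1, e)
            best = None
            for i, c in enumerate(calls):
                err = abs(c.resolved_start - (a + 1)) + abs(c.resolved_end - b)
                if best is None or err < best[0]:
                    best = (err, i)
            if best is not None and best[0] <= (e - s + 1) // 2:
                found += 1
                matched.add(best[1])
                worst_bp_error = max(worst_bp_error, best[0])
        false_calls += len(calls) - len(matched)
    return {
        "recall": found / total,
        "max_breakpoint_error_bp": worst_bp_error,
        "false_calls": false_calls,
        "n": total,
    }


# ---------------------------------------------------------------------------
# residual-heterozygosity estimator accuracy
# ---------------------------------------------------------------------------


def het_estimator_benchmark(
    seed: int = 0, n_strains: int = 20, n_markers: int = 5_000
) -> dict:
    """Mean absolute error of the trio heterozygosity estimator against
    the simulator's realized fraction, at zero genotyping noise."""
    panel = simdata.simulate_founder_panel(
        2, 1_000_000, n_markers // 2, allele_seed=_child_seed(seed, 3)
    )
    errors = []
    for i in range(n_strains):
        ped = Pedigree(
            simdata.random_funnel(np.random.default_rng(_child_seed(seed, 400 + i))),
            6, seed=_child_seed(seed, 500 + i),
        )
        genome = simdata.simulate_cc_strain(panel, ped, crossover_rate_per_bp=1e-5)
        trio = pd.concat(
            [
                simdata.emit_array_genotypes(genome, panel, seed=_child_seed(seed, 600 + 3 * i + j))
                for j in range(3)
            ],
            axis=1,
        )
        trio.columns = ["m1", "m2", "m3"]
        est = hetscan.trio_het_estimate(trio, panel.markers)
        errors.append(abs(est.fraction - genome.realized_het_fraction))
    return {"mae": float(np.mean(errors)), "n": n_strains}


# ---------------------------------------------------------------------------
# sib-mating heterozygosity decay
# ---------------------------------------------------------------------------


def het_decay_benchmark(
    seed: int = 0, n_replicates: int = 2_000, generations=(2, 5, 10)
) -> dict:
    """Monte-Carlo mean heterozygosity under the funnel + sib-mating
    design versus the exact recurrence, as z-scores (mean difference over
    the Monte-Carlo standard error)."""
    panel = simdata.simulate_founder_panel(1, 100_000, 10, allele_seed=_child_seed(seed, 4))
    out = {}
    for g in generations:
        vals = np.array(
            [
                simdata.simulate_cc_strain(
                    panel, Pedigree(tuple(range(8)), g, seed=_child_seed(seed, 1_000_000 * g + r))
                ).realized_het_fraction
                for r in range(n_replicates)
            ]
        )
        expected = simdata.sib_mating_het_expectation(g)
        se = float(vals.std(ddof=1) / np.sqrt(n_replicates))
        out[g] = {
            "mc_mean": float(vals.mean()),
            "exact": expected,
            "z": float((vals.mean() - expected) / se),
        }
    out["max_abs_z"] = max(abs(v["z"]) for k, v in out.items() if isinstance(v, dict))
    out["n"] = n_replicates
    return out


# ---------------------------------------------------------------------------
# enrichment-test calibration
# ---------------------------------------------------------------------------


def enrichment_type1_benchmark(
    seed: int = 0,
    n_datasets: int = 200,
    n_strains: int = 8,
    n_permutations: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the wild-derived enrichment test on null
    populations where heterozygous intervals are independent of founder
    identity (the neutral breeding simulator).

    With m permutations the smallest achievable p is 1/(m+1), so the exact
    attainable level at alpha = 0.05 is floor(alpha (m+1)) / (m+1).
    """
    panel = simdata.simulate_founder_panel(1, 100_000, 10, allele_seed=_child_seed(seed, 5))
    rejections = tested = 0
    for rep in range(n_datasets):
        strains, het = {}, {}
        for i in range(n_strains):
            s = _child_seed(seed, 10_000 + rep * 100 + i)
            ped = Pedigree(simdata.random_funnel(np.random.default_rng(s)), 6, seed=s)
            genome = simdata.simulate_cc_strain(panel, ped)
            strains[f"S{i}"] = simdata.strain_segments(genome)
            ivs = genome.het_segments("chr1")
            if ivs:
                het[f"S{i}"] = {"chr1": ivs}
        try:
            res = popstats.wild_enrichment_test(
                strains, het, panel.chrom_lengths,
                n_permutations=n_permutations, seed=_child_seed(seed, 20_000 + rep),
            )
        except popstats.UndefinedTestError:
            continue
        tested += 1
        rejections += res.p_value < alpha
    # p-values live on {1/(m+1), ..., 1}; p < alpha selects the ranks
    # strictly below alpha (m+1), so the attainable level is slightly
    # below nominal (9/200 = 0.045 at alpha 0.05, m 199)
    exact_level = (int(np.ceil(alpha * (n_permutations + 1))) - 1) / (n_permutations + 1)
    return {
        "rate": rejections / tested,
        "nominal": alpha,
        "exact_attainable_level": exact_level,
        "n": tested,
    }
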