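"""Founder-contribution accounting and wild-derived enrichment testing.

Works on per-strain diplotype mosaics represented as
``{chrom: [(start, end, (f, g)), ...]}`` with 1-based inclusive segments
and unordered founder-index pairs — the shape produced both by the
simulator's ground truth (`simdata.strain_segments`) and by reconstructed
mosaics (`mosaic_segments`).

A heterozygous segment contributes half its length to each of its two
founders, so each strain's eight founder frequencies sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founders import FOUNDER_IDS, N_FOUNDERS, WILD_DERIVED_INDICES
from .haprecon import ChromosomeMosaic

StrainSegments = dict[str, list[tuple[int, int, tuple[int, int]]]]


class UndefinedTestError(ValueError):
    pass


def mosaic_segments(mosaics: list[ChromosomeMosaic]) -> StrainSegments:
    """Adapt reconstructed chromosome mosaics to the segment-dict shape."""
    return {
        m.chrom: [(s.start, s.end, s.founders) for s in m.segments] for m in mosaics
    }


def founder_frequencies(segments: StrainSegments) -> np.ndarray:
    """Per-strain founder frequencies: founder F gets the homozygous-F
    length plus half of every heterozygous length involving F, over the
    assayed length."""
    length = np.zeros(N_FOUNDERS)
    total = 0
    for segs in segments.values():
        for start, end, (fa, fb) in segs:
            n = end - start + 1
            total += n
            if fa == fb:
                length[fa] += n
            else:
                length[fa] += n / 2
                length[fb] += n / 2
    if total == 0:
        raise ValueError("empty mosaic")
    return length / total


def founder_frequency_table(strains: dict[str, StrainSegments]) -> pd.DataFrame:
    """Per-strain founder-frequency table (one row per strain, one column
    per founder, plus the across-strain average row)."""
    rows = {name: founder_frequencies(segs) for name, segs in strains.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FOUNDER_IDS))
    df.loc["Average"] = df.mean(axis=0)
    return df


def _dosage_at(segments, pos: int) -> np.ndarray | None:
    for start, end, (fa, fb) in segments:
        if start <= pos <= end:
            d = np.zeros(N_FOUNDERS)
            d[fa] += 0.5
            d[fb] += 0.5
            return d
    return None


def population_locus_frequency(
    strains: dict[str, StrainSegments], chrom: str, grid_positions
) -> pd.DataFrame:
    """Founder frequencies across strains at each grid position of one
    chromosome (mean diploid dosage: 1, 1/2 or 0 per strain). Positions
    outside every strain's assayed span are excluded."""
    rows = []
    kept = []
    for pos in grid_positions:
        dosages = []
        for segs in strains.values():
            d = _dosage_at(segs.get(chrom, []), pos)
            if d is not None:
                dosages.append(d)
        if not dosages:
            continue
        kept.append(pos)
        rows.append(np.mean(dosages, axis=0))
    return pd.DataFrame(rows, index=pd.Index(kept, name="position"), columns=list(FOUNDER_IDS))


# ---------------------------------------------------------------------------
# wild-derived enrichment in heterozygous regions
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    observed: float  # wild dosage-length inside het intervals (bp)
    expected: float  # mean of the permutation null
    p_value: float
    n_permutations: int
    seed: int


def _wild_length_profile(segments, wild_set) -> list[tuple[int, int, float]]:
    """Per segment: (start, end, wild dosage in {0, 1/2, 1})."""
    out = []
    for start, end, (fa, fb) in segments:
        d = (0.5 if fa in wild_set else 0.0) + (0.5 if fb in wild_set else 0.0)
        out.append((start, end, d))
    return out


def _overlap_statistic(profile, intervals, chrom_len: int, offset: int = 0) -> float:
    """Wild dosage-length of ``profile`` inside ``intervals`` rotated
    circularly by ``offset`` on a chromosome of length ``chrom_len``."""
    total = 0.0
    for s, e, d in profile:
        if d == 0.0:
            continue
        for a, b in intervals:
            length = b - a
            a = (a - 1 + offset) % chrom_len + 1
            b2 = a + length
            pieces = [(a, b2)] if b2 <= chrom_len else [(a, chrom_len), (1, b2 - chrom_len)]
            for pa, pb in pieces:
                lo, hi = max(s, pa), min(e, pb)
                if lo <= hi:
                    total += d * (hi - lo + 1)
    return total


def wild_enrichment_test(
    strains: dict[str, StrainSegments],
    het_intervals: dict[str, dict[str, list[tuple[int, int]]]],
    chrom_lengths: dict[str, int],
    wild_set=WILD_DERIVED_INDICES,
    n_permutations: int = 999,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for enrichment of wild-derived haplotypes inside
    regions of residual heterozygosity.

    The statistic is the total wild-derived dosage-length falling inside
    heterozygous intervals, summed over strains. The null rotates each
    strain's het intervals circularly and independently per chromosome,
    preserving interval number, lengths and chromosome structure;
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    wild_set = set(wild_set)
    jobs = []  # (profile, intervals, chrom_len)
    for name, segs in strains.items():
        ivs_by_chrom = het_intervals.get(name, {})
        for chrom, segments in segs.items():
            ivs = ivs_by_chrom.get(chrom, [])
            if not ivs:
                continue
            profile = _wild_length_profile(segments, wild_set)
            jobs.append((profile, ivs, chrom_lengths[chrom]))
    if not jobs:
        raise UndefinedTestError("no heterozygous intervals to test")
    observed = sum(_overlap_statistic(p, ivs, L) for p, ivs, L in jobs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for it in range(n_permutations):
        total = 0.0
        for profile, ivs, L in jobs:
            total += _overlap_statistic(profile, ivs, L, offset=int(rng.integers(0, L)))
        null[it] = total
    p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return EnrichmentResult(
        observed=float(observed), expected=float(null.mean()), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# founder representation gaps
# ---------------------------------------------------------------------------


def min_founder_representation(
    strains: dict[str, StrainSegments], chrom: str, grid_positions
) -> tuple[pd.DataFrame, dict[str, list[tuple[int, int]]]]:
    """Per grid position and founder, the number of strains carrying at
    least half a dose; plus, per founder, the maximal grid runs with zero
    carriers (reported as position intervals)."""
    grid_positions = list(grid_positions)
    counts = np.zeros((len(grid_positions), N_FOUNDERS), dtype=int)
    for segs in strains.values():
        for i, pos in enumerate(grid_positions):
            d = _dosage_at(segs.get(chrom, []), pos)
            if d is not None:
                counts[i] += (d >= 0.5).astype(int)
    df = pd.DataFrame(counts, index=pd.Index(grid_positions, name="position"),
                      columns=list(FOUNDER_IDS))
    uncovered: dict[str, list[tuple[int, int]]] = {}
    for fi, fid in enumerate(FOUNDER_IDS):
        runs = []
        i = 0
        while i < len(grid_positions):
            if counts[i, fi] > 0:
                i += 1
                continue
            j = i
            while j + 1 < len(grid_positions) and counts[j + 1, fi] == 0:
                j += 1
            runs.append((grid_positions[i], grid_positions[j]))
            i = j + 1
        uncovered[fid] = runs
    return df, uncovered
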