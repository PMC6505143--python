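"""Synthetic Collaborative Cross data generator.

Produces the objects every downstream stage consumes, with known ground
truth: an eight-founder panel with informative biallelic markers, CC
funnel pedigrees (two generations of outcrossing followed by brother x
sister inbreeding) realized as founder-mosaic diploid genomes, array-style
genotype calls with configurable error/H/N corruption, and short reads
with implanted deletions.

Coordinates are 1-based inclusive throughout; haplotypes are ordered
segment lists ``(start, end, founder_index)`` tiling each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FOUNDER_IDS, N_FOUNDERS

# a haplotype is a list of (start, end, founder_index), 1-based inclusive
Segment = tuple[int, int, int]
Haplotype = list[Segment]

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderPanel:
    """Eight synthetic founder genomes plus an informative marker set.

    ``sequences[founder][chrom]`` is the founder's chromosome sequence;
    founders share a common backbone and differ at marker positions, where
    ``marker_alleles`` stores the per-founder allele (8 columns in canonical
    founder order). Every marker is biallelic and informative (both alleles
    present among the founders) and founders never carry H or N.
    """

    founder_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    chrom_lengths: dict[str, int]
    sequences: dict[str, dict[str, str]]
    markers: pd.DataFrame  # index marker_id; columns: chromosome, position
    marker_alleles: np.ndarray  # (n_markers, 8) of single characters

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def alleles_for_chrom(self, chrom: str) -> tuple[pd.DataFrame, np.ndarray]:
        mask = (self.markers["chromosome"] == chrom).to_numpy()
        return self.markers.loc[mask], self.marker_alleles[mask]


def simulate_founder_panel(
    n_chromosomes: int = 1,
    chrom_length_bp: int = 100_000,
    n_markers: int = 100,
    allele_seed: int = 0,
    include_x: bool = False,
) -> FounderPanel:
    """Generate a synthetic eight-founder panel.

    Parameters
    ----------
    n_chromosomes : number of autosomes.
    chrom_length_bp : length of every chromosome (>= 1000).
    n_markers : markers per chromosome (>= 2); positions are strictly
        increasing and seed-reproducible.
    allele_seed : RNG seed.
    include_x : append an "X" chromosome (same length and marker count).
    """
    if n_chromosomes < 1 or n_markers < 2 or chrom_length_bp < 1000:
        raise ValueError(
            "need n_chromosomes >= 1, n_markers >= 2, chrom_length_bp >= 1000"
        )
    rng = np.random.default_rng(allele_seed)
    chroms = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    if include_x:
        chroms = chroms + ("chrX",)
    chrom_lengths = {c: int(chrom_length_bp) for c in chroms}

    backbone = {
        c: "".join(rng.choice(list(ALPHABET), size=chrom_length_bp))
        for c in chroms
    }

    rows = []
    allele_rows = []
    for c in chroms:
        positions = np.sort(
            rng.choice(np.arange(1, chrom_length_bp + 1), size=n_markers, replace=False)
        )
        for j, pos in enumerate(positions):
            ref, alt = rng.choice(list(ALPHABET), size=2, replace=False)
            # random biallelic assignment, redrawn until informative
            while True:
                is_alt = rng.random(N_FOUNDERS) < 0.5
                if is_alt.any() and not is_alt.all():
                    break
            alleles = np.where(is_alt, alt, ref)
            rows.append((f"{c}_m{j:05d}", c, int(pos)))
            allele_rows.append(alleles)
    markers = pd.DataFrame(rows, columns=["marker", "chromosome", "position"])
    markers = markers.set_index("marker")
    marker_alleles = np.array(allele_rows)

    sequences: dict[str, dict[str, str]] = {}
    for fi, fid in enumerate(FOUNDER_IDS):
        sequences[fid] = {}
        for c in chroms:
            seq = list(backbone[c])
            sub = markers["chromosome"] == c
            for pos, allele in zip(
                markers.loc[sub, "position"], marker_alleles[sub.to_numpy(), fi]
            ):
                seq[pos - 1] = allele
            sequences[fid][c] = "".join(seq)

    return FounderPanel(
        founder_ids=FOUNDER_IDS,
        chromosomes=chroms,
        chrom_lengths=chrom_lengths,
        sequences=sequences,
        markers=markers,
        marker_alleles=marker_alleles,
    )


# ---------------------------------------------------------------------------
# pedigree and breeding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pedigree:
    """A CC funnel: founder order, inbreeding depth, and RNG seed."""

    funnel_order: tuple[int, ...] = tuple(range(8))
    n_inbreeding_generations: int = 0
    seed: int = 0

    def __post_init__(self):
        if sorted(self.funnel_order) != list(range(8)):
            raise ValueError("funnel_order must be a permutation of 0..7")
        if self.n_inbreeding_generations < 0:
            raise ValueError("n_inbreeding_generations must be >= 0")


@dataclass
class Individual:
    """A diploid mosaic genome: per chromosome a pair of haplotypes.

    Males carry a single X haplotype (stored as a 1-tuple).
    """

    haplotypes: dict[str, tuple[Haplotype, ...]]
    sex: str = "female"


@dataclass
class TrueStrainGenome:
    """Ground-truth realized genome of a simulated CC strain."""

    haplotypes: dict[str, tuple[Haplotype, ...]]
    sex: str
    realized_het_fraction: float
    pedigree: Pedigree | None = None

    def het_segments(self, chrom: str) -> list[tuple[int, int]]:
        """Intervals (1-based inclusive) where the two haplotypes carry
        different founders; empty for hemizygous chromosomes."""
        haps = self.haplotypes[chrom]
        if len(haps) < 2:
            return []
        out = []
        for start, end, fa, fb in _paired_segments(haps[0], haps[1]):
            if fa != fb:
                if out and out[-1][1] == start - 1:
                    out[-1] = (out[-1][0], end)
                else:
                    out.append((start, end))
        return out

    def diplotype_at(self, chrom: str, pos: int) -> tuple[int, int]:
        haps = self.haplotypes[chrom]
        founders = tuple(_founder_at(h, pos) for h in haps)
        if len(founders) == 1:
            founders = (founders[0], founders[0])
        return (min(founders), max(founders))


def _founder_at(hap: Haplotype, pos: int) -> int:
    for start, end, f in hap:
        if start <= pos <= end:
            return f
    raise ValueError(f"position {pos} outside haplotype")


def _paired_segments(h1: Haplotype, h2: Haplotype):
    """Iterate the common refinement of two haplotypes as
    (start, end, founder1, founder2)."""
    i = j = 0
    pos = h1[0][0]
    while i < len(h1) and j < len(h2):
        s1, e1, f1 = h1[i]
        s2, e2, f2 = h2[j]
        end = min(e1, e2)
        yield (pos, end, f1, f2)
        pos = end + 1
        if e1 == end:
            i += 1
        if e2 == end:
            j += 1


def _recombine(h1: Haplotype, h2: Haplotype, breakpoints: list[int], first: int) -> Haplotype:
    """Gamete from two haplotypes with crossovers after each breakpoint
    position; ``first`` selects the starting haplotype (0 or 1)."""
    haps = (h1, h2)
    length = h1[-1][1]
    cuts = sorted(b for b in breakpoints if 1 <= b < length)
    out: Haplotype = []
    cur = first
    start = 1
    for b in cuts + [length]:
        for s, e, f in haps[cur]:
            if e < start or s > b:
                continue
            ss, ee = max(s, start), min(e, b)
            if out and out[-1][2] == f and out[-1][1] == ss - 1:
                out[-1] = (out[-1][0], ee, f)
            else:
                out.append((ss, ee, f))
        start = b + 1
        cur = 1 - cur
    return out


def _gamete(haps: tuple[Haplotype, ...], length: int, rng, crossover_rate_per_bp: float) -> Haplotype:
    if len(haps) == 1:  # hemizygous: passed through intact
        return list(haps[0])
    k = rng.poisson(crossover_rate_per_bp * length)
    breakpoints = [int(b) for b in rng.integers(1, length, size=k)] if k else []
    first = int(rng.integers(0, 2))
    return _recombine(haps[0], haps[1], breakpoints, first)


def _cross(mother: Individual, father: Individual, sex: str, panel: FounderPanel,
           rng, rate: float) -> Individual:
    haplotypes = {}
    for c in panel.chromosomes:
        L = panel.chrom_lengths[c]
        if c == "chrX":
            egg = _gamete(mother.haplotypes[c], L, rng, rate)
            if sex == "male":
                haplotypes[c] = (egg,)
            else:
                haplotypes[c] = (egg, list(father.haplotypes[c][0]))
        else:
            haplotypes[c] = (
                _gamete(mother.haplotypes[c], L, rng, rate),
                _gamete(father.haplotypes[c], L, rng, rate),
            )
    return Individual(haplotypes=haplotypes, sex=sex)


def realized_het_fraction(ind: Individual | TrueStrainGenome) -> float:
    """Fraction of the diploid genome where the two haplotypes carry
    different founder ids (hemizygous chromosomes excluded)."""
    het = tot = 0
    for c, haps in ind.haplotypes.items():
        if len(haps) < 2:
            continue
        for start, end, fa, fb in _paired_segments(haps[0], haps[1]):
            tot += end - start + 1
            if fa != fb:
                het += end - start + 1
    return het / tot if tot else 0.0


def _founder_individual(panel: FounderPanel, founder_idx: int, sex: str) -> Individual:
    haplotypes = {}
    for c in panel.chromosomes:
        L = panel.chrom_lengths[c]
        hap: Haplotype = [(1, L, founder_idx)]
        if c == "chrX" and sex == "male":
            haplotypes[c] = (hap,)
        else:
            haplotypes[c] = (list(hap), list(hap))
    return Individual(haplotypes=haplotypes, sex=sex)


def _funnel_g2f1_pair(panel: FounderPanel, pedigree: Pedigree, rng,
                      rate: float) -> tuple[Individual, Individual]:
    """Run the 8-way funnel (AB x CD) x (EF x GH) and return two G2:F1
    full siblings (female, male) — the generation-0 breeding pair."""
    p = pedigree.funnel_order
    g1 = []
    for a, b in ((0, 1), (2, 3), (4, 5), (6, 7)):
        mom = _founder_individual(panel, p[a], "female")
        dad = _founder_individual(panel, p[b], "male")
        g1.append((_cross(mom, dad, "female", panel, rng, rate),
                   _cross(mom, dad, "male", panel, rng, rate)))
    g2_left = _cross(g1[0][0], g1[1][1], "female", panel, rng, rate)
    g2_right = _cross(g1[2][0], g1[3][1], "male", panel, rng, rate)
    sister = _cross(g2_left, g2_right, "female", panel, rng, rate)
    brother = _cross(g2_left, g2_right, "male", panel, rng, rate)
    return sister, brother


def simulate_cc_strain(
    panel: FounderPanel,
    pedigree: Pedigree,
    crossover_rate_per_bp: float = 1.0 / 100_000,
    sex: str = "female",
) -> TrueStrainGenome:
    """Realize one CC strain genome: funnel crosses, then
    ``pedigree.n_inbreeding_generations`` of brother x sister mating.

    Crossovers per meiosis are Poisson with expectation
    ``crossover_rate_per_bp * chromosome_length`` (default one crossover
    per 100 kb synthetic chromosome), placed uniformly, no interference.
    Generation 0 is the G2:F1 itself.
    """
    rng = np.random.default_rng(pedigree.seed)
    sister, brother = _funnel_g2f1_pair(panel, pedigree, rng, crossover_rate_per_bp)
    for _ in range(pedigree.n_inbreeding_generations):
        sister, brother = (
            _cross(sister, brother, "female", panel, rng, crossover_rate_per_bp),
            _cross(sister, brother, "male", panel, rng, crossover_rate_per_bp),
        )
    sampled = sister if sex == "female" else brother
    return TrueStrainGenome(
        haplotypes=sampled.haplotypes,
        sex=sex,
        realized_het_fraction=realized_het_fraction(sampled),
        pedigree=pedigree,
    )


def simulate_strain_with_ancestors(
    panel: FounderPanel,
    pedigree: Pedigree,
    delta_generations: int,
    n_ancestors: int = 3,
    n_descendants: int = 3,
    crossover_rate_per_bp: float = 1.0 / 100_000,
) -> tuple[list[TrueStrainGenome], list[TrueStrainGenome]]:
    """Sample obligate ancestors at generation g and their descendants at
    g + delta, giving nested residual heterozygosity for merge tests.

    The ancestors are full siblings of the generation-g breeding pair;
    every descendant passes through that pair, so the ancestors bound what
    can still segregate downstream.
    """
    rng = np.random.default_rng(pedigree.seed)
    rate = crossover_rate_per_bp
    sister, brother = _funnel_g2f1_pair(panel, pedigree, rng, rate)
    for _ in range(pedigree.n_inbreeding_generations):
        sister, brother = (
            _cross(sister, brother, "female", panel, rng, rate),
            _cross(sister, brother, "male", panel, rng, rate),
        )
    ancestors = [sister, brother]
    while len(ancestors) < n_ancestors:
        ancestors.append(_cross(sister, brother, "female", panel, rng, rate))
    pair = (sister, brother)
    for _ in range(delta_generations):
        pair = (
            _cross(pair[0], pair[1], "female", panel, rng, rate),
            _cross(pair[0], pair[1], "male", panel, rng, rate),
        )
    descendants = [pair[0], pair[1]]
    while len(descendants) < n_descendants:
        descendants.append(_cross(pair[0], pair[1], "female", panel, rng, rate))
    descendants = descendants[:n_descendants]

    def _wrap(ind: Individual) -> TrueStrainGenome:
        return TrueStrainGenome(
            haplotypes=ind.haplotypes,
            sex=ind.sex,
            realized_het_fraction=realized_het_fraction(ind),
            pedigree=pedigree,
        )

    return [_wrap(a) for a in ancestors[:n_ancestors]], [_wrap(d) for d in descendants]


def sib_mating_het_expectation(g: int) -> float:
    """Exact expected heterozygous fraction after g generations of full-sib
    mating, starting from a fully heterozygous G2:F1 (H_0 = 1).

    Iterates the classical recurrence H_t = H_{t-1}/2 + H_{t-2}/4 via its
    generation matrix; the dominant eigenvalue is (1 + sqrt(5))/4 ~ 0.809.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    m = np.array([[0.5, 0.25], [1.0, 0.0]])
    v = np.array([1.0, 1.0])  # (H_0, H_-1)
    for _ in range(g):
        v = m @ v
    return float(v[0])


# ---------------------------------------------------------------------------
# array genotypes
# ---------------------------------------------------------------------------


def emit_array_genotypes(
    genome: TrueStrainGenome,
    panel: FounderPanel,
    error_rate: float = 0.0,
    h_miscall_rate: float = 0.0,
    n_rate: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Array-style genotype calls for one sample at the panel's markers.

    The true call at a marker is the allele implied by the two founder
    haplotypes (H when they differ; hemizygous chromosomes report the
    single allele). Corruption, mutually exclusive per call: a random
    wrong call with ``error_rate``, an H miscall with ``h_miscall_rate``
    (homozygous markers only), an N no-call with ``n_rate``.
    """
    for r in (error_rate, h_miscall_rate, n_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if error_rate + h_miscall_rate + n_rate > 1.0:
        raise ValueError("corruption rates must sum to <= 1")
    rng = np.random.default_rng(seed)
    calls = []
    for (mid, row), alleles in zip(panel.markers.iterrows(), panel.marker_alleles):
        fa, fb = genome.diplotype_at(row["chromosome"], row["position"])
        aa, ab = alleles[fa], alleles[fb]
        true_call = aa if aa == ab else "H"
        u = rng.random()
        call = true_call
        if u < error_rate:
            vocab = sorted(set(alleles)) + ["H"]
            wrong = [v for v in vocab if v != true_call]
            call = wrong[int(rng.integers(0, len(wrong)))]
        elif u < error_rate + h_miscall_rate:
            if true_call != "H":
                call = "H"
        elif u < error_rate + h_miscall_rate + n_rate:
            call = "N"
        calls.append(call)
    return pd.Series(calls, index=panel.markers.index, name="call")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """A bag of fixed-length reads sampled uniformly from both strands."""

    reads: list[str]
    source_genome_id: str
    read_length: int
    depth: float
    error_rate: float
    seed: int
    template_length: int = 0
    deletions: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def simulate_reads(
    sequence: str,
    read_length: int = 150,
    depth: float = 10.0,
    error_rate: float = 0.0,
    seed: int = 0,
    implanted_deletions: tuple[tuple[int, int], ...] = (),
    source_genome_id: str = "synthetic",
) -> ReadSet:
    """Uniform shotgun reads from ``sequence`` after excising deletions.

    ``implanted_deletions`` are non-overlapping 1-based inclusive intervals
    removed from the template before sampling. Read count is
    ``round(depth * template_length / read_length)``; each read comes from
    a uniformly chosen start and strand, with per-base substitution errors
    at ``error_rate``.
    """
    if read_length < 45:
        raise ValueError("read_length must be >= 45")
    dels = sorted(implanted_deletions)
    for i, (s, e) in enumerate(dels):
        if s < 1 or e > len(sequence) or e < s:
            raise ValueError(f"deletion ({s}, {e}) outside sequence")
        if i and s <= dels[i - 1][1]:
            raise ValueError("deletions must be non-overlapping")
    template = sequence
    for s, e in reversed(dels):
        template = template[: s - 1] + template[e:]
    if len(template) < read_length:
        raise ValueError("template shorter than read length")
    rng = np.random.default_rng(seed)
    n_reads = round(depth * len(template) / read_length)
    starts = rng.integers(0, len(template) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads = []
    bases = np.frombuffer(ALPHABET.encode(), dtype="S1")
    for start, rc in zip(starts, strands):
        read = template[start : start + read_length]
        if error_rate > 0:
            n_err = rng.binomial(read_length, error_rate)
            if n_err:
                arr = np.frombuffer(read.encode(), dtype="S1").copy()
                pos = rng.choice(read_length, size=n_err, replace=False)
                for p in pos:
                    choices = bases[bases != arr[p]]
                    arr[p] = choices[int(rng.integers(0, len(choices)))]
                read = arr.tobytes().decode()
        reads.append(revcomp(read) if rc else read)
    return ReadSet(
        reads=reads,
        source_genome_id=source_genome_id,
        read_length=read_length,
        depth=depth,
        error_rate=error_rate,
        seed=seed,
        template_length=len(template),
        deletions=tuple(dels),
    )


def random_sequence(length: int, seed: int = 0) -> str:
    """Uniform random nucleotide sequence (deletion-scan templates)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(ALPHABET), size=length))


def random_funnel(rng) -> tuple[int, ...]:
    """A uniformly random funnel order."""
    return tuple(int(i) for i in rng.permutation(8))


def strain_segments(genome: TrueStrainGenome) -> dict[str, list[tuple[int, int, tuple[int, int]]]]:
    """Collapse a true genome into per-chromosome diplotype segments
    (start, end, unordered founder pair) — the ground-truth mosaic."""
    out: dict[str, list[tuple[int, int, tuple[int, int]]]] = {}
    for c, haps in genome.haplotypes.items():
        segs: list[tuple[int, int, tuple[int, int]]] = []
        if len(haps) == 1:
            pieces = [(s, e, (f, f)) for s, e, f in haps[0]]
        else:
            pieces = [
                (s, e, (min(fa, fb), max(fa, fb)))
                for s, e, fa, fb in _paired_segments(haps[0], haps[1])
            ]
        for s, e, pair in pieces:
            if segs and segs[-1][2] == pair and segs[-1][1] == s - 1:
                segs[-1] = (segs[-1][0], e, pair)
            else:
                segs.append((s, e, pair))
        out[c] = segs
    return out
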