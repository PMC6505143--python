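"""Founder-haplotype reconstruction over the 36 diplotype states.

A CC chromosome is a mosaic of the eight founder haplotypes; at a marker
the diploid state is an unordered founder pair, giving 8 inbred + 28
heterozygous = 36 states. This module provides the emission/transition
model, a numerically stabilized forward-backward pass returning per-marker
posterior state probabilities, linear-interpolation imputation between
marker grids, the obligate-ancestor (MRCA) merging rule with inbred-mass
redistribution, male-X handling (8 inbred states, heterozygous mass fixed
at zero), and segmentation of posterior tracks into haplotype mosaics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FOUNDER_CODES, N_FOUNDERS

logger = logging.getLogger(__name__)


class DiplotypeStateSpace:
    """Canonical ordering of unordered founder-pair states.

    States are the ``n`` inbred pairs (FF) first, then the n(n-1)/2
    heterozygous pairs (FG, F < G) in lexicographic founder order. For the
    CC, n = 8 and there are 36 states.
    """

    def __init__(self, n_founders: int = N_FOUNDERS, codes: str | None = None):
        if n_founders < 2:
            raise ValueError("need at least two founders")
        self.n_founders = n_founders
        self.codes = (codes or FOUNDER_CODES)[:n_founders]
        self.states: list[tuple[int, int]] = [(i, i) for i in range(n_founders)]
        for i in range(n_founders):
            for j in range(i + 1, n_founders):
                self.states.append((i, j))
        self.names = [self.codes[i] + self.codes[j] for i, j in self.states]
        self._index = {s: k for k, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, i: int, j: int) -> int:
        return self._index[(min(i, j), max(i, j))]

    def is_inbred(self, state: int) -> bool:
        return state < self.n_founders


STATE_SPACE_36 = DiplotypeStateSpace(8)
CANONICAL_STATE_NAMES = tuple(STATE_SPACE_36.names)


@dataclass(frozen=True)
class HmmParams:
    """Genotyping error rate and recombination scale of the HMM.

    ``epsilon`` is the per-call genotyping error probability; ``rho`` is
    the expected founder switches per bp per meiosis-equivalent, setting
    the per-haplotype switch probability 1 - exp(-rho * d) over a gap of
    d bp. The defaults suit the synthetic genomes in this package (one
    crossover per 100 kb chromosome).
    """

    epsilon: float = 0.005
    rho: float = 2.0 / 100_000
    prior: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class StateProbabilityTrack:
    """Per-marker posterior probability vectors over diplotype states."""

    markers: pd.DataFrame  # index marker_id; columns chromosome, position
    probs: np.ndarray  # (n_markers, n_states)
    sample_id: str = ""
    chromosome_kind: str = "autosome"  # autosome | female_x | male_x
    space: DiplotypeStateSpace = field(default_factory=lambda: STATE_SPACE_36)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != len(self.markers):
            raise ValueError("probs shape does not match markers")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every probability row must sum to 1")
        if self.chromosome_kind == "male_x":
            het = self.probs[:, self.space.n_founders :]
            if het.size and het.max() > 0:
                raise ValueError("male X track has mass on heterozygous states")


@dataclass
class MosaicSegment:
    chrom: str
    start: int
    end: int
    founders: tuple[int, int]  # unordered pair (f <= g)
    mean_posterior: float
    uncertain: bool = False


@dataclass
class ChromosomeMosaic:
    """Ordered diplotype segments tiling the assayed span of a chromosome."""

    chrom: str
    segments: list[MosaicSegment]

    def founder_pair_at(self, pos: int) -> tuple[int, int] | None:
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg.founders
        return None


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


def _expected_call(state: tuple[int, int], alleles) -> str:
    a, b = alleles[state[0]], alleles[state[1]]
    return a if a == b else "H"


def _call_vocabulary(alleles) -> list[str]:
    return sorted(set(alleles)) + ["H"]


def emission_probability(
    call: str,
    state: int,
    founder_alleles,
    epsilon: float,
    space: DiplotypeStateSpace | None = None,
) -> float:
    """P(observed call | diplotype state) at one marker.

    The expected call under a state is the shared founder allele, or H for
    a discordant pair. The expected call has probability 1 - epsilon; the
    remainder is split uniformly over the other calls in the marker's
    vocabulary. N is uninformative and emits 1 under every state.
    """
    space = space or STATE_SPACE_36
    if call == "N":
        return 1.0
    vocab = _call_vocabulary(founder_alleles)
    expected = _expected_call(space.states[state], founder_alleles)
    if call == expected:
        return 1.0 - epsilon
    return epsilon / (len(vocab) - 1)


def _emission_matrix(calls, founder_alleles, epsilon, space) -> np.ndarray:
    n = len(calls)
    out = np.empty((n, space.n_states))
    for m in range(n):
        call = calls[m]
        if call == "N":
            out[m, :] = 1.0
            continue
        alleles = founder_alleles[m]
        vocab = _call_vocabulary(alleles)
        wrong = epsilon / (len(vocab) - 1)
        for k, st in enumerate(space.states):
            out[m, k] = 1.0 - epsilon if call == _expected_call(st, alleles) else wrong
    return out


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


def haplotype_transition(distance_bp: float, rho: float, n_founders: int = N_FOUNDERS) -> np.ndarray:
    """Single-haplotype founder transition matrix over a gap of d bp.

    The haplotype origin follows a jump process with rate ``rho`` per bp
    whose jumps land uniformly on the other founders; over distance d the
    switch probability is r = (n-1)/n * (1 - exp(-n rho d / (n-1))),
    spread uniformly over the other n-1 founders. This is the matrix
    exponential of the uniform-jump generator, so transitions compose
    across consecutive gaps and rows approach the uniform stationary
    distribution as d grows."""
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    n = n_founders
    r = (n - 1) / n * (1.0 - np.exp(-n * rho * distance_bp / (n - 1)))
    t = np.full((n, n), r / (n - 1))
    np.fill_diagonal(t, 1.0 - r)
    return t


def transition_matrix(
    distance_bp: float, rho: float, space: DiplotypeStateSpace | None = None
) -> np.ndarray:
    """Diplotype transition matrix: the two haplotypes recombine
    independently and the ordered product is folded onto unordered pairs.
    Rows sum to 1; d = 0 gives the identity."""
    space = space or STATE_SPACE_36
    t = haplotype_transition(distance_bp, rho, space.n_founders)
    n = space.n_states
    out = np.empty((n, n))
    for s, (a, b) in enumerate(space.states):
        for u, (c, d) in enumerate(space.states):
            if c == d:
                out[s, u] = t[a, c] * t[b, d]
            else:
                out[s, u] = t[a, c] * t[b, d] + t[a, d] * t[b, c]
    return out


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def forward_backward(
    calls,
    marker_map: pd.DataFrame,
    founder_alleles: np.ndarray,
    params: HmmParams | None = None,
    chromosome_kind: str = "autosome",
    sample_id: str = "",
) -> StateProbabilityTrack:
    """Posterior marginal diplotype probabilities at every marker.

    ``calls`` is a length-n sequence over {allele, H, N}; ``marker_map``
    carries chromosome and 1-based position per marker; ``founder_alleles``
    is (n_markers, n_founders). The pass is scaled per position, so each
    returned row sums to 1. Male X chromosomes run in the inbred-only
    state space and are expanded back to the full space with zero
    heterozygous mass.
    """
    params = params or HmmParams()
    calls = list(calls)
    founder_alleles = np.asarray(founder_alleles)
    n = len(calls)
    if n < 1 or len(marker_map) != n:
        raise ValueError("need >= 1 marker and matching marker map")
    n_founders = founder_alleles.shape[1]
    space = DiplotypeStateSpace(n_founders)

    if chromosome_kind == "male_x":
        probs8 = _forward_backward_inbred(calls, marker_map, founder_alleles, params)
        probs = expand_male_x_matrix(probs8, space)
        return StateProbabilityTrack(
            markers=marker_map, probs=probs, sample_id=sample_id,
            chromosome_kind="male_x", space=space,
        )

    emis = _emission_matrix(calls, founder_alleles, params.epsilon, space)
    prior = params.prior
    if prior is None:
        prior = np.full(space.n_states, 1.0 / space.n_states)
    if all(c == "N" for c in calls):
        logger.warning("all calls are N for %s; returning the prior", sample_id or "sample")
        return StateProbabilityTrack(
            markers=marker_map, probs=np.tile(prior, (n, 1)), sample_id=sample_id,
            chromosome_kind=chromosome_kind, space=space,
        )
    positions = marker_map["position"].to_numpy()
    trans = [
        transition_matrix(positions[m] - positions[m - 1], params.rho, space)
        for m in range(1, n)
    ]
    probs = _scaled_forward_backward(prior, trans, emis)
    return StateProbabilityTrack(
        markers=marker_map, probs=probs, sample_id=sample_id,
        chromosome_kind=chromosome_kind, space=space,
    )


def _scaled_forward_backward(prior, trans, emis) -> np.ndarray:
    n, k = emis.shape
    alpha = np.empty((n, k))
    scale = np.empty(n)
    a = prior * emis[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for m in range(1, n):
        a = (alpha[m - 1] @ trans[m - 1]) * emis[m]
        scale[m] = a.sum()
        alpha[m] = a / scale[m]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for m in range(n - 2, -1, -1):
        beta[m] = (trans[m] @ (beta[m + 1] * emis[m + 1])) / scale[m + 1]
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def _forward_backward_inbred(calls, marker_map, founder_alleles, params) -> np.ndarray:
    """8-state (inbred-only) pass for hemizygous male X chromosomes."""
    n = len(calls)
    n_founders = founder_alleles.shape[1]
    emis = np.empty((n, n_founders))
    for m in range(n):
        call = calls[m]
        if call == "N":
            emis[m, :] = 1.0
            continue
        alleles = founder_alleles[m]
        vocab = _call_vocabulary(alleles)
        wrong = params.epsilon / (len(vocab) - 1)
        for f in range(n_founders):
            emis[m, f] = 1.0 - params.epsilon if call == alleles[f] else wrong
    prior = np.full(n_founders, 1.0 / n_founders)
    positions = marker_map["position"].to_numpy()
    trans = [
        haplotype_transition(positions[m] - positions[m - 1], params.rho, n_founders)
        for m in range(1, n)
    ]
    return _scaled_forward_backward(prior, trans, emis)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_probabilities(
    dense_track: StateProbabilityTrack, target_positions, target_ids=None
) -> StateProbabilityTrack:
    """Impute state probabilities at a sparser marker grid by elementwise
    linear interpolation between flanking dense markers (renormalized);
    targets outside the dense range take the nearest end marker's vector."""
    if len(dense_track.markers) == 0:
        raise ValueError("dense track is empty")
    target_positions = np.asarray(target_positions)
    xs = dense_track.markers["position"].to_numpy().astype(float)
    chrom = dense_track.markers["chromosome"].iloc[0]
    cols = [
        np.interp(target_positions, xs, dense_track.probs[:, k])
        for k in range(dense_track.probs.shape[1])
    ]
    probs = np.column_stack(cols)
    probs = probs / probs.sum(axis=1, keepdims=True)
    if target_ids is None:
        target_ids = [f"{chrom}_t{j:05d}" for j in range(len(target_positions))]
    markers = pd.DataFrame(
        {"chromosome": chrom, "position": target_positions}, index=pd.Index(target_ids, name="marker")
    )
    return StateProbabilityTrack(
        markers=markers, probs=probs, sample_id=dense_track.sample_id,
        chromosome_kind=dense_track.chromosome_kind, space=dense_track.space,
    )


# ---------------------------------------------------------------------------
# obligate-ancestor merging
# ---------------------------------------------------------------------------


def merge_ancestors(vectors, space: DiplotypeStateSpace | None = None) -> np.ndarray:
    """Combine per-ancestor state vectors at one marker into the strain
    consensus.

    Rule: find each ancestor's maximum-probability state. When two or more
    ancestors have inbred maxima on *different* founders, each such
    ancestor's inbred mass is redistributed onto the heterozygous states
    pairing its founder with the other conflicting founders (split equally
    when more than one), and the inbred entry zeroed — both haplotypes
    demonstrably still segregate in the strain. Then take the elementwise
    maximum across ancestors and normalize.
    """
    space = space or STATE_SPACE_36
    vecs = [np.asarray(v, dtype=float).copy() for v in vectors]
    if not vecs:
        raise ValueError("need at least one ancestor vector")
    for v in vecs:
        if v.shape != (space.n_states,):
            raise ValueError("vector length does not match state space")
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError("ancestor vectors must be normalized")
    argmaxes = [int(np.argmax(v)) for v in vecs]
    inbred_founders = {argmaxes[i] for i, a in enumerate(argmaxes) if space.is_inbred(a)}
    if len(inbred_founders) >= 2:
        for i, v in enumerate(vecs):
            a = argmaxes[i]
            if not space.is_inbred(a):
                continue
            others = sorted(inbred_founders - {a})
            share = v[a] / len(others)
            for g in others:
                v[space.index(a, g)] += share
            v[a] = 0.0
    merged = np.max(np.vstack(vecs), axis=0)
    total = merged.sum()
    if total <= 0:
        raise ValueError("merged vector has no mass")
    return merged / total


def merge_ancestor_tracks(tracks: list[StateProbabilityTrack]) -> StateProbabilityTrack:
    """Marker-wise `merge_ancestors` over aligned ancestor tracks."""
    if not tracks:
        raise ValueError("need at least one ancestor track")
    base = tracks[0]
    for t in tracks[1:]:
        if len(t.markers) != len(base.markers):
            raise ValueError("ancestor tracks must share a marker grid")
    probs = np.vstack(
        [
            merge_ancestors([t.probs[m] for t in tracks], base.space)
            for m in range(len(base.markers))
        ]
    )
    kind = base.chromosome_kind
    if any(t.chromosome_kind == "male_x" for t in tracks) and kind != "male_x":
        kind = base.chromosome_kind  # merged strain track keeps diploid kind
    return StateProbabilityTrack(
        markers=base.markers, probs=probs, sample_id="merged",
        chromosome_kind=kind, space=base.space,
    )


def expand_male_x(vector8, space: DiplotypeStateSpace | None = None) -> np.ndarray:
    """Extend an inbred-only (8-state) vector to the full state space with
    zero probability on every heterozygous state."""
    space = space or STATE_SPACE_36
    v = np.asarray(vector8, dtype=float)
    if v.shape != (space.n_founders,):
        raise ValueError("expected one entry per founder")
    out = np.zeros(space.n_states)
    out[: space.n_founders] = v
    return out


def expand_male_x_matrix(probs8: np.ndarray, space: DiplotypeStateSpace | None = None) -> np.ndarray:
    space = space or STATE_SPACE_36
    out = np.zeros((probs8.shape[0], space.n_states))
    out[:, : space.n_founders] = probs8
    return out


# ---------------------------------------------------------------------------
# mosaic extraction
# ---------------------------------------------------------------------------


def mosaic_from_track(track: StateProbabilityTrack, min_posterior: float = 0.5) -> ChromosomeMosaic:
    """Segment a posterior track into a haplotype mosaic.

    Per-marker argmax states (ties to the lowest canonical index) are
    merged into runs; segment boundaries fall at the midpoint between
    flanking markers of different argmax. Segments whose mean posterior of
    the argmax state is below ``min_posterior`` are flagged uncertain.
    """
    chrom = str(track.markers["chromosome"].iloc[0])
    positions = track.markers["position"].to_numpy()
    argmax = track.probs.argmax(axis=1)
    best = track.probs[np.arange(len(argmax)), argmax]
    segments: list[MosaicSegment] = []
    run_start = 0
    for m in range(1, len(argmax) + 1):
        if m == len(argmax) or argmax[m] != argmax[run_start]:
            if not segments:
                start = int(positions[run_start])
            else:
                start = segments[-1].end + 1
            if m == len(argmax):
                end = int(positions[-1])
            else:
                end = int((positions[m - 1] + positions[m]) // 2)
            post = float(best[run_start:m].mean())
            state = track.space.states[argmax[run_start]]
            segments.append(
                MosaicSegment(
                    chrom=chrom, start=start, end=end, founders=state,
                    mean_posterior=post, uncertain=post < min_posterior,
                )
            )
            run_start = m
    return ChromosomeMosaic(chrom=chrom, segments=segments)
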