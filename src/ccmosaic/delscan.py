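"""Strain-private homozygous deletion discovery from a read k-mer index.

The read archive is exposed through exactly two queries — how many reads
contain a 45-mer (in either orientation), and which reads those are —
the same contract a multi-string BWT of the raw reads offers. The
reference is tiled with overlapping 45-mers every 15 bp; tiles supported
by fewer than 3 reads are "absent", runs of absent tiles longer than
500 bp in non-repetitive sequence are deletion candidates, and candidate
breakpoints are resolved by majority-vote consensus extension of the
flanking reads across the novel junction. An extension that reconnects
with the reference without skipping sequence adjudicates the candidate as
a simple polymorphism instead.

Coordinates are 1-based inclusive except where noted; micro-homology at a
junction is placed leftmost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .simdata import revcomp

logger = logging.getLogger(__name__)

K = 45
TILE_STEP = 15
PRESENCE_THRESHOLD = 3
MIN_DELETION_BP = 500
POLYMORPHISM_EDIT_MAX = 5


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Exact 45-mer index over a read set.

    ``count(q)`` is the number of reads containing q or its reverse
    complement as a substring; ``reads_containing(q)`` returns those
    reads. k-mers containing N never match. Reads shorter than k are
    skipped (and counted in ``n_skipped``).
    """

    def __init__(self, reads, k: int = K):
        self.k = k
        self.reads: list[str] = []
        self.read_length = 0
        self.n_skipped = 0
        self._counts: dict[str, int] = {}
        self._forward: dict[str, int] = {}
        for read in reads:
            if len(read) < k:
                self.n_skipped += 1
                continue
            self.reads.append(read)
            self.read_length = max(self.read_length, len(read))
            seen_canon = set()
            seen_fwd = set()
            for i in range(len(read) - k + 1):
                kmer = read[i : i + k]
                if "N" in kmer:
                    continue
                seen_fwd.add(kmer)
                seen_canon.add(canonical(kmer))
            for c in seen_canon:
                self._counts[c] = self._counts.get(c, 0) + 1
            for f in seen_fwd:
                self._forward[f] = self._forward.get(f, 0) + 1
        if self.n_skipped:
            logger.info("skipped %d reads shorter than %d bp", self.n_skipped, k)

    def count(self, q: str) -> int:
        """Reads containing q in either orientation."""
        if len(q) != self.k:
            raise ValueError(f"query must be a {self.k}-mer")
        if "N" in q:
            return 0
        return self._counts.get(canonical(q), 0)

    def count_forward(self, q: str) -> int:
        """Reads containing q literally (as given)."""
        if "N" in q:
            return 0
        return self._forward.get(q, 0)

    def reads_containing(self, q: str) -> list[str]:
        """The reads containing q in either orientation, each returned in
        the orientation in which it contains q."""
        if "N" in q:
            return []
        rc = revcomp(q)
        out = []
        for read in self.reads:
            if q in read:
                out.append(read)
            elif rc in read:
                out.append(revcomp(read))
        return out


def build_kmer_index(reads, k: int = K) -> KmerIndex:
    return KmerIndex(reads, k=k)


# ---------------------------------------------------------------------------
# reference tiling
# ---------------------------------------------------------------------------


@dataclass
class TileMatrix:
    """Read support for reference 45-mers sampled every 15 bp."""

    starts: np.ndarray  # 1-based tile start positions
    forward_counts: np.ndarray
    revcomp_counts: np.ndarray
    counts: np.ndarray  # either-orientation read counts
    present: np.ndarray  # counts >= presence_threshold
    repetitive: np.ndarray  # reference-internal multiplicity > 1
    presence_threshold: int
    chrom: str = "ref"

    def __len__(self) -> int:
        return len(self.starts)


def tile_reference(
    reference: str,
    index: KmerIndex,
    presence_threshold: int = PRESENCE_THRESHOLD,
    chrom: str = "ref",
) -> TileMatrix:
    """Archive per-tile read counts: tiles start at 1, 16, 31, ... while
    the 45 bp window fits. A tile is repetitive when its 45-mer occurs
    more than once in the reference (either strand)."""
    if len(reference) < K:
        raise ValueError("reference shorter than one tile")
    ref_mult: dict[str, int] = {}
    for i in range(len(reference) - K + 1):
        c = canonical(reference[i : i + K])
        ref_mult[c] = ref_mult.get(c, 0) + 1
    starts = np.arange(1, len(reference) - K + 2, TILE_STEP)
    fwd = np.empty(len(starts), dtype=int)
    rcc = np.empty(len(starts), dtype=int)
    cnt = np.empty(len(starts), dtype=int)
    rep = np.empty(len(starts), dtype=bool)
    for t, s in enumerate(starts):
        kmer = reference[s - 1 : s - 1 + K]
        fwd[t] = index.count_forward(kmer)
        rcc[t] = index.count_forward(revcomp(kmer))
        cnt[t] = index.count(kmer)
        rep[t] = ref_mult.get(canonical(kmer), 0) > 1
    return TileMatrix(
        starts=starts, forward_counts=fwd, revcomp_counts=rcc, counts=cnt,
        present=cnt >= presence_threshold, repetitive=rep,
        presence_threshold=presence_threshold, chrom=chrom,
    )


# ---------------------------------------------------------------------------
# candidate intervals
# ---------------------------------------------------------------------------


@dataclass
class CandidateInterval:
    chrom: str
    tile_start: int  # first absent 45-mer start (1-based)
    tile_end: int  # last absent 45-mer start (1-based)
    n_tiles: int
    repetitive_fraction: float

    @property
    def span_bp(self) -> int:
        return self.tile_end - self.tile_start

    @property
    def size_kb(self) -> float:
        return tile_size_kb(self.tile_start, self.tile_end)


def tile_size_kb(tile_start: int, tile_end: int) -> float:
    """Deletion size bookkeeping from tile coordinates:
    (last absent 45-mer start - first absent 45-mer start) / 1000."""
    return (tile_end - tile_start) / 1000.0


def find_missing_intervals(
    tiles: TileMatrix, min_size_bp: int = MIN_DELETION_BP,
    max_repetitive_fraction: float = 0.5,
) -> list[CandidateInterval]:
    """Maximal runs of absent tiles spanning more than ``min_size_bp`` in
    mostly non-repetitive sequence."""
    out = []
    absent = ~tiles.present
    i = 0
    n = len(tiles)
    while i < n:
        if not absent[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and absent[j + 1]:
            j += 1
        rep_frac = float(tiles.repetitive[i : j + 1].mean())
        cand = CandidateInterval(
            chrom=tiles.chrom,
            tile_start=int(tiles.starts[i]),
            tile_end=int(tiles.starts[j]),
            n_tiles=j - i + 1,
            repetitive_fraction=rep_frac,
        )
        if cand.span_bp > min_size_bp and rep_frac < max_repetitive_fraction:
            out.append(cand)
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# breakpoint resolution
# ---------------------------------------------------------------------------


@dataclass
class GapAdjudication:
    outcome: str  # deletion | closed_polymorphism | unresolved
    consensus: str = ""
    window_edit_distances: list[int] = field(default_factory=list)
    diagnostic: str = ""


@dataclass
class DeletionCall:
    chrom: str
    tile_start: int
    tile_end: int
    resolved_start: int  # first deleted base, 1-based
    resolved_end: int  # last deleted base, 1-based
    size_kb: float
    spanning_reads: int = 0
    homozygous: bool | None = None
    unique: bool | None = None
    haplotype: str = "unknown"


def _extend_consensus(index: KmerIndex, seed: str, max_extension: int,
                      min_votes: int = 2) -> str:
    """Extend ``seed`` rightward by majority vote over the reads containing
    its terminal 45-mer, re-anchoring as the consensus grows. When the
    terminal anchor has no supporting reads (a coverage dip), anchors
    slightly further back are retried."""
    consensus = seed
    k = index.k
    target = len(seed) + max_extension
    max_back = max(0, index.read_length - k)
    while len(consensus) < target:
        # recruit every read overlapping the consensus end by >= k bases:
        # anchors slide back toward the read length so a local coverage
        # dip at the very end does not orphan reads that span it; each
        # read votes once, at its (read, alignment) placement
        recruits: set[tuple[str, int]] = set()
        for back in range(0, max_back + 1, 5):
            if len(consensus) < k + back:
                break
            anchor = consensus[len(consensus) - k - back : len(consensus) - back]
            for read in index.reads_containing(anchor):
                at = read.find(anchor)
                recruits.add((read, len(consensus) - k - back - at))
            if recruits and back >= 20:
                break
        votes: dict[int, dict[str, int]] = {}
        for read, start in recruits:
            for d in range(len(read)):
                p = start + d
                if p < len(consensus):
                    continue
                if p >= len(consensus) + 60:
                    break
                votes.setdefault(p, {})
                votes[p][read[d]] = votes[p].get(read[d], 0) + 1
        added = 0
        p = len(consensus)
        while p in votes:
            tally = votes[p]
            total = sum(tally.values())
            if total < min_votes:
                break
            base, best = max(tally.items(), key=lambda kv: kv[1])
            if best * 2 <= total:
                break
            consensus += base
            added += 1
            p += 1
        if added == 0:
            break
    return consensus[: target]


def _leftmost(reference: str, a: int, b: int) -> tuple[int, int]:
    """Shift a 0-based half-open deletion [a, b) leftward through
    micro-homology: [a-1, b-1) spells the same junction iff
    reference[a-1] == reference[b-1]."""
    while a > 0 and reference[a - 1] == reference[b - 1]:
        a -= 1
        b -= 1
    return a, b


def _resolve_one_side(
    tile_start: int,
    tile_end: int,
    span_bp: int,
    index: KmerIndex,
    reference: str,
    polymorphism_edit_max: int,
    window: int,
    min_votes: int = 2,
) -> tuple[GapAdjudication, tuple[int, int] | None]:
    """Left-flank consensus extension across one candidate interval.

    Returns the adjudication and, for a deletion, the 0-based half-open
    deleted interval on ``reference`` (not yet micro-homology-normalized).
    """
    k = index.k
    # left anchor: last read-supported tile position before the interval
    anchor_pos = None
    probe = tile_start - TILE_STEP
    while probe >= 1:
        if index.count(reference[probe - 1 : probe - 1 + k]) >= PRESENCE_THRESHOLD:
            anchor_pos = probe
            break
        probe -= TILE_STEP
    if anchor_pos is None:
        return GapAdjudication(outcome="unresolved", diagnostic="no supported left flank"), None
    seed = reference[anchor_pos - 1 : anchor_pos - 1 + k]
    if not index.reads_containing(seed):
        return GapAdjudication(outcome="unresolved", diagnostic="no reads at left boundary"), None
    # the junction lies within ~2 tiles of the anchor, so a few hundred
    # bases of extension suffice regardless of the deletion's size
    max_ext = min(span_bp, 2 * TILE_STEP + k) + 4 * k + 200
    consensus = _extend_consensus(index, seed, max_ext, min_votes=min_votes)
    if len(consensus) <= k + 10:
        return GapAdjudication(outcome="unresolved", consensus=consensus,
                               diagnostic="consensus extension stalled"), None

    left0 = anchor_pos - 1  # 0-based consensus origin on the reference
    gap_close_pos = tile_end + k  # 1-based; past the interval
    # window-by-window comparison against the reference continuation
    dists = []
    bad_at = None
    for w0 in range(0, len(consensus) - window + 1, window):
        cw = consensus[w0 : w0 + window]
        r0 = max(0, left0 + w0 - 10)
        rw = reference[r0 : left0 + w0 + window + 10]
        d = edlib.align(cw, rw, mode="HW")["editDistance"]
        dists.append(d)
        if d > polymorphism_edit_max:
            bad_at = w0
            break
    if bad_at is None:
        if left0 + len(consensus) >= gap_close_pos:
            return GapAdjudication(outcome="closed_polymorphism", consensus=consensus,
                                   window_edit_distances=dists), None
        return GapAdjudication(outcome="unresolved", consensus=consensus,
                               window_edit_distances=dists,
                               diagnostic="gap not closed"), None

    # deletion hypothesis: greedy prefix match, then relocate the tail
    i = 0
    while i < len(consensus) and left0 + i < len(reference) \
            and consensus[i] == reference[left0 + i]:
        i += 1
    tail = consensus[i:]
    if len(tail) < 25:
        return GapAdjudication(outcome="unresolved", consensus=consensus,
                               window_edit_distances=dists,
                               diagnostic="consensus too short past junction"), None
    probe_len = min(35, len(tail))
    search_from = left0 + i + 1
    search_to = tile_end + k + span_bp + 500
    q = reference.find(tail[:probe_len], search_from, min(len(reference), search_to))
    if q < 0:
        return GapAdjudication(outcome="unresolved", consensus=consensus,
                               window_edit_distances=dists,
                               diagnostic="junction tail not found downstream"), None
    # confirm the remainder of the consensus tracks the reference from q
    check = min(len(tail), 120)
    d = edlib.align(tail[:check], reference[q : q + check + 10], mode="HW")["editDistance"]
    if d > polymorphism_edit_max:
        return GapAdjudication(outcome="unresolved", consensus=consensus,
                               window_edit_distances=dists,
                               diagnostic="tail alignment inconsistent"), None
    return (
        GapAdjudication(outcome="deletion", consensus=consensus, window_edit_distances=dists),
        (left0 + i, q),
    )


def resolve_breakpoints(
    candidate: CandidateInterval,
    index: KmerIndex,
    reference: str,
    polymorphism_edit_max: int = POLYMORPHISM_EDIT_MAX,
    window: int = K,
) -> tuple[GapAdjudication, DeletionCall | None]:
    """Adjudicate a candidate interval by flanking-consensus extension.

    From the last read-supported tile left of the interval, the flanking
    reads are assembled into a consensus extended across the gap. The
    consensus is compared window-by-window against the reference: small
    edit distances throughout, reconnecting past the interval, mean a
    simple polymorphism; a divergence whose continuation re-matches the
    reference *downstream* of skipped sequence is a deletion, with
    base-precise breakpoints placed leftmost under micro-homology. If the
    left flank cannot carry the extension (for instance across a coverage
    dip adjoining the interval), the same procedure runs from the right
    boundary on the reverse-complement strand.
    """
    L = len(reference)
    mirrored_start = L - candidate.tile_end - (index.k - 1)
    mirrored_end = L - candidate.tile_start - (index.k - 2)
    adj = GapAdjudication(outcome="unresolved", diagnostic="not attempted")
    ab = None
    # a coverage dip adjoining the interval can starve one flank; try the
    # robust (2-read) consensus on both strands before falling back to
    # single-read extension
    for min_votes in (2, 1):
        adj, ab = _resolve_one_side(
            candidate.tile_start, candidate.tile_end, candidate.span_bp,
            index, reference, polymorphism_edit_max, window, min_votes=min_votes,
        )
        if adj.outcome != "unresolved":
            break
        if mirrored_start >= 1:
            adj_r, ab_r = _resolve_one_side(
                mirrored_start, mirrored_end, candidate.span_bp,
                index, revcomp(reference), polymorphism_edit_max, window,
                min_votes=min_votes,
            )
            if adj_r.outcome != "unresolved":
                adj = adj_r
                ab = (L - ab_r[1], L - ab_r[0]) if ab_r is not None else None
                break
    if adj.outcome != "deletion" or ab is None:
        return adj, None
    a, b = _leftmost(reference, *ab)
    call = DeletionCall(
        chrom=candidate.chrom,
        tile_start=candidate.tile_start,
        tile_end=candidate.tile_end,
        resolved_start=a + 1,
        resolved_end=b,
        size_kb=candidate.size_kb,
    )
    return adj, call


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_call(
    call: DeletionCall,
    index: KmerIndex,
    reference: str,
    tiles: TileMatrix,
    comparison_indices: dict[str, KmerIndex] | None = None,
    mosaic=None,
    presence_threshold: int = PRESENCE_THRESHOLD,
) -> DeletionCall:
    """Attach zygosity, junction-spanning read support, strain uniqueness,
    and the founder-haplotype label to a resolved deletion.

    Homozygous iff every non-repetitive interior tile is unsupported;
    spanning reads count the 45-mer straddling the novel junction; the
    call is strain-unique iff every comparison read set still supports the
    interior tiles; the haplotype comes from the strain's mosaic at the
    deleted interval.
    """
    k = index.k
    interior = (tiles.starts >= call.tile_start) & (tiles.starts <= call.tile_end)
    nonrep = interior & ~tiles.repetitive
    if nonrep.any():
        call.homozygous = bool((tiles.counts[nonrep] < presence_threshold).all())
    a0, b0 = call.resolved_start - 1, call.resolved_end  # 0-based half-open
    left = reference[max(0, a0 - (k // 2)) : a0]
    right = reference[b0 : b0 + (k - len(left))]
    junction = (left + right)[:k]
    call.spanning_reads = index.count(junction) if len(junction) == k else 0
    if comparison_indices:
        interior_kmers = [
            reference[s - 1 : s - 1 + k] for s in tiles.starts[nonrep]
        ]
        unique = True
        for other in comparison_indices.values():
            counts = [other.count(q) for q in interior_kmers]
            if counts and all(c < presence_threshold for c in counts):
                unique = False  # the comparison strain lacks the same tiles
                break
        call.unique = unique
    if mosaic is not None:
        mid = (call.resolved_start + call.resolved_end) // 2
        pair = mosaic.founder_pair_at(mid)
        if pair is not None:
            from .founders import FOUNDER_IDS

            call.haplotype = (
                FOUNDER_IDS[pair[0]] if pair[0] == pair[1]
                else f"{FOUNDER_IDS[pair[0]]}/{FOUNDER_IDS[pair[1]]}"
            )
    return call


def scan_for_deletions(
    reference: str,
    reads,
    min_size_bp: int = MIN_DELETION_BP,
    presence_threshold: int = PRESENCE_THRESHOLD,
    comparison_indices: dict[str, KmerIndex] | None = None,
    mosaic=None,
    chrom: str = "ref",
) -> tuple[list[DeletionCall], list[GapAdjudication], TileMatrix]:
    """Full pipeline: index, tile, detect, resolve, classify."""
    index = build_kmer_index(reads)
    tiles = tile_reference(reference, index, presence_threshold, chrom=chrom)
    calls = []
    adjudications = []
    for cand in find_missing_intervals(tiles, min_size_bp=min_size_bp):
        adj, call = resolve_breakpoints(cand, index, reference)
        adjudications.append(adj)
        if call is not None:
            call = classify_call(
                call, index, reference, tiles,
                comparison_indices=comparison_indices, mosaic=mosaic,
                presence_threshold=presence_threshold,
            )
            if call.homozygous is not False and call.size_kb * 1000 > min_size_bp:
                calls.append(call)
    return calls, adjudications, tiles
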