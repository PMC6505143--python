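"""Residual-heterozygosity estimation from genotype trios.

A nominally inbred strain still segregates two founder haplotypes in part
of its genome. Genotyping three mice per strain on an array exposes this:
at an informative marker, any H call or any disagreement among the three
samples is evidence that the locus is not yet fixed. Runs of evidence
markers are combined into clusters whose summed span, over the assayed
span, conservatively estimates the heterozygous genome fraction.

Marker selection mirrors the array QC used for such surveys: markers must
be biallelic and informative among the eight founders, free of H/N calls
in founders, concordant across founder replicates, and their founder
alleles must perfectly predict F1 hybrid genotypes.

N is treated as missing throughout: a trio marker with at least one non-N
call is assayed; all-N markers drop out of numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

FILTER_NAMES = ("biallelic", "informative", "founder_hn", "replicate_discordant", "f1_mismatch")


class UndefinedEstimateError(ValueError):
    """No comparable data to estimate from."""


@dataclass
class InformativeMarkerSet:
    """Markers passing all founder-based filters, with the per-founder
    consensus allele table and per-filter drop counts."""

    markers: pd.DataFrame  # index marker; columns chromosome, position
    founder_alleles: pd.DataFrame  # index marker; one column per founder
    drop_counts: dict[str, int] = field(default_factory=dict)

    def alleles_array(self) -> np.ndarray:
        return self.founder_alleles.to_numpy(dtype="<U1")


def select_informative_markers(
    founder_genotypes: GenotypeMatrix,
    founder_of_sample: dict[str, str],
    f1_genotypes: GenotypeMatrix | None = None,
    f1_parents: dict[str, tuple[str, str]] | None = None,
) -> InformativeMarkerSet:
    """Apply the five marker filters and return the retained set.

    ``founder_of_sample`` maps each founder-genotype column to its founder
    id (several replicates per founder allowed). ``f1_parents`` maps each
    F1 sample column to its two parental founder ids.
    """
    founders = sorted(set(founder_of_sample.values()))
    drop = {name: 0 for name in FILTER_NAMES}
    kept = []
    consensus_rows = []
    for marker in founder_genotypes.markers.index:
        row = founder_genotypes.calls.loc[marker]
        per_founder = {}
        failed = None
        # H/N and replicate concordance inside founders
        for f in founders:
            reps = [row[s] for s, fo in founder_of_sample.items() if fo == f]
            if any(c in ("H", "N") for c in reps):
                failed = failed or "founder_hn"
            elif len(set(reps)) > 1:
                failed = failed or "replicate_discordant"
            else:
                per_founder[f] = reps[0]
        if failed is None:
            alleles = set(per_founder.values())
            if len(alleles) > 2:
                failed = "biallelic"
            elif len(alleles) < 2:
                failed = "informative"
        if failed is None and f1_genotypes is not None and f1_parents:
            if marker in f1_genotypes.calls.index:
                obs = f1_genotypes.calls.loc[marker]
                for s, (pa, pb) in f1_parents.items():
                    expected = (
                        per_founder[pa] if per_founder[pa] == per_founder[pb] else "H"
                    )
                    if obs[s] != "N" and obs[s] != expected:
                        failed = "f1_mismatch"
                        break
        if failed is None:
            kept.append(marker)
            consensus_rows.append([per_founder[f] for f in founders])
        else:
            drop[failed] += 1
    markers = founder_genotypes.markers.loc[kept]
    founder_alleles = pd.DataFrame(consensus_rows, index=markers.index, columns=founders)
    return InformativeMarkerSet(markers=markers, founder_alleles=founder_alleles, drop_counts=drop)


# ---------------------------------------------------------------------------
# trio evidence
# ---------------------------------------------------------------------------


def trio_marker_evidence(calls) -> bool | None:
    """Evidence of residual heterozygosity from one marker's three calls:
    True iff any call is H or the non-N calls disagree; None (marker not
    assayed for this trio) when all three calls are N."""
    calls = tuple(calls)
    if len(calls) != 3:
        raise ValueError("a trio has exactly three calls")
    non_n = [c for c in calls if c != "N"]
    if not non_n:
        return None
    return "H" in non_n or len(set(non_n)) > 1


@dataclass
class EvidenceCluster:
    chrom: str
    first_pos: int
    last_pos: int
    n_markers: int
    span_bp: int


@dataclass
class HetEvidenceTrack:
    """Per-marker trio evidence plus the combined evidence clusters."""

    evidence: pd.Series  # index marker; values True/False/None
    clusters: list[EvidenceCluster]
    assayed_span_bp: int


@dataclass
class HetEstimate:
    strain: str
    assayed_bp: int
    het_bp: int
    fraction: float
    n_clusters: int


#: default cluster-combining gap tolerance. A biallelic marker
#: distinguishes the two founder haplotypes actually segregating in a
#: heterozygous region only about half the time, so evidence markers
#: arrive interleaved with evidence-free ones; bridging up to 7
#: consecutive evidence-free markers lets a genuinely heterozygous run
#: split only with probability ~0.5^8 (~0.4%), while runs of homozygous
#: sequence longer than 8 markers still separate clusters.
MAX_GAP_MARKERS = 7


def cluster_evidence(
    evidence: pd.Series, marker_map: pd.DataFrame, max_gap_markers: int = MAX_GAP_MARKERS
) -> HetEvidenceTrack:
    """Combine runs of evidence markers into clusters.

    Flagged markers separated by at most ``max_gap_markers`` consecutive
    unflagged assayed markers belong to one cluster (``max_gap_markers=0``
    breaks a run at every unflagged assayed marker). A cluster spans first
    to last flagged marker (inclusive); a singleton cluster gets the
    chromosome's mean inter-marker spacing (rounded) as its span. Markers
    the trio did not assay (all-N, evidence None) are skipped: they
    neither break nor extend a run.
    """
    clusters: list[EvidenceCluster] = []
    assayed_span = 0
    for chrom in marker_map["chromosome"].unique():
        sel = marker_map["chromosome"] == chrom
        ids = marker_map.index[sel]
        pos = marker_map.loc[sel, "position"].to_numpy()
        flags = evidence.loc[ids].to_numpy(dtype=object)
        assayed = np.array([f is not None for f in flags])
        if not assayed.any():
            continue
        a_pos = pos[assayed]
        a_flags = np.array([bool(f) for f in flags[assayed]])
        assayed_span += int(a_pos[-1] - a_pos[0] + 1)
        spacing = (a_pos[-1] - a_pos[0]) / (len(a_pos) - 1) if len(a_pos) > 1 else 1.0
        flagged = np.nonzero(a_flags)[0]
        if len(flagged) == 0:
            continue
        runs = [[flagged[0], flagged[0]]]
        for i in flagged[1:]:
            if i - runs[-1][1] - 1 <= max_gap_markers:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for i, j in runs:
            n = int(a_flags[i : j + 1].sum())
            span = int(a_pos[j] - a_pos[i] + 1) if j > i else int(round(spacing))
            clusters.append(
                EvidenceCluster(
                    chrom=str(chrom), first_pos=int(a_pos[i]), last_pos=int(a_pos[j]),
                    n_markers=n, span_bp=span,
                )
            )
    return HetEvidenceTrack(evidence=evidence, clusters=clusters, assayed_span_bp=assayed_span)


def estimate_het_fraction(
    track: HetEvidenceTrack, marker_map: pd.DataFrame, strain: str = ""
) -> HetEstimate:
    """Heterozygous genome fraction: summed cluster span over the per-
    chromosome assayed span (first to last assayed marker)."""
    if track.assayed_span_bp <= 0:
        raise UndefinedEstimateError("no assayed markers")
    het_bp = sum(c.span_bp for c in track.clusters)
    return HetEstimate(
        strain=strain,
        assayed_bp=track.assayed_span_bp,
        het_bp=het_bp,
        fraction=het_bp / track.assayed_span_bp,
        n_clusters=len(track.clusters),
    )


def trio_het_estimate(
    trio_calls: pd.DataFrame,
    marker_map: pd.DataFrame,
    strain: str = "",
    max_gap_markers: int = MAX_GAP_MARKERS,
) -> HetEstimate:
    """Convenience pipeline: per-marker trio evidence, clustering, and the
    genome-fraction estimate, from a markers x 3-samples call table."""
    if trio_calls.shape[1] != 3:
        raise ValueError("expected exactly three samples")
    evidence = trio_calls.apply(lambda row: trio_marker_evidence(tuple(row)), axis=1)
    track = cluster_evidence(evidence, marker_map, max_gap_markers=max_gap_markers)
    return estimate_het_fraction(track, marker_map, strain=strain)


# ---------------------------------------------------------------------------
# concordance / identity matching
# ---------------------------------------------------------------------------


def concordance(calls_a: pd.Series, calls_b: pd.Series, shared_markers=None) -> float:
    """Fraction of matching calls among markers where neither sample is N."""
    if shared_markers is None:
        shared_markers = calls_a.index.intersection(calls_b.index)
    a = calls_a.loc[shared_markers]
    b = calls_b.loc[shared_markers]
    mask = (a != "N") & (b != "N")
    n = int(mask.sum())
    if n == 0:
        raise UndefinedEstimateError("no comparable markers")
    return float((a[mask] == b[mask]).mean())


@dataclass
class MatchResult:
    best: list[str]  # all tied best strains
    concordances: pd.Series
    flagged: bool  # best concordance below the warning threshold


def match_sample_to_strain(
    sample_calls: pd.Series,
    reference_panel: pd.DataFrame,
    warn_threshold: float = 0.9,
) -> MatchResult:
    """Match a sample against per-strain reference call vectors by
    concordance; ties are reported, not silently resolved."""
    if reference_panel.shape[1] == 0:
        raise ValueError("empty reference panel")
    scores = {}
    for strain in reference_panel.columns:
        scores[strain] = concordance(sample_calls, reference_panel[strain])
    scores = pd.Series(scores).sort_values(ascending=False)
    top = scores.max()
    best = list(scores.index[np.isclose(scores.to_numpy(), top, atol=1e-12)])
    return MatchResult(best=best, concordances=scores, flagged=bool(top < warn_threshold))
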