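"""Readers and writers for the pipeline's external formats.

Genotype call tables and probability tracks travel as CSV, intervals as
0-based half-open BED (internal coordinates are 1-based inclusive),
sequences as FASTA and reads as FASTQ via Biopython. Every writer/reader
pair round-trips valid data exactly.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .haprecon import DiplotypeStateSpace, StateProbabilityTrack

logger = logging.getLogger("ccmosaic")

CALL_VOCABULARY = frozenset("ACGTHN")

MARKER_COLUMNS = ("marker", "chromosome", "position")


class FormatError(ValueError):
    """A file violates the expected layout or vocabulary."""


class ValidationError(ValueError):
    """Structurally valid data with inconsistent content."""


def get_logger(level: int = logging.INFO) -> logging.Logger:
    """Package logger writing to stderr."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Markers x samples categorical call table with its marker map."""

    markers: pd.DataFrame  # index marker; columns chromosome, position
    calls: pd.DataFrame  # index marker; one column per sample

    def __post_init__(self):
        if not self.markers.index.equals(self.calls.index):
            raise ValidationError("marker map and calls are misaligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape


def _validate_calls(calls: pd.DataFrame) -> None:
    for sample in calls.columns:
        bad = ~calls[sample].isin(CALL_VOCABULARY)
        if bad.any():
            marker = calls.index[bad.to_numpy()][0]
            token = calls.at[marker, sample]
            raise FormatError(
                f"invalid call {token!r} at marker {marker!r}, sample {sample!r}"
            )


def read_genotype_csv(path) -> GenotypeMatrix:
    """Read a genotype CSV: marker, chromosome, position, then one column
    per sample. Duplicate marker ids are an error; unsorted positions are
    sorted with a logged warning."""
    df = pd.read_csv(path, dtype={"marker": str, "chromosome": str})
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise FormatError(f"duplicate marker id {dup!r}")
    df = df.set_index("marker")
    sorted_df = df.sort_values(["chromosome", "position"], kind="stable")
    if not sorted_df.index.equals(df.index):
        logger.warning("positions not sorted in %s; sorting", path)
        df = sorted_df
    markers = df[["chromosome", "position"]].copy()
    markers["position"] = markers["position"].astype(int)
    calls = df.drop(columns=["chromosome", "position"]).astype(str)
    _validate_calls(calls)
    return GenotypeMatrix(markers=markers, calls=calls)


def write_genotype_csv(matrix: GenotypeMatrix, path) -> None:
    _validate_calls(matrix.calls)
    out = matrix.markers.join(matrix.calls)
    out.index.name = "marker"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# probability tracks
# ---------------------------------------------------------------------------


def write_probability_track(track: StateProbabilityTrack, path) -> None:
    """Write a state-probability track as CSV with one column per state in
    canonical order (inbred states first, then pairs)."""
    sums = track.probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")
    df = track.markers.copy()
    for k, name in enumerate(track.space.names):
        df[name] = track.probs[:, k]
    df.index.name = "marker"
    df.to_csv(path, float_format="%.17g")


def read_probability_track(path, n_founders: int = 8) -> StateProbabilityTrack:
    space = DiplotypeStateSpace(n_founders)
    df = pd.read_csv(path, dtype={"marker": str, "chromosome": str}).set_index("marker")
    missing = [n for n in space.names if n not in df.columns]
    if missing:
        raise FormatError(f"missing state columns: {missing[:3]}...")
    probs = df[list(space.names)].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = np.argmax(np.abs(sums - 1.0))
        raise ValidationError(
            f"row {df.index[bad]!r} sums to {sums[bad]:.6f}, expected 1"
        )
    markers = df[["chromosome", "position"]].copy()
    markers["position"] = markers["position"].astype(int)
    kind = "male_x" if probs[:, space.n_founders:].max(initial=0.0) == 0.0 else "autosome"
    return StateProbabilityTrack(
        markers=markers, probs=probs / sums[:, None], chromosome_kind=kind, space=space
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(intervals, path, header: str = "ccmosaic intervals") -> None:
    """Write (chrom, start, end[, name]) intervals with 1-based inclusive
    coordinates as 0-based half-open BED. Intervals are written as given
    (no merging); an empty list yields a header-only file."""
    lines = [f"# {header}"]
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = str(iv[3]) if len(iv) > 3 else "."
        if end < start:
            raise ValidationError(f"interval end < start: {iv}")
        lines.append(f"{chrom}\t{start - 1}\t{end}\t{name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED back to 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else "."
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]), name))
    return out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads, path, prefix: str = "read") -> None:
    """Write a bag of reads with constant dummy quality 'I' (Q40)."""
    records = []
    for i, read in enumerate(reads):
        rec = SeqRecord(Seq(read), id=f"{prefix}_{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(read)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]
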