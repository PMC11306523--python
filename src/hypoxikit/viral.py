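"""Viral (HPV) RNA presence calling from read alignments to viral genomes.

A sample is called HPV-positive for a viral genome when at least
``min_reads`` reads map to that genome AND the pileup contains a contiguous
run of at least ``min_span`` bases at depth >= ``min_depth``. The two
conditions are evaluated independently: the read count genome-wide, the run
from the base-resolution depth vector. Coordinates are 0-based half-open
internally and 1-based inclusive in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 400
DEFAULT_MIN_SPAN = 200
DEFAULT_MIN_DEPTH = 5


@dataclass(frozen=True)
class ViralCoverageSummary:
    """Per-virus mapped-read count and per-base depth vector."""

    virus_id: str
    genome_length: int
    mapped_reads: int
    depth: np.ndarray  # len == genome_length, non-negative ints

    def __post_init__(self) -> None:
        if len(self.depth) != self.genome_length:
            raise ValueError("depth vector length must equal genome length")
        if (np.asarray(self.depth) < 0).any():
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class HPVCall:
    """Presence call for one viral genome with its evidence values."""

    virus_id: str
    positive: bool
    mapped_reads: int
    longest_run_at_min_depth: int
    evidence_region: tuple[int, int]  # 0-based half-open

    def region_1based(self) -> tuple[int, int]:
        """Evidence region as 1-based inclusive coordinates for reports."""
        start, end = self.evidence_region
        return (start + 1, end)


def read_alignment_tsv(path) -> list[tuple[str, int, int]]:
    """Read per-read alignment intervals from TSV with columns
    virus_id, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"virus_id", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return [
        (str(v), int(s), int(e))
        for v, s, e in zip(df["virus_id"], df["start"], df["end"])
    ]


def read_alignment_sam(path) -> list[tuple[str, int, int]]:
    """Extract (reference, start, end) intervals from a SAM/BAM file.

    Unmapped, secondary and supplementary records are ignored; the interval
    is the reference span of the primary alignment.
    """
    import pysam

    intervals = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            intervals.append(
                (rec.reference_name, rec.reference_start, rec.reference_end)
            )
    return intervals


def summarize_alignments(
    alignments, genome_lengths: dict[str, int]
) -> list[ViralCoverageSummary]:
    """Build per-virus read counts and pileup depth vectors.

    ``alignments`` is an iterable of (virus_id, start, end) half-open
    0-based intervals (see :func:`read_alignment_tsv` /
    :func:`read_alignment_sam`). Out-of-bounds intervals raise with the
    offending read index.
    """
    counts: dict[str, int] = {v: 0 for v in genome_lengths}
    # difference arrays give O(reads + genome) pileup construction
    diffs: dict[str, np.ndarray] = {
        v: np.zeros(length + 1, dtype=np.int64) for v, length in genome_lengths.items()
    }
    for i, (virus, start, end) in enumerate(alignments):
        if virus not in genome_lengths:
            raise ValueError(f"read {i}: unknown virus {virus!r}")
        length = genome_lengths[virus]
        if start < 0 or end > length or end <= start:
            raise ValueError(
                f"read {i}: interval [{start}, {end}) out of bounds for "
                f"{virus!r} (length {length})"
            )
        counts[virus] += 1
        diffs[virus][start] += 1
        diffs[virus][end] -= 1
    summaries = []
    for virus, length in genome_lengths.items():
        if counts[virus] == 0:
            continue
        depth = np.cumsum(diffs[virus][:-1])
        summaries.append(
            ViralCoverageSummary(
                virus_id=virus,
                genome_length=length,
                mapped_reads=counts[virus],
                depth=depth,
            )
        )
    return summaries


def longest_run_at_depth(depth, min_depth: int = DEFAULT_MIN_DEPTH):
    """Length and location of the longest run of consecutive positions with
    depth >= min_depth. Ties break leftmost; returns (length, start, end)
    with a 0-based half-open interval, (0, 0, 0) when no base qualifies."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    ok = np.asarray(depth) >= min_depth
    if not ok.any():
        return 0, 0, 0
    padded = np.concatenate(([False], ok, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    best = int(lengths.argmax())  # argmax takes first maximum -> leftmost tie-break
    return int(lengths[best]), int(starts[best]), int(ends[best])


def call_hpv_status(
    summary: ViralCoverageSummary,
    min_reads: int = DEFAULT_MIN_READS,
    min_span: int = DEFAULT_MIN_SPAN,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> HPVCall:
    """Dual-threshold presence call: positive iff mapped reads >= min_reads
    and the longest depth->=min_depth run spans >= min_span bases. Evidence
    values are reported regardless of the call."""
    run_len, start, end = longest_run_at_depth(summary.depth, min_depth)
    positive = summary.mapped_reads >= min_reads and run_len >= min_span
    return HPVCall(
        virus_id=summary.virus_id,
        positive=positive,
        mapped_reads=summary.mapped_reads,
        longest_run_at_min_depth=run_len,
        evidence_region=(start, end),
    )
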