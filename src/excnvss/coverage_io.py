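"""Capture targets, per-base coverage extraction and the concatenated coordinate axis.

Exome CNV calling from read depth operates on a single signal obtained by
joining every capture target end-to-end ("concatenated" or transcript
coordinates).  This module reads targets from BED, builds per-base coverage
tracks over that axis from a BAM or a precomputed depth file, and maintains
the bidirectional map between concatenated indices and genomic coordinates.

Conventions: BED half-open 0-based externally, concatenated indices 0-based
internally.  Strand is ignored; read-depth CNV calling is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CoverageIOError(ValueError):
    """Malformed targets, depth records or alignment input."""


@dataclass(frozen=True)
class TargetSet:
    """Ordered, merged capture intervals with concatenation offsets.

    Attributes
    ----------
    chroms, starts, ends
        Per-target genomic interval (half-open, 0-based), sorted by
        ``(chrom, start)`` and non-overlapping.
    offsets
        Start index of each target on the concatenated axis;
        ``offsets[i + 1] - offsets[i]`` equals the length of target ``i``.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        chroms = np.asarray(self.chroms, dtype=object)
        if not (len(chroms) == len(starts) == len(ends)):
            raise CoverageIOError("chroms/starts/ends length mismatch")
        if len(starts) == 0:
            raise CoverageIOError("no targets")
        if np.any(ends <= starts):
            raise CoverageIOError("every target length must be >= 1")
        lengths = ends - starts
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "offsets", offsets.astype(np.int64))
        # sorted and non-overlapping within each chromosome
        for i in range(1, len(starts)):
            if chroms[i] == chroms[i - 1]:
                if starts[i] < ends[i - 1]:
                    raise CoverageIOError(
                        f"targets overlap or are unsorted at record {i}"
                    )

    @property
    def n_targets(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_length(self) -> int:
        """Length of the concatenated axis (sum of target lengths)."""
        return int(self.offsets[-1] + (self.ends[-1] - self.starts[-1]))

    def to_genomic(self, track_index: int) -> tuple[str, int]:
        """Map a concatenated index back to ``(chrom, position)``."""
        return to_genomic(track_index, self)

    def to_concat(self, chrom: str, position: int) -> int:
        """Map a genomic position inside a target to its concatenated index."""
        hits = np.flatnonzero(
            (self.chroms == chrom) & (self.starts <= position) & (position < self.ends)
        )
        if hits.size == 0:
            raise CoverageIOError(f"{chrom}:{position} not inside any target")
        i = int(hits[0])
        return int(self.offsets[i] + position - self.starts[i])

    def target_of_index(self, track_index) -> np.ndarray:
        """Target id(s) containing the given concatenated index/indices."""
        idx = np.asarray(track_index, dtype=np.int64)
        n = self.total_length
        if np.any(idx < 0) or np.any(idx >= n):
            raise CoverageIOError("concatenated index out of range")
        return np.searchsorted(self.offsets, idx, side="right") - 1


@dataclass
class CoverageTrack:
    """Concatenated base-level depth over a :class:`TargetSet`."""

    values: np.ndarray
    target_set: TargetSet
    sample_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.target_set.total_length
        if self.values.shape != (n,):
            raise CoverageIOError(
                f"track length {self.values.shape} does not match "
                f"concatenated target length {n}"
            )
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise CoverageIOError("coverage values must be finite and >= 0")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.values == 0))


def read_targets(path) -> TargetSet:
    """Read capture targets from a BED file, merging overlapping intervals.

    Overlapping and book-ended intervals are merged before concatenation so
    that every genomic base appears exactly once on the concatenated axis.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoverageIOError(f"line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoverageIOError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise CoverageIOError(f"line {lineno}: invalid interval {start}-{end}")
            records.append((fields[0], start, end))
    if not records:
        raise CoverageIOError("no targets")
    records.sort(key=lambda r: (r[0], r[1]))
    merged: list[list] = []
    for chrom, start, end in records:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    chroms = np.array([m[0] for m in merged], dtype=object)
    starts = np.array([m[1] for m in merged], dtype=np.int64)
    ends = np.array([m[2] for m in merged], dtype=np.int64)
    return TargetSet(chroms, starts, ends)


def extract_coverage(bam_path, targets: TargetSet, min_mapq: int = 0) -> CoverageTrack:
    """Per-base read depth over the concatenated axis from an indexed BAM.

    A read contributes to every reference base its alignment spans, with
    deletions counted as covered and introns (N) and clips not; secondary,
    supplementary, duplicate and unmapped records are excluded, as are reads
    below ``min_mapq``.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise CoverageIOError(f"BAM {bam_path} has no index")
        contigs = set(bam.references)
        missing = sorted({str(c) for c in targets.chroms} - contigs)
        if missing:
            raise CoverageIOError(
                "contigs in targets but not in BAM: " + ", ".join(missing)
            )
        values = np.zeros(targets.total_length, dtype=np.float64)
        for i in range(targets.n_targets):
            chrom = str(targets.chroms[i])
            start, end = int(targets.starts[i]), int(targets.ends[i])
            off = int(targets.offsets[i])
            # difference array over [start, end); +1 at span start, -1 past end
            diff = np.zeros(end - start + 1, dtype=np.float64)
            for read in bam.fetch(chrom, start, end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.mapping_quality < min_mapq
                ):
                    continue
                for s, e in _covered_spans(read):
                    s, e = max(s, start), min(e, end)
                    if s < e:
                        diff[s - start] += 1
                        diff[e - start] -= 1
            values[off : off + (end - start)] = np.cumsum(diff[:-1])
    return CoverageTrack(values, targets)


def _covered_spans(read):
    """Reference spans covered by a read: M/=/X and D consume and cover,
    N consumes but does not cover, clips/insertions consume nothing."""
    pos = read.reference_start
    spans = []
    cur_start = None
    for op, length in read.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 3:  # N
            if cur_start is not None:
                spans.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P consume no reference
    if cur_start is not None:
        spans.append((cur_start, pos))
    return spans


def read_depth_track(path, targets: TargetSet) -> CoverageTrack:
    """Per-base depth from a bedGraph/TSV (chrom, start, end, depth) file.

    Bases inside targets with no record get depth 0; records outside targets
    are ignored.  Overlapping depth records are rejected as ambiguous.
    """
    values = np.zeros(targets.total_length, dtype=np.float64)
    seen = np.zeros(targets.total_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CoverageIOError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, depth = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if depth < 0:
                raise CoverageIOError(f"line {lineno}: negative depth value")
            mask = (targets.chroms == chrom) & (targets.starts < end) & (
                targets.ends > start
            )
            for i in np.flatnonzero(mask):
                s = max(start, int(targets.starts[i]))
                e = min(end, int(targets.ends[i]))
                lo = int(targets.offsets[i]) + s - int(targets.starts[i])
                hi = lo + (e - s)
                if np.any(seen[lo:hi]):
                    raise CoverageIOError(f"line {lineno}: overlapping depth records")
                seen[lo:hi] = True
                values[lo:hi] = depth
    return CoverageTrack(values, targets)


def to_genomic(track_index: int, targets: TargetSet) -> tuple[str, int]:
    """Map a concatenated index to its genomic ``(chrom, position)``."""
    n = targets.total_length
    if not 0 <= track_index < n:
        raise CoverageIOError(f"index {track_index} out of range [0, {n})")
    i = int(np.searchsorted(targets.offsets, track_index, side="right") - 1)
    return str(targets.chroms[i]), int(
        targets.starts[i] + track_index - targets.offsets[i]
    )


def write_targets_bed(targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(targets.n_targets):
            fh.write(
                f"{targets.chroms[i]}\t{targets.starts[i]}\t{targets.ends[i]}"
                f"\ttarget_{i}\n"
            )


def write_depth_bedgraph(track: CoverageTrack, path) -> None:
    """Export a track as bedGraph, run-length compressed per target."""
    ts = track.target_set
    with open(path, "w") as fh:
        for i in range(ts.n_targets):
            off, length = int(ts.offsets[i]), int(ts.ends[i] - ts.starts[i])
            vals = track.values[off : off + length]
            # run-length encode
            change = np.flatnonzero(np.diff(vals)) + 1
            bounds = np.concatenate([[0], change, [length]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(
                    f"{ts.chroms[i]}\t{ts.starts[i] + a}\t{ts.starts[i] + b}"
                    f"\t{vals[a]:g}\n"
                )
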