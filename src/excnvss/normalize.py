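"""Four-step coverage normalization of the concatenated depth signal.

The protocol turns raw per-base depth into a signal suitable for scale-space
filtering:

1. *Ratio evaluation* — per-base test/control ratio with a guard ``epsilon``
   for near-zero depths, scaled by the library-size factor
   ``omega = total_control_mass / total_test_mass``.  In test-only (noRatio)
   mode the raw test depths pass through with ``omega = 1``.
2. *Segmentation* — each target is cut into consecutive bins of exactly
   ``bin_size`` bases; remnant bases that do not fill a bin are trimmed
   half from the front (``floor(rem / 2)``), the rest from the back.
3. *Segment-mean normalization* — every bin mean is converted to a t-score
   against the grand mean and standard error of all bin means, then all
   scores are shifted so the minimum is exactly zero.
4. *Base-level redistribution* — within each bin, values are shifted so the
   bin mean equals its normalized mean while per-base deviations (and hence
   the within-bin standard deviation) are preserved.

Sample standard deviation (``ddof=1``) is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coverage_io import CoverageTrack, TargetSet

DEFAULT_EPSILON = 1e-3
DEFAULT_BIN_SIZE = 30


class NormalizationError(ValueError):
    pass


@dataclass
class RatioTrack:
    """Per-base depth ratio (or raw depth in noRatio mode), library-size scaled."""

    values: np.ndarray
    omega: float
    epsilon: float
    target_set: TargetSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise NormalizationError("ratio values must be finite and >= 0")
        if self.omega <= 0:
            raise NormalizationError("omega must be positive")


@dataclass
class SegmentPartition:
    """Exact-size binning of each target with flank remnants trimmed."""

    bin_size: int
    seg_target_id: np.ndarray  # target id per segment
    seg_concat_start: np.ndarray  # concatenated start index per segment
    kept_mask: np.ndarray  # bool over the concatenated axis

    @property
    def n_segments(self) -> int:
        return len(self.seg_concat_start)

    def kept_indices(self) -> np.ndarray:
        """Original concatenated index of every kept base, segment-major."""
        b = self.bin_size
        return (self.seg_concat_start[:, None] + np.arange(b)[None, :]).ravel()


@dataclass
class SegmentStats:
    raw_mean: np.ndarray
    raw_std: np.ndarray
    norm_mean: np.ndarray
    grand_mean: float
    grand_std: float
    total_segments: int


@dataclass
class NormalizedTrack:
    """Caller input: redistributed values over kept indices only."""

    values: np.ndarray
    partition: SegmentPartition
    index_map: np.ndarray  # kept index -> original concatenated index


def compute_ratio(
    test: CoverageTrack,
    control: CoverageTrack,
    epsilon: float = DEFAULT_EPSILON,
    strict_literal: bool = False,
) -> RatioTrack:
    """Per-base ratio r = t/c with near-zero guards, scaled by omega.

    Guard branches (default order): both depths below ``epsilon`` -> 1
    (no evidence either way); test below ``epsilon`` -> 0; control below
    ``epsilon`` with test above -> t / epsilon (denominator capped, keeping
    the value finite while preserving "high ratio" semantics); otherwise
    t / c.  ``strict_literal=True`` tests the test-depth branch first, which
    makes the joint branch unreachable.
    """
    if test.values.shape != control.values.shape:
        raise NormalizationError("test and control track lengths differ")
    if epsilon < 0:
        raise NormalizationError("epsilon must be >= 0")
    t, c = test.values, control.values
    m_t, m_c = t.sum(), c.sum()
    if m_t == 0 or m_c == 0:
        raise NormalizationError("no coverage in test and/or control track")
    omega = float(m_c / m_t)

    low_t = t < epsilon
    low_c = c < epsilon
    r = np.empty_like(t)
    safe = ~low_t & ~low_c
    r[safe] = t[safe] / c[safe]
    capped = ~low_t & low_c
    r[capped] = t[capped] / epsilon if epsilon > 0 else 0.0
    if np.any(capped):
        warnings.warn(
            f"{int(capped.sum())} bases with control depth < epsilon <= test "
            "depth; ratio capped at test/epsilon",
            stacklevel=2,
        )
    if strict_literal:
        r[low_t] = 0.0
    else:
        r[low_t] = 0.0
        r[low_t & low_c] = 1.0
    return RatioTrack(omega * r, omega=omega, epsilon=epsilon, target_set=test.target_set)


def passthrough_test(test: CoverageTrack) -> RatioTrack:
    """noRatio mode: raw test depths with omega fixed at 1."""
    return RatioTrack(
        test.values.copy(), omega=1.0, epsilon=DEFAULT_EPSILON,
        target_set=test.target_set,
    )


def partition(
    track: RatioTrack, targets: TargetSet, bin_size: int = DEFAULT_BIN_SIZE
) -> SegmentPartition:
    """Cut every target into ``floor(n_i / bin_size)`` exact-size segments.

    The first ``floor(mod(n_i, bin_size) / 2)`` bases of each target and the
    remaining remnant at its end are trimmed; targets shorter than
    ``bin_size`` contribute no segments.
    """
    if bin_size < 2:
        raise NormalizationError("bin_size must be >= 2")
    lengths = targets.lengths
    n_seg = lengths // bin_size
    prefix = (lengths % bin_size) // 2
    seg_tid = np.repeat(np.arange(targets.n_targets), n_seg)
    # start of segment s within target i: offsets[i] + prefix[i] + s*bin_size
    within = np.concatenate(
        [np.arange(k, dtype=np.int64) for k in n_seg if k > 0]
    ) if np.any(n_seg > 0) else np.empty(0, dtype=np.int64)
    starts = (
        targets.offsets[seg_tid] + prefix[seg_tid] + within * bin_size
    ).astype(np.int64)
    kept_mask = np.zeros(targets.total_length, dtype=bool)
    if starts.size:
        idx = (starts[:, None] + np.arange(bin_size)[None, :]).ravel()
        kept_mask[idx] = True
    return SegmentPartition(
        bin_size=bin_size,
        seg_target_id=seg_tid.astype(np.int64),
        seg_concat_start=starts,
        kept_mask=kept_mask,
    )


def normalize_means(track: RatioTrack, part: SegmentPartition) -> SegmentStats:
    """Segment means as min-shifted t-scores against the grand distribution.

    ``t = (m - grand_mean) / (grand_std / sqrt(N))`` with ``N`` the total
    segment count; afterwards all scores are shifted by the minimum so the
    smallest normalized mean is exactly 0.  Zero grand standard deviation
    (all bins identical) yields all-zero scores.
    """
    n = part.n_segments
    if n < 2:
        raise NormalizationError("need at least 2 segments")
    seg_vals = track.values[part.kept_indices()].reshape(n, part.bin_size)
    raw_mean = seg_vals.mean(axis=1)
    raw_std = seg_vals.std(axis=1, ddof=1)
    grand_mean = float(raw_mean.mean())
    grand_std = float(raw_mean.std(ddof=1))
    if grand_std == 0.0:
        t = np.zeros(n)
    else:
        t = (raw_mean - grand_mean) / (grand_std / np.sqrt(n))
    norm_mean = t - t.min()
    return SegmentStats(
        raw_mean=raw_mean,
        raw_std=raw_std,
        norm_mean=norm_mean,
        grand_mean=grand_mean,
        grand_std=grand_std,
        total_segments=n,
    )


def redistribute(
    track: RatioTrack, part: SegmentPartition, stats: SegmentStats
) -> NormalizedTrack:
    """Shift each segment so its mean equals the normalized mean.

    Per-base deviations from the segment mean are kept, so the within-segment
    standard deviation is unchanged.
    """
    if stats.total_segments != part.n_segments:
        raise NormalizationError("stats were computed from a different partition")
    idx = part.kept_indices()
    seg_vals = track.values[idx].reshape(part.n_segments, part.bin_size)
    out = seg_vals + (stats.norm_mean - stats.raw_mean)[:, None]
    return NormalizedTrack(values=out.ravel(), partition=part, index_map=idx)


def write_normalized_tsv(norm: NormalizedTrack, targets: TargetSet, path) -> None:
    """Debug export: (concat_index, chrom, pos, value) for every kept base."""
    from .coverage_io import to_genomic

    with open(path, "w") as fh:
        fh.write("concat_index\tchrom\tpos\tvalue\n")
        for kept, idx in enumerate(norm.index_map):
            chrom, pos = to_genomic(int(idx), targets)
            fh.write(f"{idx}\t{chrom}\t{pos}\t{norm.values[kept]:.6g}\n")


def normalize_track(
    test: CoverageTrack,
    control: CoverageTrack | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    epsilon: float = DEFAULT_EPSILON,
    strict_literal: bool = False,
) -> NormalizedTrack:
    """Full four-step protocol; noRatio mode when ``control`` is None."""
    if control is None:
        ratio = passthrough_test(test)
    else:
        ratio = compute_ratio(test, control, epsilon, strict_literal=strict_literal)
    part = partition(ratio, test.target_set, bin_size)
    stats = normalize_means(ratio, part)
    return redistribute(ratio, part, stats)
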