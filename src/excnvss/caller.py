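"""CNV declaration from the fingerprint map.

Per layer, two parametric baselines are taken from the empirical distribution
of the smoothed signal: the upper baseline is the smallest value among the
top ``(1 - p_max)`` fraction by rank, the lower baseline the largest value
among the bottom ``p_min`` fraction.  Candidate intervals run between two
adjacent zero crossings of opposite sign, with no crossing in between, and
qualify when the mean of the layer over the interval (endpoints inclusive)
lies above the upper or below the lower baseline.

Declaration proceeds from the coarsest informative layer downward: intervals
overlapping regions already declared at coarser layers are skipped, accepted
intervals are traced down the fingerprint map to layer 0 (nearest crossing of
the same sign within a +-3 sigma window per step, position carried through
layers where the contour vanishes), typed gain or loss by which baseline the
mean breaches, and mapped back to genomic coordinates.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .coverage_io import CoverageTrack, TargetSet
from .scalespace import (
    ScaleSchedule,
    ScaleSpace,
    ZeroCrossingMap,
    second_difference,
    smooth_layer,
    zero_crossings,
    _angular_freqs,
)

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 0.9875
DEFAULT_P_MIN_RATIO = 0.0125
DEFAULT_P_MIN_NORATIO = 0.04
MIN_CROSSINGS = 3  # a layer is informative with more than two nonzero entries


class CallerError(ValueError):
    pass


@dataclass
class BaselineSet:
    """Per-layer quantile baselines; NaN where a layer is uninformative."""

    upper: np.ndarray
    lower: np.ndarray
    p_max: float
    p_min: float
    valid_layers: np.ndarray


@dataclass
class Interval:
    """Putative CNV interval at one layer, endpoints on zero crossings."""

    layer: int
    left: int
    right: int
    mean_signal: float
    sign_left: int
    sign_right: int


@dataclass
class CNVCall:
    kind: str  # "gain" | "loss"
    concat_left: int  # inclusive, original concatenated axis
    concat_right: int  # inclusive
    origin_layer: int
    genomic_spans: list  # (chrom, start, end) half-open
    covered_targets: list
    score: float
    norm_left: int = 0  # extent on the normalized (caller-input) axis
    norm_right: int = 0


def _rank_baselines(values: np.ndarray, p_max: float, p_min: float):
    """Upper/lower baselines by rank counting, ties included by value."""
    n = values.size
    c_hi = min(max(int(np.ceil((1.0 - p_max) * n - 1e-9)), 1), n)
    c_lo = min(max(int(np.ceil(p_min * n - 1e-9)), 1), n)
    upper = float(np.partition(values, n - c_hi)[n - c_hi])
    lower = float(np.partition(values, c_lo - 1)[c_lo - 1])
    return upper, lower


def compute_baselines(
    space: ScaleSpace,
    zmap: ZeroCrossingMap,
    p_max: float = DEFAULT_P_MAX,
    p_min: float = DEFAULT_P_MIN_RATIO,
) -> BaselineSet:
    """Quantile baselines for every layer with more than two zero crossings."""
    if not 0 < p_min < p_max < 1:
        raise CallerError("need 0 < p_min < p_max < 1")
    l = space.schedule.n_layers
    upper = np.full(l, np.nan)
    lower = np.full(l, np.nan)
    valid = []
    for k in range(l):
        if zmap.counts[k] >= MIN_CROSSINGS:
            upper[k], lower[k] = _rank_baselines(space.image[k], p_max, p_min)
            valid.append(k)
    if not valid:
        raise CallerError("no signal at any scale")
    return BaselineSet(
        upper=upper, lower=lower, p_max=p_max, p_min=p_min,
        valid_layers=np.array(valid),
    )


def auto_pmin(test: CoverageTrack, floor_pmin: float = DEFAULT_P_MIN_RATIO) -> float:
    """p_min from the zero-depth fraction of the test track, floored.

    Uncovered bases produce zero ratios that pile up in the lower tail of the
    smoothed signal; setting p_min past that pile keeps the lower baseline in
    the informative part of the distribution.
    """
    p = max(floor_pmin, test.zero_fraction)
    if p > 0.5:
        warnings.warn(
            f"zero-depth fraction {p:.3f} too large for a lower quantile; "
            "capping p_min at 0.5",
            stacklevel=2,
        )
        p = 0.5
    return p


# --- per-layer summaries shared by the array API and the streaming path ---


@dataclass
class _LayerSummary:
    layer: int
    pos_plus: np.ndarray  # positions of +1 crossings (sorted)
    pos_minus: np.ndarray  # positions of -1 crossings (sorted)
    valid: bool
    upper: float
    lower: float
    cand_left: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cand_right: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cand_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    cand_sign_left: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))


def _summarize_layer(
    k: int,
    layer_values: np.ndarray,
    z_row: np.ndarray,
    p_max: float,
    p_min: float,
    baselines: tuple[float, float] | None = None,
) -> _LayerSummary:
    positions = np.flatnonzero(z_row)
    signs = z_row[positions]
    pos_plus = positions[signs > 0]
    pos_minus = positions[signs < 0]
    if positions.size < MIN_CROSSINGS:
        return _LayerSummary(k, pos_plus, pos_minus, False, np.nan, np.nan)
    if baselines is None:
        upper, lower = _rank_baselines(layer_values, p_max, p_min)
    else:
        upper, lower = baselines
    # candidate intervals: adjacent crossings of opposite sign
    flip = signs[:-1] * signs[1:] < 0
    left = positions[:-1][flip]
    right = positions[1:][flip]
    if left.size:
        csum = np.concatenate([[0.0], np.cumsum(layer_values)])
        mean = (csum[right + 1] - csum[left]) / (right - left + 1)
        keep = (mean > upper) | (mean < lower)
        left, right, mean = left[keep], right[keep], mean[keep]
        sign_left = signs[:-1][flip][keep]
    else:
        mean = np.empty(0)
        sign_left = np.empty(0, dtype=np.int8)
    return _LayerSummary(
        k, pos_plus, pos_minus, True, upper, lower,
        cand_left=left, cand_right=right, cand_mean=mean,
        cand_sign_left=sign_left.astype(np.int8),
    )


# --- exclusion-set bookkeeping (sorted disjoint inclusive intervals) ---


class _Exclusions:
    def __init__(self):
        self.los: list[int] = []
        self.his: list[int] = []

    def overlaps(self, lo: int, hi: int) -> bool:
        j = bisect_right(self.los, hi)
        return j > 0 and self.his[j - 1] >= lo

    def insert(self, lo: int, hi: int) -> None:
        j = bisect_left(self.los, lo)
        self.los.insert(j, lo)
        self.his.insert(j, hi)

    def largest_free_piece(self, lo: int, hi: int):
        """Longest sub-interval of [lo, hi] avoiding all exclusions."""
        pieces = []
        cur = lo
        j = bisect_right(self.los, hi)
        i = bisect_left(self.his, lo)
        for k in range(i, j):
            a, b = self.los[k], self.his[k]
            if b < lo or a > hi:
                continue
            if a > cur:
                pieces.append((cur, a - 1))
            cur = max(cur, b + 1)
        if cur <= hi:
            pieces.append((cur, hi))
        if not pieces:
            return None
        return max(pieces, key=lambda p: (p[1] - p[0], -p[0]))


def find_intervals(
    layer_k: int,
    zmap: ZeroCrossingMap,
    space: ScaleSpace,
    baselines: BaselineSet,
    excluded=(),
) -> list[Interval]:
    """Putative CNV intervals at one layer, left to right.

    An interval must (1) contain no index of any excluded range, (2) run
    between adjacent zero crossings of opposite sign with only zeros in
    between, and (3) have a layer mean beyond one of the baselines.
    """
    if layer_k not in baselines.valid_layers:
        raise CallerError(f"layer {layer_k} has no baselines")
    summary = _summarize_layer(
        layer_k, space.image[layer_k], zmap.z[layer_k],
        baselines.p_max, baselines.p_min,
        baselines=(float(baselines.upper[layer_k]), float(baselines.lower[layer_k])),
    )
    excl = _Exclusions()
    for lo, hi in excluded:
        excl.insert(int(lo), int(hi))
    out = []
    for l, u, m, sl in zip(
        summary.cand_left, summary.cand_right, summary.cand_mean,
        summary.cand_sign_left,
    ):
        if excl.overlaps(int(l), int(u)):
            continue
        out.append(
            Interval(layer_k, int(l), int(u), float(m), int(sl), int(-sl))
        )
    return out


def _trace_endpoint(
    pos: int, sign: int, layer: int, summaries: list[_LayerSummary],
    sigmas: np.ndarray,
) -> int:
    p = pos
    for kk in range(layer - 1, -1, -1):
        same = summaries[kk].pos_plus if sign > 0 else summaries[kk].pos_minus
        if same.size == 0:
            continue
        w = int(np.ceil(3.0 * sigmas[kk]))
        j = np.searchsorted(same, p)
        best, best_d = None, None
        for cand in (j - 1, j):
            if 0 <= cand < same.size:
                q = int(same[cand])
                d = abs(q - p)
                if d <= w and (best_d is None or d < best_d or (d == best_d and q < best)):
                    best, best_d = q, d
        if best is not None:
            p = best
    return p


def trace_to_base(interval: Interval, zmap: ZeroCrossingMap) -> tuple[int, int]:
    """Follow both interval endpoints down the fingerprint map to layer 0."""
    if zmap.schedule is None:
        raise CallerError("zero-crossing map carries no scale schedule")
    sigmas = zmap.schedule.sigmas
    summaries = []
    for k in range(interval.layer):
        row = zmap.z[k]
        positions = np.flatnonzero(row)
        signs = row[positions]
        summaries.append(
            _LayerSummary(
                k, positions[signs > 0], positions[signs < 0], True,
                np.nan, np.nan,
            )
        )
    lo = _trace_endpoint(interval.left, interval.sign_left, interval.layer, summaries, sigmas)
    hi = _trace_endpoint(interval.right, interval.sign_right, interval.layer, summaries, sigmas)
    if lo >= hi:
        raise CallerError("traced interval collapsed (left >= right)")
    return lo, hi


def _make_call(
    kind: str, origin_layer: int, score: float, norm_lo: int, norm_hi: int,
    targets: TargetSet, index_map: np.ndarray,
) -> CNVCall:
    cl = int(index_map[norm_lo])
    cr = int(index_map[norm_hi])
    i0 = int(targets.target_of_index(cl))
    i1 = int(targets.target_of_index(cr))
    spans = []
    for i in range(i0, i1 + 1):
        off = int(targets.offsets[i])
        length = int(targets.ends[i] - targets.starts[i])
        gs = int(targets.starts[i]) + max(cl - off, 0)
        ge = int(targets.starts[i]) + min(cr + 1 - off, length)
        spans.append((str(targets.chroms[i]), gs, ge))
    return CNVCall(
        kind=kind, concat_left=cl, concat_right=cr, origin_layer=origin_layer,
        genomic_spans=spans, covered_targets=list(range(i0, i1 + 1)),
        score=score, norm_left=norm_lo, norm_right=norm_hi,
    )


def _declare_calls(
    summaries: list[_LayerSummary],
    schedule: ScaleSchedule,
    targets: TargetSet,
    index_map: np.ndarray,
) -> list[CNVCall]:
    """Top-down interval declaration with exclusion and contour tracing."""
    sigmas = schedule.sigmas
    valid_layers = [s.layer for s in summaries if s.valid]
    if not valid_layers:
        return []
    excl = _Exclusions()
    calls = []
    for k in sorted(valid_layers, reverse=True):
        s = summaries[k]
        for l, u, m, sl in zip(
            s.cand_left, s.cand_right, s.cand_mean, s.cand_sign_left
        ):
            l, u, m, sl = int(l), int(u), float(m), int(sl)
            if excl.overlaps(l, u):
                continue
            if m > s.upper:
                kind = "gain"
            elif m < s.lower:
                kind = "loss"
            else:  # pragma: no cover - candidates are prefiltered
                continue
            lo = _trace_endpoint(l, sl, k, summaries, sigmas)
            hi = _trace_endpoint(u, -sl, k, summaries, sigmas)
            if lo >= hi:
                logger.warning(
                    "traced interval collapsed at layer %d (%d..%d); dropped",
                    k, l, u,
                )
                continue
            piece = excl.largest_free_piece(lo, hi)
            if piece is None:
                continue
            lo, hi = piece
            excl.insert(lo, hi)
            calls.append(_make_call(kind, k, m, lo, hi, targets, index_map))
    calls.sort(key=lambda c: c.concat_left)
    return calls


def call_cnvs(
    space: ScaleSpace,
    zmap: ZeroCrossingMap,
    baselines: BaselineSet,
    targets: TargetSet,
    index_map: np.ndarray,
) -> list[CNVCall]:
    """Declare CNVs from a fully materialized scale space."""
    summaries = []
    for k in range(space.schedule.n_layers):
        bl = None
        if not np.isnan(baselines.upper[k]):
            bl = (float(baselines.upper[k]), float(baselines.lower[k]))
        summaries.append(
            _summarize_layer(
                k, space.image[k], zmap.z[k], baselines.p_max,
                baselines.p_min, baselines=bl,
            )
        )
    return _declare_calls(summaries, space.schedule, targets, index_map)


def run_streaming_caller(
    values: np.ndarray,
    index_map: np.ndarray,
    targets: TargetSet,
    schedule: ScaleSchedule | None = None,
    p_max: float = DEFAULT_P_MAX,
    p_min: float = DEFAULT_P_MIN_RATIO,
) -> list[CNVCall]:
    """Layer-by-layer caller that never materializes the full scale space.

    Equivalent to ``build_scale_space`` + ``fingerprint`` +
    ``compute_baselines`` + ``call_cnvs`` but holds only one smoothed layer
    in memory at a time, so genome-scale concatenated signals fit easily.
    """
    from scipy import fft as sp_fft

    if not 0 < p_min < p_max < 1:
        raise CallerError("need 0 < p_min < p_max < 1")
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if schedule is None:
        schedule = ScaleSchedule.for_signal(n)
    spectrum = sp_fft.rfft(values)
    w = _angular_freqs(n)
    summaries = []
    for k, sigma in enumerate(schedule.sigmas):
        c_k = smooth_layer(spectrum, sigma, n, w)
        z_row = zero_crossings(second_difference(c_k))
        s = _summarize_layer(k, c_k, z_row, p_max, p_min)
        summaries.append(s)
        logger.info(
            "layer %d (sigma %.0f): %d crossings, %d qualifying intervals",
            k, sigma, s.pos_plus.size + s.pos_minus.size, s.cand_left.size,
        )
    return _declare_calls(summaries, schedule, targets, index_map)


def write_calls(calls: list[CNVCall], path) -> None:
    """BED6+ export: one line per contiguous genomic span of each call."""
    rows = []
    for ci, call in enumerate(calls):
        for chrom, start, end in call.genomic_spans:
            rows.append(
                (
                    chrom, start, end, call.kind.upper(), call.score, ".",
                    call.origin_layer, ci,
                    ",".join(map(str, call.covered_targets)),
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\torigin_layer"
            "\tcall_id\tcovered_target_ids\n"
        )
        for r in rows:
            fh.write(
                f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]:.6g}\t{r[5]}"
                f"\t{r[6]}\t{r[7]}\t{r[8]}\n"
            )


def read_calls(path, targets: TargetSet) -> list[CNVCall]:
    """Re-parse a calls BED written by :func:`write_calls`."""
    by_id: dict[int, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            cid = int(f[7])
            rec = by_id.setdefault(
                cid,
                {
                    "kind": f[3].lower(), "score": float(f[4]),
                    "layer": int(f[6]),
                    "targets": [int(x) for x in f[8].split(",")],
                    "spans": [],
                },
            )
            rec["spans"].append((f[0], int(f[1]), int(f[2])))
    calls = []
    for cid in sorted(by_id):
        rec = by_id[cid]
        spans = sorted(rec["spans"], key=lambda s: (s[0], s[1]))
        cl = targets.to_concat(spans[0][0], spans[0][1])
        cr = targets.to_concat(spans[-1][0], spans[-1][2] - 1)
        calls.append(
            CNVCall(
                kind=rec["kind"], concat_left=cl, concat_right=cr,
                origin_layer=rec["layer"], genomic_spans=spans,
                covered_targets=rec["targets"], score=rec["score"],
            )
        )
    calls.sort(key=lambda c: c.concat_left)
    return calls
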