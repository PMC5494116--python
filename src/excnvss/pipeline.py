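"""End-to-end orchestration: coverage in, CNV calls out."""

from __future__ import annotations

from .caller import (
    CNVCall,
    DEFAULT_P_MAX,
    DEFAULT_P_MIN_NORATIO,
    DEFAULT_P_MIN_RATIO,
    auto_pmin,
    run_streaming_caller,
)
from .coverage_io import CoverageTrack
from .normalize import DEFAULT_BIN_SIZE, DEFAULT_EPSILON, normalize_track
from .scalespace import ScaleSchedule


def call_pipeline(
    test: CoverageTrack,
    control: CoverageTrack | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    epsilon: float = DEFAULT_EPSILON,
    p_max: float = DEFAULT_P_MAX,
    p_min: float | None = None,
    schedule: ScaleSchedule | None = None,
    base_sigma: float = 100.0,
    growth: float = 1.1,
    max_layers: int = 50,
    use_auto_pmin: bool = False,
    strict_literal: bool = False,
) -> list[CNVCall]:
    """Normalize, filter and call CNVs on one test (and optional control) track.

    Ratio mode when ``control`` is given, test-only (noRatio) mode otherwise;
    ``p_min`` defaults to 0.0125 in ratio mode and 0.04 in noRatio mode, the
    best-performing settings of the simulation study.
    """
    if p_min is None:
        p_min = DEFAULT_P_MIN_RATIO if control is not None else DEFAULT_P_MIN_NORATIO
    if use_auto_pmin:
        p_min = auto_pmin(test, floor_pmin=p_min)
    normalized = normalize_track(
        test, control, bin_size=bin_size, epsilon=epsilon,
        strict_literal=strict_literal,
    )
    n = normalized.values.size
    if schedule is None:
        schedule = ScaleSchedule.for_signal(
            n, base_sigma=base_sigma, growth=growth, max_layers=max_layers
        )
    return run_streaming_caller(
        normalized.values,
        normalized.index_map,
        test.target_set,
        schedule=schedule,
        p_max=p_max,
        p_min=p_min,
    )
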