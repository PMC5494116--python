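"""Target-level scoring of call sets against simulated truth.

A truth region (a run of whole targets) is *validated* when matching-kind
calls cover strictly more than ``min_overlap_frac`` (default 30%) of its
transcript length — transcript coordinates count only bases inside targets,
i.e. the concatenated axis.  FNR is the percentage of truth regions not
validated.  FPR is the percentage of targets outside any truth region that
are touched by a call (per-target specificity); an alternative
precision-style rate over called targets is available via ``fpr_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import CNVCall
from .coverage_io import TargetSet
from .simulate import SIZE_CLASS_BOUNDS, TruthSet


class EvaluationError(ValueError):
    pass


def size_class(transcript_length: int) -> str:
    """Size class of a truth region by its transcript length."""
    if transcript_length < 160:
        return "small"
    if transcript_length < 300:
        return "medium"
    return "large"


@dataclass
class EvalResult:
    n_truth_regions: int
    n_validated: int
    n_called_target_regions: int
    n_false_positive_regions: int
    fnr: float  # percent; NaN when truth is empty
    fpr: float  # percent
    by_size: dict = field(default_factory=dict)
    by_kind: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_truth_regions": self.n_truth_regions,
            "n_validated": self.n_validated,
            "n_called_target_regions": self.n_called_target_regions,
            "n_false_positive_regions": self.n_false_positive_regions,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "by_size": self.by_size,
            "by_kind": self.by_kind,
        }


def _covered_length(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total length of [lo, hi) covered by a union of half-open intervals."""
    clipped = sorted(
        (max(a, lo), min(b, hi)) for a, b in intervals if a < hi and b > lo
    )
    total, cur = 0, lo
    for a, b in clipped:
        a = max(a, cur)
        if b > a:
            total += b - a
            cur = b
    return total


def validate_regions(
    calls: list[CNVCall],
    truth: TruthSet,
    targets: TargetSet,
    min_overlap_frac: float = 0.30,
    match_kind: bool = True,
    fpr_mode: str = "target",
) -> EvalResult:
    """Score calls against truth with the 30%-overlap target-level rule."""
    if not 0 < min_overlap_frac <= 1:
        raise EvaluationError("min_overlap_frac must be in (0, 1]")
    call_iv = {
        "gain": [
            (c.concat_left, c.concat_right + 1) for c in calls if c.kind == "gain"
        ],
        "loss": [
            (c.concat_left, c.concat_right + 1) for c in calls if c.kind == "loss"
        ],
    }
    all_iv = call_iv["gain"] + call_iv["loss"]

    bounds = truth.concat_bounds(targets) if truth.events else np.empty((0, 2), int)
    n_truth = len(truth.events)
    n_validated = 0
    by_size: dict[str, dict] = {}
    by_kind: dict[str, dict] = {}
    for ev, (lo, hi) in zip(truth.events, bounds):
        ivs = call_iv[ev.kind] if match_kind else all_iv
        covered = _covered_length(ivs, int(lo), int(hi))
        ok = covered > min_overlap_frac * (hi - lo)
        n_validated += ok
        cls = size_class(int(hi - lo))
        for key, table in ((cls, by_size), (ev.kind, by_kind)):
            d = table.setdefault(key, {"n_truth": 0, "n_validated": 0})
            d["n_truth"] += 1
            d["n_validated"] += ok
    for table in (by_size, by_kind):
        for d in table.values():
            d["fnr"] = 100.0 * (1 - d["n_validated"] / d["n_truth"])

    # per-target false positives
    truth_targets = set(truth.covered_target_ids().tolist())
    called_targets: set[int] = set()
    for c in calls:
        called_targets.update(c.covered_targets)
    fp_targets = called_targets - truth_targets
    n_outside = targets.n_targets - len(truth_targets)
    if fpr_mode == "target":
        fpr = 100.0 * len(fp_targets) / n_outside if n_outside else float("nan")
    elif fpr_mode == "precision":
        fpr = (
            100.0 * len(fp_targets) / len(called_targets)
            if called_targets
            else float("nan")
        )
    else:
        raise EvaluationError(f"unknown fpr_mode {fpr_mode!r}")
    fnr = 100.0 * (1 - n_validated / n_truth) if n_truth else float("nan")
    return EvalResult(
        n_truth_regions=n_truth,
        n_validated=n_validated,
        n_called_target_regions=len(called_targets),
        n_false_positive_regions=len(fp_targets),
        fnr=fnr,
        fpr=fpr,
        by_size=by_size,
        by_kind=by_kind,
    )


def sweep_thresholds(
    datasets: list,
    grid: list[tuple[float, float]],
    mode: str = "ratio",
    bin_size: int = 30,
    min_overlap_frac: float = 0.30,
    **caller_kwargs,
) -> pd.DataFrame:
    """FNR/FPR over a (p_max, p_min) grid, averaged over replicates.

    ``datasets`` is a list of ``(targets, truth, test, control)`` tuples, e.g.
    from :func:`excnvss.simulate.simulate_dataset`.  Returns one row per grid
    point with mean and standard deviation of FNR, FPR and call counts.
    """
    from .pipeline import call_pipeline

    if not grid:
        raise EvaluationError("empty threshold grid")
    rows = []
    for p_max, p_min in grid:
        fnrs, fprs, counts = [], [], []
        for targets, truth, test, control in datasets:
            calls = call_pipeline(
                test,
                control=control if mode == "ratio" else None,
                bin_size=bin_size,
                p_max=p_max,
                p_min=p_min,
                **caller_kwargs,
            )
            res = validate_regions(
                calls, truth, targets, min_overlap_frac=min_overlap_frac
            )
            fnrs.append(res.fnr)
            fprs.append(res.fpr)
            counts.append(len(calls))
        rows.append(
            {
                "p_max": p_max,
                "p_min": p_min,
                "fnr_mean": float(np.mean(fnrs)),
                "fnr_sd": float(np.std(fnrs, ddof=1)) if len(fnrs) > 1 else 0.0,
                "fpr_mean": float(np.mean(fprs)),
                "fpr_sd": float(np.std(fprs, ddof=1)) if len(fprs) > 1 else 0.0,
                "calls_mean": float(np.mean(counts)),
            }
        )
    return pd.DataFrame(rows)
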