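"""Coverage-level exome simulation with planted CNVs and a matched control.

The generator emulates a targeted-capture experiment at the depth level (no
reads, no alignment): target lengths follow a shifted, truncated log-normal
law calibrated to a 115 bp minimum, ~240 bp mean and 8,551 bp maximum; mean
depth defaults to 40x for both samples; per-base depth is negative-binomial
around a per-target capture-bias factor (log-normal, shared by test and
control, so the test/control ratio cancels it); CNV events occupy
non-overlapping runs of consecutive targets and scale the test mean by 0.5
(heterozygous loss) or 1.5 (heterozygous gain).  The control carries no
events.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coverage_io import CoverageTrack, TargetSet


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated replicate."""

    n_targets: int = 21000
    len_min: int = 115
    len_mean: float = 240.0
    len_max: int = 8551
    len_log_sigma: float = 1.0  # shape of the shifted log-normal length law
    gap_min: int = 200
    gap_max: int = 5000
    mean_depth_test: float = 40.0
    mean_depth_control: float = 40.0
    dispersion: float = 8.0  # negative-binomial size; inf -> Poisson
    n_events: int = 25
    span_min: int = 1  # consecutive targets per event
    span_max: int = 5
    multiplier_loss: float = 0.5
    multiplier_gain: float = 1.5
    event_kind: str = "both"  # "both" (fair coin) | "gain" | "loss"
    bias_amplitude: float = 0.3  # log-sd of the shared per-target bias
    seed: int = 0

    def rngs(self) -> tuple[np.random.Generator, ...]:
        """Independent streams for targets, events and coverage."""
        return tuple(
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed).spawn(3)
        )


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # "gain" | "loss"
    first_target: int
    last_target: int
    multiplier: float


@dataclass
class TruthSet:
    """Planted CNV events, each a run of whole targets."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        covered = set()
        for ev in self.events:
            ids = range(ev.first_target, ev.last_target + 1)
            if covered & set(ids):
                raise SimulationError("truth events overlap in target space")
            covered.update(ids)

    def covered_target_ids(self) -> np.ndarray:
        ids = [
            t for ev in self.events
            for t in range(ev.first_target, ev.last_target + 1)
        ]
        return np.array(sorted(ids), dtype=np.int64)

    def concat_bounds(self, targets: TargetSet) -> np.ndarray:
        """Half-open (lo, hi) concatenated extent of each event."""
        out = np.empty((len(self.events), 2), dtype=np.int64)
        for i, ev in enumerate(self.events):
            lo = int(targets.offsets[ev.first_target])
            hi = int(
                targets.offsets[ev.last_target]
                + targets.lengths[ev.last_target]
            )
            out[i] = (lo, hi)
        return out

    def transcript_lengths(self, targets: TargetSet) -> np.ndarray:
        b = self.concat_bounds(targets)
        return b[:, 1] - b[:, 0]


def simulate_targets(config: SimConfig, rng: np.random.Generator | None = None) -> TargetSet:
    """Synthetic capture design on one chromosome.

    Lengths are ``len_min + floor(X)`` with ``X`` log-normal whose mean is
    calibrated to ``len_mean - len_min``, clipped at ``len_max``; inter-target
    gaps are uniform in ``[gap_min, gap_max]``.
    """
    if config.n_targets < 1:
        raise SimulationError("n_targets must be >= 1")
    excess = config.len_mean - config.len_min
    if excess <= 0 or config.len_max <= config.len_min:
        raise SimulationError("infeasible target length law")
    if rng is None:
        rng = config.rngs()[0]
    sigma = config.len_log_sigma
    mu = np.log(excess) - 0.5 * sigma**2
    lengths = config.len_min + np.floor(rng.lognormal(mu, sigma, config.n_targets))
    lengths = np.minimum(lengths, config.len_max).astype(np.int64)
    gaps = rng.integers(config.gap_min, config.gap_max + 1, config.n_targets)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    ends = starts + lengths
    chroms = np.array(["chrS"] * config.n_targets, dtype=object)
    return TargetSet(chroms, starts, ends)


def plant_events(
    targets: TargetSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Place non-overlapping CNV events on random runs of consecutive targets.

    At least one unaffected target is kept between events so adjacent truth
    regions remain distinct on the concatenated axis.
    """
    if rng is None:
        rng = config.rngs()[1]
    n = targets.n_targets
    if config.n_events * config.span_max > n:
        raise SimulationError("too many events for the number of targets")
    used = np.zeros(n, dtype=bool)
    events = []
    max_tries = 1000 * max(config.n_events, 1)
    tries = 0
    while len(events) < config.n_events:
        if tries >= max_tries:
            raise SimulationError("could not place events without overlap")
        tries += 1
        span = int(rng.integers(config.span_min, config.span_max + 1))
        t0 = int(rng.integers(0, n - span + 1))
        lo, hi = max(t0 - 1, 0), min(t0 + span + 1, n)  # 1-target buffer
        if used[lo:hi].any():
            continue
        used[t0 : t0 + span] = True
        if config.event_kind == "both":
            kind = "gain" if rng.random() < 0.5 else "loss"
        else:
            kind = config.event_kind
        mult = config.multiplier_gain if kind == "gain" else config.multiplier_loss
        events.append(TruthEvent(kind, t0, t0 + span - 1, mult))
    events.sort(key=lambda e: e.first_target)
    return TruthSet(events)


SIZE_CLASS_BOUNDS = {"small": (100, 159), "medium": (160, 299), "large": (300, 8260)}


def plant_events_stratified(
    targets: TargetSet,
    class_counts: dict,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Plant events whose transcript lengths fall in given size classes.

    ``class_counts`` maps class names (see :data:`SIZE_CLASS_BOUNDS`) to the
    number of events to plant in that class.  Small and medium events are
    single targets of matching length; large events are single long targets
    or short runs of consecutive targets whose summed length lands in range.
    """
    if rng is None:
        rng = config.rngs()[1]
    lengths = targets.lengths
    n = targets.n_targets
    used = np.zeros(n, dtype=bool)
    events = []

    def free(t0, t1):
        return not used[max(t0 - 1, 0) : min(t1 + 2, n)].any()

    for cls, count in class_counts.items():
        lo, hi = SIZE_CLASS_BOUNDS[cls]
        singles = np.flatnonzero((lengths >= lo) & (lengths <= hi))
        rng.shuffle(singles)
        placed = 0
        for t in singles:
            if placed >= count:
                break
            t = int(t)
            if not free(t, t):
                continue
            used[t] = True
            kind = "gain" if rng.random() < 0.5 else "loss"
            mult = (
                config.multiplier_gain if kind == "gain"
                else config.multiplier_loss
            )
            events.append(TruthEvent(kind, t, t, mult))
            placed += 1
        # fall back to runs of consecutive targets for the large class
        tries = 0
        while placed < count and tries < 200 * count:
            tries += 1
            span = int(rng.integers(2, 5))
            t0 = int(rng.integers(0, n - span + 1))
            if not free(t0, t0 + span - 1):
                continue
            total = int(lengths[t0 : t0 + span].sum())
            if not lo <= total <= hi:
                continue
            used[t0 : t0 + span] = True
            kind = "gain" if rng.random() < 0.5 else "loss"
            mult = (
                config.multiplier_gain if kind == "gain"
                else config.multiplier_loss
            )
            events.append(TruthEvent(kind, t0, t0 + span - 1, mult))
            placed += 1
        if placed < count:
            raise SimulationError(
                f"could not place {count} events in size class {cls}"
            )
    events.sort(key=lambda e: e.first_target)
    return TruthSet(events)


def simulate_coverage(
    targets: TargetSet,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Test and control depth tracks with shared per-target capture bias."""
    if rng is None:
        rng = config.rngs()[2]
    n = targets.n_targets
    for ev in truth.events:
        if not 0 <= ev.first_target <= ev.last_target < n:
            raise SimulationError("truth event outside target range")
    lengths = targets.lengths
    if config.bias_amplitude > 0:
        bias = rng.lognormal(
            -0.5 * config.bias_amplitude**2, config.bias_amplitude, n
        )
    else:
        bias = np.ones(n)
    mult = np.ones(n)
    for ev in truth.events:
        mult[ev.first_target : ev.last_target + 1] = ev.multiplier
    mu_test = np.repeat(config.mean_depth_test * bias * mult, lengths)
    mu_control = np.repeat(config.mean_depth_control * bias, lengths)

    def draw(mu):
        if np.isinf(config.dispersion):
            return rng.poisson(mu).astype(np.float64)
        r = config.dispersion
        return rng.negative_binomial(r, r / (r + mu)).astype(np.float64)

    test = CoverageTrack(draw(mu_test), targets, sample_label="test")
    control = CoverageTrack(draw(mu_control), targets, sample_label="control")
    return test, control


def simulate_dataset(config: SimConfig):
    """Targets, truth and both coverage tracks for one replicate."""
    rng_t, rng_e, rng_c = config.rngs()
    targets = simulate_targets(config, rng_t)
    truth = plant_events(targets, config, rng_e)
    test, control = simulate_coverage(targets, truth, config, rng_c)
    return targets, truth, test, control


def write_truth_bed(truth: TruthSet, targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tkind\tmultiplier\tfirst_target\tlast_target\n")
        for ev in truth.events:
            chrom = str(targets.chroms[ev.first_target])
            start = int(targets.starts[ev.first_target])
            end = int(targets.ends[ev.last_target])
            fh.write(
                f"{chrom}\t{start}\t{end}\t{ev.kind}\t{ev.multiplier}"
                f"\t{ev.first_target}\t{ev.last_target}\n"
            )


def read_truth_bed(path) -> TruthSet:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            events.append(TruthEvent(f[3], int(f[5]), int(f[6]), float(f[4])))
    return TruthSet(events)


def config_with(config: SimConfig, **kwargs) -> SimConfig:
    return replace(config, **kwargs)
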