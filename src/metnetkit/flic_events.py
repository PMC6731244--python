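"""Feeding-interaction and feeding-event analytics for 5 Hz signals.

An interaction is a sample strictly above the signal threshold (default
40).  An event is a maximal run of at least ``min_run`` consecutive
interactions; runs still active at the final sample are censored.
Group statistics use a device-stratified bootstrap of the median with
BCa intervals, and a stratified randomization test on the difference in
medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SAMPLE_RATE_HZ",
    "FlicTrace",
    "FeedingEvent",
    "FeedingSummary",
    "BootstrapResult",
    "detect_interactions",
    "detect_events",
    "summarize_fly",
    "stratified_bca_bootstrap",
    "randomization_test_medians",
]

logger = logging.getLogger(__name__)

SAMPLE_RATE_HZ = 5.0
SAMPLE_SECONDS = 1.0 / SAMPLE_RATE_HZ

DEFAULT_THRESHOLD = 40.0
DEFAULT_MIN_RUN = 5


@dataclass
class FlicTrace:
    fly_id: str
    device_id: str
    signal: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"trace {self.fly_id!r}: signal contains non-finite values")

    @property
    def duration_seconds(self) -> float:
        return len(self.signal) / self.sample_rate


@dataclass(frozen=True)
class FeedingEvent:
    start: int  # sample index, inclusive
    end: int  # sample index, inclusive

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1

    @property
    def duration_seconds(self) -> float:
        return self.n_samples * SAMPLE_SECONDS


@dataclass(frozen=True)
class FeedingSummary:
    fly_id: str
    device_id: str
    n_interactions: int
    n_events: int
    mean_event_duration_s: float  # NaN when no events
    mean_inter_event_interval_min: float  # NaN unless >= 2 events
    latency_min: float  # NaN when no interactions
    ate: bool  # any interaction at all


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    method: str = "BCa"


def detect_interactions(
    tr: FlicTrace, threshold: float = DEFAULT_THRESHOLD
) -> tuple[np.ndarray, int]:
    """Boolean interaction mask (signal strictly above *threshold*) + count."""
    if len(tr.signal) == 0:
        raise ValueError("trace is empty")
    mask = tr.signal > threshold
    return mask, int(mask.sum())


def detect_events(
    mask: np.ndarray, min_run: int = DEFAULT_MIN_RUN, censor_end: bool = True
) -> list[FeedingEvent]:
    """Maximal runs of True of length >= *min_run*, as disjoint ordered events.

    With *censor_end*, a run that is still True at the last sample is
    dropped (the event did not conclude within the recording).
    """
    mask = np.asarray(mask, dtype=bool)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1  # inclusive
    events = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_run:
            continue
        if censor_end and e == len(mask) - 1:
            continue
        events.append(FeedingEvent(int(s), int(e)))
    return events


def summarize_fly(
    tr: FlicTrace,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    censor_end: bool = True,
) -> FeedingSummary:
    """Per-fly behavioral statistics.

    Latency is the time to the *first interaction* (minutes).  The
    inter-event interval averages only the gaps between consecutive
    events (end of one to start of the next) and needs >= 2 events.
    Undefined statistics are NaN, never 0.
    """
    mask, n_interactions = detect_interactions(tr, threshold)
    events = detect_events(mask, min_run=min_run, censor_end=censor_end)

    if events:
        mean_duration = float(np.mean([ev.duration_seconds for ev in events]))
    else:
        mean_duration = math.nan
    if len(events) >= 2:
        gaps = [
            (events[i + 1].start - events[i].end - 1) * SAMPLE_SECONDS
            for i in range(len(events) - 1)
        ]
        mean_interval_min = float(np.mean(gaps) / 60.0)
    else:
        mean_interval_min = math.nan
    if n_interactions:
        first = int(np.flatnonzero(mask)[0])
        latency_min = first * SAMPLE_SECONDS / 60.0
    else:
        latency_min = math.nan
    return FeedingSummary(
        fly_id=tr.fly_id,
        device_id=tr.device_id,
        n_interactions=n_interactions,
        n_events=len(events),
        mean_event_duration_s=mean_duration,
        mean_inter_event_interval_min=mean_interval_min,
        latency_min=latency_min,
        ate=n_interactions > 0,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _strata_indices(strata: Sequence) -> list[np.ndarray]:
    strata = np.asarray(strata)
    out = []
    for s in sorted(set(strata.tolist()), key=str):
        idx = np.flatnonzero(strata == s)
        if len(idx) == 1:
            logger.warning("stratum %r has a single member", s)
        out.append(idx)
    return out


def _stratified_boot_medians(
    values: np.ndarray, groups: list[np.ndarray], n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized: n_boot medians of within-stratum resamples."""
    columns = []
    for idx in groups:
        draw = rng.integers(0, len(idx), size=(n_boot, len(idx)))
        columns.append(values[idx[draw]])
    return np.median(np.concatenate(columns, axis=1), axis=1)


def stratified_bca_bootstrap(
    values: Sequence[float],
    strata: Sequence,
    n_boot: int = 1000,
    seed: int | None = None,
    confidence: float = 0.95,
) -> BootstrapResult:
    """BCa bootstrap CI for the median, resampling within strata.

    Flies are resampled with replacement inside each stratum (device);
    the statistic is the pooled median.  Bias correction comes from the
    bootstrap distribution, acceleration from a leave-one-fly-out
    jackknife.  Reproducible bit-for-bit for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    if len(values) < 2:
        raise ValueError("need >= 2 observations")
    if len(values) != len(strata):
        raise ValueError("values and strata must align")
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite (drop undefined statistics first)")
    rng = np.random.default_rng(seed)
    groups = _strata_indices(strata)
    observed = float(np.median(values))
    boot = _stratified_boot_medians(values, groups, n_boot, rng)

    if np.allclose(boot, boot[0]) and math.isclose(boot[0], observed):
        return BootstrapResult(observed, observed, observed, n_boot)

    # bias correction
    prop_below = np.mean(boot < observed) + 0.5 * np.mean(boot == observed)
    prop_below = min(max(prop_below, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop_below)

    # acceleration from jackknife over flies
    n = len(values)
    jack = np.empty(n)
    for i in range(n):
        jack[i] = np.median(np.delete(values, i))
    jmean = jack.mean()
    num = ((jmean - jack) ** 3).sum()
    den = 6.0 * (((jmean - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0

    alpha = (1.0 - confidence) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        z = stats.norm.ppf(q)
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        lo_hi.append(float(stats.norm.cdf(adj)))
    ci_low, ci_high = np.quantile(boot, lo_hi)
    return BootstrapResult(observed, float(ci_low), float(ci_high), n_boot)


def randomization_test_medians(
    group_a: Sequence[float],
    group_b: Sequence[float],
    strata_a: Sequence | None = None,
    strata_b: Sequence | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for the difference in group medians.

    Labels are shuffled within strata (all observations of one stratum
    are permuted among themselves, preserving per-stratum group sizes).
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if strata_a is None:
        strata_a = np.zeros(len(a))
    if strata_b is None:
        strata_b = np.zeros(len(b))
    strata = np.concatenate([np.asarray(strata_a), np.asarray(strata_b)])
    pooled = np.concatenate([a, b])
    is_a = np.concatenate([np.ones(len(a), dtype=bool), np.zeros(len(b), dtype=bool)])
    observed = abs(float(np.median(a) - np.median(b)))

    rng = np.random.default_rng(seed)
    # Permute values within each stratum (vectorized over permutations);
    # per-stratum group sizes are preserved by construction.
    a_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    for s in sorted(set(strata.tolist()), key=str):
        idx = np.flatnonzero(strata == s)
        n_as = int(is_a[idx].sum())
        block = rng.permuted(np.tile(pooled[idx], (n_perm, 1)), axis=1)
        if n_as:
            a_parts.append(block[:, :n_as])
        if n_as < len(idx):
            b_parts.append(block[:, n_as:])
    null = np.median(np.concatenate(a_parts, axis=1), axis=1) - np.median(
        np.concatenate(b_parts, axis=1), axis=1
    )
    exceed = int(np.sum(np.abs(null) >= observed - 1e-12))
    return (1.0 + exceed) / (1.0 + n_perm)
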