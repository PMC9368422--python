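"""Synthetic therapy sessions with known affective ground truth.

The generator emulates the study conditions end to end: a piecewise-constant
SAM-region trajectory per PAD dimension with skewed occupancy, a consumer-EEG
metric stream consistent with that trajectory, and a panel of imperfect human
reviewers who annotate only perceived changes. Because the ground truth is
known, downstream stages can be tested for exact recovery and the reviewer
agreement parameter can be re-measured from the pipeline's own output.

Truth process
-------------
Per dimension, a continuous-time Markov jump process on regions 1..5: from
region i the process jumps to j != i at rate lam * pi_j, where pi is the
configured stationary vector. This chain is reversible with stationary
distribution exactly pi, successive regions always differ, the dwell in each
region is exponential, and lam is chosen so the *overall* mean dwell (time
between changes, long run) equals ``mean_dwell_s``. Change points are then
quantized up to the sampling grid so that the sampled metric stream carries
the complete trajectory.

Reviewers
---------
Each reviewer emits a bootstrap event at t=0 and, at each true change point,
an event with probability ``p_detect``; its timestamp gets Gaussian jitter
(sd ``jitter_sd_s``) truncated so the reviewer's events stay ordered, and
each dimension's label equals the truth with probability ``p_agree``,
otherwise an adjacent region distinct from the truth (SAM scales are
ordinal; mistakes concentrate next to the diagonal).

All randomness flows from ``config.seed`` through per-stage substreams, so a
fixed (seed, config) pair reproduces the session byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import MappingConfig, SyntheticConfig
from .mapping import discretize_array, invert_pad_array, map_metrics_array
from .types import (
    DIMENSIONS,
    HUMAN,
    MACHINE,
    N_REGIONS,
    AnnotationEvent,
    MetricSample,
    PADRegion,
)

# substream indices so each stage draws from an independent, reproducible stream
_TRUTH, _METRICS, _REVIEWERS = 0, 1, 2


@dataclass(frozen=True)
class TruthInterval:
    """Ground-truth half-open span of one dimension's region."""

    start: float
    end: float
    region: int


@dataclass
class SyntheticSession:
    """One generated session: ground truth plus everything observable."""

    session_id: str
    config: SyntheticConfig
    truth: dict[str, list[TruthInterval]]
    metrics: list[MetricSample]
    machine_events: list[AnnotationEvent]
    reviewer_events: dict[str, list[AnnotationEvent]]


def _rng(config: SyntheticConfig, stage: int, session_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, session_index, stage])


def generate_truth(config: SyntheticConfig,
                   session_index: int = 0) -> dict[str, list[TruthInterval]]:
    """Draw one region trajectory per PAD dimension.

    Intervals tile [0, session_length_s) exactly; change points sit on the
    sampling grid and successive regions differ.
    """
    rng = _rng(config, _TRUTH, session_index)
    dt = 1.0 / config.sample_rate_hz
    length = config.session_length_s
    truth: dict[str, list[TruthInterval]] = {}
    for dim in DIMENSIONS:
        pi = config.stationary(dim)
        intervals: list[TruthInterval] = []
        if pi.max() >= 1.0 - 1e-12:
            region = int(pi.argmax()) + 1
            truth[dim] = [TruthInterval(0.0, length, region)]
            continue
        # overall change rate 1/mean_dwell under stationarity
        lam = 1.0 / (config.mean_dwell_s * (1.0 - float(pi @ pi)))
        region = int(rng.choice(N_REGIONS, p=pi)) + 1
        t = 0.0
        while t < length:
            hold_rate = lam * (1.0 - pi[region - 1])
            dwell = rng.exponential(1.0 / hold_rate)
            t_next = np.ceil((t + dwell) / dt) * dt  # quantize up to the grid
            t_next = max(t_next, t + dt)
            if t_next >= length:
                intervals.append(TruthInterval(t, length, region))
                break
            intervals.append(TruthInterval(t, float(t_next), region))
            jump_p = pi.copy()
            jump_p[region - 1] = 0.0
            jump_p /= jump_p.sum()
            region = int(rng.choice(N_REGIONS, p=jump_p)) + 1
            t = float(t_next)
        truth[dim] = intervals
    return truth


def region_at(intervals: Sequence[TruthInterval], times: np.ndarray) -> np.ndarray:
    """Region of each query time (vectorized lookup over tiling intervals)."""
    starts = np.asarray([iv.start for iv in intervals])
    regions = np.asarray([iv.region for iv in intervals], dtype=np.int64)
    idx = np.searchsorted(starts, np.asarray(times), side="right") - 1
    return regions[np.clip(idx, 0, len(intervals) - 1)]


def change_points(truth: dict[str, list[TruthInterval]]) -> np.ndarray:
    """Sorted union of interior change times across the three dimensions."""
    times = sorted({iv.start for ivs in truth.values() for iv in ivs} - {0.0})
    return np.asarray(times)


def generate_metrics(truth: dict[str, list[TruthInterval]],
                     config: SyntheticConfig,
                     mapping: MappingConfig | None = None,
                     session_index: int = 0) -> list[MetricSample]:
    """Sample a metric stream consistent with the true region trajectory.

    At each sample time a continuous PAD vector is drawn uniformly inside the
    true region's bin, pushed back through the (invertible) metric-to-PAD
    map, perturbed with Gaussian noise of sd ``metric_noise_sd``, and clipped
    to [0,1].
    """
    mapping = mapping or MappingConfig()
    rng = _rng(config, _METRICS, session_index)
    dt = 1.0 / config.sample_rate_hz
    n = int(round(config.session_length_s * config.sample_rate_hz))
    times = np.arange(n) * dt
    width = 1.0 / N_REGIONS
    pad = np.empty((n, 3))
    for d, dim in enumerate(DIMENSIONS):
        regions = region_at(truth[dim], times)
        low = (regions - 1) * width
        u = rng.uniform(0.0, width, size=n)
        # keep strictly inside the bin so discretization is float-safe
        pad[:, d] = low + np.clip(u, 1e-9, width - 1e-9)
    metrics = invert_pad_array(pad, mapping)
    if config.metric_noise_sd > 0:
        metrics = metrics + rng.normal(0.0, config.metric_noise_sd, size=metrics.shape)
    metrics = np.clip(metrics, 0.0, 1.0)
    return [MetricSample(float(t), *map(float, row)) for t, row in zip(times, metrics)]


def _noisy_region(true_region: int, p_agree: float, rng: np.random.Generator) -> int:
    if rng.uniform() < p_agree:
        return true_region
    if true_region == 1:
        return 2
    if true_region == N_REGIONS:
        return N_REGIONS - 1
    return true_region + (1 if rng.uniform() < 0.5 else -1)


def generate_reviewers(truth: dict[str, list[TruthInterval]],
                       config: SyntheticConfig,
                       session_id: str = "S1",
                       session_index: int = 0) -> dict[str, list[AnnotationEvent]]:
    """Simulate each reviewer's change-point annotation stream."""
    rng = _rng(config, _REVIEWERS, session_index)
    changes = change_points(truth)
    length = config.session_length_s
    event_times = np.concatenate(([0.0], changes))
    true_triples = np.column_stack([
        region_at(truth[dim], event_times) for dim in DIMENSIONS
    ])
    reviewers: dict[str, list[AnnotationEvent]] = {}
    for j in range(config.n_reviewers):
        rid = f"R{j + 1}"
        events: list[AnnotationEvent] = []
        prev_t = -1.0
        for t, true_triple in zip(event_times, true_triples):
            if t > 0.0 and rng.uniform() >= config.p_detect:
                continue
            t_emit = float(t)
            if t > 0.0 and config.jitter_sd_s > 0:
                t_emit = float(t + rng.normal(0.0, config.jitter_sd_s))
            # truncate jitter so the reviewer's stream stays strictly ordered
            if prev_t + 1e-6 >= length - 1e-6:
                break  # no room left before session end
            t_emit = min(max(t_emit, prev_t + 1e-6), length - 1e-6)
            region = PADRegion(*(
                _noisy_region(int(r), config.p_agree, rng) for r in true_triple
            ))
            events.append(AnnotationEvent(
                session_id=session_id, source=HUMAN, reviewer_id=rid,
                t=t_emit, region=region,
            ))
            prev_t = t_emit
        reviewers[rid] = events
    return reviewers


def detect_machine_events(samples: Sequence[MetricSample],
                          session_id: str = "S1",
                          mapping: MappingConfig | None = None) -> list[AnnotationEvent]:
    """Run the metric stream through map -> discretize and emit change events.

    One event at the first sample, then one whenever the discretized region
    triple differs from the previous sample's.
    """
    mapping = mapping or MappingConfig()
    values = np.asarray([s.values() for s in samples])
    times = np.asarray([s.t for s in samples])
    regions = discretize_array(map_metrics_array(values, mapping))
    events = []
    prev = None
    for t, triple in zip(times, regions):
        triple = tuple(int(x) for x in triple)
        if triple != prev:
            events.append(AnnotationEvent(
                session_id=session_id, source=MACHINE, reviewer_id="",
                t=float(t), region=PADRegion(*triple),
            ))
            prev = triple
    return events


def generate_session(config: SyntheticConfig,
                     session_id: str = "S1",
                     mapping: MappingConfig | None = None,
                     session_index: int = 0) -> SyntheticSession:
    """Generate one complete session (truth, metrics, machine + human events)."""
    mapping = mapping or MappingConfig()
    truth = generate_truth(config, session_index)
    metrics = generate_metrics(truth, config, mapping, session_index)
    machine = detect_machine_events(metrics, session_id, mapping)
    reviewers = generate_reviewers(truth, config, session_id, session_index)
    return SyntheticSession(
        session_id=session_id, config=config, truth=truth, metrics=metrics,
        machine_events=machine, reviewer_events=reviewers,
    )


def generate_cohort(config: SyntheticConfig,
                    n_sessions: int,
                    mapping: MappingConfig | None = None) -> list[SyntheticSession]:
    """Generate ``n_sessions`` independent sessions from one seed."""
    return [
        generate_session(config, session_id=f"S{i + 1}", mapping=mapping,
                         session_index=i)
        for i in range(n_sessions)
    ]
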