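import numpy as np
import pytest

from affectgait import (
    AnnotationEvent,
    AnnotationInterval,
    PADRegion,
    SyntheticConfig,
)
from affectgait.types import HUMAN, MACHINE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, fully attentive cohort: every downstream stage should
    recover the ground truth exactly."""
    return SyntheticConfig(
        seed=42, session_length_s=300.0, sample_rate_hz=1.0,
        mean_dwell_s=30.0, metric_noise_sd=0.0,
        n_reviewers=2, p_detect=1.0, p_agree=1.0, jitter_sd_s=0.0,
    )


def make_event(t, regions=(2, 2, 2), source=MACHINE, reviewer="",
               session="S1"):
    if source == HUMAN and not reviewer:
        reviewer = "R1"
    return AnnotationEvent(session_id=session, source=source,
                           reviewer_id=reviewer, t=t,
                           region=PADRegion(*regions))


def make_interval(start, end, regions=(2, 2, 2), source=MACHINE,
                  reviewer="", session="S1"):
    return AnnotationInterval(session_id=session, source=source,
                              reviewer_id=reviewer, start=start, end=end,
                              region=PADRegion(*regions))


def sweepline_matches(machine, humans):
    """Independent oracle: count machine x human interval pairs sharing at
    least one elementary segment of the merged breakpoint grid."""
    out = {}
    for rid, intervals in humans.items():
        points = sorted({iv.start for iv in machine} | {iv.end for iv in machine}
                        | {iv.start for iv in intervals} | {iv.end for iv in intervals})
        pairs = set()
        overlap = {}
        for lo, hi in zip(points, points[1:]):
            mid = (lo + hi) / 2
            m_idx = next((i for i, iv in enumerate(machine)
                          if iv.start <= mid < iv.end), None)
            h_idx = next((j for j, iv in enumerate(intervals)
                          if iv.start <= mid < iv.end), None)
            if m_idx is not None and h_idx is not None:
                pairs.add((m_idx, h_idx))
                overlap[(m_idx, h_idx)] = overlap.get((m_idx, h_idx), 0.0) + (hi - lo)
        out[rid] = (pairs, overlap)
    return out
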