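"""Metric-to-PAD translation and SAM region discretization.

The five consumer-EEG performance metrics (engagement, boredom, excitement,
frustration, meditation; each in [0,1]) are mapped affinely to the continuous
pleasure-arousal-dominance cube, then each dimension is binned into the five
self-assessment-Manikin regions with equal-width, left-closed bins:

    region r  <=>  value in [(r-1)/5, r/5),   with 1.0 assigned to region 5.

Region labels follow the SAM pictographs; only the arousal list (calm, dull,
neutral, wide-awake, excited) plus "unsatisfied", "pleased" and
"powerlessness" are standard here — the remaining names are configurable
placeholders.
"""
from __future__ import annotations

import numpy as np

from .config import MappingConfig
from .errors import MappingNotInvertibleError, UsageError
from .types import DIMENSIONS, N_REGIONS, MetricSample, PADRegion, PADVector

DEFAULT_LABELS: dict[str, tuple[str, ...]] = {
    "pleasure": ("very-unsatisfied", "unsatisfied", "neutral", "pleased", "very-pleased"),
    "arousal": ("calm", "dull", "neutral", "wide-awake", "excited"),
    "dominance": ("powerlessness", "low-control", "neutral", "in-control", "dominant"),
}


def map_metrics_to_pad(sample: MetricSample, cfg: MappingConfig | None = None) -> PADVector:
    """Translate one metric sample to a continuous PAD vector.

    PAD = clip(weights @ metrics + offsets); linear and order-preserving in
    every positively-weighted metric.
    """
    cfg = cfg or MappingConfig()
    pad = map_metrics_array(np.asarray([sample.values()]), cfg)[0]
    return PADVector(*pad)


def map_metrics_array(metrics: np.ndarray, cfg: MappingConfig | None = None) -> np.ndarray:
    """Vectorized mapping: (n, 5) metric array -> (n, 3) PAD array."""
    cfg = cfg or MappingConfig()
    metrics = np.asarray(metrics, dtype=float)
    pad = metrics @ cfg.weight_matrix().T + cfg.offset_vector()
    if cfg.clip:
        pad = np.clip(pad, 0.0, 1.0)
    return pad


def discretize_pad(v: PADVector) -> PADRegion:
    """Bin each PAD component into its SAM region (1..5)."""
    return PADRegion(*(int(r) for r in discretize_array(np.asarray([v]))[0]))


def discretize_array(pad: np.ndarray) -> np.ndarray:
    """Vectorized discretization: values in [0,1] -> integer regions 1..5.

    Equivalent to floor(5*value) + 1 clamped to 5 (so 1.0 lands in region 5).
    """
    pad = np.asarray(pad, dtype=float)
    regions = np.floor(pad * N_REGIONS).astype(np.int64) + 1
    return np.clip(regions, 1, N_REGIONS)


def invert_pad_array(pad: np.ndarray, cfg: MappingConfig | None = None,
                     atol: float = 1e-9) -> np.ndarray:
    """Map PAD targets back to metric vectors: (n, 3) -> (n, 5).

    Uses the minimum-norm affine inverse centred at the metric midpoint
    m = 0.5 + W^+ (pad - W@0.5 - offsets); for the default disjoint-support
    matrix this is exact and stays inside [0,1]^5 for every PAD in the cube.
    Raises :class:`MappingNotInvertibleError` when the candidate metrics fall
    outside [0,1]^5 or fail to reproduce the target within ``atol``.
    """
    cfg = cfg or MappingConfig()
    pad = np.atleast_2d(np.asarray(pad, dtype=float))
    w = cfg.weight_matrix()
    o = cfg.offset_vector()
    centre = np.full(w.shape[1], 0.5)
    pinv = np.linalg.pinv(w)
    metrics = centre + (pad - (w @ centre + o)) @ pinv.T
    if metrics.min() < -atol or metrics.max() > 1 + atol:
        raise MappingNotInvertibleError(
            "configured mapping has no metric preimage in [0,1]^5 for some "
            "requested PAD values"
        )
    metrics = np.clip(metrics, 0.0, 1.0)
    residual = np.abs(metrics @ w.T + o - pad).max()
    if residual > max(atol, 1e-7):
        raise MappingNotInvertibleError(
            f"mapping not invertible on the requested targets "
            f"(max residual {residual:.3g})"
        )
    return metrics


def label_region(dimension: str, region: int,
                 table: dict[str, tuple[str, ...]] | None = None) -> str:
    """Look up the label of ``region`` (1..5) on ``dimension``."""
    table = table or DEFAULT_LABELS
    if dimension not in table:
        raise UsageError(
            f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}"
        )
    if not 1 <= int(region) <= N_REGIONS:
        raise UsageError(f"region {region} outside 1..{N_REGIONS}")
    labels = table[dimension]
    if len(labels) != N_REGIONS:
        raise UsageError(f"label table for {dimension} must have {N_REGIONS} entries")
    return labels[int(region) - 1]
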