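"""Stage-routed explanation products built from model internals.

Four products, one per scoring convention:

1. **Detection boxes** — intervals where a pattern filter's activation
   amplitude exceeds a threshold (sleep spindles, k-complexes, sawtooth
   waves): the scorer checks whether the model located the right patterns.
2. **Delta wave blocks** — the delta filter's activation digitized at a
   threshold; maximal runs of 1 are the "blocks" a scorer counts, and their
   coverage feeds the N3 rule: delta waves must account for more than 20%
   of the signal (strictly).
3. **Alpha activation surface** — the rectified alpha-filter activation,
   whose overall level tracks alpha amplitude changes at the W/N1 boundary.
4. **Saliency highlights** — intervals whose input-gradient saliency exceeds
   a per-epoch percentile: where the model "looked".

Only the products mandated for the predicted stage are routed into the
bundle (W: alpha+highlights, N1: alpha+highlights, N2: boxes+alpha+
highlights, N3: delta+highlights, REM: boxes+alpha+highlights).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert

from .stager import (
    ActivationTrace,
    SaliencyMap,
    StagePrediction,
    StagerModel,
    compute_activation,
    compute_saliency,
    predict_epoch,
)
from .synthetic import STAGES, EpochSignal, EventAnnotation
from .templates import ValidationError

__all__ = [
    "DetectionBox",
    "DeltaBlockSet",
    "AlphaSurface",
    "SaliencyHighlight",
    "ExplanationBundle",
    "ThresholdSet",
    "ROUTING",
    "BOX_PATTERNS",
    "DELTA_COVERAGE_THRESHOLD",
    "activation_envelope",
    "detect_boxes",
    "digitize_activation",
    "close_gaps",
    "delta_blocks",
    "delta_ratio_rule",
    "alpha_surface",
    "saliency_highlights",
    "route_explanations",
    "calibrate_thresholds",
    "explain_epoch",
    "bundle_to_json",
]

logger = logging.getLogger(__name__)

#: The N3 rule threshold: delta waves must cover MORE than 20% of the epoch.
DELTA_COVERAGE_THRESHOLD = 0.20

#: Component-presence matrix per predicted stage.
ROUTING = {
    "W": frozenset({"alpha", "highlights"}),
    "N1": frozenset({"alpha", "highlights"}),
    "N2": frozenset({"boxes", "alpha", "highlights"}),
    "N3": frozenset({"delta", "highlights"}),
    "REM": frozenset({"boxes", "alpha", "highlights"}),
}

#: Which pattern filters feed the detection boxes of each stage.
BOX_PATTERNS = {"N2": ("spindle", "kcomplex"), "REM": ("sawtooth",)}

#: Event-detection defaults (seconds): minimum box lengths are shorter than
#: any canonical event; gaps up to merge_gap are bridged.
DEFAULT_MIN_LEN_S = {"spindle": 0.3, "kcomplex": 0.3, "delta": 0.25}
DEFAULT_MERGE_GAP_S = 0.1
_FALLBACK_QUANTILE = 0.95


@dataclass(frozen=True)
class DetectionBox:
    start: int
    end: int
    pattern: str
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid box [{self.start}, {self.end})")


@dataclass(frozen=True)
class DeltaBlockSet:
    binary: np.ndarray
    blocks: tuple[tuple[int, int], ...]
    count: int
    coverage: float


@dataclass(frozen=True)
class AlphaSurface:
    values: np.ndarray


@dataclass(frozen=True)
class SaliencyHighlight:
    regions: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class ExplanationBundle:
    epoch_index: int
    prediction: StagePrediction
    boxes: tuple[DetectionBox, ...] | None = None
    delta: DeltaBlockSet | None = None
    alpha: AlphaSurface | None = None
    highlights: SaliencyHighlight | None = None

    def present_components(self) -> frozenset[str]:
        present = set()
        if self.boxes is not None:
            present.add("boxes")
        if self.delta is not None:
            present.add("delta")
        if self.alpha is not None:
            present.add("alpha")
        if self.highlights is not None:
            present.add("highlights")
        return frozenset(present)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-pattern detection thresholds in activation-envelope units."""

    thresholds: dict[str, float]
    calibrated: frozenset[str] = frozenset()

    def __getitem__(self, pattern: str) -> float:
        return self.thresholds[pattern]


# ---------------------------------------------------------------------------
# Primitive operations

def activation_envelope(trace: ActivationTrace) -> ActivationTrace:
    """Analytic (Hilbert) amplitude of an activation trace.

    Template activations oscillate at the pattern's frequency; detection is
    based on their amplitude, so thresholding runs on the envelope rather
    than the signed values.
    """
    return replace(trace, values=np.abs(hilbert(trace.values)))


def _runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = values > threshold  # strict, per the "higher than" rule
    if not above.any():
        return []
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    ends = list(np.flatnonzero(~above[1:] & above[:-1]) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(values.size)
    return list(zip(starts, ends))


def detect_boxes(
    trace: ActivationTrace,
    threshold: float,
    min_len: int,
    merge_gap: int,
) -> list[DetectionBox]:
    """Maximal runs above threshold, gap-merged, with short runs dropped."""
    if trace.values.size == 0:
        raise ValidationError("empty activation trace")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if min_len < 1 or merge_gap < 0:
        raise ValidationError("min_len must be >= 1 and merge_gap >= 0")
    runs = _runs_above(trace.values, threshold)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [
        DetectionBox(
            start=s, end=e, pattern=trace.filter_pattern, score=float(trace.values[s:e].max())
        )
        for s, e in merged
        if e - s >= min_len
    ]


def digitize_activation(trace: ActivationTrace, threshold: float) -> np.ndarray:
    """1 where the activation is strictly higher than the threshold, else 0."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return (trace.values > threshold).astype(np.int8)


def close_gaps(binary: np.ndarray, max_gap: int) -> np.ndarray:
    """Bridge runs of 0 no longer than ``max_gap`` between runs of 1."""
    out = np.asarray(binary).astype(np.int8).copy()
    ones = np.flatnonzero(out)
    if ones.size < 2:
        return out
    gaps = np.diff(ones)
    for pos, gap in zip(ones[:-1], gaps):
        if 1 < gap <= max_gap + 1:
            out[pos : pos + gap] = 1
    return out


def delta_blocks(binary: np.ndarray) -> DeltaBlockSet:
    """Maximal runs of 1 = blocks of slow waves; the scorer counts these."""
    binary = np.asarray(binary)
    if binary.ndim != 1 or not np.isin(binary, (0, 1)).all():
        raise ValidationError("delta_blocks expects a 1-D 0/1 vector")
    binary = binary.astype(np.int8)
    blocks = tuple((int(s), int(e)) for s, e in _runs_above(binary.astype(float), 0.5))
    return DeltaBlockSet(
        binary=binary,
        blocks=blocks,
        count=len(blocks),
        coverage=float(binary.mean()) if binary.size else 0.0,
    )


def delta_ratio_rule(delta: DeltaBlockSet) -> bool:
    """N3 rule: true iff delta coverage strictly exceeds 20% of the epoch."""
    return delta.coverage > DELTA_COVERAGE_THRESHOLD


def alpha_surface(trace: ActivationTrace) -> AlphaSurface:
    """Rectified alpha-filter activation; its area tracks alpha amplitude."""
    if trace.filter_pattern != "alpha":
        raise ValidationError(
            f"alpha_surface requires an alpha-pattern trace, got {trace.filter_pattern!r}"
        )
    return AlphaSurface(values=np.maximum(trace.values, 0.0))


def saliency_highlights(saliency: SaliencyMap, percentile: float) -> SaliencyHighlight:
    """Maximal runs strictly above this epoch's saliency percentile."""
    if not (0 < percentile < 100):
        raise ValidationError("percentile must lie strictly between 0 and 100")
    cut = float(np.percentile(saliency.values, percentile))
    regions = tuple((int(s), int(e)) for s, e in _runs_above(saliency.values, cut))
    return SaliencyHighlight(regions=regions)


def route_explanations(
    prediction: StagePrediction,
    boxes: tuple[DetectionBox, ...],
    delta: DeltaBlockSet,
    alpha: AlphaSurface,
    highlights: SaliencyHighlight,
    epoch_index: int = 0,
) -> ExplanationBundle:
    """Keep exactly the components mandated for the predicted stage."""
    for name, product in (("boxes", boxes), ("delta", delta), ("alpha", alpha), ("highlights", highlights)):
        if product is None:
            raise ValidationError(f"required product {name!r} missing; compute all four first")
    wanted = ROUTING[prediction.predicted_stage]
    return ExplanationBundle(
        epoch_index=epoch_index,
        prediction=prediction,
        boxes=tuple(boxes) if "boxes" in wanted else None,
        delta=delta if "delta" in wanted else None,
        alpha=alpha if "alpha" in wanted else None,
        highlights=highlights if "highlights" in wanted else None,
    )


# ---------------------------------------------------------------------------
# Threshold calibration against planted events

def _event_pattern(event_type: str) -> str:
    return "delta" if event_type == "delta_wave" else event_type


def _interval_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def event_level_f1(
    boxes: list[DetectionBox], events: list[tuple[int, int]], iou: float = 0.3
) -> float:
    """Greedy one-to-one matching of boxes to planted events at an IoU cut."""
    if not boxes and not events:
        return 1.0
    matched_events: set[int] = set()
    tp = 0
    for box in boxes:
        best_j, best_iou = -1, iou
        for j, ev in enumerate(events):
            if j in matched_events:
                continue
            val = _interval_iou((box.start, box.end), ev)
            if val >= best_iou:
                best_j, best_iou = j, val
        if best_j >= 0:
            matched_events.add(best_j)
            tp += 1
    denom = len(boxes) + len(events)
    return 2.0 * tp / denom if denom else 1.0


def _min_len_samples(pattern: str, fs: float) -> int:
    return max(1, int(round(DEFAULT_MIN_LEN_S.get(pattern, 0.25) * fs)))


def calibrate_thresholds(
    model: StagerModel,
    calibration_epochs: list[tuple[EpochSignal, list[EventAnnotation]]],
    n_grid: int = 24,
    iou: float = 0.3,
) -> ThresholdSet:
    """Pick per-pattern detection thresholds maximizing event-level F1 of
    detect_boxes on the planted events; patterns without any calibration
    events fall back to a high quantile of their envelope distribution."""
    fs = calibration_epochs[0][0].fs if calibration_epochs else 100.0
    envelopes: dict[str, list[np.ndarray]] = {p: [] for p in model.template_patterns}
    truth: dict[str, list[list[tuple[int, int]]]] = {p: [] for p in model.template_patterns}
    for epoch, events in calibration_epochs:
        per_pattern: dict[str, list[tuple[int, int]]] = {p: [] for p in model.template_patterns}
        for ev in events:
            pattern = _event_pattern(ev.event_type)
            if pattern in per_pattern:
                per_pattern[pattern].append((ev.start, ev.end))
        for pattern in model.template_patterns:
            env = activation_envelope(compute_activation(model, epoch, pattern))
            envelopes[pattern].append(env.values)
            truth[pattern].append(per_pattern[pattern])

    thresholds: dict[str, float] = {}
    calibrated: set[str] = set()
    merge_gap = int(round(DEFAULT_MERGE_GAP_S * fs))
    for pattern in model.template_patterns:
        all_events = [ev for evs in truth[pattern] for ev in evs]
        if not envelopes[pattern]:
            thresholds[pattern] = 0.0
            warnings.warn(f"no calibration epochs; pattern {pattern!r} threshold defaults to 0")
            continue
        pooled = np.concatenate(envelopes[pattern])
        if not all_events:
            thresholds[pattern] = float(np.quantile(pooled, _FALLBACK_QUANTILE))
            warnings.warn(
                f"no calibration events for pattern {pattern!r}; "
                f"falling back to the {_FALLBACK_QUANTILE:.0%} envelope quantile"
            )
            continue
        lo, hi = float(np.quantile(pooled, 0.5)), float(pooled.max())
        grid = np.linspace(lo, hi, n_grid, endpoint=False)
        min_len = _min_len_samples(pattern, fs)
        best_thr, best_f1 = grid[0], -1.0
        for thr in grid:
            f1s = []
            for env, evs in zip(envelopes[pattern], truth[pattern]):
                boxes = detect_boxes(
                    ActivationTrace(values=env, filter_pattern=pattern),
                    threshold=float(thr),
                    min_len=min_len,
                    merge_gap=merge_gap,
                )
                f1s.append(event_level_f1(boxes, evs, iou=iou))
            mean_f1 = float(np.mean(f1s))
            if mean_f1 > best_f1:  # ties keep the lowest threshold
                best_f1, best_thr = mean_f1, float(thr)
        thresholds[pattern] = best_thr
        calibrated.add(pattern)
        logger.info("calibrated %s threshold=%.3f (event F1=%.3f)", pattern, best_thr, best_f1)
    return ThresholdSet(thresholds=thresholds, calibrated=frozenset(calibrated))


# ---------------------------------------------------------------------------
# Whole-epoch driver

def explain_epoch(
    model: StagerModel,
    epoch: EpochSignal,
    thresholds: ThresholdSet,
    epoch_index: int = 0,
    saliency_percentile: float = 90.0,
    prediction: StagePrediction | None = None,
) -> ExplanationBundle:
    """Compute all four products for one epoch and route them by stage."""
    if prediction is None:
        prediction = predict_epoch(model, epoch)
    fs = epoch.fs
    merge_gap = int(round(DEFAULT_MERGE_GAP_S * fs))

    boxes: list[DetectionBox] = []
    for pattern in BOX_PATTERNS.get(prediction.predicted_stage, BOX_PATTERNS["N2"]):
        env = activation_envelope(compute_activation(model, epoch, pattern))
        boxes.extend(
            detect_boxes(env, thresholds[pattern], _min_len_samples(pattern, fs), merge_gap)
        )
    delta_env = activation_envelope(compute_activation(model, epoch, "delta"))
    binary = close_gaps(digitize_activation(delta_env, thresholds["delta"]), merge_gap)
    delta = delta_blocks(binary)
    alpha = alpha_surface(compute_activation(model, epoch, "alpha"))
    sal = compute_saliency(model, epoch, prediction.predicted_stage)
    highlights = saliency_highlights(sal, saliency_percentile)
    return route_explanations(
        prediction, tuple(boxes), delta, alpha, highlights, epoch_index=epoch_index
    )


def bundle_to_json(bundle: ExplanationBundle) -> dict:
    """JSON-serializable form (the digitized delta vector itself is omitted)."""
    out: dict = {
        "epoch_index": bundle.epoch_index,
        "predicted_stage": bundle.prediction.predicted_stage,
        "probabilities": {s: float(p) for s, p in zip(STAGES, bundle.prediction.probabilities)},
    }
    if bundle.boxes is not None:
        out["boxes"] = [
            {"start": b.start, "end": b.end, "pattern": b.pattern, "score": b.score}
            for b in bundle.boxes
        ]
    if bundle.delta is not None:
        out["delta"] = {
            "blocks": [list(b) for b in bundle.delta.blocks],
            "count": bundle.delta.count,
            "coverage": bundle.delta.coverage,
            "meets_n3_rule": delta_ratio_rule(bundle.delta),
        }
    if bundle.alpha is not None:
        out["alpha"] = {"values": bundle.alpha.values.tolist()}
    if bundle.highlights is not None:
        out["highlights"] = {"regions": [list(r) for r in bundle.highlights.regions]}
    return out
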