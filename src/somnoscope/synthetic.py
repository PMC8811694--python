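"""Seeded synthetic single-channel sleep EEG with ground truth.

Generates whole-night recordings as 30-second epochs, one AASM stage per
epoch (W, N1, N2, N3, REM), with the stage-characteristic content a scorer
looks for:

* W  — high-amplitude alpha rhythm (10 Hz);
* N1 — attenuated alpha plus theta background, optional vertex sharp waves;
* N2 — theta background with sleep spindles and/or k-complexes;
* N3 — delta waves covering a configurable fraction of the epoch;
* REM — theta background with sawtooth wave trains.

Transient events are planted using the same canonical morphologies as the
template filters and are annotated with exact half-open sample intervals, so
detection and calibration can be scored against ground truth.  An optional
sweat artifact (slow high-amplitude baseline sway, < 0.5 Hz) reproduces the
classic confound of delta scoring.  Every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .templates import ValidationError, canonical_waveform

__all__ = [
    "STAGES",
    "EVENT_TYPES",
    "Hypnogram",
    "EventAnnotation",
    "EpochSignal",
    "EpochSynthesisParams",
    "SyntheticRecording",
    "EvalSegment",
    "SingleEpochItem",
    "EvalDataset",
    "DEFAULT_TRANSITION_MATRIX",
    "generate_hypnogram",
    "synthesize_epoch",
    "generate_recording",
    "iter_epochs",
    "band_energy_ratio",
    "build_eval_sets",
]

#: Fixed stage order used everywhere (argmax tie-breaks follow it too).
STAGES = ("W", "N1", "N2", "N3", "REM")

EVENT_TYPES = (
    "spindle",
    "kcomplex",
    "delta_wave",
    "sawtooth",
    "vertex_sharp",
    "alpha_burst",
    "sweat_artifact",
)

#: Event type -> characteristic frequency band (Hz) used for annotation
#: soundness checks and band-power features.
EVENT_BANDS = {
    "spindle": (11.0, 16.0),
    "kcomplex": (0.5, 2.5),
    "delta_wave": (0.5, 4.0),
    "sawtooth": (2.0, 5.0),
    "vertex_sharp": (1.0, 5.0),
    "alpha_burst": (8.0, 13.0),
    "sweat_artifact": (0.05, 0.5),
}

#: Plausible whole-night stage dynamics: sticky stages, W->N1->N2->N3
#: descent, REM reached mostly from N2, occasional awakenings.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        [0.70, 0.25, 0.03, 0.01, 0.01],  # W
        [0.10, 0.50, 0.35, 0.01, 0.04],  # N1
        [0.03, 0.05, 0.75, 0.12, 0.05],  # N2
        [0.01, 0.02, 0.15, 0.80, 0.02],  # N3
        [0.05, 0.10, 0.10, 0.01, 0.74],  # REM
    ]
)


@dataclass(frozen=True)
class Hypnogram:
    stages: tuple[str, ...]
    epoch_duration: float = 30.0

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage labels {sorted(set(bad))}; expected {STAGES}")
        if self.epoch_duration <= 0:
            raise ValidationError("epoch_duration must be positive")
        object.__setattr__(self, "stages", tuple(self.stages))

    def __len__(self) -> int:
        return len(self.stages)


@dataclass(frozen=True)
class EventAnnotation:
    """Half-open sample interval [start, end) of one transient event,
    expressed in recording-level sample indices."""

    event_type: str
    start: int
    end: int
    epoch_index: int = 0

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid event interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class EpochSignal:
    """One 30-s single-channel EEG window (µV) plus sampling metadata."""

    signal: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.signal.size / self.fs


@dataclass(frozen=True)
class EpochSynthesisParams:
    """Free parameters of the epoch recipes.

    Amplitudes are µV; the sleep literature gives no single canonical value,
    so defaults follow typical adult scalp EEG scales (alpha ~20-40 µV,
    delta slow waves > 75 µV peak-to-peak criterion, spindles ~10-30 µV).
    ``n_*`` counts of None mean "draw a stage-typical count from the seed".
    """

    noise_sd: float = 5.0
    epoch_duration: float = 30.0
    sweat: bool = False
    delta_coverage: float = 0.35
    n_spindles: int | None = None
    n_kcomplexes: int | None = None
    n_delta_waves: int | None = None
    n_sawtooth: int | None = None
    n_vertex: int | None = None
    alpha_amp: float = 30.0
    alpha_attenuation: float = 0.4
    theta_amp: float = 15.0
    delta_amp: float = 75.0
    spindle_amp: float = 25.0
    kcomplex_amp: float = 80.0
    sawtooth_amp: float = 40.0
    vertex_amp: float = 60.0
    sweat_amp: float = 120.0
    sweat_freq: float = 0.3
    alpha_freq: float = 10.0
    theta_freq: float = 6.5
    event_durations: dict = field(
        default_factory=lambda: {
            "spindle": 1.0,
            "kcomplex": 1.0,
            "delta_wave": 1.0,
            "sawtooth": 1.5,
            "vertex_sharp": 0.3,
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_coverage <= 1.0):
            raise ValidationError(f"delta_coverage must lie in [0, 1]; got {self.delta_coverage}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticRecording:
    signal: np.ndarray
    fs: float
    hypnogram: Hypnogram
    events: tuple[EventAnnotation, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        object.__setattr__(self, "events", tuple(self.events))
        expected = int(round(len(self.hypnogram) * self.hypnogram.epoch_duration * self.fs))
        if self.signal.size != expected:
            raise ValidationError(
                f"signal length {self.signal.size} != n_epochs * epoch_duration * fs = {expected}"
            )

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.hypnogram.epoch_duration * self.fs))


def generate_hypnogram(
    n_epochs: int,
    transition_matrix: np.ndarray = DEFAULT_TRANSITION_MATRIX,
    initial_stage: str = "W",
    seed: int = 0,
    epoch_duration: float = 30.0,
) -> Hypnogram:
    """Markov-sample a stage sequence of length ``n_epochs``."""
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    if initial_stage not in STAGES:
        raise ValidationError(f"unknown stage label {initial_stage!r}")
    matrix = np.asarray(transition_matrix, dtype=float)
    if matrix.shape != (5, 5) or np.any(matrix < 0) or np.any(
        np.abs(matrix.sum(axis=1) - 1.0) > 1e-9
    ):
        raise ValidationError("transition_matrix must be 5x5 with non-negative rows summing to 1")
    rng = np.random.default_rng(seed)
    state = STAGES.index(initial_stage)
    stages = [STAGES[state]]
    for _ in range(n_epochs - 1):
        state = rng.choice(5, p=matrix[state])
        stages.append(STAGES[state])
    return Hypnogram(stages=tuple(stages), epoch_duration=epoch_duration)


def _place_events(rng: np.random.Generator, n_events: int, length: int, n_samples: int):
    """Non-overlapping starts: jittered placement within evenly spaced slots."""
    if n_events <= 0:
        return []
    slot = n_samples // n_events
    if slot < length:
        raise ValidationError(
            f"cannot place {n_events} events of {length} samples in {n_samples} samples"
        )
    starts = []
    for i in range(n_events):
        jitter = int(rng.integers(0, slot - length + 1)) if slot > length else 0
        starts.append(i * slot + jitter)
    return starts


def _event_wave(event_type: str, fs: float, duration: float) -> np.ndarray:
    pattern = "delta" if event_type == "delta_wave" else event_type
    return canonical_waveform(pattern, fs, duration)


def synthesize_epoch(
    stage: str,
    fs: float,
    params: EpochSynthesisParams = EpochSynthesisParams(),
    seed: int = 0,
) -> tuple[EpochSignal, list[EventAnnotation]]:
    """Synthesize one 30-s epoch following the stage recipe.

    Returns the signal and the exact sample intervals of every planted
    transient event (epoch-relative indices, ``epoch_index`` 0).
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage label {stage!r}")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(params.epoch_duration * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    events: list[EventAnnotation] = []

    def add_tone(freq: float, amp: float) -> None:
        signal[:] += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))

    def add_events(event_type: str, count: int, amp: float) -> None:
        duration = params.event_durations[event_type]
        wave = _event_wave(event_type, fs, duration)
        for start in _place_events(rng, count, wave.size, n):
            end = min(start + wave.size, n)
            signal[start:end] += amp * wave[: end - start]
            events.append(EventAnnotation(event_type, start, end, 0))

    def drawn(requested: int | None, lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1)) if requested is None else int(requested)

    if stage == "W":
        add_tone(params.alpha_freq, params.alpha_amp)
    elif stage == "N1":
        add_tone(params.alpha_freq, params.alpha_amp * params.alpha_attenuation)
        add_tone(params.theta_freq, params.theta_amp)
        add_events("vertex_sharp", drawn(params.n_vertex, 0, 1), params.vertex_amp)
    elif stage == "N2":
        add_tone(params.theta_freq, params.theta_amp)
        n_sp = drawn(params.n_spindles, 0, 2)
        n_kc = drawn(params.n_kcomplexes, 0, 2)
        if n_sp == 0 and n_kc == 0 and params.n_spindles is None:
            n_sp = 1  # N2 must carry at least one spindle or k-complex
        add_events("spindle", n_sp, params.spindle_amp)
        add_events("kcomplex", n_kc, params.kcomplex_amp)
    elif stage == "N3":
        add_tone(params.theta_freq, 0.3 * params.theta_amp)
        wave_len = int(round(params.event_durations["delta_wave"] * fs))
        if params.n_delta_waves is not None:
            n_delta = int(params.n_delta_waves)
        else:
            n_delta = int(round(params.delta_coverage * n / wave_len))
        add_events("delta_wave", n_delta, params.delta_amp)
    else:  # REM
        add_tone(params.theta_freq, params.theta_amp)
        add_events("sawtooth", drawn(params.n_sawtooth, 1, 2), params.sawtooth_amp)

    if params.sweat:
        add_tone(params.sweat_freq, params.sweat_amp)
        events.append(EventAnnotation("sweat_artifact", 0, n, 0))
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, size=n)
    return EpochSignal(signal=signal, fs=fs), events


def generate_recording(
    hypnogram: Hypnogram,
    fs: float = 100.0,
    params: EpochSynthesisParams = EpochSynthesisParams(),
    seed: int = 0,
) -> SyntheticRecording:
    """Concatenate per-epoch syntheses with continuous sample indexing."""
    params = replace(params, epoch_duration=hypnogram.epoch_duration)
    spe = int(round(hypnogram.epoch_duration * fs))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(hypnogram)) >> 1
    chunks, events = [], []
    for idx, (stage, child) in enumerate(zip(hypnogram.stages, child_seeds)):
        epoch, epoch_events = synthesize_epoch(stage, fs, params, seed=int(child))
        chunks.append(epoch.signal)
        offset = idx * spe
        events.extend(
            EventAnnotation(ev.event_type, ev.start + offset, ev.end + offset, idx)
            for ev in epoch_events
        )
    return SyntheticRecording(
        signal=np.concatenate(chunks), fs=fs, hypnogram=hypnogram, events=tuple(events), seed=seed
    )


def band_energy_ratio(
    signal: np.ndarray,
    fs: float,
    events: list[EventAnnotation],
    event_type: str,
    dilate_s: float = 0.25,
) -> float:
    """Fraction of the event type's characteristic-band energy that lies
    within the (slightly dilated) union of its annotated intervals.

    The band-pass is an FFT-domain brick wall, which has no edge transients
    for the continuous background rhythms; intervals are dilated by
    ``dilate_s`` to absorb the band-limited spread of short transients.
    For a sound annotation at zero noise this ratio is close to 1.
    """
    signal = np.asarray(signal, dtype=float)
    lo, hi = EVENT_BANDS[event_type]
    spectrum = np.fft.rfft(signal)
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / fs)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    banded = np.fft.irfft(spectrum, n=signal.size)
    total = float((banded**2).sum())
    if total == 0.0:
        return 1.0
    pad = int(round(dilate_s * fs))
    mask = np.zeros(signal.size, dtype=bool)
    for ev in events:
        if ev.event_type == event_type:
            mask[max(0, ev.start - pad) : min(signal.size, ev.end + pad)] = True
    return float((banded[mask] ** 2).sum() / total)


def iter_epochs(recording: SyntheticRecording) -> list[tuple[EpochSignal, str]]:
    """Segment a recording into its labeled 30-s epochs."""
    spe = recording.samples_per_epoch
    return [
        (EpochSignal(recording.signal[i * spe : (i + 1) * spe], recording.fs), stage)
        for i, stage in enumerate(recording.hypnogram.stages)
    ]


@dataclass(frozen=True)
class EvalSegment:
    """A contiguous multi-epoch evaluation segment with >= 2 distinct stages."""

    recording_index: int
    start_epoch: int
    stages: tuple[str, ...]
    signal: np.ndarray
    fs: float


@dataclass(frozen=True)
class SingleEpochItem:
    recording_index: int
    epoch_index: int
    stage: str
    epoch: EpochSignal


@dataclass(frozen=True)
class EvalDataset:
    segments: tuple[EvalSegment, ...]
    single_epochs: tuple[SingleEpochItem, ...]


def build_eval_sets(
    recordings: list[SyntheticRecording],
    segment_minutes: float = 15.0,
    n_segments: int = 4,
    n_single_epochs: int = 30,
    seed: int = 0,
    max_attempts: int = 1000,
) -> EvalDataset:
    """Draw evaluation material: contiguous segments that contain at least one
    stage change, plus disconnected single epochs sampled across stages."""
    if not recordings:
        raise ValidationError("no recordings supplied")
    rng = np.random.default_rng(seed)
    epoch_duration = recordings[0].hypnogram.epoch_duration
    epochs_per_segment = segment_minutes * 60.0 / epoch_duration
    if abs(epochs_per_segment - round(epochs_per_segment)) > 1e-9:
        raise ValidationError("segment_minutes must be a whole number of epochs")
    eps = int(round(epochs_per_segment))
    hosts = [i for i, r in enumerate(recordings) if len(r.hypnogram) >= eps]
    if n_segments > 0 and not hosts:
        raise ValidationError(
            f"no recording is long enough to host a {segment_minutes}-minute segment ({eps} epochs)"
        )

    segments: list[EvalSegment] = []
    used: set[tuple[int, int]] = set()
    attempts = 0
    while len(segments) < n_segments:
        if attempts >= max_attempts:
            raise ValidationError(
                f"could not find {n_segments} segments with >= 2 distinct stages "
                f"after {max_attempts} draws; the hypnograms may be too uniform"
            )
        attempts += 1
        rec_idx = int(rng.choice(hosts))
        rec = recordings[rec_idx]
        start = int(rng.integers(0, len(rec.hypnogram) - eps + 1))
        stages = rec.hypnogram.stages[start : start + eps]
        if len(set(stages)) < 2 or (rec_idx, start) in used:
            continue
        used.add((rec_idx, start))
        spe = rec.samples_per_epoch
        segments.append(
            EvalSegment(
                recording_index=rec_idx,
                start_epoch=start,
                stages=stages,
                signal=rec.signal[start * spe : (start + eps) * spe],
                fs=rec.fs,
            )
        )

    # Single epochs: round-robin over stages so the set spans all stages present.
    by_stage: dict[str, list[tuple[int, int]]] = {s: [] for s in STAGES}
    for rec_idx, rec in enumerate(recordings):
        for ep_idx, stage in enumerate(rec.hypnogram.stages):
            by_stage[stage].append((rec_idx, ep_idx))
    pools = {s: list(rng.permutation(len(v))) for s, v in by_stage.items() if v}
    singles: list[SingleEpochItem] = []
    stage_cycle = [s for s in STAGES if s in pools]
    cursor = 0
    while len(singles) < n_single_epochs:
        if not stage_cycle:
            raise ValidationError(
                f"recordings contain only {len(singles)} epochs; cannot draw {n_single_epochs}"
            )
        stage = stage_cycle[cursor % len(stage_cycle)]
        cursor += 1
        if not pools[stage]:
            stage_cycle.remove(stage)
            continue
        rec_idx, ep_idx = by_stage[stage][pools[stage].pop()]
        rec = recordings[rec_idx]
        spe = rec.samples_per_epoch
        singles.append(
            SingleEpochItem(
                recording_index=rec_idx,
                epoch_index=ep_idx,
                stage=stage,
                epoch=EpochSignal(rec.signal[ep_idx * spe : (ep_idx + 1) * spe], rec.fs),
            )
        )
    return EvalDataset(segments=tuple(segments), single_epochs=tuple(singles))
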