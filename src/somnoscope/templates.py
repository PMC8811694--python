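"""Clinical template filters and the filter-refinement procedure.

A template filter is a short 1-D convolution kernel whose morphology matches
one of the seven EEG graphoelements a sleep technician scores by eye: alpha
waves, theta waves, delta (slow) waves, sawtooth waves, vertex sharp waves,
sleep spindles and k-complexes.  Refinement cleans a kernel so that only the
clinically meaningful content survives: delta kernels are low-pass filtered
(delta activity lives below 4 Hz), spindle kernels are zeroed outside the
burst support, and k-complex kernels are region-selected and then low-pass
filtered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import sawtooth as _sawtooth_wave

__all__ = [
    "PATTERNS",
    "TemplateFilter",
    "RefinementSpec",
    "ValidationError",
    "canonical_waveform",
    "canonical_support",
    "make_canonical_template",
    "lowpass_refine",
    "zero_outside_region",
    "select_and_lowpass",
    "refine_filter_bank",
    "default_refinement_specs",
    "bank_to_json",
    "bank_from_json",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


#: The seven EEG pattern identities carried by template filters.
PATTERNS = ("alpha", "theta", "delta", "sawtooth", "vertex_sharp", "spindle", "kcomplex")

# Canonical oscillation frequencies (Hz).  AASM band conventions: delta
# 0.5-4, theta 4-8, alpha 8-13, spindles 11-16 Hz.
CANONICAL_FREQ = {
    "alpha": 10.0,
    "theta": 6.5,
    "delta": 1.5,
    "sawtooth": 3.0,
    "spindle": 13.0,
}

# Fraction of the kernel span occupied by transient patterns.  Oscillatory
# patterns span the whole kernel; spindles/k-complexes are compact bursts so
# their support is the central region (this is what the "zero outside the
# spindle" refinement keeps).
_SUPPORT_FRACTION = {
    "spindle": (0.20, 0.80),
    "kcomplex": (0.15, 0.85),
    "vertex_sharp": (0.30, 0.70),
}


@dataclass(frozen=True)
class TemplateFilter:
    """A 1-D convolution kernel tagged with a clinical pattern identity."""

    kernel: np.ndarray
    pattern: str
    fs: float

    def __post_init__(self) -> None:
        kernel = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", kernel)
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if kernel.ndim != 1 or kernel.size < 3:
            raise ValidationError("kernel must be a 1-D array of length >= 3")
        if not np.all(np.isfinite(kernel)):
            raise ValidationError("kernel contains non-finite values")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return self.kernel.size


@dataclass(frozen=True)
class RefinementSpec:
    """How to refine filters of one pattern.

    ``apply_order`` controls whether region selection or low-pass filtering
    runs first when both are present; the k-complex refinement selects the
    transient region and low-pass filters afterwards.
    """

    pattern: str
    lowpass_cutoff: float | None = None
    keep_region: tuple[int, int] | None = None
    apply_order: tuple[str, str] = ("select", "lowpass")

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if set(self.apply_order) != {"select", "lowpass"}:
            raise ValidationError("apply_order must be a permutation of ('select', 'lowpass')")


def canonical_waveform(pattern: str, fs: float, duration: float) -> np.ndarray:
    """Deterministic unit-peak waveform with the pattern's canonical morphology.

    The same morphologies are used to synthesize events in the data
    generator, so a canonical template acts as a matched filter for its
    pattern.
    """
    if pattern not in PATTERNS:
        raise ValidationError(f"unknown pattern {pattern!r}")
    n = int(round(duration * fs))
    if n < 3:
        raise ValidationError("duration * fs must be >= 3 samples")
    t = np.arange(n) / fs
    window = np.hanning(n)
    if pattern in ("alpha", "theta", "delta"):
        wave = np.sin(2 * np.pi * CANONICAL_FREQ[pattern] * t) * window
    elif pattern == "sawtooth":
        wave = _sawtooth_wave(2 * np.pi * CANONICAL_FREQ["sawtooth"] * t, width=0.5) * window
    elif pattern == "spindle":
        lo, hi = _SUPPORT_FRACTION["spindle"]
        env = np.zeros(n)
        i0, i1 = int(lo * n), int(hi * n)
        env[i0:i1] = np.hanning(max(i1 - i0, 1))
        wave = np.sin(2 * np.pi * CANONICAL_FREQ["spindle"] * t) * env
    elif pattern == "vertex_sharp":
        # Brief high-amplitude monophasic (negative) transient.
        sigma = 0.04  # seconds
        wave = -np.exp(-0.5 * ((t - t[n // 2]) / sigma) ** 2)
    else:  # kcomplex: biphasic, a sharp negative wave then a slower positive one
        t1, s1 = 0.40 * duration, 0.06 * duration
        t2, s2 = 0.65 * duration, 0.12 * duration
        wave = -np.exp(-0.5 * ((t - t1) / s1) ** 2) + 0.8 * np.exp(-0.5 * ((t - t2) / s2) ** 2)
        lo, hi = _SUPPORT_FRACTION["kcomplex"]
        mask = np.zeros(n)
        i0, i1 = int(lo * n), int(hi * n)
        mask[i0:i1] = 1.0
        wave = wave * mask
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak
    return wave


def canonical_support(pattern: str, kernel_len: int) -> tuple[int, int]:
    """Half-open sample interval of the pattern's support within a kernel."""
    lo, hi = _SUPPORT_FRACTION.get(pattern, (0.0, 1.0))
    return int(lo * kernel_len), max(int(hi * kernel_len), int(lo * kernel_len) + 1)


def make_canonical_template(pattern: str, fs: float, duration: float) -> TemplateFilter:
    """Build a unit-L2-norm canonical template filter."""
    wave = canonical_waveform(pattern, fs, duration)
    norm = np.linalg.norm(wave)
    if norm > 0:
        wave = wave / norm
    return TemplateFilter(kernel=wave, pattern=pattern, fs=fs)


def _lowpass_kernel(kernel: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    # Zero-phase FFT-domain brick-wall mask: bins at or above the cutoff are
    # zeroed.  Exactly idempotent and leaves zero power above the cutoff.
    spectrum = np.fft.rfft(kernel)
    freqs = np.fft.rfftfreq(kernel.size, d=1.0 / fs)
    spectrum[freqs >= cutoff] = 0.0
    return np.fft.irfft(spectrum, n=kernel.size)


def lowpass_refine(filt: TemplateFilter, cutoff: float) -> TemplateFilter:
    """Remove spectral content at or above ``cutoff`` (Hz), preserving phase."""
    if not (0 < cutoff < filt.fs / 2):
        raise ValidationError(f"cutoff must lie in (0, fs/2)=(0, {filt.fs / 2}); got {cutoff}")
    return replace(filt, kernel=_lowpass_kernel(filt.kernel, filt.fs, cutoff))


def zero_outside_region(filt: TemplateFilter, keep_region: tuple[int, int]) -> TemplateFilter:
    """Zero every kernel sample outside the half-open ``keep_region``."""
    start, end = keep_region
    n = len(filt)
    if not (0 <= start < end <= n):
        raise ValidationError(f"keep_region {keep_region} is empty or outside the kernel span [0, {n})")
    out = np.zeros_like(filt.kernel)
    out[start:end] = filt.kernel[start:end]
    return replace(filt, kernel=out)


def select_and_lowpass(
    filt: TemplateFilter, keep_region: tuple[int, int], cutoff: float
) -> TemplateFilter:
    """Region selection followed by low-pass filtering (the k-complex recipe)."""
    return lowpass_refine(zero_outside_region(filt, keep_region), cutoff)


def default_refinement_specs(kernel_len: int) -> list[RefinementSpec]:
    """The three worked refinement cases: delta low-passed below 4 Hz, spindle
    zeroed outside the burst support, k-complex region-selected then
    low-passed; the other four patterns pass through untouched."""
    return [
        RefinementSpec(pattern="delta", lowpass_cutoff=4.0),
        RefinementSpec(pattern="spindle", keep_region=canonical_support("spindle", kernel_len)),
        RefinementSpec(
            pattern="kcomplex",
            lowpass_cutoff=4.0,
            keep_region=canonical_support("kcomplex", kernel_len),
        ),
    ]


def _apply_spec(filt: TemplateFilter, spec: RefinementSpec) -> TemplateFilter:
    for step in spec.apply_order:
        if step == "select" and spec.keep_region is not None:
            filt = zero_outside_region(filt, spec.keep_region)
        elif step == "lowpass" and spec.lowpass_cutoff is not None:
            filt = lowpass_refine(filt, spec.lowpass_cutoff)
    return filt


def refine_filter_bank(
    filters: list[TemplateFilter], specs: list[RefinementSpec]
) -> list[TemplateFilter]:
    """Apply each pattern's refinement spec to the matching filters."""
    by_pattern: dict[str, RefinementSpec] = {}
    for spec in specs:
        if spec.pattern in by_pattern:
            raise ValidationError(f"duplicate refinement spec for pattern {spec.pattern!r}")
        by_pattern[spec.pattern] = spec
    known = {f.pattern for f in filters}
    for pattern in by_pattern:
        if pattern not in known:
            raise ValidationError(f"refinement spec for pattern {pattern!r} absent from the bank")
    return [
        _apply_spec(f, by_pattern[f.pattern]) if f.pattern in by_pattern else f for f in filters
    ]


def bank_to_json(filters: list[TemplateFilter], path) -> None:
    payload = [
        {"pattern": f.pattern, "fs": f.fs, "kernel": f.kernel.tolist()} for f in filters
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def bank_from_json(path) -> list[TemplateFilter]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        TemplateFilter(kernel=np.asarray(item["kernel"], dtype=float), pattern=item["pattern"], fs=item["fs"])
        for item in payload
    ]
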