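"""Readers, writers, configuration, rendering and the end-to-end pipeline.

Formats: EDF (16-bit, physical units µV) or a two-column CSV dialect
(``time_s,eeg_uv``) for recordings; two-column TSV (``epoch_index<TAB>stage``)
for hypnograms; JSON lines for event annotations; YAML for run
configuration; deterministic SVG plus a JSON layer manifest for rendered
epochs.  EDF reading goes through mne; the EDF writer here emits the plain
16-bit continuous-record layout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .evalstats import ScoringRecord, macro_f1
from .explainer import (
    ExplanationBundle,
    bundle_to_json,
    calibrate_thresholds,
    explain_epoch,
)
from .stager import StagerConfig, build_model, predict_epoch, save_model, train_model
from .synthetic import (
    STAGES,
    EpochSignal,
    EpochSynthesisParams,
    EventAnnotation,
    Hypnogram,
    build_eval_sets,
    generate_hypnogram,
    generate_recording,
    iter_epochs,
)
from .templates import (
    PATTERNS,
    RefinementSpec,
    ValidationError,
    canonical_support,
    make_canonical_template,
    refine_filter_bank,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_recording",
    "write_recording_csv",
    "write_recording_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_scores_csv",
    "render_epoch",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# Configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_recordings: int = 20
    n_epochs: int = 60
    noise_sd: float = 5.0
    delta_coverage: float = 0.35
    sweat: bool = False


class StagerSection(_Strict):
    n_free_filters: int = 8
    kernel_len: int = 100
    pool_len: int = 100
    hidden: int = 32
    learning_rate: float = 1e-3
    train_epochs: int = 30
    batch_size: int = 64
    freeze_templates: bool = True


class RefinementSection(_Strict):
    # The delta rationale (content < 4 Hz) fixes the delta cutoff; the
    # k-complex cutoff and the region selections are package defaults.
    delta_cutoff_hz: float = 4.0
    kcomplex_cutoff_hz: float = 4.0


class ExplainerSection(_Strict):
    saliency_percentile: float = 90.0
    calibration_epochs: int = 100


class EvalSection(_Strict):
    segment_minutes: float = 15.0
    n_segments: int = 4
    n_single_epochs: int = 30


class RunConfig(_Strict):
    seed: int = 0
    fs: float = 100.0
    epoch_duration: float = 30.0
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    stager: StagerSection = Field(default_factory=StagerSection)
    refinement: RefinementSection = Field(default_factory=RefinementSection)
    explainer: ExplainerSection = Field(default_factory=ExplainerSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError
        raise ValidationError(f"invalid configuration {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Recordings

def write_recording_csv(signal: np.ndarray, fs: float, path) -> None:
    time_s = np.arange(len(signal)) / fs
    pd.DataFrame({"time_s": time_s, "eeg_uv": signal}).to_csv(path, index=False)


def _read_recording_csv(path) -> tuple[np.ndarray, float, dict]:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "eeg_uv"]:
        raise ValidationError(
            f"{path}: expected CSV header 'time_s,eeg_uv', got {list(df.columns)}"
        )
    if len(df) < 2:
        raise ValidationError(f"{path}: recording must contain at least 2 samples")
    dt = np.diff(df["time_s"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    return df["eeg_uv"].to_numpy(dtype=float), fs, {"format": "csv"}


def write_recording_edf(signal: np.ndarray, fs: float, path, label: str = "EEG") -> None:
    """Minimal single-channel EDF writer (16-bit, 1-second data records)."""
    signal = np.asarray(signal, dtype=float)
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(len(signal) / spr))
    padded = np.zeros(n_records * spr)
    padded[: len(signal)] = signal
    pmax = float(max(np.max(np.abs(padded)), 1.0))
    # quantize with the header-printed physical range so reader and writer
    # agree on the scale exactly
    pmax = float(f"{pmax:.6g}")
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((padded - pmin) * scale) + dmin, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2000 X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad("1", 4),
            # per-signal fields
            pad(label, 16),
            pad("", 80),
            pad("uV", 8),
            pad(f"{pmin:.6g}", 8),
            pad(f"{pmax:.6g}", 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),
            pad(str(spr), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def _read_recording_edf(path) -> tuple[np.ndarray, float, dict]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    signal = raw.get_data()[0] * 1e6  # mne returns volts; recordings are µV
    return signal, fs, {"format": "edf", "channels": raw.ch_names}


def read_recording(path, format: str | None = None) -> tuple[np.ndarray, float, dict]:
    """Read a single-channel recording from EDF or CSV; returns (µV, fs, meta)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    format = format.lower()
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        try:
            return _read_recording_edf(path)
        except ValidationError:
            raise
        except Exception as exc:
            raise ValidationError(f"{path}: unreadable EDF file ({exc})") from exc
    raise ValidationError(f"unknown recording format {format!r}; expected EDF or CSV")


# ---------------------------------------------------------------------------
# Hypnograms and events

def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index\tstage\n")
        for i, stage in enumerate(hypnogram.stages):
            fh.write(f"{i}\t{stage}\n")


def read_hypnogram(path, epoch_duration: float = 30.0) -> Hypnogram:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty hypnogram file")
    if lines[0] != "epoch_index\tstage":
        raise ValidationError(f"{path}: expected header 'epoch_index\\tstage'")
    stages = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected two tab-separated fields")
        idx_str, stage = fields
        if stage not in STAGES:
            raise ValidationError(f"{path}:{lineno}: unknown stage token {stage!r}")
        if int(idx_str) != len(stages):
            raise ValidationError(
                f"{path}:{lineno}: epoch index {idx_str} breaks the contiguous 0..n sequence"
            )
        stages.append(stage)
    if not stages:
        raise ValidationError(f"{path}: hypnogram contains a header but no epochs")
    return Hypnogram(stages=tuple(stages), epoch_duration=epoch_duration)


def write_events(events, path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "event_type": ev.event_type,
                        "start": ev.start,
                        "end": ev.end,
                        "epoch_index": ev.epoch_index,
                    }
                )
                + "\n"
            )


def read_events(path) -> list[EventAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                payload = json.loads(line)
                out.append(EventAnnotation(**payload))
    return out


def read_scores_csv(path) -> list[ScoringRecord]:
    """Long-format scoring table: segment_id, rater_id, setting, epoch_index, stage."""
    df = pd.read_csv(path)
    required = {"segment_id", "rater_id", "setting", "epoch_index", "stage"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for (segment, rater, setting), group in df.groupby(
        ["segment_id", "rater_id", "setting"], sort=True
    ):
        group = group.sort_values("epoch_index")
        records.append(
            ScoringRecord(
                segment_id=str(segment),
                rater_id=str(rater),
                setting=str(setting),
                stages=tuple(group["stage"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Rendering

_BOX_COLORS = {"kcomplex": "red", "spindle": "blue", "sawtooth": "purple"}


def render_epoch(epoch: EpochSignal, bundle: ExplanationBundle, out_path) -> dict:
    """Render one epoch's EEG trace with its routed overlays to SVG.

    Colors follow the in-tool convention: red k-complex / blue spindle
    boxes, green delta blocks, pink saliency highlights, with the alpha
    surface in its own panel.  Output is deterministic (no timestamps); a
    JSON layer manifest is written next to the figure and returned.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = epoch.signal.size
    for name, bound in (
        ("boxes", max((b.end for b in bundle.boxes), default=0) if bundle.boxes else 0),
        ("delta", bundle.delta.binary.size if bundle.delta is not None else 0),
        ("alpha", bundle.alpha.values.size if bundle.alpha is not None else 0),
        ("highlights", max((r[1] for r in bundle.highlights.regions), default=0) if bundle.highlights else 0),
    ):
        if bound > n:
            raise ValidationError(f"bundle component {name!r} extends past the epoch ({bound} > {n})")

    with matplotlib.rc_context({"svg.hashsalt": "somnoscope"}):
        t = np.arange(n) / epoch.fs
        n_panels = 2 if bundle.alpha is not None else 1
        fig, axes = plt.subplots(
            n_panels, 1, figsize=(10, 2.2 * n_panels), sharex=True, squeeze=False
        )
        ax = axes[0, 0]
        ax.plot(t, epoch.signal, color="black", linewidth=0.5)
        layers = ["eeg"]
        if bundle.highlights is not None and bundle.highlights.regions:
            for start, end in bundle.highlights.regions:
                ax.axvspan(start / epoch.fs, end / epoch.fs, color="pink", alpha=0.5, lw=0)
            layers.append("saliency_highlights")
        if bundle.delta is not None and bundle.delta.blocks:
            for start, end in bundle.delta.blocks:
                ax.axvspan(start / epoch.fs, end / epoch.fs, color="green", alpha=0.3, lw=0)
            layers.append("delta_blocks")
        if bundle.boxes:
            lo, hi = float(epoch.signal.min()), float(epoch.signal.max())
            for box in bundle.boxes:
                ax.add_patch(
                    plt.Rectangle(
                        (box.start / epoch.fs, lo),
                        (box.end - box.start) / epoch.fs,
                        hi - lo,
                        fill=False,
                        edgecolor=_BOX_COLORS.get(box.pattern, "gray"),
                        linewidth=1.2,
                    )
                )
            layers.append("detection_boxes")
        ax.set_ylabel("EEG (µV)")
        ax.set_title(f"epoch {bundle.epoch_index}: predicted {bundle.prediction.predicted_stage}")
        if bundle.alpha is not None:
            ax2 = axes[-1, 0]
            ax2.fill_between(t, 0, bundle.alpha.values, color="orange", alpha=0.7, lw=0)
            ax2.set_ylabel("alpha surface")
            layers.append("alpha_surface")
        axes[-1, 0].set_xlabel("time (s)")
        fig.savefig(out_path, format="svg", metadata={"Date": None})
        plt.close(fig)

    manifest = {
        "epoch_index": bundle.epoch_index,
        "predicted_stage": bundle.prediction.predicted_stage,
        "layers": layers,
    }
    manifest_path = Path(str(out_path) + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# End-to-end pipeline

def _stage(stage_name: str):
    class _StageContext:
        def __enter__(self):
            logger.info("pipeline stage: %s", stage_name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage_name, str(exc)) from exc
            return False

    return _StageContext()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """simulate -> train -> calibrate -> predict -> explain -> evaluate.

    Writes the config copy, a log, the trained checkpoint, metrics
    (JSON + CSV), explanation bundles (JSON lines) and a few renderings
    into ``out_dir``; every random draw derives from ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("somnoscope")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "somnoscope %s | seed=%d | config_hash=%s", __version__, config.seed, config_hash(config)
        )
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))

        seeds = np.random.SeedSequence(config.seed).generate_state(4 + config.simulate.n_recordings) >> 1
        params = EpochSynthesisParams(
            noise_sd=config.simulate.noise_sd,
            delta_coverage=config.simulate.delta_coverage,
            sweat=config.simulate.sweat,
            epoch_duration=config.epoch_duration,
        )

        with _stage("simulate"):
            recordings = []
            for i in range(config.simulate.n_recordings):
                hyp = generate_hypnogram(
                    config.simulate.n_epochs,
                    seed=int(seeds[4 + i]),
                    epoch_duration=config.epoch_duration,
                )
                recordings.append(
                    generate_recording(hyp, config.fs, params, seed=int(seeds[4 + i]))
                )
            n = len(recordings)
            n_train = max(1, int(round(0.8 * n)))
            n_val = max(1, int(round(0.1 * n)))
            n_train = min(n_train, n - 2) if n >= 3 else max(1, n - 2)
            train_recs = recordings[:n_train]
            val_recs = recordings[n_train : n_train + n_val]
            test_recs = recordings[n_train + n_val :] or recordings[-1:]
            if not val_recs:
                val_recs = recordings[-1:]

        with _stage("train"):
            input_len = int(round(config.epoch_duration * config.fs))
            stager_cfg = StagerConfig(
                n_template_filters=len(PATTERNS),
                n_free_filters=config.stager.n_free_filters,
                kernel_len=config.stager.kernel_len,
                pool_len=config.stager.pool_len,
                hidden=config.stager.hidden,
                input_len=input_len,
                learning_rate=config.stager.learning_rate,
                train_epochs=config.stager.train_epochs,
                batch_size=config.stager.batch_size,
                freeze_templates=config.stager.freeze_templates,
                seed=int(seeds[0]),
            )
            duration = config.stager.kernel_len / config.fs
            bank = [make_canonical_template(p, config.fs, duration) for p in PATTERNS]
            specs = [
                RefinementSpec(pattern="delta", lowpass_cutoff=config.refinement.delta_cutoff_hz),
                RefinementSpec(
                    pattern="spindle",
                    keep_region=canonical_support("spindle", config.stager.kernel_len),
                ),
                RefinementSpec(
                    pattern="kcomplex",
                    lowpass_cutoff=config.refinement.kcomplex_cutoff_hz,
                    keep_region=canonical_support("kcomplex", config.stager.kernel_len),
                ),
            ]
            bank = refine_filter_bank(bank, specs)
            model = build_model(stager_cfg, bank)
            train_set = [ep for rec in train_recs for ep in iter_epochs(rec)]
            val_set = [ep for rec in val_recs for ep in iter_epochs(rec)]
            model, history = train_model(model, train_set, val_set, stager_cfg)
            save_model(model, out_dir / "model.npz")
            logger.info("best validation macro-F1 = %.3f", history.best_val_macro_f1)

        with _stage("calibrate"):
            calib: list[tuple[EpochSignal, list[EventAnnotation]]] = []
            for rec in val_recs:
                spe = rec.samples_per_epoch
                for idx, (epoch, _) in enumerate(iter_epochs(rec)):
                    evs = [
                        EventAnnotation(e.event_type, e.start - idx * spe, e.end - idx * spe, 0)
                        for e in rec.events
                        if e.epoch_index == idx
                    ]
                    calib.append((epoch, evs))
                    if len(calib) >= config.explainer.calibration_epochs:
                        break
                if len(calib) >= config.explainer.calibration_epochs:
                    break
            thresholds = calibrate_thresholds(model, calib)

        with _stage("predict"):
            eval_sets = build_eval_sets(
                test_recs,
                segment_minutes=config.eval.segment_minutes,
                n_segments=config.eval.n_segments,
                n_single_epochs=config.eval.n_single_epochs,
                seed=int(seeds[1]),
            )
            spe = input_len
            segment_results = []
            for seg in eval_sets.segments:
                preds = []
                for i in range(len(seg.stages)):
                    ep = EpochSignal(seg.signal[i * spe : (i + 1) * spe], seg.fs)
                    preds.append(predict_epoch(model, ep).predicted_stage)
                segment_results.append(
                    {
                        "recording_index": seg.recording_index,
                        "start_epoch": seg.start_epoch,
                        "macro_f1": macro_f1(preds, list(seg.stages)),
                    }
                )
            single_preds = [
                predict_epoch(model, item.epoch).predicted_stage
                for item in eval_sets.single_epochs
            ]
            single_truth = [item.stage for item in eval_sets.single_epochs]

        with _stage("explain"):
            bundles_path = out_dir / "bundles.jsonl"
            with open(bundles_path, "w") as fh:
                for j, item in enumerate(eval_sets.single_epochs):
                    bundle = explain_epoch(
                        model,
                        item.epoch,
                        thresholds,
                        epoch_index=item.epoch_index,
                        saliency_percentile=config.explainer.saliency_percentile,
                    )
                    fh.write(json.dumps(bundle_to_json(bundle)) + "\n")
                    if j < 3:
                        render_epoch(item.epoch, bundle, out_dir / f"epoch_{j}.svg")

        with _stage("evaluate"):
            metrics = {
                "seed": config.seed,
                "config_hash": config_hash(config),
                "version": __version__,
                "best_val_macro_f1": history.best_val_macro_f1,
                "segments": segment_results,
                "segment_macro_f1_mean": float(
                    np.mean([s["macro_f1"] for s in segment_results])
                )
                if segment_results
                else None,
                "single_epoch_macro_f1": macro_f1(single_preds, single_truth)
                if single_preds
                else None,
                "thresholds": {k: float(v) for k, v in thresholds.thresholds.items()},
            }
            (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
            pd.DataFrame(segment_results).to_csv(out_dir / "segment_metrics.csv", index=False)
        return out_dir
    finally:
        root.removeHandler(handler)
        handler.close()
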