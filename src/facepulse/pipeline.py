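"""Configured, logged, reproducible end-to-end runs.

``run_pipeline`` chains simulate -> rois -> extract -> timelag -> stats ->
maps -> evm and writes every stage artefact plus a manifest (config hash,
seeds, per-stage status and timing, warning log, file list).  All
randomised stages draw child seeds from the master seed through
``numpy.random.SeedSequence``, so a stage can be re-run independently and a
whole run is bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import AnalysisConfig, analyze_recording, build_maps
from .evm import EvmParams, magnify
from .landmarks import LandmarkSet, load_landmarks
from .synthetic import PulseModelParams, default_params, generate_video
from .video import FrameSequence


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, problems: list[str]):
        super().__init__("invalid configuration:\n- " + "\n- ".join(problems))
        self.problems = problems


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Defaults mirror the acquisition and analysis settings the pipeline
    targets: 40 fps, 80 px ROIs, pulse band 0.5-4 Hz, breathing band
    0.2-0.5 Hz, mid-forehead reference region 20, top-50 quality ranking,
    5000 bootstrap resamples, goodness half-width 0.1 Hz with a 50%
    exclusion threshold.
    """

    out_dir: str = "facepulse_run"
    fps: float = 40.0
    frames_dir: str | None = None        # existing recording; None -> simulate
    landmarks_file: str | None = None
    simulate: bool = True
    frame_size: tuple[int, int] = (512, 512)
    duration_s: float = 30.0
    roi_size: int = 80
    pulse_band: tuple[float, float] = (0.5, 4.0)
    breath_band: tuple[float, float] = (0.2, 0.5)
    reference_region: int = 20
    top_n: int = 50
    n_boot: int = 5000
    goodness_b: float = 0.1
    goodness_band: tuple[float, float] = (0.5, 4.0)
    goodness_threshold: float = 0.5
    evm: EvmParams = field(default_factory=EvmParams)
    evm_enabled: bool = False
    seed: int = 0
    write_frames: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw: dict) -> RunConfig:
    """Inject defaults, normalise units, and reject contradictions."""
    problems: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "evm" in kwargs and isinstance(kwargs["evm"], dict):
        kwargs["evm"] = EvmParams(**{k: tuple(v) if k == "band" else v
                                     for k, v in kwargs["evm"].items()})
    for key in ("pulse_band", "breath_band", "goodness_band", "frame_size"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if problems:
        raise ConfigError(problems)
    cfg = RunConfig(**kwargs)

    if "fps" not in raw and cfg.frames_dir is None and not cfg.simulate:
        problems.append("fps must be given when no recording metadata is available")
    nyq = cfg.fps / 2.0
    for name, band in (("pulse_band", cfg.pulse_band),
                       ("breath_band", cfg.breath_band),
                       ("goodness_band", cfg.goodness_band)):
        if not 0 < band[0] < band[1]:
            problems.append(f"{name} {band} must be increasing and positive")
        elif band[1] >= nyq:
            problems.append(f"{name} upper edge {band[1]} Hz is at or above "
                            f"Nyquist {nyq} Hz for fps {cfg.fps}")
    if cfg.roi_size <= 0:
        problems.append("roi_size must be positive")
    if not 0 <= cfg.reference_region <= 97:
        problems.append("reference_region must be a region id 0-97")
    if cfg.top_n > 98:
        warnings.warn(f"top_n={cfg.top_n} clamped to the 98 available regions")
        cfg.top_n = 98
    if cfg.top_n < 1:
        problems.append("top_n must be at least 1")
    if cfg.n_boot < 100:
        problems.append("n_boot below 100 gives meaningless intervals")
    if not cfg.simulate and cfg.frames_dir is None:
        problems.append("either simulate=true or frames_dir must be given")
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    import yaml
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(), "config_hash": config.config_hash(),
        "seed": config.seed, "version": __version__,
        "stages": {}, "files": [], "warnings": [],
    }
    children = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    def _record(name: str, t0: float, **extra) -> None:
        manifest["stages"][name] = {"status": "complete",
                                    "seconds": round(time.time() - t0, 3), **extra}

    def _write(path: Path) -> None:
        manifest["files"].append(str(path.relative_to(out)))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            # --- acquire frames -------------------------------------------------
            t0 = time.time()
            truth = None
            if config.frames_dir is not None:
                frames = FrameSequence.read(config.frames_dir, fps=config.fps)
                if config.landmarks_file is None:
                    raise ConfigError(["landmarks_file is required with frames_dir"])
                landmarks = load_landmarks(config.landmarks_file, frames.frame_size)
                _record("load", t0, n_frames=frames.n_frames)
            else:
                params = default_params(fps=config.fps, duration_s=config.duration_s,
                                        seed=stage_seeds[0])
                frames, truth = generate_video(params, frame_size=config.frame_size)
                landmarks = truth.landmark_set
                if config.write_frames:
                    frames.write(out / "frames")
                truth_path = out / "ground_truth.json"
                truth_path.write_text(json.dumps({
                    "region_lags_ms": {r: v * 1000 for r, v in
                                       truth.region_lags_s.items()},
                    "region_amplitudes": truth.region_amplitudes,
                    "heart_rate_bpm": params.heart_rate_hz * 60,
                    "breath_rate_bpm": params.breath_rate_hz * 60}, indent=1))
                _write(truth_path)
                landmarks.save(out / "landmarks.json")
                _write(out / "landmarks.json")
                _record("simulate", t0, n_frames=frames.n_frames,
                        seed=stage_seeds[0])

            # --- regional analysis ---------------------------------------------
            t0 = time.time()
            acfg = AnalysisConfig(
                roi_size=config.roi_size, pulse_band=config.pulse_band,
                breath_band=config.breath_band,
                reference_region=config.reference_region, top_n=config.top_n,
                goodness_b=config.goodness_b, goodness_band=config.goodness_band,
                goodness_threshold=config.goodness_threshold)
            analysis = analyze_recording(frames, landmarks, acfg)
            for name, frame in (("signals", analysis.signals_frame()),
                                ("quality", analysis.quality_frame()),
                                ("lags", analysis.lag_frame())):
                p = out / f"{name}.csv"
                frame.to_csv(p, index=False, float_format="%.10g")
                _write(p)
            _record("extract", t0, n_regions=len(analysis.signals),
                    n_lags=len(analysis.lags_ms))

            # --- maps -----------------------------------------------------------
            t0 = time.time()
            face_maps = build_maps(analysis)
            bounds = {}
            for kind, fmap in face_maps.items():
                fmap.to_csv(out / f"map_{kind}.csv")
                _write(out / f"map_{kind}.csv")
                fmap.render(analysis.regions, out / f"map_{kind}.png")
                _write(out / f"map_{kind}.png")
                bounds[kind] = fmap.color_bounds
            (out / "map_bounds.json").write_text(json.dumps(bounds, default=str))
            _write(out / "map_bounds.json")
            _record("maps", t0)

            # --- EVM ------------------------------------------------------------
            if config.evm_enabled:
                t0 = time.time()
                result = magnify(frames, config.evm)
                result.frames.write(out / "evm_frames")
                _record("evm", t0, clip_fraction=result.clip_fraction)
        except Exception as exc:
            failed_stage = next((s for s in ("load", "simulate", "extract",
                                             "maps", "evm")
                                 if s not in manifest["stages"]), "unknown")
            manifest["stages"][failed_stage] = {"status": "failed",
                                                "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          default=str))
            raise
        finally:
            manifest["warnings"] = [str(w.message) for w in caught]

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
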