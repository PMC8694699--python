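"""End-to-end pipeline: simulate recordings, analyze them, report trends.

``run_simulate`` writes a synthetic data set (videos, traces, ethograms,
ground truth) for a grid of temperatures and flies, with a manifest
recording seeds and content hashes.  ``run_full`` drives the analysis
over such a data set: leg-movement counting, bout-cycle extraction,
periodicity classification, per-fly summaries and the temperature-trend /
coupling report.  All stochastic behavior derives from the single config
seed, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import boutcycles, io, legmotion, rhythm, simgen, thermal

__all__ = ["PipelineConfig", "run_simulate", "run_full", "analyze_recording"]

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURES = (18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0)


@dataclass
class PipelineConfig:
    """Configuration shared by the simulation and analysis drivers.

    Thresholds default to the study's printed constants: dynamics
    threshold theta = 5.0; 31-frame confidence smoothing; cycle peak
    prominence 0.1 / height 0.05; PI prominence and height 0.2; 280-frame
    cycle cutoff (380 for the TNT condition).
    """

    out_dir: str = "groomrhythm_out"
    condition: str = "dusted"
    temperatures: tuple = DEFAULT_TEMPERATURES
    n_flies: int = 8
    duration_s: float = 90.0
    frame_rate_hz: float = 60.0
    seed: int = 0
    write_video: bool = True
    # analysis parameters
    window_hop: int = legmotion.WINDOW_FRAMES
    theta: float = 5.0
    cycle_prominence: float = boutcycles.PEAK_PROMINENCE
    cycle_height: float = boutcycles.PEAK_HEIGHT
    max_cycle_frames: int | None = None     # None -> 280, or 380 for tnt
    pi_prominence: float = rhythm.PI_PROMINENCE
    pi_height: float = rhythm.PI_HEIGHT
    long_window_frames: int = rhythm.LONG_WINDOW_FRAMES
    long_hop: int = 333

    def resolved_max_cycle_frames(self) -> int:
        if self.max_cycle_frames is not None:
            return self.max_cycle_frames
        return (boutcycles.MAX_CYCLE_FRAMES_TNT if self.condition == "tnt"
                else boutcycles.MAX_CYCLE_FRAMES)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML (JSON is a subset of YAML); kwargs override."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "temperatures" in data:
            data["temperatures"] = tuple(float(t) for t in data["temperatures"])
        return cls(**data)


def _fly_seed(base: int, temp_index: int, fly: int) -> int:
    return (base + 10_007 * temp_index + 101 * fly) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: PipelineConfig) -> Path:
    """Write a synthetic data set and manifest; returns the output dir."""
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e
    entries = []
    for ti, temp in enumerate(config.temperatures):
        for fly in range(config.n_flies):
            seed = _fly_seed(config.seed, ti, fly)
            cfg = simgen.preset(config.condition, temp,
                                duration_s=config.duration_s, seed=seed)
            stem = f"{config.condition}_T{temp:g}_fly{fly}"
            files = {}
            if config.write_video:
                stack, traces, eth, gt = simgen.generate_recording(cfg)
                io.write_video(stack, out / f"{stem}.tif")
                files["video"] = f"{stem}.tif"
            else:
                traces, gt = simgen.generate_traces(cfg)
                eth = np.where(gt.mode == "f", "front_leg_rub",
                               np.where(gt.mode == "h", "head_clean",
                                        "standing"))
            io.write_traces(traces, out / f"{stem}_traces.csv")
            io.write_ethogram(eth, out / f"{stem}_ethogram.csv")
            (out / f"{stem}_truth.json").write_text(json.dumps({
                "f_fast_hz": gt.f_fast_hz,
                "f_slow_hz": gt.f_slow_hz,
                "realized_periodic_fraction": gt.realized_periodic_fraction,
                "bout_boundaries": gt.bout_boundaries.tolist(),
                "episodes": [[e.start, e.end, e.periodic] for e in gt.episodes],
            }) + "\n")
            files.update({"traces": f"{stem}_traces.csv",
                          "ethogram": f"{stem}_ethogram.csv",
                          "truth": f"{stem}_truth.json"})
            entries.append({
                "fly_id": stem, "condition": config.condition,
                "temperature_C": temp, "seed": seed, "files": files,
                "hashes": {k: _sha256(out / v) for k, v in files.items()},
            })
    manifest = {
        "config": dataclasses.asdict(config),
        "max_cycle_frames": config.resolved_max_cycle_frames(),
        "recordings": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    return out


def analyze_recording(
    config: PipelineConfig,
    traces: simgen.ProbabilityTracePair,
    ethogram: np.ndarray,
    stack: simgen.FrameStack | None,
    metadata: dict,
) -> thermal.FlySummary:
    """Run the full per-recording analysis chain into a FlySummary."""
    leg_series = None
    if stack is not None:
        leg_series = legmotion.leg_frequency_series(
            stack, ethogram, hop=config.window_hop, theta=config.theta)
    bc = boutcycles.confidence(traces)
    cycles = boutcycles.extract_cycles(
        bc, max_duration_frames=config.resolved_max_cycle_frames(),
        prominence=config.cycle_prominence, height=config.cycle_height)
    groom = np.isin(ethogram, sorted(simgen.GROOMING_LABELS))
    long_results = []
    if bc.n_frames >= config.long_window_frames:
        for t in rhythm.long_scale_acf(bc, window_frames=config.long_window_frames,
                                       hop=config.long_hop):
            s = t.window_start_frame
            if not groom[s:s + config.long_window_frames].all():
                continue
            long_results.append(rhythm.periodicity_index(
                t, prominence=config.pi_prominence, height=config.pi_height))
    rhythm_results = {
        "long": long_results,
        "long_window_s": config.long_window_frames / traces.frame_rate_hz,
    }
    return thermal.summarize_fly(leg_series, cycles, rhythm_results, metadata)


def run_full(config: PipelineConfig, data_dir: str | Path | None = None) -> dict:
    """Analyze a simulated data set end to end; returns the report dict.

    Reads the manifest in ``data_dir`` (default: ``config.out_dir``),
    analyzes every recording, writes per-fly summary JSONs and a
    ``report.json`` with fast/slow temperature trends and their coupling.
    """
    data = Path(data_dir if data_dir is not None else config.out_dir)
    manifest_path = data / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"no manifest.json in {data}; run the simulate step first")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("recordings"):
        raise ValueError(f"manifest in {data} lists no recordings")
    summaries = []
    for rec in manifest["recordings"]:
        files = rec["files"]
        try:
            traces = io.read_traces(data / files["traces"])
            eth = io.read_ethogram(data / files["ethogram"])
            stack = (io.read_video(data / files["video"])
                     if "video" in files else None)
            summaries.append(analyze_recording(
                config, traces, eth, stack,
                {"fly_id": rec["fly_id"], "condition": rec["condition"],
                 "temperature_C": rec["temperature_C"]}))
        except Exception as e:
            raise RuntimeError(
                f"stage=analyze recording={rec['fly_id']}: {e}") from e
    for s in summaries:
        io.write_summary(s, data / f"{s.fly_id}_summary.json")
    df = thermal.summaries_frame(summaries)
    report: dict = {"n_recordings": len(summaries),
                    "condition": config.condition}
    try:
        fast = thermal.thermal_trend(df, "fast")
        slow = thermal.thermal_trend(df, "slow")
        report["fast_trend"] = {
            "slope_hz_per_C": fast.slope_hz_per_C,
            "r_squared": fast.r_squared, "p_value": fast.p_value,
            "means_hz": fast.means_hz.tolist(),
            "temperatures": fast.temperatures.tolist(),
        }
        report["slow_trend"] = {
            "slope_hz_per_C": slow.slope_hz_per_C,
            "r_squared": slow.r_squared, "p_value": slow.p_value,
            "means_hz": slow.means_hz.tolist(),
            "temperatures": slow.temperatures.tolist(),
        }
        report["coupling"] = thermal.coupling(fast, slow)
        report["normalized_rates"] = {
            "fast": thermal.normalized_rates(fast).tolist(),
            "slow": thermal.normalized_rates(slow).tolist(),
        }
    except ValueError as e:
        logger.warning("trend analysis skipped: %s", e)
        report["trend_error"] = str(e)
    report["movements_per_cycle_grand_mean"] = float(
        np.nanmean(df["movements_per_cycle_mean"]))
    report["periodic_fraction_long_mean"] = float(
        np.nanmean(df["periodic_fraction_long"]))
    (data / "report.json").write_text(json.dumps(report, indent=1,
                                                 sort_keys=True) + "\n")
    return report
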