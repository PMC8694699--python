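"""File formats: TIFF video stacks, trace/ethogram/cycles CSV, summary JSON.

All writers round-trip bit-exactly through their readers.  Videos are
8-bit grayscale multi-page TIFF with the frame rate in a JSON sidecar
(``<stem>.json``); traces and ethograms are per-frame CSV; parse errors
name the offending line.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .boutcycles import Cycle, CycleSet
from .simgen import ETHOGRAM_LABELS, FrameStack, ProbabilityTracePair
from .thermal import FlySummary

__all__ = [
    "write_video",
    "read_video",
    "write_traces",
    "read_traces",
    "write_ethogram",
    "read_ethogram",
    "write_cycles",
    "read_cycles",
    "write_summary",
    "read_summary",
]


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_video(stack: FrameStack, path: str | Path) -> None:
    """8-bit grayscale multi-page TIFF plus a frame-rate sidecar JSON."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"frame_rate_hz": stack.frame_rate_hz, "n_frames": int(frames.shape[0])},
        indent=1) + "\n")


def read_video(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(frames=frames.astype(np.float32),
                      frame_rate_hz=float(meta["frame_rate_hz"]))


def write_traces(traces: ProbabilityTracePair, path: str | Path) -> None:
    """CSV with columns frame, p_f, p_h; frame rate in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={traces.frame_rate_hz!r}\n")
        fh.write("frame,p_f,p_h\n")
        for i, (f, h) in enumerate(zip(traces.p_f, traces.p_h)):
            fh.write(f"{i},{float(f)!r},{float(h)!r}\n")


def read_traces(path: str | Path) -> ProbabilityTracePair:
    path = Path(path)
    frame_rate = 60.0
    p_f: list[float] = []
    p_h: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "frame_rate_hz=" in line:
                    frame_rate = float(line.split("=", 1)[1])
                continue
            if line.startswith("frame,"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, "
                                  f"got {len(parts)}")
            try:
                f, h = float(parts[1]), float(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            for name, v in (("p_f", f), ("p_h", h)):
                if not (0.0 <= v <= 1.0):
                    raise FormatError(
                        f"{path}:{lineno}: {name}={v!r} outside [0, 1]")
            p_f.append(f)
            p_h.append(h)
    return ProbabilityTracePair(p_f=np.array(p_f), p_h=np.array(p_h),
                                frame_rate_hz=frame_rate)


def write_ethogram(labels: np.ndarray, path: str | Path) -> None:
    """CSV with columns frame, label over the 7-category alphabet."""
    path = Path(path)
    bad = set(np.unique(labels)) - set(ETHOGRAM_LABELS)
    if bad:
        raise ValueError(f"labels outside the ethogram alphabet: {sorted(bad)}")
    with open(path, "w") as fh:
        fh.write("frame,label\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i},{lab}\n")


def read_ethogram(path: str | Path) -> np.ndarray:
    path = Path(path)
    labels: list[str] = []
    allowed = set(ETHOGRAM_LABELS)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("frame,"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, "
                                  f"got {len(parts)}")
            if parts[1] not in allowed:
                raise FormatError(
                    f"{path}:{lineno}: label {parts[1]!r} not in the "
                    f"7-category alphabet {ETHOGRAM_LABELS}")
            labels.append(parts[1])
    return np.array(labels, dtype="<U16")


def write_cycles(cycles: CycleSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# max_duration_frames={cycles.max_duration_frames}"
                 f" frame_rate_hz={cycles.frame_rate_hz!r}\n")
        fh.write("kind,start_frame,end_frame,length_frames,freq_hz\n")
        for c in cycles.cycles:
            fh.write(f"{c.kind},{c.start_frame},{c.end_frame},"
                     f"{c.length_frames},{float(c.frequency_hz)!r}\n")


def read_cycles(path: str | Path) -> CycleSet:
    path = Path(path)
    max_dur = 280
    frame_rate = 60.0
    out: list[Cycle] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("kind,"):
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    k, _, v = tok.partition("=")
                    if k == "max_duration_frames":
                        max_dur = int(v)
                    elif k == "frame_rate_hz":
                        frame_rate = float(v)
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields, "
                                  f"got {len(parts)}")
            if parts[0] not in ("ff", "hh"):
                raise FormatError(f"{path}:{lineno}: cycle kind {parts[0]!r} "
                                  "must be 'ff' or 'hh'")
            try:
                start, end, length = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            out.append(Cycle(kind=parts[0], start_frame=start, end_frame=end,
                             length_frames=length,
                             length_s=length / frame_rate,
                             frequency_hz=float(parts[4])))
    return CycleSet(cycles=out, max_duration_frames=max_dur,
                    frame_rate_hz=frame_rate)


def write_summary(summary: FlySummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(summary), indent=1,
                                     sort_keys=True) + "\n")


def read_summary(path: str | Path) -> FlySummary:
    return FlySummary(**json.loads(Path(path).read_text()))
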