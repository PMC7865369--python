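"""Frame sequences: the in-memory video container and PNG-directory I/O.

A recording is an ordered stack of frames with a known frame rate and
channel layout.  On disk a sequence is a directory of zero-padded numbered
PNG files plus a ``meta.json`` sidecar recording fps and channel layout,
which keeps everything plain-text-adjacent and tool-inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np


class FrameReadError(RuntimeError):
    """A frame file could not be decoded; carries the frame index."""

    def __init__(self, index: int, path: Path, cause: Exception):
        super().__init__(f"frame {index} unreadable at {path}: {cause}")
        self.index = index
        self.path = path


@dataclass
class FrameSequence:
    """Ordered image stack with frame rate and channel layout.

    ``data`` is ``(T, H, W)`` for monochrome-green recordings or
    ``(T, H, W, 3)`` for RGB; dtype uint8 for recorded/synthetic video,
    float for intermediate processing.
    """

    data: np.ndarray
    fps: float
    channel_layout: str = "green"   # "green" (monochrome) or "rgb"

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("frame data must be (T, H, W) or (T, H, W, 3)")
        if self.channel_layout not in ("green", "rgb"):
            raise ValueError(f"unknown channel layout {self.channel_layout!r}")
        if self.channel_layout == "rgb" and (self.data.ndim != 4 or self.data.shape[-1] != 3):
            raise ValueError("rgb layout requires (T, H, W, 3) data")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        """(width, height)."""
        return self.data.shape[2], self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def green(self) -> np.ndarray:
        """The green-channel stack ``(T, H, W)``."""
        if self.channel_layout == "green":
            return self.data
        return self.data[..., 1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def write(self, directory: str | Path) -> Path:
        """Write frames as zero-padded PNGs plus a ``meta.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = max(6, len(str(self.n_frames)))
        arr = self.data
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        for i in range(self.n_frames):
            iio.imwrite(directory / f"frame_{i:0{width}d}.png", arr[i])
        meta = {"fps": self.fps, "n_frames": self.n_frames,
                "frame_size": list(self.frame_size),
                "channel_layout": self.channel_layout}
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def read(cls, directory: str | Path, fps: float | None = None) -> "FrameSequence":
        """Read a PNG frame directory; fps comes from ``meta.json`` unless given."""
        directory = Path(directory)
        meta_path = directory / "meta.json"
        layout = "green"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            fps = fps if fps is not None else meta["fps"]
            layout = meta.get("channel_layout", "green")
        if fps is None:
            raise ValueError("fps not given and no meta.json sidecar found")
        paths = sorted(directory.glob("frame_*.png"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.png files under {directory}")
        frames = []
        for i, p in enumerate(paths):
            try:
                frames.append(iio.imread(p))
            except Exception as exc:  # decoding failure names the frame
                raise FrameReadError(i, p, exc) from exc
        data = np.stack(frames)
        if data.ndim == 4 and data.shape[-1] == 3:
            layout = "rgb"
        return cls(data=data, fps=float(fps), channel_layout=layout)
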