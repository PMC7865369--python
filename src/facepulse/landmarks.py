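"""Facial landmark sets and the detector adapter surface.

A :class:`LandmarkSet` is 81 named 2-D points in pixel coordinates plus the
frame size they refer to.  Landmark detection itself is deliberately out of
scope: points come either from the shipped canonical template
(:func:`generate_landmark_template`), from a JSON file written by any
detector (:func:`load_landmarks`), or from a callable adapter that maps a
first frame to an ``(81, 2)`` array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

N_LANDMARKS = 81

LandmarkDetector = Callable[[np.ndarray], np.ndarray]
"""Adapter type: first video frame -> (81, 2) array of (x, y) pixel points."""


class LandmarkError(ValueError):
    """Raised for malformed or out-of-bounds landmark sets."""


def _load_mesh_data() -> dict:
    with resources.files("facepulse.data").joinpath("face_mesh.json").open() as fh:
        return json.load(fh)


_MESH_CACHE: dict | None = None


def mesh_data() -> dict:
    """The frozen canonical mesh (points, connectivity, pairing tables)."""
    global _MESH_CACHE
    if _MESH_CACHE is None:
        _MESH_CACHE = _load_mesh_data()
    return _MESH_CACHE


@dataclass(frozen=True)
class LandmarkSet:
    """81 facial landmarks in pixel coordinates.

    Parameters
    ----------
    points
        ``(81, 2)`` float array of (x, y), x rightward, y downward, 0-based
        pixel-centre convention.
    frame_size
        ``(width, height)`` of the frame the points refer to, or ``None``
        when the landmarks are not yet bound to a frame.
    """

    points: np.ndarray
    frame_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkError(
                f"expected {N_LANDMARKS} landmarks of (x, y), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise LandmarkError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.frame_size is not None:
            w, h = self.frame_size
            out = np.flatnonzero((pts[:, 0] < 0) | (pts[:, 0] > w - 1)
                                 | (pts[:, 1] < 0) | (pts[:, 1] > h - 1))
            if out.size:
                raise LandmarkError(
                    f"landmarks outside {w}x{h} frame bounds: indices {out.tolist()}")

    @property
    def mirror_permutation(self) -> np.ndarray:
        """Self-inverse permutation pairing left and right landmarks."""
        return np.asarray(mesh_data()["landmark_mirror"], dtype=int)

    def mirrored(self) -> "LandmarkSet":
        """The set reflected about the vertical axis through the face centre."""
        pts = self.points.copy()
        cx = (pts[:, 0].min() + pts[:, 0].max()) / 2.0
        pts[:, 0] = 2 * cx - pts[:, 0]
        return LandmarkSet(pts, self.frame_size)

    def save(self, path: str | Path) -> None:
        payload = {"points": self.points.tolist(),
                   "frame_size": list(self.frame_size) if self.frame_size else None}
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_landmark_template(scale: float = 1.0,
                               offset: tuple[float, float] = (0.0, 0.0),
                               frame_size: tuple[int, int] | None = None) -> LandmarkSet:
    """Instantiate the canonical 81-point template at a given scale/position.

    ``scale`` is approximately the face height in pixels; ``offset`` places
    the face centre.  Deterministic for fixed arguments.  If ``frame_size``
    is given, points falling outside the frame raise :class:`LandmarkError`
    naming the offending indices.
    """
    if scale <= 0:
        raise LandmarkError("scale must be positive")
    canon = np.asarray(mesh_data()["points"], dtype=float)
    pts = canon * scale + np.asarray(offset, dtype=float)
    return LandmarkSet(pts, frame_size)


def load_landmarks(path: str | Path,
                   frame_size: tuple[int, int] | None = None) -> LandmarkSet:
    """Read a landmark set from a JSON file (list of 81 [x, y] pairs or
    the dict written by :meth:`LandmarkSet.save`)."""
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        pts = payload["points"]
        fs = payload.get("frame_size")
        if frame_size is None and fs is not None:
            frame_size = tuple(fs)  # type: ignore[assignment]
    else:
        pts = payload
    return LandmarkSet(np.asarray(pts, dtype=float), frame_size)


def detect_landmarks(first_frame: np.ndarray,
                     detector: LandmarkDetector,
                     frame_size: tuple[int, int] | None = None) -> LandmarkSet:
    """Run a pluggable detector adapter on the first frame."""
    pts = np.asarray(detector(first_frame), dtype=float)
    if frame_size is None:
        h, w = first_frame.shape[:2]
        frame_size = (w, h)
    return LandmarkSet(pts, frame_size)
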