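"""Facial region geometry: 98 triangular regions, centroid sampling
rectangles, the reusable first-frame ROI mask, quality ranking, and the
meta-region/area grouping.

The face is partitioned into 98 non-overlapping triangles whose vertices
are landmarks; a fixed-size square ROI (80 px by default, matching typical
full-resolution recordings) is centred on each triangle centroid and the
regional pulse signal is the spatial mean over that rectangle.  The mask is
built once from the first frame's geometry and reused for every following
frame, which assumes a statically positioned face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkSet, mesh_data

N_REGIONS = 98


class RegionError(ValueError):
    """Raised for degenerate or inconsistent region geometry."""


@dataclass(frozen=True)
class TriangleRegion:
    """One triangular facial region."""

    region_id: int
    vertex_ids: tuple[int, int, int]
    vertices: np.ndarray      # (3, 2) pixel coordinates
    centroid: tuple[float, float]

    @property
    def area(self) -> float:
        (ax, ay), (bx, by), (cx, cy) = self.vertices
        return 0.5 * abs((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))


@dataclass(frozen=True)
class RectROI:
    """Square sampling rectangle centred on a region centroid."""

    region_id: int
    x: int              # top-left, inclusive
    y: int
    width: int
    height: int
    clipped: bool = False   # True when the rect exceeds the frame bounds

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


def build_triangulation(landmarks: LandmarkSet) -> list[TriangleRegion]:
    """The 98 triangular regions defined by the shipped connectivity table.

    Region ids follow the canonical numbering (0-97, top of the face to the
    chin, left to right within each row strip).  Raises
    :class:`RegionError` if any triangle degenerates (collinear landmarks).
    """
    tris = mesh_data()["triangles"]
    pts = landmarks.points
    regions = []
    for rid, vids in enumerate(tris):
        verts = pts[list(vids)]
        region = TriangleRegion(
            region_id=rid,
            vertex_ids=tuple(int(v) for v in vids),
            vertices=verts,
            centroid=tuple(verts.mean(axis=0)),
        )
        if region.area <= 0:
            raise RegionError(f"region {rid} is degenerate (collinear landmarks {vids})")
        regions.append(region)
    return regions


def region_mirror_table() -> np.ndarray:
    """Permutation mapping each region id to its left/right mirror partner."""
    return np.asarray(mesh_data()["region_mirror"], dtype=int)


def build_roi_rects(regions: list[TriangleRegion], size: int = 80,
                    frame_size: tuple[int, int] | None = None) -> list[RectROI]:
    """One square ROI per region, centred on the centroid.

    Top-left = round(centroid) - size // 2.  Rectangles extending past the
    frame are flagged ``clipped`` (and later excluded from quality ranking)
    rather than silently shrunk.
    """
    if size <= 0:
        raise RegionError("ROI size must be positive")
    rects = []
    for region in regions:
        cx, cy = region.centroid
        x = int(round(cx)) - size // 2
        y = int(round(cy)) - size // 2
        clipped = False
        if frame_size is not None:
            w, h = frame_size
            clipped = x < 0 or y < 0 or x + size > w or y + size > h
        rects.append(RectROI(region.region_id, x, y, size, size, clipped))
    return rects


@dataclass
class ROIMask:
    """First-frame ROI mask: pixel membership for every region rectangle.

    Overlapping rectangles are supported — a pixel may belong to several
    regions and each region's spatial mean is always taken over its full
    rectangle.  The mask is geometry-only, so applying it to any frame of a
    static-face recording is equivalent to recomputing the rectangles.
    """

    frame_size: tuple[int, int]
    rects: list[RectROI] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.rects:
            raise RegionError("cannot build a ROI mask from an empty rect list")

    def labels_image(self) -> np.ndarray:
        """Label count image (how many regions claim each pixel); mainly
        for visualisation and overlap diagnostics."""
        w, h = self.frame_size
        img = np.zeros((h, w), dtype=np.int16)
        for r in self.rects:
            ys, xs = r.slices
            img[max(ys.start, 0):ys.stop, max(xs.start, 0):xs.stop] += 1
        return img

    def region_pixels(self, region_id: int) -> tuple[slice, slice]:
        for r in self.rects:
            if r.region_id == region_id:
                return r.slices
        raise KeyError(region_id)

    def extract_means(self, frame: np.ndarray) -> dict[int, float]:
        """Spatial mean of each region rectangle on one (green) frame."""
        out = {}
        for r in self.rects:
            ys, xs = r.slices
            patch = frame[ys, xs]
            if patch.size == 0:
                raise RegionError(f"region {r.region_id} rectangle is empty")
            out[r.region_id] = float(patch.mean(dtype=np.float64))
        return out


def build_roi_mask(rects: list[RectROI], frame_size: tuple[int, int]) -> ROIMask:
    """Bundle the first frame's rectangles into a reusable mask."""
    return ROIMask(frame_size=frame_size, rects=list(rects))


def select_top_regions(quality: dict[int, float], n: int = 50) -> list[int]:
    """Region ids sorted by quality score, best first, truncated to ``n``.

    Ties break toward the lower region id.  Non-finite scores are rejected.
    """
    for rid, q in quality.items():
        if not np.isfinite(q):
            raise RegionError(f"non-finite quality score for region {rid}")
    if n > len(quality):
        warnings.warn(f"requested top {n} of only {len(quality)} regions; truncating")
        n = len(quality)
    ranked = sorted(quality, key=lambda rid: (-quality[rid], rid))
    return ranked[:n]


@dataclass(frozen=True)
class MetaRegionTable:
    """The symmetric meta-regions retained for inter-region statistics.

    38 meta-regions (19 left/right pairs) grouped into 6 anatomical areas
    per face side, plus the mid-forehead reference region.
    """

    pairs_by_area: dict[str, list[tuple[int, int]]]
    reference_region: int

    @classmethod
    def canonical(cls) -> "MetaRegionTable":
        data = mesh_data()
        pairs = {area: [tuple(p) for p in plist]
                 for area, plist in data["meta_regions"].items()}
        return cls(pairs_by_area=pairs, reference_region=int(data["reference_region"]))

    @property
    def areas(self) -> list[str]:
        return list(self.pairs_by_area)

    def meta_region_ids(self) -> list[int]:
        ids = [rid for pairs in self.pairs_by_area.values() for p in pairs for rid in p]
        return sorted(ids)

    def side_ids(self, side: str) -> dict[str, list[int]]:
        """Area -> region ids for one face side ('left' or 'right')."""
        k = {"left": 0, "right": 1}[side]
        return {area: [p[k] for p in pairs] for area, pairs in self.pairs_by_area.items()}

    def area_of(self, region_id: int) -> tuple[str, str]:
        """(area, side) for a meta-region id."""
        for area, pairs in self.pairs_by_area.items():
            for left, right in pairs:
                if region_id == left:
                    return area, "left"
                if region_id == right:
                    return area, "right"
        raise KeyError(region_id)
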