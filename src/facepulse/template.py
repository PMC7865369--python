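"""Canonical facial landmark template and triangular region connectivity.

The package ships a hand-authored, frontal, bilaterally symmetric face
template with 81 landmarks.  61 of them form a seven-row structural mesh
(hairline, mid-forehead, brow, eye line, cheek line, mouth line, chin) that
is triangulated into 98 non-overlapping triangular regions covering the
face; the remaining 20 landmarks mark eye and mouth detail and sit strictly
inside mesh triangles.  The template stands in for the output of a facial
landmark detector: any detector producing 81 points in this indexing can be
plugged in through :mod:`facepulse.landmarks`.

The frozen connectivity (triangles, mirror pairing tables, meta-region
grouping) lives in ``facepulse/data/face_mesh.json``; this module is the
generator that produced it and is kept so the template can be regenerated
or re-derived after editing the row layout.

Coordinate convention: x rightward, y downward, origin at the face centre;
the canonical face spans roughly x in [-0.72, 0.72] and y in [-0.5, 0.5],
so ``scale`` is approximately the face height in pixels.
"""

from __future__ import annotations

import numpy as np

# Row layout of the structural mesh: point count, centre y, half extent in x,
# and bow of the row arc (y(x) = y_c + curv * (x / halfx)^2; positive bows the
# row upward at the centre in image coordinates).
ROW_COUNTS = [7, 9, 7, 11, 11, 11, 5]
ROW_Y = [0.04, 0.17, 0.30, 0.44, 0.62, 0.80, 0.96]
ROW_HALFX = [0.52, 0.62, 0.68, 0.72, 0.70, 0.58, 0.34]
ROW_CURV = [0.10, 0.06, 0.04, 0.02, 0.00, -0.02, -0.06]

# vertical shift that centres the canonical face on y = 0
_Y_CENTER = 0.52

N_MESH_POINTS = sum(ROW_COUNTS)  # 61
N_LANDMARKS = 81
N_REGIONS = 98

# anchor points used to pick the triangles that host eye / mouth detail
_LEFT_EYE_CENTER = (-0.35, 0.40)
_LEFT_MOUTH_CENTER = (-0.15, 0.80)
_N_EYE_POINTS = 6   # per eye
_N_MOUTH_POINTS = 8  # total, 4 per side


def _build_rows() -> list[np.ndarray]:
    rows = []
    for n, yc, hx, c in zip(ROW_COUNTS, ROW_Y, ROW_HALFX, ROW_CURV):
        x = np.linspace(-hx, hx, n)
        y = yc + c * (x / hx) ** 2
        rows.append(np.column_stack([x, y]))
    return rows


def _strip_triangles(pts: np.ndarray, i0_top: int, n_top: int,
                     i0_bot: int, n_bot: int) -> list[tuple[int, int, int]]:
    """Mirror-symmetric triangulation of the strip between two odd-count rows.

    The right half is swept centre-outward with a two-pointer walk that always
    advances along the shorter new diagonal; the left half is its mirror
    image, so the strip triangulation maps onto itself under x -> -x.
    """
    ct, cb = (n_top - 1) // 2, (n_bot - 1) // 2
    tris_right: list[tuple[int, int, int]] = []
    it = ib = 0
    nt, nb = n_top - 1 - ct, n_bot - 1 - cb
    while it < nt or ib < nb:
        adv_top = it < nt
        if it < nt and ib < nb:
            d_top = np.linalg.norm(pts[i0_top + ct + it + 1] - pts[i0_bot + cb + ib])
            d_bot = np.linalg.norm(pts[i0_bot + cb + ib + 1] - pts[i0_top + ct + it])
            adv_top = d_top <= d_bot
        if adv_top:
            tris_right.append((i0_top + ct + it, i0_bot + cb + ib, i0_top + ct + it + 1))
            it += 1
        else:
            tris_right.append((i0_top + ct + it, i0_bot + cb + ib, i0_bot + cb + ib + 1))
            ib += 1

    def _mirror(idx: int) -> int:
        if idx >= i0_bot:
            return i0_bot + 2 * cb - (idx - i0_bot)
        return i0_top + 2 * ct - (idx - i0_top)

    tris_left = [tuple(_mirror(v) for v in tri) for tri in tris_right]
    return tris_left + tris_right  # type: ignore[return-value]


def _mesh_points_and_triangles() -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    rows = _build_rows()
    pts = np.vstack(rows)
    offsets = np.cumsum([0] + ROW_COUNTS)
    tris: list[tuple[int, int, int]] = []
    for k in range(len(rows) - 1):
        strip = _strip_triangles(pts, offsets[k], ROW_COUNTS[k],
                                 offsets[k + 1], ROW_COUNTS[k + 1])
        cx = [pts[list(t)].mean(axis=0)[0] for t in strip]
        order = np.argsort(cx, kind="stable")
        tris.extend(strip[i] for i in order)
    return pts, tris


def _mesh_mirror_permutation() -> np.ndarray:
    """Landmark index permutation realised by x -> -x on the mesh rows."""
    perm = np.empty(N_MESH_POINTS, dtype=int)
    start = 0
    for n in ROW_COUNTS:
        for i in range(n):
            perm[start + i] = start + (n - 1 - i)
        start += n
    return perm


def _pick_feature_triangles(pts: np.ndarray, tris: list[tuple[int, int, int]],
                            centroids: np.ndarray) -> tuple[list[int], list[int]]:
    """Triangle ids hosting the left-eye ring and the left half of the mouth."""
    left = centroids[:, 0] < 0
    d_eye = np.hypot(centroids[:, 0] - _LEFT_EYE_CENTER[0],
                     centroids[:, 1] - _LEFT_EYE_CENTER[1])
    d_eye[~left] = np.inf
    eye_ids = sorted(np.argsort(d_eye, kind="stable")[:_N_EYE_POINTS].tolist())
    d_mouth = np.hypot(centroids[:, 0] - _LEFT_MOUTH_CENTER[0],
                       centroids[:, 1] - _LEFT_MOUTH_CENTER[1])
    d_mouth[~left] = np.inf
    d_mouth[eye_ids] = np.inf
    mouth_ids = sorted(np.argsort(d_mouth, kind="stable")[:_N_MOUTH_POINTS // 2].tolist())
    return eye_ids, mouth_ids


# Meta-region grouping: 19 mirror pairs (left id, right id) of triangular
# regions, grouped into 6 anatomical areas per face side.  Region 20 (the
# left-of-midline triangle between the mid-forehead and brow rows) is the
# mid-forehead reference and belongs to no area.
META_AREA_PAIRS: dict[str, list[tuple[int, int]]] = {
    "forehead": [(6, 7), (5, 8), (4, 9), (19, 22)],
    "nose_bridge": [(35, 36), (53, 54)],
    "mid_cheek": [(45, 62), (46, 61), (47, 60), (48, 59)],
    "nasolabial_fold": [(67, 80), (68, 79), (69, 78)],
    "upper_perioral": [(71, 76), (72, 75), (73, 74)],
    "chin": [(90, 91), (89, 92), (88, 93)],
}

REFERENCE_REGION = 20


def build_canonical_mesh() -> dict:
    """Build the full canonical template as a plain serialisable dict.

    Returns a dict with keys ``points`` (81 x 2, canonical coordinates),
    ``triangles`` (98 x 3 landmark indices), ``landmark_mirror`` (length-81
    self-inverse permutation for x -> -x), ``region_mirror`` (length-98
    permutation), ``meta_regions`` (area -> list of [left, right] region-id
    pairs) and ``reference_region``.
    """
    mesh_pts, tris = _mesh_points_and_triangles()
    centroids = np.array([mesh_pts[list(t)].mean(axis=0) for t in tris])

    eye_tris, mouth_tris = _pick_feature_triangles(mesh_pts, tris, centroids)
    left_eye = centroids[eye_tris]
    right_eye = left_eye * [-1, 1]
    left_mouth = centroids[mouth_tris]
    right_mouth = left_mouth * [-1, 1]
    points = np.vstack([mesh_pts, left_eye, right_eye, left_mouth, right_mouth])
    points[:, 1] -= _Y_CENTER
    assert points.shape == (N_LANDMARKS, 2)

    # landmark mirror permutation: mesh rows reverse in place, eye block k
    # swaps with eye block k + 6, mouth halves swap
    lm_mirror = np.empty(N_LANDMARKS, dtype=int)
    lm_mirror[:N_MESH_POINTS] = _mesh_mirror_permutation()
    e0 = N_MESH_POINTS
    for k in range(_N_EYE_POINTS):
        lm_mirror[e0 + k] = e0 + _N_EYE_POINTS + k
        lm_mirror[e0 + _N_EYE_POINTS + k] = e0 + k
    m0 = e0 + 2 * _N_EYE_POINTS
    half = _N_MOUTH_POINTS // 2
    for k in range(half):
        lm_mirror[m0 + k] = m0 + half + k
        lm_mirror[m0 + half + k] = m0 + k

    # region mirror permutation via mirrored vertex sets
    tri_index = {frozenset(t): i for i, t in enumerate(tris)}
    region_mirror = np.empty(N_REGIONS, dtype=int)
    for i, t in enumerate(tris):
        mt = frozenset(int(lm_mirror[v]) for v in t)
        region_mirror[i] = tri_index[mt]

    return {
        "points": points.tolist(),
        "triangles": [list(map(int, t)) for t in tris],
        "landmark_mirror": lm_mirror.tolist(),
        "region_mirror": region_mirror.tolist(),
        "meta_regions": {area: [list(p) for p in pairs]
                         for area, pairs in META_AREA_PAIRS.items()},
        "reference_region": REFERENCE_REGION,
    }
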