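"""From raw per-timepoint tiles to registered binary vessel masks.

Three steps produce the binary vessel shapes everything downstream runs
on: (1) *stitching* — overlapping tiles of one sprouting region are
mosaicked using scale/rotation-invariant keypoint matches with
outlier-robust transform estimation; (2) *registration* — the trapezoidal
posts caging the gel are detected (Hough transform on their edges) and
used as landmarks to estimate the similarity transform (scale, rotation,
translation) aligning every frame to a reference frame; (3) *vessel
segmentation* — the gel region is isolated (above the cell-gel interface,
which is fit with an outlier-robust parabola, and outside the posts), a
global Otsu threshold binarizes it, and morphological closing, erosion
and area opening clean the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure, morphology, transform
from skimage.filters import threshold_otsu

# intensity below which pixels are considered post silhouette
POST_INTENSITY_CUTOFF = 60.0


@dataclass
class StitchResult:
    mosaic: np.ndarray
    offsets: list[tuple[float, float]]   # (dx, dy) of each tile in mosaic coords

    def __array__(self, dtype=None, copy=None):
        a = np.asarray(self.mosaic)
        return a.astype(dtype) if dtype is not None else a


@dataclass
class PostModel:
    """Detected registration posts: Hough-normal edge lines and polygons."""

    edge_lines: list[tuple[float, float]]        # (rho px, theta rad), theta in [0, pi)
    polygons: list[np.ndarray]                   # (k, 2) arrays of (x, y) vertices
    centroids: np.ndarray                        # (n, 2) array of (x, y)


@dataclass
class GelRegion:
    """Gel region: above the parabolic cell-gel interface, outside posts."""

    parabola: tuple[float, float, float]         # y = a x^2 + b x + c
    post_polygons: list[np.ndarray] = field(default_factory=list)

    def interface_y(self, x) -> np.ndarray:
        a, b, c = self.parabola
        x = np.asarray(x, dtype=float)
        return a * x**2 + b * x + c

    def mask(self, shape: tuple[int, int], interface_margin: float = 0.0) -> np.ndarray:
        """Boolean gel mask; ``interface_margin`` retracts the gel that many
        px above the fitted interface (guards against the 1-2 px raggedness
        of the real interface around the fit)."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        m = yy < self.interface_y(xx) - interface_margin
        for poly in self.post_polygons:
            rr, cc = _polygon_pixels(poly, (h, w))
            m[rr, cc] = False
        return m


def _polygon_pixels(poly_xy: np.ndarray, shape):
    from skimage.draw import polygon as _poly

    return _poly(poly_xy[:, 1], poly_xy[:, 0], shape=shape)


# ---------------------------------------------------------------------------
# stitching

def _pairwise_transform(tile_a: np.ndarray, tile_b: np.ndarray, min_inliers: int = 8):
    """Similarity transform mapping tile_b coordinates into tile_a's frame,
    from ratio-tested keypoint matches + RANSAC."""
    sift = feature.SIFT()
    try:
        sift.detect_and_extract(tile_a.astype(float))
        ka, da = sift.keypoints, sift.descriptors
        sift.detect_and_extract(tile_b.astype(float))
        kb, db = sift.keypoints, sift.descriptors
    except RuntimeError as e:
        raise ValueError(f"keypoint detection failed: {e}") from e
    matches = feature.match_descriptors(da, db, cross_check=True, max_ratio=0.8)
    if len(matches) < min_inliers:
        raise ValueError(f"only {len(matches)} keypoint matches between tiles; need >= {min_inliers}")
    src = kb[matches[:, 1]][:, ::-1]   # (x, y)
    dst = ka[matches[:, 0]][:, ::-1]
    model, inliers = measure.ransac(
        (src, dst),
        transform.SimilarityTransform,
        min_samples=3,
        residual_threshold=1.0,
        max_trials=500,
        rng=0,
    )
    n_in = int(inliers.sum()) if inliers is not None else 0
    if model is None or n_in < min_inliers:
        raise ValueError(f"only {n_in} inlier matches between tiles; need >= {min_inliers}")
    return model


def stitch_tiles(tiles) -> StitchResult:
    """Mosaic overlapping tiles; overlap regions are averaged.

    Accepts a plain list of images or a :class:`~sprouttrack.phantoms.TileSet`.
    A single tile is returned unchanged.  Raises ``ValueError`` with a
    diagnostic when a tile pair has too few reliable matches.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no tiles")
    if len(tiles) == 1:
        return StitchResult(mosaic=tiles[0].copy(), offsets=[(0.0, 0.0)])

    # chain transforms to tile 0
    to_ref = [transform.SimilarityTransform()]
    for a, b in zip(tiles, tiles[1:]):
        t = _pairwise_transform(a, b)
        to_ref.append(transform.SimilarityTransform(matrix=to_ref[-1].params @ t.params))

    corners = []
    for img, t in zip(tiles, to_ref):
        h, w = img.shape
        c = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        corners.append(t(c))
    allc = np.vstack(corners)
    x0, y0 = np.floor(allc.min(axis=0))
    x1, y1 = np.ceil(allc.max(axis=0))
    out_w, out_h = int(x1 - x0), int(y1 - y0)
    shift = transform.SimilarityTransform(translation=(-x0, -y0))

    acc = np.zeros((out_h, out_w))
    wgt = np.zeros((out_h, out_w))
    offsets = []
    for img, t in zip(tiles, to_ref):
        full = transform.SimilarityTransform(matrix=shift.params @ t.params)
        warped = transform.warp(img.astype(float), full.inverse, output_shape=(out_h, out_w),
                                order=1, cval=np.nan, preserve_range=True)
        valid = ~np.isnan(warped)
        acc[valid] += warped[valid]
        wgt[valid] += 1
        offsets.append((float(full.translation[0]), float(full.translation[1])))
    with np.errstate(invalid="ignore"):
        mosaic = np.where(wgt > 0, acc / np.maximum(wgt, 1), 0.0)
    return StitchResult(mosaic=mosaic, offsets=offsets)


# ---------------------------------------------------------------------------
# post detection and registration

def detect_posts(image: np.ndarray, intensity_cutoff: float = POST_INTENSITY_CUTOFF,
                 min_area: int = 40, max_area: int = 4000) -> PostModel:
    """Find the trapezoidal posts near the left/right gel boundaries.

    Posts are the darkest structures in the image; compact connected
    components near the lateral borders are taken and each component's
    edges are represented by Hough-transform lines.  Raises ``ValueError``
    when no post is found on both boundaries.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    dark = img < intensity_cutoff
    lab, n = ndimage.label(dark)
    lines: list[tuple[float, float]] = []
    polygons: list[np.ndarray] = []
    centroids: list[tuple[float, float]] = []
    sides = set()
    for region in measure.regionprops(lab):
        if not (min_area <= region.area <= max_area):
            continue
        minr, minc, maxr, maxc = region.bbox
        if (maxr - minr) > 0.3 * h:     # too tall for a post (e.g. a border band)
            continue
        if minr <= 0 or minc <= 0 or maxr >= h or maxc >= w:
            continue                    # clipped at the border: centroid unreliable
        near_left = minc <= 0.2 * w
        near_right = maxc >= 0.8 * w
        if not (near_left or near_right):
            continue
        sides.add("L" if near_left else "R")
        comp = lab[minr:maxr, minc:maxc] == region.label
        edges = comp ^ ndimage.binary_erosion(comp)
        hspace, angles, dists = transform.hough_line(edges)
        peaks = transform.hough_line_peaks(hspace, angles, dists, num_peaks=4)
        for _, theta, rho in zip(*peaks):
            # shift rho to full-image coordinates and normalize theta to [0, pi)
            rho_full = rho + minc * np.cos(theta) + minr * np.sin(theta)
            t = float(theta)
            if t < 0:
                t += np.pi
                rho_full = -rho_full
            lines.append((float(rho_full), t))
        contour = measure.find_contours(np.pad(comp, 1).astype(float), 0.5)
        if contour:
            c = contour[0] - 1.0
            poly = np.column_stack([c[:, 1] + minc, c[:, 0] + minr])
            polygons.append(poly[:: max(1, len(poly) // 12)])
        cy, cx = region.centroid
        centroids.append((cx, cy))
    if len(centroids) < 2 or len(sides) < 2:
        raise ValueError("posts not found on both gel boundaries")
    order = np.lexsort(np.array(centroids).T[::-1])
    return PostModel(
        edge_lines=lines,
        polygons=[polygons[i] for i in order if i < len(polygons)],
        centroids=np.array(centroids)[order],
    )


def register_to_reference(
    image: np.ndarray, reference: np.ndarray, max_match_dist: float = 60.0
) -> tuple[transform.SimilarityTransform, np.ndarray]:
    """Similarity transform aligning ``image`` onto ``reference`` using the
    posts as correspondences; returns (transform, resampled image).

    The transform maps image coordinates into reference coordinates.
    Raises ``ValueError`` with fewer than two corresponding posts.
    """
    posts_img = detect_posts(image)
    posts_ref = detect_posts(reference)

    def _match(offset):
        src, dst, used = [], [], set()
        for cx, cy in posts_img.centroids:
            p = np.array([cx, cy]) + offset
            d = np.linalg.norm(posts_ref.centroids - p, axis=1)
            j = int(np.argmin(d))
            if d[j] <= max_match_dist and j not in used:
                used.add(j)
                src.append((cx, cy))
                dst.append(tuple(posts_ref.centroids[j]))
        return np.array(src), np.array(dst)

    src, dst = _match(np.zeros(2))
    if len(src) >= 2:       # re-match after removing the bulk translation
        src, dst = _match(np.median(dst - src, axis=0))
    if len(src) < 2:
        raise ValueError(f"only {len(src)} corresponding posts; need >= 2")
    tf = transform.SimilarityTransform.from_estimate(src, dst)
    if not tf:
        raise ValueError("similarity estimation failed")
    # drop correspondences a clipped/merged detection has biased, refit
    if len(src) > 2:
        res = np.linalg.norm(tf(src) - dst, axis=1)
        keep = res <= max(2.0, 3.0 * np.median(res))
        if 2 <= keep.sum() < len(src):
            tf2 = transform.SimilarityTransform.from_estimate(src[keep], dst[keep])
            if tf2:
                tf = tf2
    aligned = transform.warp(
        np.asarray(image, dtype=float), tf.inverse, order=1, preserve_range=True
    )
    return tf, aligned


def decompose_about_center(tf: transform.SimilarityTransform, image_size: tuple[int, int]):
    """(dx, dy, dtheta_deg, scale) of a similarity transform expressed as
    rotation/scaling about the image center followed by translation."""
    h, w = image_size
    center = np.array([[w / 2, h / 2]])
    moved = tf(center)[0] - center[0]
    return (
        float(moved[0]),
        float(moved[1]),
        float(np.rad2deg(tf.rotation)),
        float(tf.scale),
    )


# ---------------------------------------------------------------------------
# gel region and segmentation

def fit_cell_gel_interface(
    image: np.ndarray,
    monolayer_band: int = 100,
    posts: PostModel | None = None,
    n_clip: int = 3,
) -> GelRegion:
    """Parabola fit to the cell-gel interface along the bottom of the image.

    Edge points are the tops of the bottom-anchored bright band in each
    column (by Otsu within the band); the fit is least squares with
    iterative outlier clipping (columns where a vessel meets the monolayer
    pull the edge upward and are rejected).  With fewer than 5 edge points
    a horizontal line at the band top is used, with a warning.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    band = img[h - monolayer_band:, :]
    try:
        thr = threshold_otsu(band)
    except ValueError:
        thr = band.mean()
    fg = band > thr
    xs, ys = [], []
    for c in range(w):
        col = fg[:, c]
        if not col[-1]:
            continue
        # top of the contiguous run touching the bottom
        run_top = len(col) - 1
        while run_top > 0 and col[run_top - 1]:
            run_top -= 1
        ys.append(h - monolayer_band + run_top)
        xs.append(c)
    xs, ys = np.array(xs, dtype=float), np.array(ys, dtype=float)
    if len(xs) < 5:
        warnings.warn("too few interface edge points; horizontal fallback", stacklevel=2)
        return GelRegion(parabola=(0.0, 0.0, float(h - monolayer_band)),
                         post_polygons=posts.polygons if posts else [])
    keep = np.ones(len(xs), dtype=bool)
    coef = np.polyfit(xs, ys, 2)
    for _ in range(n_clip):
        res = ys - np.polyval(coef, xs)
        s = res[keep].std()
        if s == 0:
            break
        keep = np.abs(res) < 2.5 * s
        if keep.sum() < 5:
            break
        coef = np.polyfit(xs[keep], ys[keep], 2)
    return GelRegion(parabola=(float(coef[0]), float(coef[1]), float(coef[2])),
                     post_polygons=posts.polygons if posts else [])


def segment_vessels(
    image: np.ndarray,
    gel: GelRegion,
    min_object_area: int = 50,
    closing_radius: int = 2,
    erosion_radius: int = 2,
    interface_margin: float = 3.0,
) -> np.ndarray:
    """Binary vessel mask of the gel region.

    Pixels outside the gel are discarded; a global Otsu threshold
    binarizes the remainder; closing fills holes in the vessel area,
    erosion shrinks residual noise, and area opening removes components
    below ``min_object_area``.  A degenerate (near-unimodal) histogram
    yields an empty mask with a warning.
    """
    img = np.asarray(image, dtype=float)
    gmask = gel.mask(img.shape, interface_margin=interface_margin)
    if not gmask.any():
        warnings.warn("empty gel region", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    # The global threshold is computed with the monolayer band included
    # (posts excluded): the cell sheet guarantees a bimodal histogram even
    # in early frames where the sprouts are still small.
    tmask = np.ones(img.shape, dtype=bool)
    for poly in gel.post_polygons:
        rr, cc = _polygon_pixels(poly, img.shape)
        tmask[rr, cc] = False
    vals = img[tmask]
    thr = threshold_otsu(vals)
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if len(lo) == 0 or len(hi) == 0 or (hi.mean() - lo.mean()) < 25:
        warnings.warn("near-unimodal histogram: Otsu threshold unreliable; empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    mask = (img > thr) & gmask
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
        mask &= gmask
    mask = ndimage.binary_fill_holes(mask)
    if erosion_radius > 0:
        mask = morphology.binary_erosion(mask, morphology.disk(erosion_radius))
    if min_object_area > 0:
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = np.concatenate([[False], sizes >= min_object_area])
            mask = keep[lab]
    return mask.astype(bool)
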