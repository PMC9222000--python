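"""Per-nucleus morphometric descriptor battery.

Given an RGB scene and an integer label mask, this module measures the
38-descriptor battery used throughout the pipeline: size (areas, perimeters,
diameters, radii, ferets, box and ellipse measures), shape (aspect,
roundness, radius ratio, box-counting fractal dimension of the boundary,
bright "holes"), intensity / optical density (per-channel and luminance gray
levels, integrated optical density), and chromatin texture (margination,
heterogeneity, clumpiness).

Conventions
-----------
* Gray levels use 0 = black on the 8-bit scale; optical density is
  ``OD = 256 - gray`` (the convention the integrated-OD arithmetic depends
  on).  Luminance is the unweighted mean of R, G and B.
* Lengths are reported in micrometres (pixel measures times
  ``pixel_size_um``), areas in square micrometres; shape descriptors are
  dimensionless and computed in pixel space.
* Boundaries are ordered 8-connected pixel chains (Moore tracing).  The raw
  chain length weights axial steps 1 and diagonal steps sqrt(2)
  (``perimeter2``); the corrected chain length (``perimeter3``) uses the
  Vossepoel-Smeulders weights 0.948 / 1.340 plus a ``pi`` closed-curve term
  for the half-pixel offset between pixel centers and the region outline,
  which removes the ~5% staircase bias of the raw chain code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

from .synth import LabeledScene

log = logging.getLogger(__name__)

#: Canonical column order of the descriptor battery (38 descriptors), plus
#: the derived mean optical density appended last.
FEATURE_COLUMNS = [
    "nuclear_area",
    "aspect",
    "area_per_box",
    "gray_mean",
    "axis_major",
    "axis_minor",
    "diameter_max",
    "diameter_min",
    "diameter_mean",
    "radius_max",
    "radius_min",
    "holes",
    "radius_ratio",
    "roundness",
    "gray_red",
    "gray_green",
    "gray_blue",
    "length",
    "width",
    "perimeter2",
    "iod",
    "perimeter_convex",
    "perimeter_ellipse",
    "perimeter_ratio",
    "fractal_dimension",
    "box_width",
    "box_height",
    "feret_min",
    "feret_mean",
    "gray_min",
    "gray_max",
    "gray_std",
    "margination",
    "heterogeneity",
    "clumpiness",
    "gray_sum",
    "perimeter3",
    "perimeter_length",
    "od_mean",
]

MIN_AREA_PX = 10
MIN_TEXTURE_AREA_PX = 30

# Chain-code step weights: raw (axial, diagonal) and the
# Vossepoel-Smeulders corrected pair.
_RAW_STEPS = (1.0, math.sqrt(2.0))
_VS_STEPS = (0.948, 1.340)

# 8-neighbourhood scanned clockwise starting north, image coordinates
# (row increases downward).
_OFFSETS = (
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
)
_OFFSET_INDEX = {off: i for i, off in enumerate(_OFFSETS)}
_EIGHT = np.ones((3, 3), dtype=bool)


class DegenerateNucleusError(ValueError):
    """Raised for labels whose region is too small or not a single component."""


@dataclass
class NucleusGeometry:
    """Geometric substrate of one nucleus.

    ``mask`` is a one-pixel-padded boolean crop; ``offset`` maps local to
    scene coordinates; ``boundary`` is the ordered 8-connected outer boundary
    chain (local ``(row, col)``, counter-clockwise in right-handed x/y);
    ``image`` is the aligned RGB crop when the geometry was extracted from a
    scene (``None`` for mask-only geometries).
    """

    mask: np.ndarray
    offset: tuple[int, int]
    boundary: np.ndarray
    centroid: tuple[float, float]
    pixel_size_um: float
    label: int = 0
    image: np.ndarray | None = None
    _polar: np.ndarray | None = field(default=None, repr=False)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def luminance(self) -> np.ndarray:
        """Mean-RGB luminance crop (float); requires an image crop."""
        if self.image is None:
            raise ValueError("geometry carries no image data")
        return self.image.astype(np.float64).mean(axis=2)

    def polar_radii(self, n_bins: int = 360) -> np.ndarray:
        """Outline radius r(theta) from the centroid, one value per 1-degree
        bin, in pixels.

        Per bin the maximum boundary-pixel distance is taken (outer outline
        of a star-convex region) plus half a pixel for the center-to-outline
        offset; empty bins are filled by circular linear interpolation.
        """
        if self._polar is not None and len(self._polar) == n_bins:
            return self._polar
        cy, cx = self.centroid
        dy = self.boundary[:, 0] - cy
        dx = self.boundary[:, 1] - cx
        ang = np.arctan2(-dy, dx) % (2.0 * np.pi)  # y-up convention
        dist = np.hypot(dx, dy)
        bins = np.minimum((ang / (2.0 * np.pi) * n_bins).astype(int), n_bins - 1)
        r = np.full(n_bins, -np.inf)
        np.maximum.at(r, bins, dist)
        empty = ~np.isfinite(r)
        if empty.any():
            idx = np.arange(n_bins)
            good = idx[~empty]
            r[empty] = np.interp(
                idx[empty], good, r[good], period=n_bins
            )
        self._polar = r + 0.5
        return self._polar


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered 8-connected boundary chain of a single foreground component.

    Moore-neighbour tracing from the first foreground pixel in raster order;
    terminates when the (pixel, backtrack) state repeats, which handles
    one-pixel-wide appendages (their pixels appear twice in the chain, as a
    chain code requires).  The returned chain is oriented counter-clockwise
    in right-handed coordinates (x = col, y = -row).
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    start = (int(rows[0]), int(cols[0]))
    if rows.size == 1:
        return np.array([start])
    cur = start
    prev = (start[0], start[1] - 1)  # west of start is background by raster order
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    chain: list[tuple[int, int]] = []
    while (cur, prev) not in seen:
        seen.add((cur, prev))
        chain.append(cur)
        d = _OFFSET_INDEX[(prev[0] - cur[0], prev[1] - cur[1])]
        nxt = None
        for i in range(1, 9):
            nd = (d + i) % 8
            cand = (cur[0] + _OFFSETS[nd][0], cur[1] + _OFFSETS[nd][1])
            if mask[cand]:
                nxt = cand
                back = (d + i - 1) % 8
                prev = (cur[0] + _OFFSETS[back][0], cur[1] + _OFFSETS[back][1])
                break
        if nxt is None:  # isolated pixel (unreachable for area >= 2)
            break
        cur = nxt
    boundary = np.array(chain)
    # Orient counter-clockwise in (x, y) = (col, -row).
    x = boundary[:, 1].astype(float)
    y = -boundary[:, 0].astype(float)
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if signed < 0:
        boundary = boundary[::-1]
    return boundary


def chain_length(boundary: np.ndarray, steps: tuple[float, float] = _RAW_STEPS) -> float:
    """Chain-code length of a closed boundary, in pixels."""
    if len(boundary) < 2:
        return 0.0
    diff = np.abs(np.diff(np.vstack([boundary, boundary[:1]]), axis=0))
    diagonal = (diff[:, 0] == 1) & (diff[:, 1] == 1)
    axial = diff.sum(axis=1) == 1
    return float(axial.sum() * steps[0] + diagonal.sum() * steps[1])


def _corrected_perimeter_px(boundary: np.ndarray) -> float:
    # VS-corrected chain length plus the half-pixel outline offset (2*pi*0.5).
    return chain_length(boundary, _VS_STEPS) + math.pi


def geometry_from_mask(
    mask: np.ndarray,
    pixel_size_um: float,
    image: np.ndarray | None = None,
    label: int = 0,
    offset: tuple[int, int] = (0, 0),
) -> NucleusGeometry:
    """Build a :class:`NucleusGeometry` from a boolean mask (plus optional
    aligned RGB crop), enforcing the single-component and minimum-area
    contracts."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateNucleusError(f"label {label}: empty region")
    n_comp = ndimage.label(mask, structure=_EIGHT)[1]
    if n_comp != 1:
        raise DegenerateNucleusError(
            f"label {label}: expected one 8-connected component, found {n_comp}"
        )
    area = int(mask.sum())
    if area < MIN_AREA_PX:
        raise DegenerateNucleusError(
            f"label {label}: area {area} px below minimum {MIN_AREA_PX} px"
        )
    padded = np.pad(mask, 1)
    boundary = trace_boundary(padded) - 1  # back to crop coordinates
    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()), float(cols.mean()))
    if image is not None:
        image = np.asarray(image)
        if image.shape[:2] != mask.shape:
            raise ValueError("image crop and mask shape mismatch")
    return NucleusGeometry(
        mask=mask,
        offset=offset,
        boundary=boundary,
        centroid=centroid,
        pixel_size_um=float(pixel_size_um),
        label=label,
        image=image,
    )


def extract_geometry(scene: LabeledScene, label: int) -> NucleusGeometry:
    """Crop and trace nucleus ``label`` from a labeled scene.

    Raises ``KeyError`` if the label is absent and
    :class:`DegenerateNucleusError` for sub-minimal or multi-component
    regions.
    """
    where = scene.labels == label
    if not where.any():
        raise KeyError(f"label {label} not present in mask")
    rows, cols = np.nonzero(where)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    mask = where[r0:r1, c0:c1]
    image = scene.image[r0:r1, c0:c1]
    return geometry_from_mask(
        mask,
        scene.pixel_size_um,
        image=image,
        label=label,
        offset=(int(r0), int(c0)),
    )


def _binary_holes(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask) & ~mask


def _feret_profile(geom: NucleusGeometry, n_dirs: int = 180) -> np.ndarray:
    """Caliper extent (px) of the nucleus over ``n_dirs`` directions on a
    1-degree grid; pixel width (+1) included."""
    theta = np.arange(n_dirs) * np.pi / n_dirs
    x = geom.boundary[:, 1].astype(float)
    y = -geom.boundary[:, 0].astype(float)
    proj = np.outer(np.cos(theta), x) + np.outer(np.sin(theta), y)
    return proj.max(axis=1) - proj.min(axis=1) + 1.0


def size_features(geom: NucleusGeometry) -> dict[str, float]:
    """Size descriptors, lengths in micrometres and areas in square
    micrometres.

    Diameters are measured through the centroid on a 1-degree polar grid
    (360 radius bins, 180 diameters); ferets are caliper extents over the
    same 180 directions; ``length``/``width`` are the maximal feret and the
    feret orthogonal to it; axis lengths come from second-order central
    moments (the moment-equivalent ellipse); ``perimeter_ellipse`` is that
    ellipse's Ramanujan perimeter; ``perimeter_length`` is the half-outline
    length of the battery's scale convention.
    """
    psz = geom.pixel_size_um
    area_px = geom.area_px
    out: dict[str, float] = {}
    out["nuclear_area"] = area_px * psz**2

    per2_px = chain_length(geom.boundary, _RAW_STEPS)
    holes_mask = _binary_holes(geom.mask)
    if holes_mask.any():
        hole_labels, n_holes = ndimage.label(holes_mask, structure=_EIGHT)
        for h in range(1, n_holes + 1):
            padded = np.pad(hole_labels == h, 1)
            per2_px += chain_length(trace_boundary(padded), _RAW_STEPS)
    per3_px = _corrected_perimeter_px(geom.boundary)
    out["perimeter2"] = per2_px * psz
    out["perimeter3"] = per3_px * psz
    out["perimeter_length"] = 0.5 * per3_px * psz

    pts = np.column_stack(
        [geom.boundary[:, 1].astype(float), -geom.boundary[:, 0].astype(float)]
    )
    unique_pts = np.unique(pts, axis=0)
    try:
        hull = ConvexHull(unique_pts)
        hv = unique_pts[hull.vertices]
        hull_per = float(
            np.sqrt(((hv - np.roll(hv, -1, axis=0)) ** 2).sum(axis=1)).sum()
        )
    except Exception:  # < 3 points or collinear (zero-width region)
        span = unique_pts.max(axis=0) - unique_pts.min(axis=0)
        hull_per = 2.0 * float(np.hypot(*span))
    out["perimeter_convex"] = (hull_per + math.pi) * psz

    # Moment-equivalent ellipse axes (4*sqrt(eigenvalue), regionprops
    # convention).
    rows, cols = np.nonzero(geom.mask)
    cy, cx = geom.centroid
    dy = rows - cy
    dx = cols - cx
    cov = np.array(
        [[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]]
    )
    evals = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    axis_major_px = 4.0 * math.sqrt(lam_major)
    axis_minor_px = 4.0 * math.sqrt(lam_minor)
    out["axis_major"] = axis_major_px * psz
    out["axis_minor"] = axis_minor_px * psz
    a, b = axis_major_px / 2.0, axis_minor_px / 2.0
    if a > 0 and b > 0:
        h3 = 3.0 * ((a - b) / (a + b)) ** 2
        ell = math.pi * (a + b) * (1.0 + h3 / (10.0 + math.sqrt(4.0 - h3)))
    else:
        ell = 0.0
    out["perimeter_ellipse"] = ell * psz
    out["perimeter_ratio"] = out["perimeter_convex"] / out["perimeter3"]

    # Polar radii and centroid diameters.
    r = geom.polar_radii(360)
    half = len(r) // 2
    diameters = r[:half] + r[half:]
    out["diameter_max"] = diameters.max() * psz
    out["diameter_min"] = diameters.min() * psz
    out["diameter_mean"] = diameters.mean() * psz
    dist = np.hypot(
        geom.boundary[:, 0] - cy, geom.boundary[:, 1] - cx
    )
    out["radius_max"] = (dist.max() + 0.5) * psz
    out["radius_min"] = (dist.min() + 0.5) * psz

    # Bounding box and ferets.
    nrows = rows.max() - rows.min() + 1
    ncols = cols.max() - cols.min() + 1
    out["box_width"] = ncols * psz
    out["box_height"] = nrows * psz

    ferets = _feret_profile(geom)
    out["feret_min"] = ferets.min() * psz
    out["feret_mean"] = ferets.mean() * psz
    imax = int(np.argmax(ferets))
    out["length"] = ferets[imax] * psz
    out["width"] = ferets[(imax + len(ferets) // 2) % len(ferets)] * psz
    return out


def box_counting_dimension(
    boundary: np.ndarray, max_box: int = 64, min_scales: int = 4
) -> float:
    """Box-counting fractal dimension of a boundary pixel chain.

    Counts occupied boxes on a size ladder of quarter-octave steps
    (2, 3, 4, 6, 8, 11, ...) capped at ``min(max_box, bbox/4)``; per size the
    minimum count over four grid offsets is used (approximating the covering
    infimum).  The dimension is the least-squares slope of log N against
    log(1/s), clipped to the admissible range [1, 2] for a curve in the
    plane.  Returns NaN when fewer than ``min_scales`` sizes are available
    (boundary too short).
    """
    pts = np.unique(boundary, axis=0)
    pts = pts - pts.min(axis=0)
    extent = int(pts.max()) + 1
    ladder = [2, 3, 4, 6, 8, 11, 16, 23, 32, 45, 64]
    cap = min(max_box, extent // 4)
    sizes = [s for s in ladder if s <= cap]
    if len(sizes) < min_scales:
        return float("nan")
    counts = []
    for s in sizes:
        best = np.inf
        for dr in (0, s // 2):
            for dc in (0, s // 2):
                keys = (pts[:, 0] + dr) // s * 100000 + (pts[:, 1] + dc) // s
                best = min(best, len(np.unique(keys)))
        counts.append(best)
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return float(np.clip(slope, 1.0, 2.0))


def _bright_hole_count(geom: NucleusGeometry) -> float:
    """Count of bright intranuclear regions (vesicle-like 'holes') fully
    enclosed by the nucleus, thresholded at luminance mean + 1 SD."""
    if geom.image is None:
        return float("nan")
    lum = geom.luminance()
    vals = lum[geom.mask]
    thr = vals.mean() + vals.std()
    bright = (lum > thr) & geom.mask
    if not bright.any():
        return 0.0
    rim = ndimage.binary_dilation(~geom.mask, structure=_EIGHT) & geom.mask
    labels, n = ndimage.label(bright, structure=_EIGHT)
    touching = np.unique(labels[rim & bright])
    touching = touching[touching > 0]
    return float(n - len(touching))


def shape_features(geom: NucleusGeometry) -> dict[str, float]:
    """Dimensionless shape descriptors.

    ``roundness`` is the isoperimetric quotient ``perimeter3^2 / (4 pi area)``
    (1 for a perfect disk, larger otherwise); ``area_per_box`` the fill
    fraction of the bounding box; ``fractal_dimension`` the box-counting
    slope of the boundary chain; ``holes`` the count of enclosed bright
    vesicle-like regions (NaN for mask-only geometries).
    """
    size = size_features(geom)
    psz = geom.pixel_size_um
    area_um2 = size["nuclear_area"]
    out = {
        "aspect": size["axis_major"] / size["axis_minor"]
        if size["axis_minor"] > 0
        else float("nan"),
        "roundness": size["perimeter3"] ** 2 / (4.0 * math.pi * area_um2),
        "area_per_box": area_um2 / (size["box_width"] * size["box_height"]),
        "radius_ratio": size["radius_max"] / size["radius_min"],
        "fractal_dimension": box_counting_dimension(geom.boundary),
        "holes": _bright_hole_count(geom),
    }
    del psz
    return out


def intensity_features(scene: LabeledScene | None, geom: NucleusGeometry) -> dict[str, float]:
    """Gray-level and optical-density descriptors over the nucleus pixels.

    Gray statistics are computed on the luminance channel; ``od_mean`` is
    ``256 - gray_mean``; ``iod`` integrates the mean OD over the nucleus
    area in square micrometres.
    """
    if geom.image is None:
        if scene is None:
            raise ValueError("no image data available")
        r0, c0 = geom.offset
        h, w = geom.mask.shape
        geom.image = scene.image[r0 : r0 + h, c0 : c0 + w]
    rgb = geom.image.astype(np.float64)
    m = geom.mask
    lum = rgb.mean(axis=2)[m]
    area_um2 = geom.area_px * geom.pixel_size_um**2
    gray_mean = float(lum.mean())
    od_mean = 256.0 - gray_mean
    return {
        "gray_mean": gray_mean,
        "gray_min": float(lum.min()),
        "gray_max": float(lum.max()),
        "gray_std": float(lum.std()),
        "gray_red": float(rgb[:, :, 0][m].mean()),
        "gray_green": float(rgb[:, :, 1][m].mean()),
        "gray_blue": float(rgb[:, :, 2][m].mean()),
        "gray_sum": float(lum.sum()),
        "od_mean": od_mean,
        "iod": od_mean * area_um2,
    }


def texture_features(scene: LabeledScene | None, geom: NucleusGeometry) -> dict[str, float]:
    """Chromatin texture descriptors: margination, heterogeneity, clumpiness.

    * heterogeneity — fraction of nucleus pixels whose luminance deviates
      from the nucleus mean by more than 10% of that mean.
    * clumpiness — fraction of those heterogeneous pixels surviving one pass
      of 3x3 majority erosion (at least 5 heterogeneous pixels in the 3x3
      neighbourhood, pixel included), i.e. cluster persistence in [0, 1].
    * margination — mean optical density of the peripheral band (pixels in
      the outer third of the centroid-to-boundary distance in their
      direction) divided by three times the whole-nucleus mean OD; equals
      exactly 1/3 for a radially uniform nucleus.

    Nuclei below 30 px are flagged missing (NaN).
    """
    if geom.image is None:
        if scene is None:
            raise ValueError("no image data available")
        r0, c0 = geom.offset
        h, w = geom.mask.shape
        geom.image = scene.image[r0 : r0 + h, c0 : c0 + w]
    nan = float("nan")
    if geom.area_px < MIN_TEXTURE_AREA_PX:
        return {"margination": nan, "heterogeneity": nan, "clumpiness": nan}
    lum = geom.luminance()
    m = geom.mask
    vals = lum[m]
    mean = vals.mean()

    if mean > 0:
        het = np.zeros_like(m)
        het[m] = np.abs(vals - mean) > 0.10 * mean
        n_het = int(het.sum())
        heterogeneity = n_het / geom.area_px
        if n_het:
            neigh = ndimage.uniform_filter(het.astype(float), size=3) * 9.0
            survivors = het & (neigh >= 4.5)  # >= 5 of 9, guard rounding
            clumpiness = float(survivors.sum()) / n_het
        else:
            clumpiness = 0.0
    else:
        heterogeneity = nan
        clumpiness = nan

    od = 256.0 - lum
    r = geom.polar_radii(360)
    rows, cols = np.nonzero(m)
    cy, cx = geom.centroid
    dy = rows - cy
    dx = cols - cx
    ang = np.arctan2(-dy, dx) % (2.0 * np.pi)
    bins = np.minimum((ang / (2.0 * np.pi) * len(r)).astype(int), len(r) - 1)
    peripheral = np.hypot(dx, dy) >= (2.0 / 3.0) * r[bins]
    od_vals = od[m]
    total_mean = od_vals.mean()
    if peripheral.any() and total_mean > 0:
        margination = od_vals[peripheral].mean() / (3.0 * total_mean)
    else:
        margination = nan
    return {
        "margination": float(margination),
        "heterogeneity": float(heterogeneity),
        "clumpiness": float(clumpiness),
    }


def extract_features(scene: LabeledScene, label: int) -> dict[str, float]:
    """Full descriptor vector for one nucleus, keyed by
    :data:`FEATURE_COLUMNS`."""
    geom = extract_geometry(scene, label)
    feats: dict[str, float] = {}
    feats.update(size_features(geom))
    feats.update(shape_features(geom))
    feats.update(intensity_features(scene, geom))
    feats.update(texture_features(scene, geom))
    return {k: feats[k] for k in FEATURE_COLUMNS}


def extract_table(
    cohort: list[tuple[str, str, LabeledScene]]
) -> pd.DataFrame:
    """Extract the descriptor battery for every nucleus of a cohort.

    Returns one row per nucleus with ``sample_id``, ``nucleus_id`` and
    ``grade_group`` followed by the descriptor columns.  Per-nucleus failures
    (degenerate regions) are logged and skipped, never imputed.
    """
    rows = []
    for sample_id, grade, scene in cohort:
        labels = np.unique(scene.labels)
        labels = labels[labels > 0]
        for lab in labels:
            try:
                feats = extract_features(scene, int(lab))
            except (DegenerateNucleusError, KeyError) as exc:
                log.warning("sample %s nucleus %d skipped: %s", sample_id, lab, exc)
                continue
            row = {"sample_id": sample_id, "nucleus_id": int(lab), "grade_group": grade}
            row.update(feats)
            rows.append(row)
    table = pd.DataFrame(rows, columns=["sample_id", "nucleus_id", "grade_group"] + FEATURE_COLUMNS)
    return table
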