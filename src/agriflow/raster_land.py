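"""Spectral land assessment from co-registered multiband reflectance grids.

Implements the two normalized-difference indices used for agricultural land
screening — NDVI = (NIR − Red)/(NIR + Red) for vegetation vigour and
NDSI = (Green − SWIR)/(Green + SWIR) for soil salinity — together with
K-means segmentation of the scalar index field and healthy-vegetation area
accounting from binary masks.

Grids follow Landsat-8 band semantics (green, red, NIR, SWIR) at a default
30 m pixel size.  Reflectance is assumed pre-scaled to physical units
(typically [0, 1]); digital-number scaling, atmospheric correction and cloud
masking are upstream concerns.

Coordinate convention: row-major 2-D arrays, (row, col) indexed from 0 at the
top-left.  Pixels where an index denominator is zero, or where any input band
is masked, are flagged invalid rather than silently propagated as NaN.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "BandStack",
    "IndexRaster",
    "ClassMap",
    "AreaSeries",
    "compute_ndvi",
    "compute_ndsi",
    "kmeans_segment",
    "healthy_mask",
    "vegetation_area",
    "salinity_classes",
    "read_grid",
    "write_grid",
    "read_band_stack",
]

SALINITY_CLASS_NAMES = ("high salinity", "moderate salinity", "low salinity")


class ShapeError(ValueError):
    """Raised when band grids do not share a single shape."""


@dataclass
class BandStack:
    """Co-registered reflectance grids for one scene.

    Parameters
    ----------
    green, red, nir, swir
        2-D reflectance arrays, all the same shape.
    valid_mask
        Boolean array, True where all bands carry usable data.  Defaults to
        all-True.
    pixel_size
        Ground size of one pixel side in meters (Landsat-8: 30).
    """

    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    valid_mask: np.ndarray | None = None
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        self.swir = np.asarray(self.swir, dtype=float)
        shapes = {self.green.shape, self.red.shape, self.nir.shape, self.swir.shape}
        if len(shapes) != 1:
            raise ShapeError(f"band grids have mismatched shapes: {sorted(shapes)}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.green.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.green.shape:
                raise ShapeError("valid_mask shape does not match band grids")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        for name in ("green", "red", "nir", "swir"):
            band = getattr(self, name)
            if not np.all(np.isfinite(band[self.valid_mask])):
                raise ValueError(f"non-finite {name} reflectance inside valid_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass
class IndexRaster:
    """A normalized-difference index field with its validity mask."""

    values: np.ndarray
    name: str
    valid_mask: np.ndarray
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ShapeError("index values and valid_mask shapes differ")
        valid = self.values[self.valid_mask]
        if valid.size and (np.any(valid < -1 - 1e-12) or np.any(valid > 1 + 1e-12)):
            raise ValueError(f"{self.name} values outside [-1, 1] on valid pixels")


@dataclass
class ClassMap:
    """K-means labelling of an index raster.

    Labels are remapped so class 0 has the highest centroid; ``centroids`` is
    therefore sorted descending.  Invalid pixels carry label -1.
    """

    labels: np.ndarray
    k: int
    centroids: list[float]
    class_names: list[str]
    valid_mask: np.ndarray
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if len(self.centroids) != self.k or len(self.class_names) != self.k:
            raise ValueError("centroids and class_names must have length k")
        if any(b > a + 1e-12 for a, b in zip(self.centroids, self.centroids[1:])):
            raise ValueError("centroids must be sorted descending")
        lab = self.labels[self.valid_mask]
        if lab.size and (lab.min() < 0 or lab.max() >= self.k):
            raise ValueError("labels on valid pixels must lie in [0, k)")


@dataclass
class AreaSeries:
    """Ordered (period label, area m²) pairs, e.g. one entry per scene date."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    def append(self, period: str, area_m2: float) -> None:
        if area_m2 < 0:
            raise ValueError("area must be non-negative")
        self.entries.append((period, float(area_m2)))


def _normalized_difference(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                           name: str, pixel_size: float) -> IndexRaster:
    num = a - b
    den = a + b
    valid = mask & (den != 0)
    values = np.zeros(a.shape, dtype=float)
    np.divide(num, den, out=values, where=valid)
    values[~valid] = np.nan
    return IndexRaster(values=values, name=name, valid_mask=valid, pixel_size=pixel_size)


def compute_ndvi(stack: BandStack) -> IndexRaster:
    """Normalized Difference Vegetation Index, (NIR − Red)/(NIR + Red).

    Pixels with NIR + Red = 0 (or masked inputs) are marked invalid.
    """
    return _normalized_difference(stack.nir, stack.red, stack.valid_mask,
                                  "NDVI", stack.pixel_size)


def compute_ndsi(stack: BandStack) -> IndexRaster:
    """Normalized Difference Salinity Index, (Green − SWIR)/(Green + SWIR)."""
    return _normalized_difference(stack.green, stack.swir, stack.valid_mask,
                                  "NDSI", stack.pixel_size)


def _exact_1d_kmeans(vals: np.ndarray, k: int,
                     max_n: int = 256) -> tuple[np.ndarray, np.ndarray] | None:
    """Globally optimal k-means for small scalar samples.

    The minimum within-cluster-sum-of-squares partition of 1-D data is
    contiguous in sorted order, so it can be found exactly by searching the
    (n−1 choose k−1) split-point combinations with prefix sums.  Returns
    (labels, centers) or None when the instance is too large (the caller then
    falls back to randomized Lloyd iterations).
    """
    import itertools as _it
    from math import comb

    n = vals.size
    if n > max_n or comb(n - 1, k - 1) > 50_000:
        return None
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    csum = np.concatenate([[0.0], np.cumsum(s)])
    csq = np.concatenate([[0.0], np.cumsum(s ** 2)])

    def seg_cost(i: int, j: int) -> float:  # cost of s[i:j]
        m = j - i
        tot = csum[j] - csum[i]
        return (csq[j] - csq[i]) - tot * tot / m

    best_cost, best_splits = np.inf, None
    for splits in _it.combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        cost = sum(seg_cost(bounds[i], bounds[i + 1]) for i in range(k))
        if cost < best_cost:
            best_cost, best_splits = cost, bounds
    labels = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c in range(k):
        i, j = best_splits[c], best_splits[c + 1]
        labels[order[i:j]] = c
        centers[c] = (csum[j] - csum[i]) / (j - i)
    return labels, centers


def kmeans_segment(index: IndexRaster, k: int, seed: int = 0,
                   class_names: Sequence[str] | None = None) -> ClassMap:
    """Segment the valid pixels of a scalar index raster with K-means.

    The clustering runs on the 1-D index values of valid pixels.  Small
    instances are solved to the global within-cluster-sum-of-squares optimum
    by exact search over contiguous sorted partitions; larger rasters use
    seeded Lloyd iterations with k-means++ restarts.  Centroids
    are reported sorted descending and labels remapped accordingly, so label 0
    always names the highest-index class.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of distinct valid values.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    vals = index.values[index.valid_mask]
    if np.unique(vals).size < k:
        raise ValueError(
            f"k={k} exceeds the {np.unique(vals).size} distinct valid values")
    exact = _exact_1d_kmeans(vals, k)
    if exact is not None:
        raw_labels, centers = exact
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
        raw_labels = km.fit_predict(vals.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
    order = np.argsort(-centers)  # descending
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = np.full(index.values.shape, -1, dtype=int)
    labels[index.valid_mask] = remap[raw_labels]
    centroids = [float(c) for c in centers[order]]
    if class_names is None:
        class_names = [f"class_{i}" for i in range(k)]
    return ClassMap(labels=labels, k=k, centroids=centroids,
                    class_names=list(class_names), valid_mask=index.valid_mask,
                    pixel_size=index.pixel_size)


def healthy_mask(classmap: ClassMap, threshold: float | None = None,
                 index: IndexRaster | None = None) -> np.ndarray:
    """Binary mask of the healthiest-vegetation pixels.

    By default this is the cluster with the highest NDVI centroid (label 0
    after descending remap).  Alternatively, a fixed index ``threshold`` can be
    supplied together with the source ``index`` raster, in which case the mask
    is ``index >= threshold`` on valid pixels.
    """
    if threshold is not None:
        if index is None:
            raise ValueError("threshold mode requires the source index raster")
        return index.valid_mask & (np.nan_to_num(index.values, nan=-np.inf) >= threshold)
    return classmap.valid_mask & (classmap.labels == 0)


def vegetation_area(mask: np.ndarray, pixel_size: float = 30.0) -> float:
    """Area in m² covered by True pixels: count × pixel_size²."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(np.count_nonzero(mask)) * float(pixel_size) ** 2


def salinity_classes(ndsi: IndexRaster, seed: int = 0) -> ClassMap:
    """Three-tier salinity map (high / moderate / low) from an NDSI raster.

    K-means with k=3; class names assigned by descending centroid since high
    NDSI flags salt-affected soil.
    """
    return kmeans_segment(ndsi, k=3, seed=seed, class_names=list(SALINITY_CLASS_NAMES))


# ---------------------------------------------------------------------------
# Plain-text grid I/O
#
# Dialect: four header lines (ncols, nrows, pixel_size, nodata), then nrows
# whitespace-separated rows of ncols values, row-major from the top-left.


def write_grid(path: str | Path, values: np.ndarray, pixel_size: float = 30.0,
               nodata: float = -9999.0, valid_mask: np.ndarray | None = None) -> None:
    """Write a 2-D grid in the plain-text dialect; masked cells get ``nodata``."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if valid_mask is not None:
        out[~np.asarray(valid_mask, dtype=bool)] = nodata
    out[~np.isfinite(out)] = nodata
    buf = _io.StringIO()
    buf.write(f"ncols {values.shape[1]}\n")
    buf.write(f"nrows {values.shape[0]}\n")
    buf.write(f"pixel_size {pixel_size:g}\n")
    buf.write(f"nodata {nodata:g}\n")
    for row in out:
        buf.write(" ".join(f"{v:.6g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a plain-text grid.

    Returns ``(values, valid_mask, pixel_size)``; cells equal to the header's
    nodata value are masked out.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and len(header) < 4:
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    for req in ("ncols", "nrows", "pixel_size", "nodata"):
        if req not in header:
            raise ValueError(f"grid header missing '{req}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.loadtxt(_io.StringIO("\n".join(lines[i:])), dtype=float)
    values = np.atleast_2d(data).reshape(nrows, ncols)
    valid = values != header["nodata"]
    values = values.astype(float)
    values[~valid] = np.nan
    return values, valid, float(header["pixel_size"])


def read_band_stack(green: str | Path, red: str | Path, nir: str | Path,
                    swir: str | Path) -> BandStack:
    """Assemble a BandStack from four plain-text grid files.

    The validity mask is the conjunction of per-band nodata masks; pixel size
    must agree across files.
    """
    arrays, masks, sizes = [], [], []
    for p in (green, red, nir, swir):
        v, m, px = read_grid(p)
        arrays.append(v)
        masks.append(m)
        sizes.append(px)
    if len(set(sizes)) != 1:
        raise ValueError(f"pixel sizes disagree across bands: {sizes}")
    mask = np.logical_and.reduce(masks)
    arrays = [np.where(mask, a, 0.0) for a in arrays]
    return BandStack(green=arrays[0], red=arrays[1], nir=arrays[2],
                     swir=arrays[3], valid_mask=mask, pixel_size=sizes[0])
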