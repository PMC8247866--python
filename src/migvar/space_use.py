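"""Gridded utilization distributions and overlap.

Two estimators are provided on a shared equal-area grid lattice:

* ``kde_ud`` — fixed-bandwidth bivariate normal kernel density on a coarse
  grid (defaults: 10-km cells, h = 100 km), used for the seasonal
  non-breeding distribution of 12-h subsampled fixes.
* ``brb_ud`` — a biased-random-bridge (movement-based) kernel for
  full-rate winter fixes on a fine grid (500-m cells): kernel mass is
  spread along time-interpolated positions of each step, with variance
  growing mid-step as sigma^2(p) = h_min^2 + 4 D T p (1 - p).

"95% UD" follows the truncation convention in which cell masses outside
the 95% isopleth are zeroed WITHOUT renormalization, so the Bhattacharyya
affinity of a 95% UD with itself is 0.95 — the maximum attainable overlap.

All grids snap their origin to multiples of the cell size, so any two UDs
with equal cell size live on one lattice and can be aligned exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.special import ndtr
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "GridUD", "BRBParams", "IsoplethSet", "GridMismatchError",
    "kde_ud", "isopleth", "truncate_ud", "estimate_diffusion", "brb_ud",
    "bhattacharyya", "common_grid", "seasonal_overlap_matrix",
    "winter_site_fidelity", "write_esri_ascii", "isopleths_to_geojson",
]


class GridMismatchError(ValueError):
    """Two UDs do not share origin/cell size/extent."""


@dataclass
class GridUD:
    """Probability masses on an equal-area grid.

    ``origin`` is the lower-left corner (metres) of cell (0, 0); masses are
    indexed ``[iy, ix]``. Untruncated masses sum to 1; truncated ones sum to
    roughly ``truncation_level`` (exceeding it by at most one cell's mass).
    """

    origin: tuple
    cell_size: float
    masses: np.ndarray
    method: str = "fixed-kernel"
    bandwidth_h: Optional[float] = None
    truncation_level: Optional[float] = None

    @property
    def shape(self):
        return self.masses.shape

    def x_edges(self):
        return self.origin[0] + self.cell_size * np.arange(self.shape[1] + 1)

    def y_edges(self):
        return self.origin[1] + self.cell_size * np.arange(self.shape[0] + 1)

    def cell_index(self, x, y):
        """Grid indices (iy, ix) of planar points; boundary maps to the
        cell above/right of the edge except at the outer edge."""
        ix = np.clip(
            np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int),
            0, self.shape[1] - 1,
        )
        iy = np.clip(
            np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int),
            0, self.shape[0] - 1,
        )
        return iy, ix


@dataclass(frozen=True)
class BRBParams:
    """Biased-random-bridge parameters (metres / seconds)."""

    t_max_s: float = 3 * 3600.0   # steps longer than this are not bridged
    l_min_m: float = 20.0         # below this the animal is considered resting
    h_min_m: float = 150.0        # minimum smoothing parameter
    diffusion_m2s: Optional[float] = None  # estimated from data when None
    n_interp: int = 10

    def __post_init__(self):
        if min(self.t_max_s, self.l_min_m, self.h_min_m) <= 0:
            raise ValueError("BRB parameters must be positive")


@dataclass
class IsoplethSet:
    level: float
    polygons: list
    member_cells: np.ndarray  # boolean mask on the UD grid
    labels: np.ndarray        # connected-component label per cell (0 = outside)

    @property
    def n_components(self):
        return int(self.labels.max())


def _snapped_grid(xmin, xmax, ymin, ymax, cell_size, pad):
    x0 = np.floor((xmin - pad) / cell_size) * cell_size
    y0 = np.floor((ymin - pad) / cell_size) * cell_size
    nx = int(np.ceil((xmax + pad - x0) / cell_size))
    ny = int(np.ceil((ymax + pad - y0) / cell_size))
    return (x0, y0), max(nx, 1), max(ny, 1)


def _accumulate_kernels(xs, ys, sigmas, weights, origin, cell_size, nx, ny):
    """Sum of axis-separable Gaussian cell integrals: exact mass of each
    kernel inside each grid cell, weighted and normalized to 1."""
    xe = origin[0] + cell_size * np.arange(nx + 1)
    ye = origin[1] + cell_size * np.arange(ny + 1)
    sig = np.asarray(sigmas, dtype=float)[:, None]
    cx = ndtr((xe[None, :] - np.asarray(xs)[:, None]) / sig)
    cy = ndtr((ye[None, :] - np.asarray(ys)[:, None]) / sig)
    ax = np.diff(cx, axis=1) * np.asarray(weights)[:, None]
    ay = np.diff(cy, axis=1)
    masses = ay.T @ ax
    total = masses.sum()
    if total <= 0:
        raise ValueError("kernel mass vanished on the grid (grid too small?)")
    return masses / total


def kde_ud(fixes, cell_size=10_000.0, h=100_000.0, pad=None, cell_mass="exact",
           min_fixes=5):
    """Fixed-kernel UD of projected fixes (DataFrame with x/y in metres).

    Cell mass is the average over fixes of the bivariate normal
    (sigma = h) probability mass inside the cell. ``cell_mass="centre"``
    uses the density-at-centre x area approximation instead.
    """
    if len(fixes) < min_fixes:
        raise ValueError(f"insufficient fixes: {len(fixes)} < {min_fixes}")
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    if pad is None:
        pad = 3.0 * h
    origin, nx, ny = _snapped_grid(x.min(), x.max(), y.min(), y.max(), cell_size, pad)
    w = np.full(len(x), 1.0 / len(x))
    if cell_mass == "exact":
        masses = _accumulate_kernels(x, y, np.full(len(x), h), w, origin, cell_size, nx, ny)
    elif cell_mass == "centre":
        xc = origin[0] + cell_size * (np.arange(nx) + 0.5)
        yc = origin[1] + cell_size * (np.arange(ny) + 0.5)
        dx2 = ((xc[None, :] - x[:, None]) / h) ** 2
        dy2 = ((yc[None, :] - y[:, None]) / h) ** 2
        dens = (np.exp(-dy2 / 2).T @ (np.exp(-dx2 / 2) * w[:, None])) / (2 * np.pi * h**2)
        masses = dens * cell_size**2
        masses = masses / masses.sum()
    else:
        raise ValueError(f"unknown cell_mass mode {cell_mass!r}")
    return GridUD(origin=origin, cell_size=cell_size, masses=masses,
                  method="fixed-kernel", bandwidth_h=h)


def isopleth(ud: GridUD, level: float) -> IsoplethSet:
    """Smallest cell set holding >= ``level`` of UD mass, as polygons.

    Cells are added in order of decreasing mass (ties broken by row-major
    index); the member set is dissolved into connected (4-neighbour)
    components and each component into a polygon.
    """
    if not 0 < level <= 1:
        raise ValueError(f"isopleth level must be in (0, 1], got {level}")
    flat = ud.masses.ravel()
    order = np.argsort(-flat, kind="stable")
    if level >= 1.0:
        member_idx = np.nonzero(flat > 0)[0]
    else:
        csum = np.cumsum(flat[order])
        target = min(level, csum[-1])
        k = int(np.searchsorted(csum, target - 1e-12)) + 1
        member_idx = order[:k]
        member_idx = member_idx[flat[member_idx] > 0]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[member_idx] = True
    mask = mask.reshape(ud.masses.shape)
    labels, n_comp = ndimage.label(mask)
    polygons = []
    cs = ud.cell_size
    x0, y0 = ud.origin
    for comp in range(1, n_comp + 1):
        iy, ix = np.nonzero(labels == comp)
        cells = [box(x0 + i * cs, y0 + j * cs, x0 + (i + 1) * cs, y0 + (j + 1) * cs)
                 for j, i in zip(iy, ix)]
        polygons.append(unary_union(cells))
    return IsoplethSet(level=level, polygons=polygons, member_cells=mask, labels=labels)


def truncate_ud(ud: GridUD, level: float = 0.95) -> GridUD:
    """Zero masses outside the ``level`` isopleth, WITHOUT renormalizing."""
    iso = isopleth(ud, level)
    masses = np.where(iso.member_cells, ud.masses, 0.0)
    return replace(ud, masses=masses, truncation_level=level)


def estimate_diffusion(fixes, params: BRBParams = BRBParams()) -> float:
    """Median-MSD plug-in estimate of the diffusion coefficient (m^2/s).

    For steps with duration <= t_max and length >= l_min,
    D = median of length^2 / (4 * duration) / ln 2. Under planar Brownian
    motion the squared step length is exponential with mean 4 D T, so the
    raw median underestimates D by a factor ln 2; dividing it out makes
    the estimator median-unbiased while keeping its robustness to the
    occasional ballistic (commuting) step. An approximation to the
    plug-in estimators used with movement-based kernels; documented as such.
    """
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    t = fixes["timestamp"].dt.tz_convert(None).to_numpy()
    dur = (t[1:] - t[:-1]) / np.timedelta64(1, "s")
    length = np.hypot(np.diff(x), np.diff(y))
    ok = (dur > 0) & (dur <= params.t_max_s) & (length >= params.l_min_m)
    if not ok.any():
        raise ValueError("no eligible steps for diffusion estimation")
    return float(np.median(length[ok] ** 2 / (4.0 * dur[ok])) / np.log(2.0))


def _brb_kernel_points(fixes, params: BRBParams, diffusion):
    """Kernel centres, bandwidths and time weights for the BRB estimator."""
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    t = fixes["timestamp"].dt.tz_convert(None).to_numpy()
    if len(x) == 1:
        return x, y, np.array([params.h_min_m]), np.array([1.0])
    dur = (t[1:] - t[:-1]) / np.timedelta64(1, "s")
    length = np.hypot(np.diff(x), np.diff(y))
    xs, ys, sig, w = [], [], [], []
    bridged = (dur > 0) & (dur <= params.t_max_s)
    p = (np.arange(params.n_interp) + 0.5) / params.n_interp
    for i in np.nonzero(bridged)[0]:
        px = x[i] + p * (x[i + 1] - x[i])
        py = y[i] + p * (y[i + 1] - y[i])
        if length[i] >= params.l_min_m:
            s2 = params.h_min_m**2 + 4.0 * diffusion * dur[i] * p * (1.0 - p)
        else:  # resting: no bridge variance inflation
            s2 = np.full_like(p, params.h_min_m**2)
        xs.append(px); ys.append(py)
        sig.append(np.sqrt(s2))
        w.append(np.full_like(p, dur[i] / params.n_interp))
    for i in np.nonzero(~bridged)[0]:
        # gap longer than t_max: endpoint kernels only, capped weight
        xs.append(x[i : i + 2]); ys.append(y[i : i + 2])
        sig.append(np.full(2, params.h_min_m))
        w.append(np.full(2, params.t_max_s / 2.0))
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(sig), np.concatenate(w))


def brb_ud(fixes, cell_size=500.0, params: BRBParams = BRBParams(), pad=None):
    """Biased-random-bridge UD of full-rate winter fixes on a fine grid."""
    if len(fixes) == 0:
        raise ValueError("empty winter window")
    diffusion = params.diffusion_m2s
    if diffusion is None:
        diffusion = estimate_diffusion(fixes, params)
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    sig_max = np.sqrt(params.h_min_m**2 + diffusion * params.t_max_s)
    if pad is None:
        pad = 3.0 * max(sig_max, cell_size)
    origin, nx, ny = _snapped_grid(x.min(), x.max(), y.min(), y.max(), cell_size, pad)
    xs, ys, sig, w = _brb_kernel_points(fixes, params, diffusion)
    masses = _accumulate_kernels(xs, ys, sig, w, origin, cell_size, nx, ny)
    return GridUD(origin=origin, cell_size=cell_size, masses=masses,
                  method="BRB", bandwidth_h=params.h_min_m)


def bhattacharyya(ud1: GridUD, ud2: GridUD) -> float:
    """Bhattacharyya affinity sum(sqrt(m1 * m2)) on a shared grid.

    Raises GridMismatchError rather than silently resampling; use
    ``common_grid`` first when extents differ.
    """
    if (ud1.origin != ud2.origin or ud1.cell_size != ud2.cell_size
            or ud1.shape != ud2.shape):
        raise GridMismatchError("UDs are not on a common grid")
    return float(np.sqrt(ud1.masses * ud2.masses).sum())


def common_grid(uds):
    """Zero-pad UDs of equal cell size to the union extent of the lattice."""
    cs = uds[0].cell_size
    if any(u.cell_size != cs for u in uds):
        raise GridMismatchError("cell sizes differ")
    for u in uds:
        for o in u.origin:
            if abs(o / cs - round(o / cs)) > 1e-6:
                raise GridMismatchError("origin not snapped to the lattice")
    x0 = min(u.origin[0] for u in uds)
    y0 = min(u.origin[1] for u in uds)
    x1 = max(u.origin[0] + u.shape[1] * cs for u in uds)
    y1 = max(u.origin[1] + u.shape[0] * cs for u in uds)
    nx = round((x1 - x0) / cs)
    ny = round((y1 - y0) / cs)
    out = []
    for u in uds:
        masses = np.zeros((ny, nx))
        ox = round((u.origin[0] - x0) / cs)
        oy = round((u.origin[1] - y0) / cs)
        masses[oy : oy + u.shape[0], ox : ox + u.shape[1]] = u.masses
        out.append(replace(u, origin=(x0, y0), masses=masses))
    return out


def _pairwise_ba(uds, level):
    aligned = common_grid(uds)
    if level is not None:
        aligned = [truncate_ud(u, level) for u in aligned]
    pairs = {}
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            pairs[(i, j)] = bhattacharyya(aligned[i], aligned[j])
    return pairs


def seasonal_overlap_matrix(uds, level=0.95):
    """Mean pairwise BA between an individual's seasonal 95% UDs.

    Returns (mean BA, dict of per-pair values keyed by season index pair).
    """
    if len(uds) < 2:
        raise ValueError("need >= 2 seasons for overlap")
    pairs = _pairwise_ba(uds, level)
    return float(np.mean(list(pairs.values()))), pairs


def winter_site_fidelity(uds, level=0.95):
    """Mean pairwise BA between an individual's winter BRB 95% UDs."""
    if len(uds) < 2:
        raise ValueError("need >= 2 winters for site fidelity")
    pairs = _pairwise_ba(uds, level)
    return float(np.mean(list(pairs.values()))), pairs


def write_esri_ascii(ud: GridUD, path, nodata=-9999):
    """Export a UD as an ESRI ASCII grid (planar equal-area metres)."""
    ny, nx = ud.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {ud.origin[0]:.3f}\nyllcorner {ud.origin[1]:.3f}\n")
        fh.write(f"cellsize {ud.cell_size:.3f}\nNODATA_value {nodata}\n")
        for row in ud.masses[::-1]:
            fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


def isopleths_to_geojson(iso: IsoplethSet, properties=None):
    """Isopleth polygons as a GeoJSON FeatureCollection (planar coords)."""
    feats = []
    for i, poly in enumerate(iso.polygons):
        props = {"level": iso.level, "component": i}
        if properties:
            props.update(properties)
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    return {"type": "FeatureCollection",
            "crs_note": "planar metres, Lambert azimuthal equal-area",
            "features": feats}
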