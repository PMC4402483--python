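"""Nuclear point clouds, cylindrical projection, and grid interpolation.

Gene expression in the early *Drosophila* embryo is measured per nucleus on
the (roughly prolate-ellipsoidal) embryo cortex, not on a regular raster.
SSA needs a regular grid, so the preprocessing pipeline is:

1. find the embryo's major (anteroposterior) axis by PCA of the nuclear
   coordinates;
2. project every nucleus onto a cylinder centred on that axis, yielding an
   axial coordinate in percent egg length (%EL, 0-100) and an angular
   coordinate in degrees (0-360, periodic);
3. interpolate the scattered per-nucleus values onto a regular
   (angular x axial) grid — Delaunay triangulation followed by linear
   interpolation, with the angular coordinate replicated at +-360 degrees so
   the interpolant is seam-free across the periodic boundary;
4. after SSA, interpolate smooth components back onto nuclear centres;
   residuals are the difference between the original per-nucleus data and
   the back-interpolated smooth component.

Only a central axial band is analyzed (the default clips follow common
practice for stripe-region analyses) to avoid the distortion near the poles
of the ellipsoid-to-cylinder transformation.  The projection does not
correct for the local radius of the ellipsoid; angular position is the raw
azimuth about the major axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

from .core import NO_DATA, GridImage

logger = logging.getLogger("ssa2d")

#: default axial grid step, percent egg length.
DEFAULT_STEP_PERCENT = 0.5

#: default angular grid step, degrees (200 rows around the circumference).
DEFAULT_ANGULAR_STEP = 1.8


@dataclass
class NuclearPointCloud:
    """Per-nucleus 3D coordinates plus named expression channels."""

    coords: np.ndarray  # (n, 3)
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 4:
            raise ValueError(f"need at least 4 nuclei, got {n}")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite nuclear coordinates")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for name, vals in self.channels.items():
            if vals.shape != (n,):
                raise ValueError(
                    f"channel {name!r} has length {vals.shape}, expected {n}"
                )

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class CylindricalProjection:
    """Cylindrical coordinates of a point cloud, channels carried through.

    ``axial`` is percent egg length in [0, 100]; ``angular`` is degrees in
    [0, 360), periodic.
    """

    axial: np.ndarray
    angular: np.ndarray
    channels: dict[str, np.ndarray]


@dataclass
class GridGeometry:
    """Coordinate axes of a gridded projection.

    ``angular`` holds the row-centre angles (degrees), ``axial`` the
    column-centre positions (%EL) — needed to interpolate grid images back
    onto nuclei.
    """

    angular: np.ndarray
    axial: np.ndarray


# --- point-cloud I/O ----------------------------------------------------------


def read_pointcloud(path, channel_names=None) -> NuclearPointCloud:
    """Read a delimited-text point cloud (one row per nucleus).

    The file carries '#' header lines, one of which names the columns, e.g.
    ``# columns: x y z hb ftz``.  Rows with a non-finite coordinate or a
    non-finite value in any requested channel are dropped (count logged).
    """
    path = Path(path)
    columns = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.lower().startswith("columns:"):
                columns = body.split(":", 1)[1].split()
    if columns is None:
        raise ValueError(f"{path}: no '# columns:' header line")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != len(columns):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns but {len(columns)} names"
        )
    frame = {name: data[:, i] for i, name in enumerate(columns)}
    for axis in ("x", "y", "z"):
        if axis not in frame:
            raise ValueError(f"{path}: missing coordinate column {axis!r}")
    available = [c for c in columns if c not in ("x", "y", "z", "id")]
    if channel_names is None:
        channel_names = available
    missing = [c for c in channel_names if c not in frame]
    if missing:
        raise ValueError(
            f"channel(s) {missing} not in file; available: {available}"
        )
    coords = np.column_stack([frame["x"], frame["y"], frame["z"]])
    keep = np.isfinite(coords).all(axis=1)
    for name in channel_names:
        keep &= np.isfinite(frame[name])
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("read_pointcloud: dropped %d row(s) with non-finite "
                       "values", dropped)
    ids = frame["id"][keep].astype(int) if "id" in frame else None
    return NuclearPointCloud(
        coords[keep],
        {name: frame[name][keep] for name in channel_names},
        ids=ids,
    )


def write_pointcloud(path, cloud: NuclearPointCloud) -> None:
    """Write a point cloud in the same dialect :func:`read_pointcloud` reads.

    Values are printed at full float64 precision so a write -> read round
    trip is bit-identical.
    """
    names = list(cloud.channels)
    cols = ["x", "y", "z"] + names
    blocks = [cloud.coords] + [cloud.channels[n][:, None] for n in names]
    if cloud.ids is not None:
        cols = ["id"] + cols
        blocks = [cloud.ids[:, None].astype(float)] + blocks
    data = np.hstack(blocks)
    header = "columns: " + " ".join(cols)
    np.savetxt(path, data, fmt="%.17g", header=header)


# --- projection ----------------------------------------------------------------


def major_axis(cloud: NuclearPointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Major (anteroposterior) axis of the embryo by PCA.

    Returns ``(axis, centroid)`` where ``axis`` is the unit first principal
    direction of the centered coordinates, its sign fixed so the first
    nonzero component is positive (deterministic under point permutation).
    """
    centroid = cloud.coords.mean(axis=0)
    centered = cloud.coords - centroid
    if np.abs(centered).max() == 0.0:
        raise ValueError("degenerate point cloud: all points coincide, "
                         "major axis undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis, centroid


def project_cylindrical(
    cloud: NuclearPointCloud,
    axis: np.ndarray | None = None,
    centroid: np.ndarray | None = None,
) -> CylindricalProjection:
    """Project nuclei onto a cylinder centred on the embryo's major axis.

    Axial position along the axis is rescaled to [0, 100] %EL; angular
    position is the azimuth (degrees, [0, 360)) about the axis in a
    deterministic orthonormal frame.  A point exactly on the axis gets
    angle 0 by convention.
    """
    if axis is None or centroid is None:
        axis, centroid = major_axis(cloud)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centered = cloud.coords - np.asarray(centroid, dtype=float)
    t = centered @ axis
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("all points project to one axial position")
    axial = (t - t.min()) / span * 100.0

    # deterministic frame orthogonal to the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    resid = centered - np.outer(t, axis)
    angular = np.degrees(np.arctan2(resid @ e2, resid @ e1)) % 360.0
    return CylindricalProjection(axial, angular, dict(cloud.channels))


# --- gridding -------------------------------------------------------------------


def to_grid(
    proj: CylindricalProjection,
    channel: str,
    step_percent: float = DEFAULT_STEP_PERCENT,
    clip_left: float = 20.0,
    clip_right: float = 5.0,
    angular_step: float = DEFAULT_ANGULAR_STEP,
) -> tuple[GridImage, GridGeometry]:
    """Interpolate a channel onto a regular cylindrical grid.

    Rows are angular bins (periodic), columns are axial bins covering
    ``[clip_left, 100 - clip_right]`` %EL in steps of ``step_percent``.
    Interpolation is Delaunay triangulation + linear interpolation on
    (axial, angular) points, with all points replicated at angular +-360 so
    the interpolant has no seam at the periodic boundary.  Grid nodes
    outside the convex hull of the replicated points are masked out.
    """
    if channel not in proj.channels:
        raise ValueError(
            f"channel {channel!r} not in projection; "
            f"available: {sorted(proj.channels)}"
        )
    lo, hi = float(clip_left), 100.0 - float(clip_right)
    if hi <= lo:
        raise ValueError(f"clipping removes everything: [{lo}, {hi}] empty")
    axial_nodes = np.arange(lo, hi + step_percent * 0.5, step_percent)
    if axial_nodes.size < 10:
        raise ValueError(
            f"only {axial_nodes.size} axial bins in [{lo}, {hi}] at step "
            f"{step_percent}; need >= 10"
        )
    n_rows = int(round(360.0 / angular_step))
    angular_nodes = np.arange(n_rows) * (360.0 / n_rows)

    in_band = (proj.axial >= lo) & (proj.axial <= hi)
    if int(in_band.sum()) < 4:
        raise ValueError(
            f"only {int(in_band.sum())} nuclei inside the retained axial "
            f"band [{lo}, {hi}] — cannot triangulate"
        )

    ax = proj.axial.astype(float).copy()
    ang = proj.angular.astype(float).copy()
    vals = np.asarray(proj.channels[channel], dtype=float)

    # nudge exact duplicates so the triangulation stays non-degenerate
    key = np.round(np.column_stack([ax, ang]), 9)
    _, first = np.unique(key, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(ax.size), first)
    if dup.size:
        logger.warning("to_grid: jittering %d duplicate (axial, angular) "
                       "point(s)", dup.size)
        ax[dup] += 1e-9 * (1 + np.arange(dup.size))

    pts = np.column_stack(
        [np.tile(ax, 3), np.concatenate([ang - 360.0, ang, ang + 360.0])]
    )
    interp = LinearNDInterpolator(pts, np.tile(vals, 3))
    grid_ax, grid_ang = np.meshgrid(axial_nodes, angular_nodes)
    grid = interp(grid_ax, grid_ang)
    mask = np.isfinite(grid)
    if not mask.any():
        raise ValueError("empty grid after clipping: no node falls inside "
                         "the data hull")
    image = GridImage(grid, mask, circular=(True, False))
    return image, GridGeometry(angular_nodes, axial_nodes)


def back_interpolate(
    image: GridImage, geometry: GridGeometry, proj: CylindricalProjection
) -> np.ndarray:
    """Interpolate a grid image back onto the nuclear centres.

    Bilinear interpolation on the regular grid with the angular axis
    extended periodically.  Nuclei outside the gridded region (axially
    clipped, or adjacent to masked-out nodes) receive the NO_DATA sentinel.
    """
    ang = geometry.angular
    vals = image.masked_values()
    ang_ext = np.concatenate([[ang[-1] - 360.0], ang, [ang[0] + 360.0]])
    vals_ext = np.vstack([vals[-1:], vals, vals[:1]])
    interp = RegularGridInterpolator(
        (ang_ext, geometry.axial),
        vals_ext,
        method="linear",
        bounds_error=False,
        fill_value=NO_DATA,
    )
    return interp(np.column_stack([proj.angular, proj.axial]))


def residual(
    cloud: NuclearPointCloud, channel: str, smooth: np.ndarray
) -> np.ndarray:
    """Per-nucleus residual: original channel minus back-interpolated smooth.

    NaN where the smooth component is undefined (nucleus outside the grid).
    """
    return np.asarray(cloud.channels[channel], dtype=float) - np.asarray(
        smooth, dtype=float
    )
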