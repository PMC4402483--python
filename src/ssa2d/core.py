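"""Core 2D singular spectrum analysis: embedding, SVD, grouping, reconstruction.

Singular spectrum analysis (SSA) decomposes a series or image into additive,
interpretable components (trend, regular oscillations, noise) without a prior
noise model.  The four steps are:

1. *Embedding*: slide a window over the image and stack the vectorized window
   contents as columns of a structured trajectory matrix (Hankel for a 1D
   series, Hankel-block-Hankel for a rectangular 2D window).
2. *Decomposition*: singular value decomposition of the trajectory matrix into
   eigentriples ``(sigma_i, U_i, V_i)``.
3. *Grouping*: partition eigentriple indices into groups that capture
   identifiable structure.
4. *Reconstruction*: project each grouped matrix back to image space by
   averaging all trajectory-matrix cells that map to the same pixel
   (diagonal averaging / hankelization, generalized per pixel).

Two extensions are supported on top of the rectangular method:

* **circular** embedding — windows may wrap across a periodic axis, which is
  what an unrolled cylindrical surface (e.g. an embryo projection) requires;
* **shaped** embedding — the image support (mask) and/or the window may be an
  arbitrary pixel set; a window placement is admissible iff every window
  offset lands on a supported pixel.

Public component indices are 1-based throughout (component 1 is the leading
eigentriple); internal arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.linalg import LinearOperator, svds

logger = logging.getLogger("ssa2d")

# --- package-wide defaults -------------------------------------------------

#: sentinel for pixels outside the support mask (never zero: zero is a
#: meaningful intensity).
NO_DATA = np.nan

#: trajectory matrices larger than this many cells go through the iterative
#: matrix-free solver instead of a dense SVD.  Dense LAPACK is fast and
#: robust up to a few 1e7 cells (the iterative solver converges poorly on
#: the near-degenerate noise spectra typical of these matrices), so the
#: matrix-free route is reserved for genuinely large embeddings.
DENSE_CELL_LIMIT = 50_000_000

#: default number of eigentriples to compute.
DEFAULT_MAX_COMPONENTS = 50

#: singular values below RANK_TOL * sigma_1 are treated as numerically zero.
RANK_TOL = 1e-10

#: default seed for any randomized solver step.
DEFAULT_SEED = 42


# --- domain types ----------------------------------------------------------


class GridImage:
    """A 2D numeric field on a regular grid with optional support mask.

    Rows index the DV/circumferential axis, columns the AP/axial axis.

    Parameters
    ----------
    values
        Real matrix of intensities.  Pixels outside the mask may hold the
        ``NO_DATA`` sentinel (NaN).
    mask
        Boolean support matrix of the same shape; ``True`` marks pixels that
        belong to the image.  Defaults to the finite entries of ``values``.
    circular
        Pair of flags ``(rows_circular, cols_circular)``; a circular axis is
        periodic, i.e. the first row/column continues the last.
    """

    __slots__ = ("values", "mask", "circular")

    def __init__(self, values, mask=None, circular=(False, False)):
        values = np.array(values, dtype=float, copy=True)
        if values.ndim != 2:
            raise ValueError(f"values must be 2D, got shape {values.shape}")
        if mask is None:
            mask = np.isfinite(values)
        else:
            mask = np.array(mask, dtype=bool, copy=True)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if not mask.any():
            raise ValueError("support mask has no true pixels")
        if not np.isfinite(values[mask]).all():
            raise ValueError("non-finite values under the support mask")
        self.values = values
        self.mask = mask
        self.circular = (bool(circular[0]), bool(circular[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> np.ndarray:
        """Values with the ``NO_DATA`` sentinel outside the mask."""
        out = np.where(self.mask, self.values, NO_DATA)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.shape
        return (
            f"GridImage({r}x{c}, {int(self.mask.sum())} supported, "
            f"circular={self.circular})"
        )


class WindowShape:
    """A moving window: a set of (row, col) offsets relative to its anchor.

    A rectangular L1 x L2 window is the full offset grid
    ``{0..L1-1} x {0..L2-1}``; any non-empty subset gives a *shaped* window.
    Offsets are normalized so the minimal row and column offsets are zero,
    and stored in row-major order (this fixes the vectorization order of
    window elements in trajectory-matrix columns).
    """

    __slots__ = ("offsets",)

    def __init__(self, offsets: Iterable[tuple[int, int]]):
        offs = sorted({(int(r), int(c)) for r, c in offsets})
        if not offs:
            raise ValueError("window must contain at least one offset")
        rmin = min(r for r, _ in offs)
        cmin = min(c for _, c in offs)
        self.offsets = tuple((r - rmin, c - cmin) for r, c in offs)

    @classmethod
    def rectangular(cls, l1: int, l2: int) -> "WindowShape":
        """Full L1 x L2 rectangular window (rows x cols)."""
        if l1 < 1 or l2 < 1:
            raise ValueError(f"window sides must be >= 1, got {l1}x{l2}")
        return cls((r, c) for r in range(l1) for c in range(l2))

    @classmethod
    def from_mask(cls, mask) -> "WindowShape":
        """Window from a boolean matrix (True pixels form the window)."""
        mask = np.asarray(mask, dtype=bool)
        rr, cc = np.nonzero(mask)
        return cls(zip(rr.tolist(), cc.tolist()))

    @property
    def shape(self) -> tuple[int, int]:
        """Bounding-box size (L1, L2)."""
        return (
            max(r for r, _ in self.offsets) + 1,
            max(c for _, c in self.offsets) + 1,
        )

    @property
    def size(self) -> int:
        return len(self.offsets)

    @property
    def is_rectangular(self) -> bool:
        l1, l2 = self.shape
        return self.size == l1 * l2

    def offset_array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=int)

    def to_mask(self) -> np.ndarray:
        l1, l2 = self.shape
        m = np.zeros((l1, l2), dtype=bool)
        off = self.offset_array()
        m[off[:, 0], off[:, 1]] = True
        return m

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        l1, l2 = self.shape
        kind = "rect" if self.is_rectangular else "shaped"
        return f"WindowShape({kind} {l1}x{l2}, {self.size} offsets)"


@dataclass
class TrajectoryMatrix:
    """The trajectory matrix X = T(image) plus its cell-to-pixel index map.

    ``pixel_index[i, k]`` is the flat image-pixel index that cell
    ``(offset i, position k)`` of the trajectory matrix reads from, so the
    dense matrix is simply ``image.values.ravel()[pixel_index]``.  The
    ``weights`` field counts, per pixel, how many trajectory cells cover it —
    the divisor of diagonal averaging at reconstruction.
    """

    image: GridImage
    window: WindowShape
    pixel_index: np.ndarray  # (n_offsets, K) int
    positions: np.ndarray  # (K, 2) anchor (row, col)
    weights: np.ndarray  # image-shaped int cover counts
    _dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_index.shape

    @property
    def ncells(self) -> int:
        return self.pixel_index.size

    def to_dense(self) -> np.ndarray:
        """Materialize the trajectory matrix (cached)."""
        if self._dense is None:
            self._dense = self.image.values.ravel()[self.pixel_index]
        return self._dense

    @property
    def matrix(self) -> np.ndarray:
        return self.to_dense()

    def operator(self, chunk_cells: int = 4_000_000) -> LinearOperator:
        """Matrix-free linear operator for the iterative SVD solver.

        Products are computed by gathering image values through the pixel
        index map in column chunks, never materializing the full matrix.
        """
        flat = self.image.values.ravel()
        idx = self.pixel_index
        m, k = idx.shape
        step = max(1, chunk_cells // max(m, 1))

        def matvec(v):
            v = np.asarray(v, dtype=float).ravel()
            out = np.zeros(m)
            for s in range(0, k, step):
                sl = slice(s, min(s + step, k))
                out += flat[idx[:, sl]] @ v[sl]
            return out

        def rmatvec(u):
            u = np.asarray(u, dtype=float).ravel()
            out = np.empty(k)
            for s in range(0, k, step):
                sl = slice(s, min(s + step, k))
                out[sl] = u @ flat[idx[:, sl]]
            return out

        return LinearOperator(
            (m, k), matvec=matvec, rmatvec=rmatvec, dtype=float
        )

    def frobenius_sq(self) -> float:
        """Squared Frobenius norm, via cover counts (no materialization)."""
        vals = np.where(self.image.mask, self.image.values, 0.0)
        return float(np.sum(self.weights * vals * vals))


@dataclass(frozen=True)
class Eigentriple:
    """One SVD term of the trajectory matrix: (sigma, U, V).

    ``U`` lives in window space (length = number of window offsets), ``V`` in
    position space (length = number of admissible anchors).  ``eigenimage``
    reshapes U onto the window bounding box (NaN off the window's offsets).
    """

    sigma: float
    U: np.ndarray
    V: np.ndarray
    window: WindowShape

    @property
    def eigenimage(self) -> np.ndarray:
        l1, l2 = self.window.shape
        img = np.full((l1, l2), np.nan)
        off = self.window.offset_array()
        img[off[:, 0], off[:, 1]] = self.U
        return img


@dataclass
class Decomposition:
    """Result of an SSA run: ordered eigentriples + grouping + components.

    ``grouping`` is a partition (list of tuples) of 1-based eigentriple
    indices; ``components`` holds the corresponding reconstructions, one
    GridImage per group, which sum to the rank-d approximation of the source
    (the source itself when d is the full rank).
    """

    source: GridImage
    window: WindowShape
    trajectory: TrajectoryMatrix
    eigentriples: list[Eigentriple]
    grouping: list[tuple[int, ...]]
    components: list[GridImage]

    @property
    def d(self) -> int:
        return len(self.eigentriples)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([et.sigma for et in self.eigentriples])

    def reconstruct(self, group: Iterable[int]) -> GridImage:
        """Reconstruct the image component for a set of 1-based indices."""
        return reconstruct(self.trajectory, self.eigentriples, group)


# --- step 1: embedding -------------------------------------------------------


def embed(image: GridImage, window: WindowShape) -> TrajectoryMatrix:
    """Build the trajectory matrix of ``image`` under a moving ``window``.

    One column per admissible anchor position; anchors are enumerated
    row-major (anchor row outer loop), and within each column the window
    elements appear in row-major offset order.  On a circular axis the
    window may wrap across the image boundary; on a non-circular axis it
    must fit inside.  A placement is admissible iff every window offset
    lands on a mask-true pixel.
    """
    rows, cols = image.shape
    l1, l2 = window.shape
    if l1 > rows or l2 > cols:
        raise ValueError(
            f"window bounding box {l1}x{l2} exceeds image {rows}x{cols}"
        )
    circ_r, circ_c = image.circular
    anchor_r = np.arange(rows if circ_r else rows - l1 + 1)
    anchor_c = np.arange(cols if circ_c else cols - l2 + 1)
    off = window.offset_array()  # (m, 2), row-major sorted

    pr = anchor_r[None, :] + off[:, 0:1]  # (m, nar)
    pc = anchor_c[None, :] + off[:, 1:2]  # (m, nac)
    if circ_r:
        pr = pr % rows
    if circ_c:
        pc = pc % cols

    # flat pixel index per (offset, anchor_row, anchor_col)
    idx = (pr[:, :, None] * cols + pc[:, None, :]).reshape(off.shape[0], -1)
    admissible = image.mask.ravel()[idx].all(axis=0)
    if not admissible.any():
        raise ValueError(
            f"no admissible window positions: window {l1}x{l2} "
            f"({window.size} offsets) does not fit the "
            f"{int(image.mask.sum())}-pixel mask of a {rows}x{cols} image"
        )
    idx = np.ascontiguousarray(idx[:, admissible])

    grid_r, grid_c = np.meshgrid(anchor_r, anchor_c, indexing="ij")
    positions = np.column_stack(
        [grid_r.ravel()[admissible], grid_c.ravel()[admissible]]
    )
    weights = np.bincount(idx.ravel(), minlength=rows * cols).reshape(
        rows, cols
    )
    return TrajectoryMatrix(image, window, idx, positions, weights)


# --- step 2: decomposition ---------------------------------------------------


def decompose(
    traj: TrajectoryMatrix,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    rank_tol: float = RANK_TOL,
    seed: int = DEFAULT_SEED,
) -> list[Eigentriple]:
    """SVD of the trajectory matrix, returning leading eigentriples.

    Eigentriples are sorted by nonincreasing singular value; numerically
    zero singular values (below ``rank_tol`` relative to the largest) are
    dropped, so an all-zero matrix yields an empty list.  Small matrices go
    through a dense SVD; matrices above ``DENSE_CELL_LIMIT`` cells use a
    seeded iterative solver on the matrix-free operator.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    m, k = traj.shape
    kmax = min(m, k)

    if traj.ncells <= DENSE_CELL_LIMIT or min(max_components, kmax) >= kmax - 1:
        u, s, vt = np.linalg.svd(traj.to_dense(), full_matrices=False)
        u, s, vt = u[:, :max_components], s[:max_components], vt[:max_components]
    else:
        ncomp = min(max_components, kmax - 1)
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(kmax)
        u, s, vt = svds(traj.operator(), k=ncomp, v0=v0, tol=1e-10)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]

    if s.size == 0 or s[0] <= 0.0:
        return []
    keep = s > s[0] * rank_tol
    triples = []
    for i in np.nonzero(keep)[0]:
        ui, vi = u[:, i].copy(), vt[i].copy()
        # deterministic sign: the largest-magnitude element of U is positive
        j = int(np.argmax(np.abs(ui)))
        if ui[j] < 0:
            ui, vi = -ui, -vi
        triples.append(Eigentriple(float(s[i]), ui, vi, traj.window))
    return triples


# --- step 4: reconstruction (step 3, grouping, is just index bookkeeping) ----


def reconstruct(
    traj: TrajectoryMatrix,
    eigentriples: Sequence[Eigentriple],
    group: Iterable[int],
) -> GridImage:
    """Reconstruct the image component for a group of 1-based indices.

    Computes the grouped low-rank matrix ``sum_i sigma_i U_i V_i^T`` and
    projects it back to image space by per-pixel averaging over all
    trajectory cells covering each pixel (diagonal averaging generalized to
    shaped/circular embeddings).  Pixels never covered by a window carry the
    ``NO_DATA`` sentinel and are dropped from the output mask.
    """
    d = len(eigentriples)
    gidx = sorted({int(g) for g in group})
    bad = [g for g in gidx if g < 1 or g > d]
    if bad:
        raise IndexError(
            f"group references missing component indices {bad} (1..{d} exist)"
        )
    rows, cols = traj.image.shape
    acc = np.zeros(rows * cols)
    if gidx:
        ug = np.column_stack([eigentriples[g - 1].U for g in gidx])
        vg = np.column_stack([eigentriples[g - 1].V for g in gidx])
        sg = np.array([eigentriples[g - 1].sigma for g in gidx])
        idx = traj.pixel_index
        m, k = idx.shape
        step = max(1, 4_000_000 // max(k, 1))
        for s in range(0, m, step):
            sl = slice(s, min(s + step, m))
            block = (ug[sl] * sg) @ vg.T  # (chunk, K)
            np.add.at(acc, idx[sl].ravel(), block.ravel())

    w = traj.weights.ravel().astype(float)
    covered = w > 0
    vals = np.full(rows * cols, NO_DATA)
    vals[covered] = acc[covered] / w[covered]
    mask = traj.image.mask & (traj.weights > 0)
    return GridImage(vals.reshape(rows, cols), mask, traj.image.circular)


# --- high-level drivers -------------------------------------------------------


def decompose_image(
    image: GridImage,
    window: WindowShape,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    grouping: Sequence[Iterable[int]] | None = None,
    rank_tol: float = RANK_TOL,
    seed: int = DEFAULT_SEED,
) -> Decomposition:
    """Run embed -> decompose -> reconstruct and package the result.

    ``grouping`` defaults to the elementary grouping {1}, {2}, ..., {d}.
    """
    traj = embed(image, window)
    ets = decompose(traj, max_components=max_components, rank_tol=rank_tol,
                    seed=seed)
    if grouping is None:
        groups = [(i,) for i in range(1, len(ets) + 1)]
    else:
        groups = [tuple(sorted(int(i) for i in g)) for g in grouping]
        seen: set[int] = set()
        for g in groups:
            if seen & set(g):
                raise ValueError(f"grouping is not disjoint at {g}")
            seen |= set(g)
            if any(i < 1 or i > len(ets) for i in g):
                raise IndexError(
                    f"group {g} outside available components 1..{len(ets)}"
                )
    comps = [reconstruct(traj, ets, g) for g in groups]
    return Decomposition(image, window, traj, ets, groups, comps)


def elementary_components(
    image: GridImage,
    window: WindowShape,
    n: int = DEFAULT_MAX_COMPONENTS,
    **kwargs,
) -> Decomposition:
    """Elementary decomposition: singleton groups {1}, ..., {min(n, d)}.

    The components sum to the rank-n approximation of the image (the image
    itself on covered pixels when n reaches the full rank).
    """
    return decompose_image(image, window, max_components=n, grouping=None,
                           **kwargs)


def ssa_1d(series, L: int, n: int | None = None, **kwargs) -> Decomposition:
    """1D SSA of a series with window length L.

    Equivalent to 2D-SSA on the N x 1 image with an L x 1 window; the
    trajectory matrix is the classical L x (N - L + 1) Hankel matrix with
    columns ``(x_1..x_L), (x_2..x_{L+1}), ...``.
    """
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if not 2 <= L <= N - 1:
        raise ValueError(f"window length L={L} outside 2..{N - 1} for N={N}")
    image = GridImage(x.reshape(-1, 1))
    if n is None:
        n = min(L, N - L + 1)
    return elementary_components(image, WindowShape.rectangular(L, 1), n,
                                 **kwargs)


def component_series(decomp: Decomposition) -> list[np.ndarray]:
    """Extract 1D component series from an N x 1 decomposition."""
    return [c.values[:, 0] for c in decomp.components]


# --- GridImage and decomposition I/O ------------------------------------------


def _circ_token(circular: tuple[bool, bool]) -> str:
    return {
        (False, False): "none",
        (True, False): "rows",
        (False, True): "cols",
        (True, True): "both",
    }[circular]


def _parse_circ(token: str) -> tuple[bool, bool]:
    table = {
        "none": (False, False),
        "rows": (True, False),
        "cols": (False, True),
        "both": (True, True),
    }
    try:
        return table[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown circular flag {token!r}") from None


def write_grid_image(
    path,
    image: GridImage,
    mask_path=None,
    axes: tuple[str, str] = ("dv", "ap"),
    fmt: str = "%.17g",
) -> None:
    """Write a GridImage as delimited text with a '#' comment header.

    Off-mask pixels are written as ``nan``.  If ``mask_path`` is given the
    support mask is written alongside as a parallel 0/1 matrix.
    """
    header = f"axes: {axes[0]} {axes[1]}\ncircular: {_circ_token(image.circular)}"
    np.savetxt(path, image.masked_values(), fmt=fmt, header=header)
    if mask_path is not None:
        np.savetxt(mask_path, image.mask.astype(int), fmt="%d")


def read_grid_image(path, mask_path=None) -> GridImage:
    """Read a GridImage written by :func:`write_grid_image`.

    The circular flags are recovered from the '#' header (defaulting to
    non-circular); the mask comes from ``mask_path`` if given, else from the
    finite entries.  Both tab/space and comma delimiters are accepted.
    """
    path = Path(path)
    circular = (False, False)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.lower().startswith("circular:"):
                circular = _parse_circ(body.split(":", 1)[1])
    text = path.read_text()
    delimiter = "," if ("," in text.splitlines()[-1]) else None
    values = np.loadtxt(path, comments="#", delimiter=delimiter, ndmin=2)
    mask = None
    if mask_path is not None:
        mask = np.loadtxt(mask_path, comments="#", delimiter=delimiter,
                          ndmin=2).astype(bool)
    return GridImage(values, mask, circular)


def read_tiff_image(path, circular=(False, False), mask=None) -> GridImage:
    """Read a single-channel grayscale TIFF as a GridImage."""
    import tifffile

    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a single-channel TIFF, got {values.shape}")
    return GridImage(values, mask, circular)


def write_tiff_image(path, image: GridImage) -> None:
    import tifffile

    tifffile.imwrite(path, image.masked_values().astype(np.float32))


def save_decomposition(dirpath, decomp: Decomposition) -> None:
    """Persist a decomposition: one matrix file per component + manifest."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    off = ";".join(f"{r},{c}" for r, c in decomp.window.offsets)
    l1, l2 = decomp.window.shape
    lines = [
        f"window_shape={l1}x{l2}",
        f"window_offsets={off}",
        f"circular={_circ_token(decomp.source.circular)}",
        f"n_eigentriples={decomp.d}",
        "sigmas=" + ",".join(f"{s:.17g}" for s in decomp.sigmas),
        "grouping=" + "|".join(",".join(map(str, g)) for g in decomp.grouping),
        f"n_components={len(decomp.components)}",
    ]
    (dirpath / "manifest.txt").write_text("\n".join(lines) + "\n")
    for i, comp in enumerate(decomp.components, start=1):
        write_grid_image(dirpath / f"component_{i:02d}.txt", comp)


def load_decomposition(dirpath) -> dict:
    """Load a persisted decomposition directory.

    Returns a dict with keys ``window`` (WindowShape), ``circular``,
    ``sigmas``, ``grouping`` and ``components`` (list of GridImage) — the
    reconstruction artifacts, not the full eigentriple set.
    """
    dirpath = Path(dirpath)
    meta: dict[str, str] = {}
    for line in (dirpath / "manifest.txt").read_text().splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            meta[key.strip()] = val.strip()
    offsets = [
        tuple(int(x) for x in pair.split(","))
        for pair in meta["window_offsets"].split(";")
    ]
    sigmas = (
        np.array([float(s) for s in meta["sigmas"].split(",")])
        if meta.get("sigmas")
        else np.array([])
    )
    grouping = [
        tuple(int(i) for i in g.split(","))
        for g in meta["grouping"].split("|")
        if g
    ]
    ncomp = int(meta["n_components"])
    comps = [
        read_grid_image(dirpath / f"component_{i:02d}.txt")
        for i in range(1, ncomp + 1)
    ]
    return {
        "window": WindowShape(offsets),
        "circular": _parse_circ(meta.get("circular", "none")),
        "sigmas": sigmas,
        "grouping": grouping,
        "components": comps,
    }
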