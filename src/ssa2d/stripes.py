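"""Stripe boundary extraction and central-stripe shape classification.

Pair-rule genes (*eve*, *ftz*) express in seven stripes transverse to the
anteroposterior axis.  Given a zero-mean oscillatory SSA reconstruction of
the striped signal (e.g. the two leading oscillatory components), stripe
boundaries are defined by the sign change: thresholding at zero converts
the reconstruction to black and white, and the positive connected regions
are the stripes.  On an unrolled cylindrical projection the row axis is
periodic, so connectivity wraps across the top/bottom seam.

The stripes are labelled 1..n from anterior to posterior; each stripe gets
an anterior and a posterior boundary polyline and a per-row axial midpoint
(centerline).  The centerline of the central stripe is then classified into
the shapes observed in real embryos: *straight*, forward *C*, *reverse-C*,
or *S*.  The classification fits the centerline with orthogonal (Legendre)
polynomials of the row coordinate: a flat centerline is straight; a
dominant quadratic term bends the stripe into a C (sign gives direction); a
dominant cubic term makes an S.  These qualitative classes are codified
quantitatively here with exposed thresholds — the flatness tolerance and
the quadratic/cubic dominance ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage

from .core import GridImage

logger = logging.getLogger("ssa2d")

#: default minimum connected-region area (pixels); smaller specks dropped.
MIN_AREA = 8

#: flatness tolerance for the 'straight' class, in axial units (columns by
#: default; ~1% egg length at the default 0.5%EL grid step).
STRAIGHT_TOL = 2.0

#: how many times larger one polynomial term must be to dominate the other.
DOMINANCE_RATIO = 2.0

SHAPE_CLASSES = ("straight", "C", "reverse-C", "S")


@dataclass(frozen=True)
class Stripe:
    """One labelled positive-sign region."""

    id: int  # 1-based, anterior -> posterior
    rows: np.ndarray  # rows the stripe spans (unwrapped order)
    anterior: np.ndarray  # (len(rows),) anterior boundary column per row
    posterior: np.ndarray  # (len(rows),) posterior boundary column per row

    @property
    def centerline(self) -> np.ndarray:
        return 0.5 * (self.anterior + self.posterior)


@dataclass
class StripeSet:
    """Thresholded stripe regions of one reconstruction."""

    binary: GridImage  # 0/1 image of the positive-sign support
    labels: np.ndarray  # int image, 0 = background, 1..n = stripes
    stripes: list[Stripe]

    @property
    def count(self) -> int:
        return len(self.stripes)


@dataclass(frozen=True)
class StripeShape:
    """Shape classification of one stripe's centerline."""

    stripe_id: int
    rows: np.ndarray
    centerline: np.ndarray  # axial midpoint per row, in axial units
    shape_class: str
    bend: float  # signed quadratic (Legendre) coefficient, axial units


def _unwrap_rows(present: np.ndarray, circular: bool) -> np.ndarray:
    """Order the rows a stripe spans, unrolling across a periodic seam.

    ``present`` is a boolean row-indicator.  If the stripe touches both the
    first and last row of a circular axis, the span is rotated to start
    after the largest absent gap so the returned order is contiguous.
    """
    n = present.size
    rows = np.nonzero(present)[0]
    if not circular or rows.size in (0, n) or not (present[0] and present[-1]):
        return rows
    absent = np.nonzero(~present)[0]
    start = (absent[-1] + 1) % n
    order = (start + np.arange(n)) % n
    return order[present[order]]


def threshold_boundaries(
    rec: GridImage, min_area: int = MIN_AREA
) -> StripeSet:
    """Extract stripes from a zero-mean reconstruction by sign thresholding.

    Positive pixels (on the support mask) form the binary stripe image;
    connected regions (4-connectivity, wrapping across the row seam when
    the row axis is circular) are labelled, regions below ``min_area``
    pixels are dropped (logged), and the survivors are renumbered 1..n by
    increasing mean axial (column) position.
    """
    positive = (rec.values > 0) & rec.mask
    if not positive.any():
        raise ValueError("no positive region: the reconstruction never "
                         "exceeds zero on its support")
    labels, nlab = ndimage.label(positive)
    if rec.circular[0] and nlab > 1:
        # merge labels that touch across the periodic row seam
        parent = list(range(nlab + 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        top, bottom = labels[0], labels[-1]
        for a, b in zip(top, bottom):
            if a > 0 and b > 0 and find(a) != find(b):
                parent[find(a)] = find(b)
        remap = np.array([find(i) for i in range(nlab + 1)])
        labels = remap[labels]

    ids = [i for i in np.unique(labels) if i != 0]
    sizes = {i: int((labels == i).sum()) for i in ids}
    small = [i for i in ids if sizes[i] < min_area]
    if small:
        logger.info("threshold_boundaries: dropping %d region(s) below "
                    "%d px", len(small), min_area)
        for i in small:
            labels[labels == i] = 0
        ids = [i for i in ids if i not in small]
    if not ids:
        raise ValueError(
            f"no positive region of at least {min_area} pixels"
        )

    # anterior -> posterior ordering by mean column
    mean_col = {i: float(np.nonzero(labels == i)[1].mean()) for i in ids}
    ordered = sorted(ids, key=lambda i: mean_col[i])
    out_labels = np.zeros_like(labels)
    stripes: list[Stripe] = []
    for new_id, old in enumerate(ordered, start=1):
        region = labels == old
        out_labels[region] = new_id
        rows = _unwrap_rows(region.any(axis=1), rec.circular[0])
        anterior = np.array(
            [np.nonzero(region[r])[0].min() for r in rows], dtype=float
        )
        posterior = np.array(
            [np.nonzero(region[r])[0].max() for r in rows], dtype=float
        )
        stripes.append(Stripe(new_id, rows, anterior, posterior))

    binary = GridImage(
        positive.astype(float), rec.mask, circular=rec.circular
    )
    return StripeSet(binary, out_labels, stripes)


def classify_shape(
    stripe_set: StripeSet,
    stripe_id: int,
    straight_tol: float = STRAIGHT_TOL,
    dominance: float = DOMINANCE_RATIO,
    axial_scale: float = 1.0,
    min_rows: int = 8,
) -> StripeShape:
    """Classify one stripe's centerline as straight / C / reverse-C / S.

    The per-row axial midpoint is fitted with Legendre polynomials of the
    normalized row coordinate (the stripe's own span mapped to [-1, 1];
    circular rows are already unrolled around the stripe).  Rules:

    * max deviation of the centerline from its mean below ``straight_tol``
      (in axial units — pass ``axial_scale`` = %EL per column to work in
      percent egg length) -> ``straight``;
    * |quadratic| >= ``dominance`` x |cubic| -> ``C`` if the quadratic
      coefficient is positive (ends bent toward larger axial values),
      ``reverse-C`` if negative;
    * |cubic| >= ``dominance`` x |quadratic| -> ``S``;
    * otherwise the larger of the two terms decides.

    The signed quadratic coefficient is returned as the bend statistic.
    """
    matches = [s for s in stripe_set.stripes if s.id == stripe_id]
    if not matches:
        raise IndexError(
            f"no stripe {stripe_id}; set holds 1..{stripe_set.count}"
        )
    stripe = matches[0]
    nrows = stripe.rows.size
    if nrows < min_rows:
        raise ValueError(
            f"stripe {stripe_id} spans only {nrows} rows; need >= {min_rows} "
            f"for shape classification"
        )
    center = stripe.centerline * float(axial_scale)
    t = np.linspace(-1.0, 1.0, nrows)
    coef = legendre.legfit(t, center, 3)
    c2, c3 = float(coef[2]), float(coef[3])

    if np.max(np.abs(center - center.mean())) < straight_tol:
        shape = "straight"
    elif abs(c2) >= dominance * abs(c3):
        shape = "C" if c2 > 0 else "reverse-C"
    elif abs(c3) >= dominance * abs(c2):
        shape = "S"
    elif abs(c3) > abs(c2):
        shape = "S"
    else:
        shape = "C" if c2 > 0 else "reverse-C"
    return StripeShape(stripe_id, stripe.rows, center, shape, c2)


def boundary_table(stripe_set: StripeSet) -> np.ndarray:
    """Flatten all boundaries to rows of (stripe_id, row, boundary, axial).

    ``boundary`` is 0 for the anterior polyline, 1 for the posterior; the
    result is ready for delimited-text export.
    """
    rows = []
    for s in stripe_set.stripes:
        for r, a, p in zip(s.rows, s.anterior, s.posterior):
            rows.append((s.id, int(r), 0, float(a)))
            rows.append((s.id, int(r), 1, float(p)))
    return np.array(rows, dtype=float)
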