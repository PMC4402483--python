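"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ssa2d import GridImage, WindowShape


def brute_force_embed(values, mask, offsets, circular):
    """Independent trajectory-matrix oracle: try every anchor, check mask.

    Enumerates anchors row-major over the full anchor grid, places every
    window offset (wrapping only on circular axes), and keeps the column iff
    all offsets land on mask-true pixels.  Returns (matrix, anchors) with
    window elements in row-major offset order.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    rows, cols = values.shape
    circ_r, circ_c = circular
    offs = sorted((int(r), int(c)) for r, c in offsets)
    l1 = max(r for r, _ in offs) + 1
    l2 = max(c for _, c in offs) + 1
    columns, anchors = [], []
    for ar in range(rows if circ_r else rows - l1 + 1):
        for ac in range(cols if circ_c else cols - l2 + 1):
            pix = []
            ok = True
            for dr, dc in offs:
                r, c = ar + dr, ac + dc
                if circ_r:
                    r %= rows
                if circ_c:
                    c %= cols
                if r >= rows or c >= cols or not mask[r, c]:
                    ok = False
                    break
                pix.append(values[r, c])
            if ok:
                columns.append(pix)
                anchors.append((ar, ac))
    if not columns:
        return np.zeros((len(offs), 0)), []
    return np.array(columns).T, anchors


def random_instance(rng, max_side=8):
    """One random (image, window) pair for randomized embedding checks.

    Guarantees at least one admissible placement by retrying; windows are
    rectangular or shaped (random subset of a bounding box), masks lose a
    few random pixels, circular flags are random per axis.
    """
    while True:
        rows = int(rng.integers(2, max_side + 1))
        cols = int(rng.integers(2, max_side + 1))
        values = rng.standard_normal((rows, cols))
        mask = np.ones((rows, cols), dtype=bool)
        n_holes = int(rng.integers(0, max(1, rows * cols // 6)))
        if n_holes:
            holes = rng.choice(rows * cols, size=n_holes, replace=False)
            mask.ravel()[holes] = False
        if not mask.any():
            continue
        l1 = int(rng.integers(1, rows + 1))
        l2 = int(rng.integers(1, cols + 1))
        if rng.random() < 0.5:
            window = WindowShape.rectangular(l1, l2)
        else:
            wmask = rng.random((l1, l2)) < 0.6
            if not wmask.any():
                continue
            window = WindowShape.from_mask(wmask)
        circular = (bool(rng.random() < 0.5), bool(rng.random() < 0.5))
        oracle, anchors = brute_force_embed(
            values, mask, window.offsets, circular
        )
        if not anchors:
            continue
        image = GridImage(np.where(mask, values, np.nan), mask, circular)
        return image, window, oracle, anchors


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_101)
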