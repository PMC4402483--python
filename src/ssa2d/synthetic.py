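"""Synthetic embryo generator: ground truth for every other module.

Emulates the statistical structure of per-nucleus gene-expression atlases
of the early *Drosophila* blastoderm:

* ~6000 nuclei quasi-uniformly covering a prolate-ellipsoidal shell
  (semi-axes a > b = c), placed on a deterministic Fibonacci lattice so
  triangulations are reproducible;
* a *gap-gene* channel: a smooth, low-frequency anteroposterior profile
  (logistic boundary, anterior-high by default, like *hb*);
* a *pair-rule* channel: a periodic 7-stripe profile along the axis, with
  an optional row-dependent phase bend that curves the stripes into C or S
  shapes;
* signed linear crosstalk: the observed gap channel is
  ``gap + alpha * pairrule`` — a negative ``alpha`` emulates an unmixing
  *overcorrection* (partial subtraction of the reference pattern), a
  positive one an *undercorrection* (partial addition);
* intensity-dependent noise: independent Gaussian per nucleus with
  ``sd = eta * |signal| + eta0`` (multiplicative plus floor).

The generator also evaluates the same fields directly on a regular grid
(:func:`generate_grid`), bypassing projection, for fast core tests.
All randomness is drawn from a seeded generator; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GridImage
from .preprocessing import NuclearPointCloud

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

BEND_SHAPES = ("none", "C", "reverse-C", "S")


@dataclass(frozen=True)
class EmbryoSpec:
    """Parameters of one synthetic embryo.

    Lengths are microns; expression amplitudes are normalized to [0, 1];
    ``axial`` coordinates inside the profiles are percent egg length.
    """

    n_nuclei: int = 6000
    semi_axes: tuple[float, float, float] = (250.0, 95.0, 95.0)
    # gap gene: anterior-high logistic boundary
    gap_center: float = 47.0  # boundary position, %EL
    gap_width: float = 4.0  # boundary steepness scale, %EL
    gap_amplitude: float = 1.0
    # pair-rule: 7 stripes across the egg
    stripe_count: int = 7
    stripe_phase: float = 0.0  # axial phase offset, %EL
    stripe_amplitude: float = 1.0
    bend_shape: str = "none"  # none | C | reverse-C | S
    bend_amplitude: float = 0.0  # peak axial phase shift, %EL
    # signed linear crosstalk into the gap channel
    crosstalk: float = 0.0  # alpha; <0 overcorrection, >0 undercorrection
    # noise: sd = eta * |signal| + eta0
    noise_eta: float = 0.05
    noise_floor: float = 0.01
    jitter: float = 0.0  # optional positional jitter, microns
    seed: int = 42

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a > 0 and b > 0 and c > 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if not (a > b and b == c):
            raise ValueError(
                f"need a prolate spheroid a > b = c, got {self.semi_axes}"
            )
        if self.n_nuclei < 100:
            raise ValueError(f"n_nuclei must be >= 100, got {self.n_nuclei}")
        for name in ("gap_amplitude", "stripe_amplitude", "noise_eta",
                     "noise_floor", "bend_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bend_shape not in BEND_SHAPES:
            raise ValueError(
                f"bend_shape must be one of {BEND_SHAPES}, "
                f"got {self.bend_shape!r}"
            )


def gap_profile(axial, spec: EmbryoSpec) -> np.ndarray:
    """Smooth anterior-high logistic trend, evaluated at %EL positions."""
    x = np.asarray(axial, dtype=float)
    return spec.gap_amplitude / (
        1.0 + np.exp((x - spec.gap_center) / spec.gap_width)
    )


def _bend_offset(angular, spec: EmbryoSpec) -> np.ndarray:
    """Row-dependent axial phase shift (in %EL) producing curved stripes.

    ``u`` runs from -1 at the seam through 0 at the ventral midline
    (180 deg) back to +1, so a quadratic bend is symmetric about the
    midline (C shapes) and a cubic one is antisymmetric (S shapes).
    """
    u = (np.asarray(angular, dtype=float) - 180.0) / 180.0
    if spec.bend_shape == "none" or spec.bend_amplitude == 0.0:
        return np.zeros_like(u)
    if spec.bend_shape == "C":
        return spec.bend_amplitude * u**2
    if spec.bend_shape == "reverse-C":
        return -spec.bend_amplitude * u**2
    return spec.bend_amplitude * u**3  # 'S'


def pairrule_profile(axial, angular, spec: EmbryoSpec) -> np.ndarray:
    """Periodic stripe profile: ``stripe_count`` stripes over 0..100 %EL.

    Nonnegative (raised sinusoid); the row-dependent bend shifts the
    stripe positions axially.
    """
    x = np.asarray(axial, dtype=float) - spec.stripe_phase
    x = x - _bend_offset(angular, spec)
    return spec.stripe_amplitude * 0.5 * (
        1.0 + np.sin(2.0 * np.pi * spec.stripe_count * x / 100.0)
    )


def _noisy(clean: np.ndarray, spec: EmbryoSpec, rng) -> np.ndarray:
    sd = spec.noise_eta * np.abs(clean) + spec.noise_floor
    return clean + sd * rng.standard_normal(clean.shape)


def fibonacci_shell(n: int, semi_axes) -> np.ndarray:
    """Quasi-uniform deterministic point set on an ellipsoid shell.

    Fibonacci sphere lattice scaled to the semi-axes; the major (a) axis is
    laid along x.
    """
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n  # along the major axis
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * GOLDEN_ANGLE
    a, b, c = semi_axes
    return np.column_stack([a * z, b * r * np.cos(phi), c * r * np.sin(phi)])


def generate(spec: EmbryoSpec) -> tuple[NuclearPointCloud, pd.DataFrame]:
    """Generate one synthetic embryo.

    Returns the observed point cloud (channels ``gap`` and ``pairrule``,
    both with noise; ``gap`` additionally carries the crosstalk term) and a
    ground-truth table with the noiseless per-nucleus components.
    """
    rng = np.random.default_rng(spec.seed)
    coords = fibonacci_shell(spec.n_nuclei, spec.semi_axes)
    if spec.jitter > 0:
        coords = coords + spec.jitter * rng.standard_normal(coords.shape)

    x = coords[:, 0]
    axial = (x - x.min()) / (x.max() - x.min()) * 100.0
    angular = np.degrees(np.arctan2(coords[:, 2], coords[:, 1])) % 360.0

    gap_true = gap_profile(axial, spec)
    pr_true = pairrule_profile(axial, angular, spec)
    crosstalk = spec.crosstalk * pr_true

    gap_obs = _noisy(gap_true + crosstalk, spec, rng)
    pr_obs = _noisy(pr_true, spec, rng)

    cloud = NuclearPointCloud(
        coords, {"gap": gap_obs, "pairrule": pr_obs}
    )
    truth = pd.DataFrame(
        {
            "axial": axial,
            "angular": angular,
            "gap_true": gap_true,
            "pairrule_true": pr_true,
            "crosstalk": crosstalk,
            "gap_observed": gap_obs,
            "pairrule_observed": pr_obs,
        }
    )
    return cloud, truth


@dataclass
class GridTruth:
    """Analytic grid fields: observed = trend + stripes + noise."""

    trend: GridImage
    stripes: GridImage
    noise: GridImage
    observed: GridImage


def generate_grid(
    n_rows: int = 60,
    n_cols: int = 150,
    spec: EmbryoSpec | None = None,
    trend_amplitude: float | None = None,
    stripe_amplitude: float | None = None,
    seed: int | None = None,
) -> GridTruth:
    """Evaluate the embryo fields directly on a regular cylindrical grid.

    Rows are angular bins (periodic), columns span 0..100 %EL.  The stripe
    field here is the *zero-mean* sinusoid (amplitude ``stripe_amplitude``
    times the crosstalk coefficient's magnitude is up to the caller:
    ``stripes`` is the plain oscillation, so core tests can scale it), and
    ``observed = trend + stripes + noise`` with the same intensity-
    dependent noise model as :func:`generate`.
    """
    if spec is None:
        spec = EmbryoSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    if trend_amplitude is not None:
        spec = replace(spec, gap_amplitude=trend_amplitude)
    if stripe_amplitude is not None:
        spec = replace(spec, stripe_amplitude=stripe_amplitude)

    rng = np.random.default_rng(spec.seed)
    angular = np.arange(n_rows) * (360.0 / n_rows)
    axial = np.linspace(0.0, 100.0, n_cols)
    ang, ax = np.meshgrid(angular, axial, indexing="ij")

    trend = gap_profile(ax, spec)
    x = ax - spec.stripe_phase - _bend_offset(ang, spec)
    stripes = spec.stripe_amplitude * np.sin(
        2.0 * np.pi * spec.stripe_count * x / 100.0
    )
    clean = trend + stripes
    sd = spec.noise_eta * np.abs(clean) + spec.noise_floor
    noise = sd * rng.standard_normal(clean.shape)

    circ = (True, False)
    return GridTruth(
        GridImage(trend, circular=circ),
        GridImage(stripes, circular=circ),
        GridImage(noise, circular=circ),
        GridImage(clean + noise, circular=circ),
    )
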