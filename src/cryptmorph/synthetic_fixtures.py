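"""Synthetic ground-truth shapes for exercising the counting pipeline.

Real organoid cross-sections are lobed blobs: a roughly circular body with
finger-like buds separated by narrow concave necks. The generator here
emulates exactly that topology with full control over the ground truth: a
radial profile r(theta) that sits on a high plateau (the lobes) and dips
smoothly to the base radius at ``k`` evenly spaced neck positions. By
construction a zero-jitter k-lobed fixture has exactly k concave boundary
regions, so every stage — concavity detection, candidate segmentation,
threshold classification, annealing recovery — can be tested against known
answers without any external image.

Lobes are plateau-shaped (smoothed rectangular fingers) rather than
sinusoidal petals so that lobe area and neck arc length can be steered
independently against the classifier's area/arc-length thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .boundary_io import BinaryMask, BoundaryPolygon
from .crypt_counting import CryptParameters, count_crypts
from .training import TrainingExample

__all__ = [
    "LobedShapeSpec",
    "make_lobed_boundary",
    "rasterize_boundary",
    "make_training_set",
]


@dataclass(frozen=True)
class LobedShapeSpec:
    """Specification of a synthetic lobed boundary.

    Parameters
    ----------
    k : int
        Number of lobes (= number of concave necks). ``k = 0`` gives a
        plain circle of ``base_radius``.
    base_radius : float
        Radius at the bottom of each neck.
    lobe_length : float
        Radial height of the lobe plateau above the base radius.
    neck_width : float
        Arc-length width of each neck dip, measured at the base radius.
        Must leave the dips non-overlapping: neck_width < 2*pi*base_radius/k.
    boundary_points : int
        Number of polygon vertices sampled on the profile.
    jitter : float
        Amplitude of uniform radial noise added per vertex (0 = exact).
    seed : int
        Seed for jitter and any stochastic sizing.
    """

    k: int
    base_radius: float = 1.0
    lobe_length: float = 0.55
    neck_width: float = 0.6
    boundary_points: int = 512
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("lobe count k must be >= 0")
        if self.base_radius <= 0 or self.boundary_points < 16:
            raise ValueError("base_radius must be positive, boundary_points >= 16")
        if self.k > 0:
            half_angle = self.neck_width / (2.0 * self.base_radius)
            if half_angle >= np.pi / self.k:
                raise ValueError(
                    f"neck dips overlap: neck_width {self.neck_width} too wide for k={self.k}"
                )


def _radial_profile(spec: LobedShapeSpec, theta: np.ndarray) -> np.ndarray:
    """Plateau-with-dips radius; C1-smooth cosine dip flanks."""
    if spec.k == 0:
        return np.full_like(theta, spec.base_radius)
    half_angle = spec.neck_width / (2.0 * spec.base_radius)
    neck_angles = 2.0 * np.pi * np.arange(spec.k) / spec.k
    # angular distance to the nearest neck centre
    d = np.abs(((theta[:, None] - neck_angles[None, :]) + np.pi) % (2 * np.pi) - np.pi)
    dmin = d.min(axis=1)
    u = np.clip(dmin / half_angle, 0.0, 1.0)
    f = 0.5 * (1.0 - np.cos(np.pi * u))  # 0 at neck centre -> 1 on plateau
    return spec.base_radius + spec.lobe_length * f


def make_lobed_boundary(spec: LobedShapeSpec) -> tuple[BoundaryPolygon, int]:
    """Generate a lobed closed boundary and its ground-truth lobe count.

    Returns the ccw polygon and ``spec.k``. Deterministic for a fixed
    ``spec`` (including seed); jitter must stay well below ``lobe_length``
    or the planted topology is destroyed (a ``ValueError`` guards gross
    misuse).
    """
    if spec.jitter >= 0.5 * max(spec.lobe_length, spec.base_radius * 0.1) and spec.k > 0:
        raise ValueError("jitter is large enough to destroy the planted lobe topology")
    theta = np.linspace(0.0, 2.0 * np.pi, spec.boundary_points, endpoint=False)
    r = _radial_profile(spec, theta)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        r = r + rng.uniform(-spec.jitter, spec.jitter, size=len(theta))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    poly = BoundaryPolygon(pts, units="pixels")
    ring = shapely.LinearRing(poly.points)
    if not ring.is_simple:
        raise ValueError("generated boundary self-intersects; reduce jitter/lobe extremes")
    return poly, spec.k


def rasterize_boundary(poly: BoundaryPolygon, resolution: int = 256) -> BinaryMask:
    """Rasterise a simple polygon to a binary mask.

    ``resolution`` is the pixel count across the polygon's larger bounding-
    box dimension. A pixel is foreground iff its centre lies inside the
    polygon. The mask uses the image convention of
    :func:`cryptmorph.boundary_io.extract_boundaries` (x = column,
    y = nrows - 1 - row), so rasterise -> extract round-trips a shape.
    """
    if resolution < 32:
        raise ValueError("resolution too coarse: need >= 32 pixels across")
    pts = poly.points
    shp = shapely.Polygon(pts)
    if not shp.is_valid or shp.area == 0:
        raise ValueError("cannot rasterise a non-simple or degenerate polygon")
    xmin, ymin, xmax, ymax = shp.bounds
    extent = max(xmax - xmin, ymax - ymin)
    scale = (resolution - 1) / extent
    margin = 2
    ncols = int(np.ceil((xmax - xmin) * scale)) + 2 * margin + 1
    nrows = int(np.ceil((ymax - ymin) * scale)) + 2 * margin + 1
    cols = np.arange(ncols)
    rows = np.arange(nrows)
    # pixel-centre world coordinates
    xs = xmin + (cols - margin) / scale
    ys = ymin + ((nrows - 1 - rows) - margin) / scale
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(shp, X.ravel(), Y.ravel()).reshape(nrows, ncols)
    return BinaryMask(grid=inside, pixel_size=1.0 / scale)


def make_training_set(
    n: int,
    planted: CryptParameters,
    day_label: str = "synthetic",
    seed: int = 0,
    k_values: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> list[TrainingExample]:
    """Build a planted-parameter training set of lobed fixtures.

    Each example is a lobed boundary with a known lobe count, sized so the
    ``planted`` classifier reproduces that count exactly — hence
    ``evaluate_objective(planted, set) == 0`` by construction (fixtures
    whose randomised geometry happens to confuse the planted classifier are
    re-drawn, up to a bounded number of attempts). Lobe counts cycle over
    ``k_values`` so any set of >= len(k_values) fixtures spans several
    distinct ground truths.
    """
    if n < 1:
        raise ValueError("need at least one fixture")
    rng = np.random.default_rng(seed)
    examples: list[TrainingExample] = []
    for i in range(n):
        k = int(k_values[i % len(k_values)])
        for _attempt in range(20):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = LobedShapeSpec(
                k=k,
                base_radius=float(rng.uniform(0.8, 1.3)),
                lobe_length=float(rng.uniform(0.45, 0.65)),
                neck_width=float(rng.uniform(0.45, 0.6)),
                boundary_points=512,
                jitter=0.0,
                seed=sub,
            )
            poly, truth = make_lobed_boundary(spec)
            if count_crypts(poly, planted).crypt_count == truth:
                examples.append(
                    TrainingExample(boundary=poly, hand_count=truth, day_label=day_label)
                )
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError(
                f"could not size a {k}-lobed fixture for the planted parameters"
            )
    return examples


def write_fixture_bundle(
    out_dir: str | Path,
    n: int,
    planted: CryptParameters,
    seed: int = 0,
    resolution: int = 192,
) -> Path:
    """Write masks (PNG), boundaries (CSV) and a manifest CSV for a set."""
    import imageio.v3 as iio
    import pandas as pd

    from .boundary_io import write_boundaries_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    examples = make_training_set(n, planted, seed=seed)
    boundaries = {}
    rows = []
    for i, ex in enumerate(examples):
        oid = f"fixture_{i:03d}"
        boundaries[oid] = ex.boundary
        mask = rasterize_boundary(ex.boundary, resolution=resolution)
        iio.imwrite(out / f"{oid}.png", (mask.grid * np.uint8(255)))
        rows.append({"organoid_id": oid, "hand_count": ex.hand_count, "day": ex.day_label})
    write_boundaries_csv(boundaries, out / "boundaries.csv")
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
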