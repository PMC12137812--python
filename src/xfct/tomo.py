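"""Phantoms, Radon projection, sinogram assembly/reduction, pair
augmentation, and dataset splitting/scaling for the sinogram-to-image
network.

Geometry follows the benchtop scan protocol: 30 angular projections in 12
degree steps over a full 360 degree rotation and 11 lateral translations at
a 3 mm step.  Projection counts are reduced by uniform-in-angle subsampling
(row indices round(i*n/k)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import radon as _sk_radon
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "PhantomImage",
    "Sinogram",
    "MinMaxScaler",
    "make_3h_phantom",
    "make_organ_phantom",
    "random_organ_phantom",
    "radon_project",
    "assemble_sinogram",
    "reduce_projections",
    "projection_count_settings",
    "augment_pair",
    "PairAugmentOps",
    "build_base_pairs",
    "augment_pairs",
    "split_pairs",
    "resize_to_input",
]

DEFAULT_N_ANGLES = 30
DEFAULT_N_TRANSLATIONS = 11
DEFAULT_TRANSLATION_STEP = 3.0  # mm


@dataclass
class PhantomImage:
    """Square 2D concentration map in wt%."""

    grid: np.ndarray
    pixel_size: float = 0.5  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("phantom grid must be square")
        if np.any(self.grid < 0):
            raise ValueError("concentrations must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def replace(self, **changes) -> "PhantomImage":
        return dataclasses.replace(self, **changes)


@dataclass
class Sinogram:
    """Projection matrix: rows are angles, columns radial/translation bins."""

    matrix: np.ndarray
    angles: np.ndarray  # degrees, strictly increasing, within [0, 360)
    translation_step: float = DEFAULT_TRANSLATION_STEP
    provenance: str = "radon"  # "radon" | "spectra"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("sinogram matrix must be 2D")
        if self.matrix.shape[0] != self.angles.size:
            raise ValueError("number of rows must equal number of angles")
        if self.angles.size > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sinogram values must be finite")

    @property
    def n_angles(self) -> int:
        return self.matrix.shape[0]

    def is_uniform(self) -> bool:
        """True when the angle grid is uniform over the full circle."""
        n = self.angles.size
        if n < 2:
            return True
        expected = self.angles[0] + np.arange(n) * (360.0 / n)
        return bool(np.allclose(self.angles, expected))

    def replace(self, **changes) -> "Sinogram":
        return dataclasses.replace(self, **changes)


class MinMaxScaler:
    """Global min-max normalization to [0, 1], fitted on training data."""

    def __init__(self) -> None:
        self.min_: float | None = None
        self.max_: float | None = None

    def fit(self, data: np.ndarray | Sequence[np.ndarray]) -> "MinMaxScaler":
        if isinstance(data, np.ndarray):
            arrs = [data]
        else:
            arrs = list(data)
        self.min_ = float(min(a.min() for a in arrs))
        self.max_ = float(max(a.max() for a in arrs))
        if self.max_ <= self.min_:
            raise ValueError("max must exceed min for min-max scaling")
        return self

    def _check(self) -> None:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, x: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(x, dtype=np.float64) - self.min_) / (self.max_ - self.min_)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(z, dtype=np.float64) * (self.max_ - self.min_) + self.min_

    @property
    def data_range(self) -> float:
        self._check()
        return self.max_ - self.min_


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _disc_mask(n: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    return (xx - c - cx) ** 2 + (yy - c - cy) ** 2 <= r**2


def make_3h_phantom(
    hole_concentrations: Sequence[float] = (1.0, 0.5, 0.3),
    grid_size: int = 63,
    pixel_size: float = 0.5,
    phantom_diameter: float = 30.0,
    hole_diameter: float = 6.0,
    hole_ring_radius: float = 8.0,
) -> PhantomImage:
    """Cylindrical phantom (30 mm diameter) with three 6 mm GNP-loaded holes
    at 120 degree spacing.  Background concentration is 0 wt%."""
    if len(hole_concentrations) != 3:
        raise ValueError("exactly three hole concentrations are required")
    if any(c < 0 for c in hole_concentrations):
        raise ValueError("concentrations must be non-negative")
    r_ph = phantom_diameter / 2 / pixel_size
    r_hole = hole_diameter / 2 / pixel_size
    r_ring = hole_ring_radius / pixel_size
    if r_ph > (grid_size - 1) / 2:
        raise ValueError("grid does not cover the phantom diameter")
    if r_ring + r_hole > r_ph:
        raise ValueError("holes extend outside the phantom disc")
    # 120-degree spacing: chord distance between hole centres
    if 2 * r_ring * np.sin(np.pi / 3) < 2 * r_hole:
        raise ValueError("holes overlap")

    grid = np.zeros((grid_size, grid_size))
    centres = []
    for i, conc in enumerate(hole_concentrations):
        ang = np.deg2rad(90 + 120 * i)
        cx, cy = r_ring * np.cos(ang), -r_ring * np.sin(ang)
        grid[_disc_mask(grid_size, cx, cy, r_hole)] = conc
        centres.append((cx, cy))
    meta = {
        "kind": "3H",
        "phantom_diameter_mm": phantom_diameter,
        "hole_diameter_mm": hole_diameter,
        "hole_concentrations": tuple(float(c) for c in hole_concentrations),
        "hole_centres_px": centres,
    }
    return PhantomImage(grid=grid, pixel_size=pixel_size, meta=meta)


def make_organ_phantom(
    region_spec: Sequence[tuple],
    grid_size: int = 64,
    pixel_size: float = 0.5,
    seed: int | None = None,
) -> PhantomImage:
    """Piecewise-constant multi-region ("organ") phantom.

    ``region_spec`` is a list of ``(cx, cy, a, b, angle_deg, concentration)``
    ellipse tuples in pixel units relative to the grid centre.  Later regions
    overwrite earlier ones.
    """
    grid = np.zeros((grid_size, grid_size))
    c = (grid_size - 1) / 2.0
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    half = (grid_size - 1) / 2.0
    for cx, cy, a, b, ang, conc in region_spec:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        if abs(cx) + max(a, b) > half + 1 or abs(cy) + max(a, b) > half + 1:
            raise ValueError("region extends outside the field of view")
        t = np.deg2rad(ang)
        xr = (xx - c - cx) * np.cos(t) + (yy - c - cy) * np.sin(t)
        yr = -(xx - c - cx) * np.sin(t) + (yy - c - cy) * np.cos(t)
        grid[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] = conc
    meta = {"kind": "organ", "n_regions": len(region_spec), "seed": seed}
    return PhantomImage(grid=grid, pixel_size=pixel_size, meta=meta)


def random_organ_phantom(
    grid_size: int = 63,
    pixel_size: float = 0.5,
    seed: int = 0,
    conc_range: tuple[float, float] = (0.1, 5.0),
) -> PhantomImage:
    """Reproducible mouse-like stand-in: low-uptake body ellipse with 2-5
    high-uptake organ ellipses (e.g. paired kidneys, tumor)."""
    rng = np.random.default_rng(seed)
    half = (grid_size - 1) / 2.0
    body_a = rng.uniform(0.55, 0.8) * half
    body_b = rng.uniform(0.45, 0.7) * half
    spec = [(0.0, 0.0, body_a, body_b, rng.uniform(0, 180), rng.uniform(0.0, 0.05))]
    n_organs = int(rng.integers(2, 6))
    for _ in range(n_organs):
        a = rng.uniform(0.06, 0.22) * half
        b = rng.uniform(0.06, 0.22) * half
        r = rng.uniform(0, 0.6) * half
        t = rng.uniform(0, 2 * np.pi)
        conc = float(rng.uniform(*conc_range))
        spec.append((r * np.cos(t), r * np.sin(t), a, b, rng.uniform(0, 180), conc))
    ph = make_organ_phantom(spec, grid_size=grid_size, pixel_size=pixel_size, seed=seed)
    ph.meta["n_organs"] = n_organs
    return ph


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def radon_project(
    img: PhantomImage,
    n_angles: int = DEFAULT_N_ANGLES,
    angle_range: float = 360.0,
) -> Sinogram:
    """Parallel-beam line integrals at equally spaced angles over
    ``angle_range`` degrees (exclusive upper bound)."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    angles = np.arange(n_angles) * (angle_range / n_angles)
    n = img.grid.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    inside = (xx - c) ** 2 + (yy - c) ** 2 <= (n // 2) ** 2
    mat = _sk_radon(img.grid * inside, theta=angles, circle=True).T
    return Sinogram(matrix=mat, angles=angles,
                    translation_step=img.pixel_size, provenance="radon")


def assemble_sinogram(
    values: Sequence[float],
    n_angles: int = DEFAULT_N_ANGLES,
    n_translations: int = DEFAULT_N_TRANSLATIONS,
    translation_step: float = DEFAULT_TRANSLATION_STEP,
    angle_range: float = 360.0,
) -> Sinogram:
    """Arrange per-position net-signal values (angle-major order) into an
    angles x translations sinogram."""
    values = np.asarray(values, dtype=np.float64)
    expected = n_angles * n_translations
    if values.size != expected:
        raise ValueError(
            f"expected {expected} values ({n_angles} angles x "
            f"{n_translations} translations), got {values.size}")
    angles = np.arange(n_angles) * (angle_range / n_angles)
    return Sinogram(matrix=values.reshape(n_angles, n_translations),
                    angles=angles, translation_step=translation_step,
                    provenance="spectra")


def reduce_projections(s: Sinogram, k: int) -> Sinogram:
    """Keep k rows at indices round(i*n/k), i = 0..k-1."""
    n = s.n_angles
    if not 1 <= k <= n:
        raise ValueError(f"target angle count {k} outside [1, {n}]")
    idx = np.unique(np.round(np.arange(k) * n / k).astype(int) % n)
    return s.replace(matrix=s.matrix[idx].copy(), angles=s.angles[idx].copy())


def projection_count_settings(n_settings: int = 20, high: int = 30, low: int = 5) -> list[int]:
    """Uniformly spaced projection counts from ``high`` down to ``low``
    (inclusive), rounded to unique integers."""
    vals = np.unique(np.round(np.linspace(high, low, n_settings)).astype(int))[::-1]
    if vals.size != n_settings:
        raise ValueError(
            f"cannot produce {n_settings} unique settings between {high} and {low}")
    return [int(v) for v in vals]


# ---------------------------------------------------------------------------
# pair augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairAugmentOps:
    """One draw of the pair augmentation operators."""

    scale: float = 1.0
    flip: bool = False           # vertical image flip (y -> -y)
    rotate_steps: int = 0        # multiples of the sinogram angular step
    noise_sd: float = 0.0        # Gaussian noise added to the sinogram only


def _flip_sinogram(s: Sinogram) -> Sinogram:
    # vertical image flip maps projection (theta, r) to (180 - theta, -r);
    # exact on a uniform full-circle grid with an even number of angles
    n = s.n_angles
    if not s.is_uniform() or n % 2 != 0:
        raise ValueError("flip requires a uniform angle grid of even size")
    rows = (n // 2 - np.arange(n)) % n
    mat = s.matrix[rows][:, ::-1].copy()
    return s.replace(matrix=mat)


def _rotate_sinogram(s: Sinogram, steps: int) -> Sinogram:
    if steps == 0:
        return s.replace(matrix=s.matrix.copy())
    if not s.is_uniform():
        raise ValueError("rotation requires a uniform angle grid")
    return s.replace(matrix=np.roll(s.matrix, -steps, axis=0))


def augment_pair(
    sino: Sinogram,
    img: PhantomImage,
    ops: PairAugmentOps,
    seed: int = 0,
) -> tuple[Sinogram, PhantomImage]:
    """Apply one augmentation draw consistently to a sinogram/image pair.

    Geometric operators act on both members (image flip/rotation maps to the
    exact sinogram row/column manipulation); Gaussian noise perturbs the
    sinogram only.  Rotation is restricted to multiples of the angular step.
    """
    grid = img.grid
    s = sino
    if ops.flip:
        grid = grid[::-1, :].copy()
        s = _flip_sinogram(s)
    if ops.rotate_steps:
        step_deg = 360.0 / s.n_angles
        grid = _sk_rotate(grid, -ops.rotate_steps * step_deg, resize=False,
                          preserve_range=True, order=1)
        grid = np.clip(grid, 0.0, None)
        s = _rotate_sinogram(s, ops.rotate_steps)
    else:
        s = s.replace(matrix=s.matrix.copy())
    if ops.scale != 1.0:
        if ops.scale < 0:
            raise ValueError("scale must be non-negative")
        grid = grid * ops.scale
        s = s.replace(matrix=s.matrix * ops.scale)
    if ops.noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s.replace(matrix=np.clip(
            s.matrix + rng.normal(0.0, ops.noise_sd * max(s.matrix.max(), 1e-12),
                                  s.matrix.shape), 0.0, None))
    return s, img.replace(grid=grid)


def build_base_pairs(
    images: Sequence[PhantomImage],
    settings: Sequence[int] | None = None,
) -> list[tuple[Sinogram, PhantomImage]]:
    """Full-view Radon projection of every image, reduced to each configured
    projection count: len(images) * len(settings) base pairs."""
    settings = list(settings) if settings is not None else projection_count_settings()
    pairs = []
    for img in images:
        full = radon_project(img, n_angles=DEFAULT_N_ANGLES)
        for k in settings:
            pairs.append((reduce_projections(full, k), img))
    return pairs


def augment_pairs(
    pairs: Sequence[tuple[Sinogram, PhantomImage]],
    factor: int = 5,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 0.02,
) -> list[tuple[Sinogram, PhantomImage]]:
    """Expand the dataset ``factor``-fold; the first draw per pair is the
    identity, subsequent draws sample flip/rotation/scaling/noise.

    Flip and rotation are only drawn for sinograms on uniform angle grids
    (they have no exact row-manipulation counterpart otherwise).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: list[tuple[Sinogram, PhantomImage]] = []
    for i, (s, img) in enumerate(pairs):
        uniform = s.is_uniform()
        for r in range(factor):
            child = int(np.random.SeedSequence((seed, i, r)).generate_state(1)[0])
            if r == 0:
                ops = PairAugmentOps()
            else:
                rng = np.random.default_rng(child)
                ops = PairAugmentOps(
                    scale=float(rng.uniform(*scale_range)),
                    flip=bool(rng.random() < 0.5)
                    if uniform and s.n_angles % 2 == 0 else False,
                    rotate_steps=int(rng.integers(0, s.n_angles)) if uniform else 0,
                    noise_sd=noise_sd,
                )
            out.append(augment_pair(s, img, ops, seed=child + 1))
    return out


def split_pairs(
    pairs: Sequence,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> dict[str, list]:
    """Disjoint exhaustive train/val/test split with the floor/remainder
    rule: 29,200 pairs -> 20,440 / 5,840 / 2,920."""
    if len(pairs) == 0:
        raise ValueError("cannot split an empty collection")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    return {
        "train": [pairs[i] for i in order[:n_train]],
        "val": [pairs[i] for i in order[n_train:n_train + n_val]],
        "test": [pairs[i] for i in order[n_train + n_val:]],
    }


def resize_to_input(s: Sinogram, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Deterministic bilinear resize of the sinogram matrix to the network
    input size (stretch, not zero-fill)."""
    if s.matrix.size == 0:
        raise ValueError("empty sinogram")
    if s.matrix.shape == tuple(target):
        return s.matrix.copy()
    return _sk_resize(s.matrix, target, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
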