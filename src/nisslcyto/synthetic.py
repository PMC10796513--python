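"""Synthetic Nissl-section generator with per-cell ground truth.

Emulates digitized thionine-stained cortical sections: six horizontal
layer bands (pial layer I at the top), dark somata on a bright textured
neuropil, four planted cell-shape archetypes (round, ellipsoid,
pyramidal, complex), glia-scale distractor objects, and cohort-level
group effects on size, shape and density.  Every generated cell carries
its planted parameters and analytically computed morphometric features,
so downstream stages can be validated against ground truth and the
statistical stack can be exercised without any segmentation
("truth-bypass" mode).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

ARCHETYPE_NAMES = ("round", "ellipsoid", "pyramidal", "complex")
LAYER_NAMES = ("I", "II", "III", "IV", "V", "VI")
GROUP_NAMES = ("calf", "adult", "old")

#: per-cell feature columns shared by the truth tables and the
#: segmentation-based morphometry tables
FEATURE_COLUMNS = [
    "area", "major_axis", "minor_axis", "perimeter",
    "invAR", "extent", "eccentricity", "solidity", "convex_circularity",
    "density_50", "density_100",
]

DENSITY_RADII = (50.0, 100.0)  # μm


class PackingError(RuntimeError):
    """Requested cell density cannot be placed without overlap."""


@dataclass(frozen=True)
class ShapeArchetype:
    """Parametric description of one planted soma shape class.

    ``size_mean`` is the mean equivalent diameter in μm (the diameter of
    the circle with the same area), ``size_cv`` its coefficient of
    variation, ``aspect_ratio`` the minor/major axis ratio of the base
    shape, and ``irregularity`` the amplitude of a smooth random
    boundary perturbation (0 = deterministic base shape).
    """

    name: str
    size_mean: float
    size_cv: float
    aspect_ratio: float
    irregularity: float

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(
                f"unknown archetype {self.name!r}; expected one of {ARCHETYPE_NAMES}"
            )
        if self.size_mean <= 0:
            raise ValueError("size_mean must be positive")
        if not 0 < self.aspect_ratio <= 1:
            raise ValueError("aspect_ratio must be in (0, 1]")
        if not 0 <= self.irregularity <= 1:
            raise ValueError("irregularity must be in [0, 1]")


def default_archetypes() -> dict[str, ShapeArchetype]:
    """Archetype defaults sized like cortical neuron somata (μm)."""
    return {
        "round": ShapeArchetype("round", 12.0, 0.15, 1.0, 0.05),
        "ellipsoid": ShapeArchetype("ellipsoid", 13.0, 0.15, 0.62, 0.05),
        "pyramidal": ShapeArchetype("pyramidal", 15.0, 0.18, 0.78, 0.04),
        "complex": ShapeArchetype("complex", 19.0, 0.18, 0.90, 0.06),
    }


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer band: thickness (μm), cell density (/mm²) and
    the mixing probabilities of the four archetypes."""

    layer_id: str
    thickness: float
    density_per_mm2: float
    shape_mix: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.layer_id not in LAYER_NAMES:
            raise ValueError(f"unknown layer {self.layer_id!r}")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.density_per_mm2 < 0:
            raise ValueError("density must be >= 0")
        mix = np.asarray(self.shape_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-6:
            raise ValueError("shape_mix must be 4 non-negative probabilities summing to 1")


def default_layers() -> list[LayerSpec]:
    """Six-layer column: cell-rich layer II, thin sparse layer IV.

    Thicknesses total 1.85 mm.  Densities are free parameters chosen to
    look like a quasi-agranular primary sensory cortex; layer II is the
    densest band and layer IV a thin cell-poor line.
    """
    #                      (round, ellipsoid, pyramidal, complex)
    return [
        LayerSpec("I", 280.0, 150.0, (0.55, 0.30, 0.05, 0.10)),
        LayerSpec("II", 220.0, 900.0, (0.20, 0.15, 0.55, 0.10)),
        LayerSpec("III", 420.0, 400.0, (0.20, 0.25, 0.45, 0.10)),
        LayerSpec("IV", 110.0, 120.0, (0.55, 0.20, 0.20, 0.05)),
        LayerSpec("V", 440.0, 350.0, (0.15, 0.20, 0.45, 0.20)),
        LayerSpec("VI", 380.0, 300.0, (0.25, 0.30, 0.30, 0.15)),
    ]


@dataclass(frozen=True)
class GroupEffect:
    """Planted age-class effect.

    ``size_multiplier`` scales the mean equivalent diameter per
    archetype (area therefore scales with the square); ``shape_shift``
    adds offsets to archetype shape parameters (keys ``aspect_ratio``
    and/or ``irregularity``) per archetype; ``density_multiplier``
    scales the expected cell count per layer.  ``restrict_layers``
    limits the size/shape effects to a subset of layers (density
    multipliers are already keyed by layer).  All-1/0 values define the
    global null.
    """

    group: str
    size_multiplier: Mapping[str, float] = field(default_factory=dict)
    shape_shift: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    density_multiplier: Mapping[str, float] = field(default_factory=dict)
    restrict_layers: frozenset | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_NAMES:
            raise ValueError(f"unknown group {self.group!r}")
        for v in self.size_multiplier.values():
            if v <= 0:
                raise ValueError("size multipliers must be positive")
        for v in self.density_multiplier.values():
            if v < 0:
                raise ValueError("density multipliers must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            all(v == 1.0 for v in self.size_multiplier.values())
            and all(v == 1.0 for v in self.density_multiplier.values())
            and all(
                all(x == 0.0 for x in d.values()) for d in self.shape_shift.values()
            )
        )

    def _active(self, layer_id: str) -> bool:
        return self.restrict_layers is None or layer_id in self.restrict_layers

    def effective_archetype(self, arch: ShapeArchetype, layer_id: str) -> ShapeArchetype:
        """Archetype with this group's size/shape effects applied."""
        if not self._active(layer_id):
            return arch
        size = arch.size_mean * self.size_multiplier.get(arch.name, 1.0)
        shift = self.shape_shift.get(arch.name, {})
        ar = float(np.clip(arch.aspect_ratio + shift.get("aspect_ratio", 0.0), 0.05, 1.0))
        irr = float(np.clip(arch.irregularity + shift.get("irregularity", 0.0), 0.0, 1.0))
        return dataclasses.replace(arch, size_mean=size, aspect_ratio=ar, irregularity=irr)

    def layer_density_multiplier(self, layer_id: str) -> float:
        return self.density_multiplier.get(layer_id, 1.0)


def identity_effects() -> dict[str, GroupEffect]:
    """Global-null effects: every group draws from the same generator."""
    return {g: GroupEffect(group=g) for g in GROUP_NAMES}


@dataclass(frozen=True)
class NoiseModel:
    """Rendering noise: neuropil texture, illumination, staining jitter,
    glia-scale distractors (below the neuron size floor)."""

    neuropil_mean: float = 0.78
    texture_sd: float = 0.035
    illumination_amp: float = 0.04
    cell_intensity: float = 0.30
    staining_jitter_sd: float = 0.05
    glia_per_mm2: float = 120.0
    glia_diameter: float = 3.5  # μm equivalent diameter, area ≈ 9.6 μm²


@dataclass(frozen=True)
class CohortSpec:
    """Study design: (4, 4, 3) animals in (calf, adult, old), two
    sections per animal, 8-bit greyscale fields of view with known
    pixel calibration."""

    n_animals: tuple[int, int, int] = (4, 4, 3)
    sections_per_animal: int = 2
    image_size: tuple[int, int] = (4000, 2000)  # rows, cols (px)
    pixel_size: float = 0.5  # μm / px
    noise: NoiseModel = field(default_factory=NoiseModel)
    touching_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_animals):
            raise ValueError("need >= 1 animal per group")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 <= self.touching_fraction < 1:
            raise ValueError("touching_fraction must be in [0, 1)")

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.image_size[0] * self.pixel_size,
                self.image_size[1] * self.pixel_size)


@dataclass
class SectionRecord:
    """One rendered section with its ground truth."""

    image: np.ndarray          # uint8 greyscale, dark cells on bright neuropil
    layer_map: np.ndarray      # uint8, 0 = background, 1..6 = layers I..VI
    truth_labels: np.ndarray   # uint32 per-cell label image (0 = background)
    cells: pd.DataFrame        # per-cell ground truth + features
    pixel_size: float
    animal: str = ""
    group: str = ""
    section: int = 0
    image_id: str = ""


@dataclass
class CohortDataset:
    metadata: pd.DataFrame               # one row per section
    cells: pd.DataFrame                  # all ground-truth cells
    sections: list[SectionRecord] | None = None


# ---------------------------------------------------------------------------
# polygon sampling
# ---------------------------------------------------------------------------

_N_VERTICES = 48
_THETA = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)


def _smooth_periodic(r: np.ndarray, sigma_rad: float) -> np.ndarray:
    """Gaussian smoothing of radial profiles along the angular axis."""
    sigma_idx = sigma_rad * _N_VERTICES / (2.0 * np.pi)
    return ndi.gaussian_filter1d(r, sigma_idx, axis=-1, mode="wrap")


def _fourier_noise(n: int, rng: np.random.Generator,
                   orders: Sequence[int] = (2, 3, 4, 5)) -> np.ndarray:
    """Smooth zero-mean periodic perturbations with peak amplitude ~1."""
    out = np.zeros((n, _N_VERTICES))
    amp = rng.uniform(0.3, 1.0, size=(n, len(orders)))
    amp /= amp.sum(axis=1, keepdims=True)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, len(orders)))
    for j, k in enumerate(orders):
        out += amp[:, [j]] * np.cos(k * _THETA[None, :] + phase[:, [j]])
    return out


def _rounded_triangle_radial(corner_frac: float = 0.35) -> np.ndarray:
    """Radial profile (on the _THETA grid) of an equilateral triangle
    whose corners are rounded by arcs of radius ``corner_frac`` times
    the inradius.  Soma-like: convex, clearly triangular footprint."""
    rho = corner_frac * 0.5  # inradius of the unit-circumradius triangle
    arcs = []
    for ang in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
        center = (1.0 - 2.0 * rho) * np.array([np.cos(ang), np.sin(ang)])
        arc = ang + np.linspace(-np.pi / 3, np.pi / 3, 16)
        arcs.append(center + rho * np.column_stack([np.cos(arc), np.sin(arc)]))
    pts = []
    for i, arc in enumerate(arcs):  # arcs joined by straight tangent edges
        nxt = arcs[(i + 1) % 3][0]
        t = np.linspace(0.0, 1.0, 18, endpoint=False)[1:, None]
        pts.extend([arc, arc[-1] * (1 - t) + nxt * t])
    pts = np.concatenate(pts)
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    order = np.argsort(phi)
    phi, rad = phi[order], np.hypot(pts[:, 0], pts[:, 1])[order]
    return np.interp(_THETA, phi, rad, period=2 * np.pi)


_PYRAMID_R = None


def _base_radial(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    theta = _THETA[None, :] + rng.uniform(0, 2 * np.pi, size=(n, 1))
    if name in ("round", "ellipsoid"):
        return np.ones((n, _N_VERTICES))
    if name == "pyramidal":
        # fixed rounded-triangle template; the random in-plane rotation
        # applied later randomises its orientation
        global _PYRAMID_R
        if _PYRAMID_R is None:
            _PYRAMID_R = _rounded_triangle_radial()
        return np.broadcast_to(_PYRAMID_R, (n, _N_VERTICES)).copy()
    if name == "complex":
        # intrinsically multi-lobed: 4-6 lobes of fixed relative depth
        k = rng.integers(4, 7, size=(n, 1))
        phase = rng.uniform(0, 2 * np.pi, size=(n, 1))
        depth = rng.uniform(0.26, 0.34, size=(n, 1))
        r = 1.0 + depth * np.cos(k * theta + phase)
        r += 0.05 * np.cos((k + 2) * theta + 3.1 * phase)
        return r
    raise ValueError(f"unknown archetype {name!r}")


def sample_cell_polygons(archetype: ShapeArchetype, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` closed soma outlines for one archetype.

    Returns an ``(n, 48, 2)`` array of vertices in μm, centred near the
    origin, counter-clockwise, each scaled so that its polygon area
    equals π d²/4 for an equivalent diameter d drawn from a lognormal
    with mean ``size_mean`` and CV ``size_cv``.
    """
    if n == 0:
        return np.zeros((0, _N_VERTICES, 2))
    r = _base_radial(archetype.name, n, rng)
    if archetype.irregularity > 0:
        r = r * (1.0 + archetype.irregularity * _fourier_noise(n, rng))
        r = _smooth_periodic(np.clip(r, 0.05, None), sigma_rad=0.10)
    # aspect ratio with a small jitter that vanishes with irregularity
    q_sd = 0.25 * archetype.irregularity * archetype.aspect_ratio
    q = archetype.aspect_ratio + (rng.normal(0.0, q_sd, size=(n, 1)) if q_sd > 0 else 0.0)
    q = np.clip(q, 0.05, 1.0)
    x = r * np.cos(_THETA)[None, :]
    y = q * r * np.sin(_THETA)[None, :]
    # random in-plane rotation
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
    xr = x * np.cos(phi) - y * np.sin(phi)
    yr = x * np.sin(phi) + y * np.cos(phi)
    coords = np.stack([xr, yr], axis=-1)
    # equivalent diameter ~ lognormal(mean=size_mean, cv=size_cv)
    cv = max(archetype.size_cv, 0.0)
    sig2 = np.log1p(cv**2)
    mu = np.log(archetype.size_mean) - 0.5 * sig2
    d = np.exp(rng.normal(mu, np.sqrt(sig2), size=n)) if cv > 0 else np.full(n, archetype.size_mean)
    target_area = np.pi * d**2 / 4.0
    area = _shoelace_area(coords)
    coords *= np.sqrt(target_area / area)[:, None, None]
    return coords


def sample_cell_shape(archetype: ShapeArchetype,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample a single soma outline; see :func:`sample_cell_polygons`."""
    return sample_cell_polygons(archetype, 1, rng)[0]


# ---------------------------------------------------------------------------
# analytic polygon morphometrics (ground-truth feature channel)
# ---------------------------------------------------------------------------

def _shoelace_area(coords: np.ndarray) -> np.ndarray:
    x, y = coords[..., 0], coords[..., 1]
    x2, y2 = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    return 0.5 * np.abs(np.sum(x * y2 - x2 * y, axis=-1))


def polygon_morphometrics(coords: np.ndarray) -> pd.DataFrame:
    """Vectorised exact morphometrics of simple polygons (μm units).

    Computes the same descriptor set as the raster morphometry module,
    but analytically from the polygon: area, moment-matched ellipse
    axes, perimeter, inverse aspect ratio, extent (axis-aligned
    bounding box), eccentricity, solidity and convex circularity.
    Density columns are left unset.
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[..., 0], coords[..., 1]
    x2, y2 = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    cross = x * y2 - x2 * y
    area_signed = 0.5 * np.sum(cross, axis=-1)
    sign = np.sign(area_signed)
    area = np.abs(area_signed)
    cx = np.sum((x + x2) * cross, axis=-1) / (6.0 * area_signed)
    cy = np.sum((y + y2) * cross, axis=-1) / (6.0 * area_signed)
    # second moments of area about the origin (standard polygon formulas)
    ixx = np.sum((y * y + y * y2 + y2 * y2) * cross, axis=-1) / 12.0
    iyy = np.sum((x * x + x * x2 + x2 * x2) * cross, axis=-1) / 12.0
    ixy = np.sum((x * y2 + 2 * x * y + 2 * x2 * y2 + x2 * y) * cross, axis=-1) / 24.0
    ixx, iyy, ixy = ixx * sign, iyy * sign, ixy * sign
    # central normalised second moments (covariance of the uniform lamina)
    sxx = iyy / area - cx**2
    syy = ixx / area - cy**2
    sxy = ixy / area - cx * cy
    tr, det_half = sxx + syy, np.sqrt(((sxx - syy) / 2.0) ** 2 + sxy**2)
    lam1 = tr / 2.0 + det_half
    lam2 = np.clip(tr / 2.0 - det_half, 1e-12, None)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    perimeter = np.sum(np.hypot(x2 - x, y2 - y), axis=-1)
    bbox_area = (x.max(axis=-1) - x.min(axis=-1)) * (y.max(axis=-1) - y.min(axis=-1))
    extent = area / bbox_area
    ecc = np.sqrt(np.clip(1.0 - lam2 / lam1, 0.0, 1.0))
    # convex hulls, vectorised through shapely
    nv = coords.shape[-2]
    rings = shapely.linearrings(
        coords.reshape(-1, 2), indices=np.repeat(np.arange(len(coords)), nv)
    )
    hulls = shapely.convex_hull(shapely.polygons(rings))
    hull_area = shapely.area(hulls)
    hull_perim = shapely.length(hulls)
    solidity = np.clip(area / hull_area, 0.0, 1.0)
    convex_circ = np.clip(4.0 * np.pi * hull_area / hull_perim**2, 0.0, 1.0)
    return pd.DataFrame({
        "area": area, "major_axis": major, "minor_axis": minor,
        "perimeter": perimeter, "invAR": minor / major, "extent": extent,
        "eccentricity": ecc, "solidity": solidity,
        "convex_circularity": convex_circ,
        "centroid_x": cx, "centroid_y": cy,
    })


def neighbor_counts(centroids: np.ndarray,
                    radii: Sequence[float] = DENSITY_RADII) -> np.ndarray:
    """Number of *other* cells within each radius of every cell.

    ``centroids`` is an (n, 2) array in μm; returns (n, len(radii))
    integer counts, self excluded.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    out = np.zeros((n, len(radii)), dtype=int)
    if n == 0:
        return out
    tree = cKDTree(centroids)
    for j, r in enumerate(radii):
        out[:, j] = tree.query_ball_point(centroids, r, return_length=True) - 1
    return out


# ---------------------------------------------------------------------------
# layer geometry and per-layer cell sampling
# ---------------------------------------------------------------------------

def layer_bands(layers: Sequence[LayerSpec]) -> list[tuple[str, float, float]]:
    """(layer_id, y_top, y_bottom) in μm from the pial edge (y=0)."""
    bands, y = [], 0.0
    for spec in layers:
        bands.append((spec.layer_id, y, y + spec.thickness))
        y += spec.thickness
    return bands


def _sample_layer_cells(
    layer: LayerSpec,
    effect: GroupEffect,
    archetypes: Mapping[str, ShapeArchetype],
    y0: float,
    y1: float,
    width: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Sample polygons (centred at origin) and archetype labels for one
    layer band; count ~ Poisson(density × band area)."""
    area_mm2 = (y1 - y0) * width / 1e6
    lam = layer.density_per_mm2 * effect.layer_density_multiplier(layer.layer_id) * area_mm2
    n = int(rng.poisson(lam))
    labels = rng.choice(4, size=n, p=np.asarray(layer.shape_mix, dtype=float))
    polys = np.zeros((n, _N_VERTICES, 2))
    names: list[str] = [""] * n
    for ai, aname in enumerate(ARCHETYPE_NAMES):
        idx = np.flatnonzero(labels == ai)
        if len(idx) == 0:
            continue
        arch = effect.effective_archetype(archetypes[aname], layer.layer_id)
        polys[idx] = sample_cell_polygons(arch, len(idx), rng)
        for i in idx:
            names[i] = aname
    return polys, names


def sample_section_truth(
    layers: Sequence[LayerSpec],
    effect: GroupEffect,
    spec: CohortSpec,
    rng: np.random.Generator,
    archetypes: Mapping[str, ShapeArchetype] | None = None,
) -> pd.DataFrame:
    """Fast ground-truth channel: per-cell features for one section
    without rendering an image.

    Cell centres are placed uniformly within their layer band (no
    overlap exclusion — irrelevant for feature statistics), polygons are
    sampled per archetype, and the full morphometric feature vector
    including the 50/100 μm neighbour counts is computed analytically.
    """
    archetypes = archetypes or default_archetypes()
    height, width = spec.field_size_um
    frames = []
    for layer, (lid, y0, y1) in zip(layers, layer_bands(layers)):
        if y1 > height + 1e-9:
            raise ValueError("layer stack deeper than the image field")
        polys, names = _sample_layer_cells(layer, effect, archetypes, y0, y1, width, rng)
        n = len(polys)
        if n == 0:
            continue
        centers = np.column_stack([
            rng.uniform(0.0, width, size=n), rng.uniform(y0, y1, size=n),
        ])
        feats = polygon_morphometrics(polys + centers[:, None, :])
        feats["layer"] = lid
        feats["cell_type"] = names
        frames.append(feats)
    if not frames:
        df = pd.DataFrame(columns=FEATURE_COLUMNS + ["layer", "cell_type",
                                                     "centroid_x", "centroid_y"])
        return df
    cells = pd.concat(frames, ignore_index=True)
    counts = neighbor_counts(cells[["centroid_x", "centroid_y"]].to_numpy())
    cells["density_50"] = counts[:, 0]
    cells["density_100"] = counts[:, 1]
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _place_centers(
    polys: np.ndarray,
    y0: float,
    y1: float,
    width: float,
    touching_fraction: float,
    rng: np.random.Generator,
    existing: list[np.ndarray],
    existing_diam: list[float],
    max_tries: int = 200,
) -> np.ndarray:
    """Dart-throwing placement with a minimum-distance constraint,
    relaxed for a configured fraction of cells so they touch/overlap a
    neighbour (exercises watershed splitting and superpixel merging)."""
    diam = 2.0 * np.sqrt(_shoelace_area(polys) / np.pi)
    n = len(polys)
    band_area = (y1 - y0) * width
    if np.sum(np.pi * (diam / 2) ** 2) > 0.45 * band_area:
        raise PackingError(
            f"requested cells cover >45% of the band [{y0:.0f},{y1:.0f}] μm; "
            "reduce density or cell size"
        )
    centers = np.zeros((n, 2))
    touch = rng.random(n) < touching_fraction
    n0 = len(existing)  # partners for touching pairs come from this band
    for i in range(n):
        placed = False
        for _ in range(max_tries):
            pairing = touch[i] and len(existing) > n0
            if pairing:
                j = n0 + int(rng.integers(len(existing) - n0))
                base, bd = existing[j], existing_diam[j]
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.38, 0.52) * (diam[i] + bd)
                cand = base + dist * np.array([np.cos(ang), np.sin(ang)])
                if not (0 <= cand[0] <= width and y0 <= cand[1] <= y1):
                    continue
                min_sep_factor = 0.30
            else:
                cand = np.array([rng.uniform(0, width), rng.uniform(y0, y1)])
                min_sep_factor = 0.62
            if existing:
                pts = np.asarray(existing)
                d = np.hypot(pts[:, 0] - cand[0], pts[:, 1] - cand[1])
                lim = min_sep_factor * (np.asarray(existing_diam) + diam[i]) / 2.0 * 2.0
                if pairing:
                    # allow closeness only to the chosen partner
                    ok = d >= lim
                    ok[j] = d[j] >= 0.30 * (bd + diam[i])
                    if not np.all(ok):
                        continue
                elif np.any(d < lim):
                    continue
            centers[i] = cand
            existing.append(cand.copy())
            existing_diam.append(float(diam[i]))
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place cell {i} in band [{y0:.0f},{y1:.0f}] μm "
                f"after {max_tries} tries"
            )
    return centers


def _rasterize(polys_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise polygons (px coordinates, (n, V, 2) as x, y) into a
    per-cell uint32 label image; later cells overwrite earlier ones."""
    from skimage.draw import polygon as draw_polygon

    labels = np.zeros(shape, dtype=np.uint32)
    for i, poly in enumerate(polys_px, start=1):
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        labels[rr, cc] = i
    return labels


def _illumination_field(shape: tuple[int, int], amp: float,
                        rng: np.random.Generator) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    zoom = (shape[0] / 8, shape[1] / 8)
    field_ = ndi.zoom(coarse, zoom, order=3)[: shape[0], : shape[1]]
    field_ = field_ / max(np.abs(field_).max(), 1e-9)
    out = np.zeros(shape)
    out[: field_.shape[0], : field_.shape[1]] = field_
    return amp * out


def render_section(
    layers: Sequence[LayerSpec],
    effect: GroupEffect,
    spec: CohortSpec,
    rng: np.random.Generator,
    archetypes: Mapping[str, ShapeArchetype] | None = None,
    animal: str = "",
    group: str = "",
    section: int = 0,
    image_id: str = "",
) -> SectionRecord:
    """Render one synthetic Nissl section with full ground truth.

    Returns the 8-bit image (dark somata on bright neuropil), the layer
    label map, the per-cell truth label image and the per-cell feature
    table.  Deterministic given the rng state.
    """
    archetypes = archetypes or default_archetypes()
    nrows, ncols = spec.image_size
    height, width = spec.field_size_um
    noise = spec.noise

    all_polys, all_names, all_layers, all_centers = [], [], [], []
    existing: list[np.ndarray] = []
    existing_diam: list[float] = []
    for layer, (lid, y0, y1) in zip(layers, layer_bands(layers)):
        if y1 > height + 1e-9:
            raise ValueError("layer stack deeper than the image field")
        polys, names = _sample_layer_cells(layer, effect, archetypes, y0, y1, width, rng)
        if len(polys) == 0:
            continue
        centers = _place_centers(polys, y0, y1, width, spec.touching_fraction,
                                 rng, existing, existing_diam)
        all_polys.append(polys + centers[:, None, :])
        all_names.extend(names)
        all_layers.extend([lid] * len(polys))
        all_centers.append(centers)

    # layer map
    layer_map = np.zeros((nrows, ncols), dtype=np.uint8)
    yy = (np.arange(nrows) + 0.5) * spec.pixel_size
    for li, (lid, y0, y1) in enumerate(layer_bands(layers), start=1):
        layer_map[(yy >= y0) & (yy < y1), :] = li

    # neuropil background
    img = np.full((nrows, ncols), noise.neuropil_mean)
    img += _illumination_field((nrows, ncols), noise.illumination_amp, rng)
    img += rng.normal(0.0, noise.texture_sd, size=(nrows, ncols))

    if all_polys:
        polys_um = np.concatenate(all_polys, axis=0)
        truth_labels = _rasterize(polys_um / spec.pixel_size, (nrows, ncols))
        shade = np.clip(
            noise.cell_intensity
            + rng.normal(0.0, noise.staining_jitter_sd, size=len(polys_um)),
            0.05, 0.6,
        )
        mask = truth_labels > 0
        img[mask] = shade[truth_labels[mask] - 1] + rng.normal(
            0.0, noise.texture_sd / 2.0, size=int(mask.sum())
        )
        cells = polygon_morphometrics(polys_um)
        counts = neighbor_counts(cells[["centroid_x", "centroid_y"]].to_numpy())
        cells["density_50"] = counts[:, 0]
        cells["density_100"] = counts[:, 1]
        cells["layer"] = all_layers
        cells["cell_type"] = all_names
        cells["label"] = np.arange(1, len(polys_um) + 1)
    else:
        truth_labels = np.zeros((nrows, ncols), dtype=np.uint32)
        cells = pd.DataFrame(columns=FEATURE_COLUMNS + ["layer", "cell_type",
                                                        "centroid_x", "centroid_y",
                                                        "label"])

    # glia-scale distractors (dark dots below the neuron size floor)
    n_glia = int(rng.poisson(noise.glia_per_mm2 * height * width / 1e6))
    if n_glia:
        gx = rng.uniform(0, ncols, size=n_glia)
        gy = rng.uniform(0, nrows, size=n_glia)
        gr = noise.glia_diameter / 2.0 / spec.pixel_size
        from skimage.draw import disk as draw_disk

        for k in range(n_glia):
            rr, cc = draw_disk((gy[k], gx[k]), max(gr, 1.0), shape=(nrows, ncols))
            keep = truth_labels[rr, cc] == 0
            img[rr[keep], cc[keep]] = noise.cell_intensity + 0.1

    image = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    cells = cells.assign(animal=animal, group=group, section=section,
                         image_id=image_id)
    return SectionRecord(image=image, layer_map=layer_map,
                         truth_labels=truth_labels, cells=cells,
                         pixel_size=spec.pixel_size, animal=animal,
                         group=group, section=section, image_id=image_id)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def cohort_metadata(spec: CohortSpec) -> pd.DataFrame:
    """One row per section: image id, animal, group, section index."""
    rows = []
    for gi, group in enumerate(GROUP_NAMES):
        for a in range(spec.n_animals[gi]):
            animal = f"{group}-{a + 1}"
            for s in range(1, spec.sections_per_animal + 1):
                rows.append({
                    "image_id": f"{animal}-s{s}", "animal": animal,
                    "group": group, "section": s,
                })
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
    layers: Sequence[LayerSpec] | None = None,
    group_effects: Mapping[str, GroupEffect] | None = None,
    archetypes: Mapping[str, ShapeArchetype] | None = None,
    render: bool = True,
) -> CohortDataset:
    """Generate the full synthetic cohort.

    With ``render=True`` every section is rendered as an image with
    layer map and truth labels; with ``render=False`` only the per-cell
    ground-truth feature tables are produced (truth-bypass mode, orders
    of magnitude faster).  Identical ``spec.seed`` gives a bit-identical
    dataset.
    """
    layers = list(layers) if layers is not None else default_layers()
    group_effects = dict(group_effects) if group_effects is not None else identity_effects()
    meta = cohort_metadata(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(meta))
    meta["seed"] = [int(s.generate_state(1)[0]) for s in seeds]
    sections: list[SectionRecord] | None = [] if render else None
    frames = []
    for i, row in meta.iterrows():
        rng = np.random.default_rng(seeds[i])
        effect = group_effects[row["group"]]
        if render:
            rec = render_section(layers, effect, spec, rng, archetypes,
                                 animal=row["animal"], group=row["group"],
                                 section=row["section"], image_id=row["image_id"])
            sections.append(rec)
            frames.append(rec.cells)
        else:
            cells = sample_section_truth(layers, effect, spec, rng, archetypes)
            cells = cells.assign(animal=row["animal"], group=row["group"],
                                 section=row["section"], image_id=row["image_id"])
            frames.append(cells)
    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return CohortDataset(metadata=meta, cells=cells, sections=sections)
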