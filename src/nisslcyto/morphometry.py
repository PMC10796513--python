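"""Per-cell morphometric descriptors in three domains.

Size: area, major/minor axis lengths, perimeter (all calibrated to μm).
Shape: inverse aspect ratio, extent, eccentricity, solidity, convex
circularity (all dimensionless).  Density: number of other neurons
within 50 and 100 μm of each neuron's centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton, regionprops

from .synthetic import DENSITY_RADII, FEATURE_COLUMNS, neighbor_counts

__all__ = [
    "MorphometricRecord", "compute_morphometrics", "compute_density",
    "assign_layer", "measure_cells", "FEATURE_COLUMNS",
]


@dataclass
class MorphometricRecord:
    """Descriptor vector for one segmented neuron (lengths in μm)."""

    area: float
    major_axis: float
    minor_axis: float
    perimeter: float
    invAR: float
    extent: float
    eccentricity: float
    solidity: float
    convex_circularity: float
    density_50: int | None = None
    density_100: int | None = None


def compute_morphometrics(mask: np.ndarray, pixel_size: float) -> MorphometricRecord:
    """Size- and shape-domain descriptors of a single-object mask.

    Axes and eccentricity come from the ellipse with the same
    normalised second central moments as the object; solidity is
    area over convex-hull area; extent is area over axis-aligned
    bounding-box area; convex circularity is 4π·A_hull/P_hull² of the
    convex hull.  Perimeters use the Crofton multi-direction estimator
    to limit rasterisation bias.

    Raises ``ValueError`` for an empty or multi-component mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, n_comp = ndi.label(mask)
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")
    props = regionprops(mask.astype(np.uint8))[0]
    px, px2 = pixel_size, pixel_size**2
    area = props.area * px2
    hull = props.image_convex
    hull_area = hull.sum() * px2
    hull_perim = perimeter_crofton(hull, directions=4) * px
    major = props.axis_major_length * px
    minor = props.axis_minor_length * px
    return MorphometricRecord(
        area=area,
        major_axis=major,
        minor_axis=minor,
        perimeter=perimeter_crofton(props.image, directions=4) * px,
        invAR=minor / major if major > 0 else 1.0,
        extent=props.extent,
        eccentricity=props.eccentricity,
        solidity=min(props.solidity, 1.0),
        convex_circularity=min(4.0 * np.pi * hull_area / hull_perim**2, 1.0),
    )


def compute_density(centroids: np.ndarray,
                    radii=DENSITY_RADII) -> np.ndarray:
    """Neighbour counts per cell for one section (self excluded).

    ``centroids`` in μm, shape (n, 2); counts are centroid-to-centroid
    across all layers of the section, without edge correction.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or len(centroids) == 0:
        raise ValueError("need at least one centroid of shape (n, 2)")
    return neighbor_counts(centroids, radii)


def assign_layer(centroid_rc: tuple[float, float], layer_map: np.ndarray,
                 layer_names=("I", "II", "III", "IV", "V", "VI")) -> str | None:
    """Layer of the centroid pixel; ``None`` for background (excluded)."""
    r = int(np.clip(round(centroid_rc[0]), 0, layer_map.shape[0] - 1))
    c = int(np.clip(round(centroid_rc[1]), 0, layer_map.shape[1] - 1))
    lab = int(layer_map[r, c])
    return None if lab == 0 else layer_names[lab - 1]


def measure_cells(cell_labels: np.ndarray, layer_map: np.ndarray,
                  pixel_size: float) -> pd.DataFrame:
    """Full per-cell table for one segmented section.

    Border-touching cells keep their centroid for the density counts of
    other cells but are flagged (``border=True``) and their own
    morphometrics are computed on the truncated mask.  Cells whose
    centroid falls on background are flagged ``excluded``.
    """
    nrows, ncols = cell_labels.shape
    rows = []
    for props in regionprops(cell_labels.astype(np.int64)):
        r0, c0, r1, c1 = props.bbox
        px, px2 = pixel_size, pixel_size**2
        hull = props.image_convex
        hull_area = hull.sum() * px2
        hull_perim = perimeter_crofton(hull, directions=4) * px
        major = props.axis_major_length * px
        minor = props.axis_minor_length * px
        layer = assign_layer(props.centroid, layer_map)
        rows.append({
            "label": props.label,
            "area": props.area * px2,
            "major_axis": major,
            "minor_axis": minor,
            "perimeter": perimeter_crofton(props.image, directions=4) * px,
            "invAR": minor / major if major > 0 else 1.0,
            "extent": props.extent,
            "eccentricity": props.eccentricity,
            "solidity": min(props.solidity, 1.0),
            "convex_circularity": min(4.0 * np.pi * hull_area / max(hull_perim, 1e-9)**2, 1.0),
            "centroid_x": props.centroid[1] * px,
            "centroid_y": props.centroid[0] * px,
            "layer": layer,
            "border": r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols,
            "excluded": layer is None,
        })
    cells = pd.DataFrame(rows)
    if len(cells):
        counts = compute_density(cells[["centroid_x", "centroid_y"]].to_numpy())
        cells["density_50"] = counts[:, 0]
        cells["density_100"] = counts[:, 1]
    return cells
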