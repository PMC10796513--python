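"""Neuron delineation in Nissl sections.

Six-stage procedure: (1) pre-processing (greyscale, Gaussian smoothing,
percentile contrast stretch, multiplicative neuropil standardisation);
(2) foreground extraction by triangle thresholding of the image
combined with a summed multi-scale Laplacian-of-Gaussian map, refined
by morphology; (3) marker definition via the extended h-maxima
transform of a second (per-scale maximum) multi-scale map; (4)
marker-controlled watershed over a relief blending gradient magnitude
with the inverted multi-scale map, deliberately over-segmenting cells
into superpixels; (5) supervised merging of adjacent superpixels by a
random-forest classifier on rotation-invariant pair features; (6)
post-processing: hole filling, opening, a glia-exclusion minimum-area
filter, Chan–Vese contour refinement, and a second random forest that
rejects false-positive objects.

Training annotations come from the synthetic generator's ground truth;
the feature schemas are versioned so real manual annotations can
substitute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology, util
from skimage import segmentation as skseg
from skimage.color import rgb2gray
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton, regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "SegConfig", "SuperpixelGraph", "preprocess", "multiscale_log_map",
    "extract_foreground", "detect_markers", "build_relief",
    "watershed_superpixels", "pair_features", "merge_superpixels",
    "train_merge_classifier", "train_fp_classifier", "refine_and_filter",
    "segment_cells", "match_objects",
]

PAIR_FEATURE_SCHEMA = "pair-features-1"
OBJECT_FEATURE_SCHEMA = "object-features-1"


@dataclass(frozen=True)
class SegConfig:
    """All tunable constants of the delineation procedure.

    Scales are in pixels; areas in μm².  ``log_sigmas`` should span the
    expected soma radii divided by √2 (LoG scale selection); defaults
    assume 0.5 μm/px and roughly 4–17 μm equivalent-diameter neurons.
    """

    gaussian_sigma: float = 1.0
    neuropil_target: float | None = 0.75      # None disables the correction
    stretch_percentiles: tuple[float, float] | None = (1.0, 99.0)
    log_sigmas: tuple[float, ...] = (3.0, 4.0, 6.0, 8.0, 11.0, 14.0)
    h_maxima: float = 0.08
    relief_alpha: float = 0.5
    min_area: float = 20.0           # μm², glia-exclusion floor
    pixel_size: float = 0.5          # μm / px
    chan_vese_iters: int = 40
    chan_vese_tol: float = 1e-3
    merge_threshold: float = 0.5
    morph_radius: int = 1

    def __post_init__(self) -> None:
        if len(self.log_sigmas) < 2 or np.any(np.diff(self.log_sigmas) <= 0):
            raise ValueError("log_sigmas must be >= 2 strictly increasing scales")
        if self.h_maxima <= 0:
            raise ValueError("h_maxima must be > 0")
        if self.min_area <= 0:
            raise ValueError("min_area must be > 0")

    @property
    def min_area_px(self) -> float:
        return self.min_area / self.pixel_size**2


@dataclass
class SuperpixelGraph:
    """Watershed over-segmentation: label image plus adjacency."""

    labels: np.ndarray                       # 0 background, >0 superpixels
    adjacency: list[tuple[int, int]]         # canonical (a < b) pairs
    boundary_len: dict[tuple[int, int], int]


# ---------------------------------------------------------------------------
# stage 1: pre-processing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Greyscale conversion, smoothing, contrast stretch, neuropil
    standardisation.  Output floats in [0, 1], cells stay dark.

    The neuropil summary is the median intensity outside a provisional
    triangle-threshold foreground; a multiplicative factor maps it to
    ``cfg.neuropil_target``.  Constant images pass through the contrast
    step unchanged.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = rgb2gray(img)
    img = util.img_as_float(img).astype(float)
    if cfg.gaussian_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.gaussian_sigma)
    if cfg.stretch_percentiles is not None:
        lo, hi = np.percentile(img, cfg.stretch_percentiles)
        if hi - lo > 1e-9:
            img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    if cfg.neuropil_target is not None:
        # provisional foreground on the darkness channel
        cellness = 1.0 - img
        if np.ptp(cellness) > 1e-9:
            thr = filters.threshold_triangle(cellness)
            neuropil = img[cellness <= thr]
        else:
            neuropil = img.ravel()
        med = np.median(neuropil)
        if med > 1e-9:
            img = img * (cfg.neuropil_target / med)
        img = np.clip(img, 0.0, 1.0)
    return img


# ---------------------------------------------------------------------------
# stage 2: multi-scale maps and foreground
# ---------------------------------------------------------------------------

def multiscale_log_map(image: np.ndarray,
                       log_sigmas=None, combine: str = "sum") -> np.ndarray:
    """Combined scale-normalised LoG map; dark-blob centres are high.

    Each scale contributes σ²·(∇²G_σ * image), which is positive at the
    centre of a dark blob; ``combine`` is "sum" (foreground map) or
    "max" (marker map).
    """
    sigmas = tuple(log_sigmas) if log_sigmas is not None else (3.0, 6.0, 11.0)
    if len(sigmas) < 1:
        raise ValueError("need >= 1 scale")
    responses = np.stack([
        s**2 * ndi.gaussian_laplace(np.asarray(image, dtype=float), s)
        for s in sigmas
    ])
    if combine == "sum":
        return responses.sum(axis=0)
    if combine == "max":
        return responses.max(axis=0)
    raise ValueError(f"unknown combine mode {combine!r}")


def _normalize(a: np.ndarray) -> np.ndarray:
    rng = np.ptp(a)
    return (a - a.min()) / rng if rng > 1e-12 else np.zeros_like(a)


def extract_foreground(image: np.ndarray, log_map: np.ndarray,
                       cfg: SegConfig) -> np.ndarray:
    """Triangle threshold of darkness + multi-scale map, then morphology.

    The operand is the inverted image plus the normalised combined map
    (both high on cells); an empty mask is a legal outcome for a blank
    section.
    """
    operand = (1.0 - np.asarray(image, dtype=float)) + _normalize(log_map)
    if np.ptp(operand) < 1e-9:
        return np.zeros(operand.shape, dtype=bool)
    thr = filters.threshold_triangle(operand)
    mask = operand > thr
    selem = morphology.disk(cfg.morph_radius)
    mask = morphology.opening(mask, selem)
    mask = morphology.closing(mask, selem)
    # shave the halo the multi-scale map adds around each blob
    mask = morphology.erosion(mask, selem)
    return ndi.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# stage 3: markers
# ---------------------------------------------------------------------------

def detect_markers(image: np.ndarray, cfg: SegConfig,
                   foreground: np.ndarray | None = None) -> np.ndarray:
    """Watershed seeds from the extended h-maxima of the marker map.

    The marker map is the per-scale *maximum* of the LoG bank (one
    dominant scale per soma).  Returns a labelled marker image; each
    connected component of the h-maxima set restricted to the
    foreground is one marker.  Zero markers is a legal outcome.
    """
    mmap = _normalize(multiscale_log_map(image, cfg.log_sigmas, combine="max"))
    peaks = morphology.h_maxima(mmap, cfg.h_maxima)
    if foreground is not None:
        dropped = peaks.astype(bool) & ~foreground
        if dropped.any():
            logger.debug("dropped %d marker pixels outside foreground",
                         int(dropped.sum()))
        peaks = peaks.astype(bool) & foreground
    return cc_label(peaks, connectivity=2)


# ---------------------------------------------------------------------------
# stage 4: watershed superpixels
# ---------------------------------------------------------------------------

def build_relief(image: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Flooding relief: (1−α)·gradient magnitude + α·inverted LoG map."""
    grad = _normalize(filters.sobel(np.asarray(image, dtype=float)))
    inv_map = 1.0 - _normalize(
        multiscale_log_map(image, cfg.log_sigmas, combine="sum"))
    a = cfg.relief_alpha
    return (1.0 - a) * grad + a * inv_map


def watershed_superpixels(relief: np.ndarray, markers: np.ndarray,
                          foreground: np.ndarray) -> SuperpixelGraph:
    """Marker-controlled watershed restricted to the foreground.

    Markers entirely outside the foreground are dropped with a warning.
    Foreground components containing no marker remain unlabelled and
    are treated as background downstream.
    """
    markers = np.asarray(markers)
    outside = np.unique(markers[(markers > 0) & ~foreground])
    inside = np.unique(markers[(markers > 0) & foreground])
    truly_outside = np.setdiff1d(outside, inside)
    if len(truly_outside):
        warnings.warn(f"{len(truly_outside)} markers outside foreground dropped",
                      stacklevel=2)
        markers = np.where(np.isin(markers, truly_outside), 0, markers)
    if not (markers > 0).any():
        raise ValueError("need >= 1 marker inside the foreground")
    labels = skseg.watershed(relief, markers=markers, mask=foreground)
    return _graph_from_labels(labels)


def _graph_from_labels(labels: np.ndarray) -> SuperpixelGraph:
    pairs: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = labels.take(range(labels.shape[axis] - 1), axis=axis).ravel()
        b = labels.take(range(1, labels.shape[axis]), axis=axis).ravel()
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        keys, cnts = np.unique(np.column_stack([lo, hi]), axis=0,
                               return_counts=True)
        for key, cnt in zip(keys, cnts):
            k = (int(key[0]), int(key[1]))
            pairs[k] = pairs.get(k, 0) + int(cnt)
    return SuperpixelGraph(labels=labels, adjacency=sorted(pairs),
                           boundary_len=pairs)


# ---------------------------------------------------------------------------
# stage 5: pair features and supervised merging
# ---------------------------------------------------------------------------

PAIR_FEATURE_NAMES = [
    "area_min", "area_max", "area_ratio", "perim_min", "perim_max",
    "solidity_min", "solidity_max", "union_solidity", "solidity_gain",
    "ecc_min", "ecc_max", "union_ecc", "union_convex_circ",
    "boundary_frac", "centroid_dist_norm",
    "int_mean_lo", "int_mean_hi", "int_mean_absdiff", "int_sd_min",
    "int_sd_max", "boundary_contrast",
]


def _region_stats(labels: np.ndarray, image: np.ndarray) -> dict[int, dict]:
    stats = {}
    for p in regionprops(labels.astype(np.int64), intensity_image=image):
        stats[p.label] = {
            "area": p.area, "perimeter": max(p.perimeter, 1.0),
            "solidity": p.solidity, "ecc": p.eccentricity,
            "centroid": np.array(p.centroid),
            "int_mean": p.intensity_mean,
            "int_sd": float(np.std(p.image_intensity[p.image])),
            "bbox": p.bbox,
        }
    return stats


def _union_stats(labels: np.ndarray, a: int, b: int,
                 sa: dict, sb: dict) -> dict:
    r0 = min(sa["bbox"][0], sb["bbox"][0])
    c0 = min(sa["bbox"][1], sb["bbox"][1])
    r1 = max(sa["bbox"][2], sb["bbox"][2])
    c1 = max(sa["bbox"][3], sb["bbox"][3])
    patch = labels[r0:r1, c0:c1]
    mask = (patch == a) | (patch == b)
    props = regionprops(mask.astype(np.uint8))[0]
    hull = props.image_convex
    hull_perim = max(perimeter_crofton(hull, directions=4), 1.0)
    return {
        "solidity": props.solidity, "ecc": props.eccentricity,
        "convex_circ": min(4 * np.pi * hull.sum() / hull_perim**2, 1.0),
    }


def pair_features(graph: SuperpixelGraph, image: np.ndarray) -> pd.DataFrame:
    """Rotation-invariant morphological/structural/intensity features
    for every adjacent superpixel pair.

    Symmetric in the pair by construction (min/max ordering), invariant
    to label permutation and to image rotation by multiples of 90°.
    """
    image = np.asarray(image, dtype=float)
    stats = _region_stats(graph.labels, image)
    rows = [
        _one_pair_features(graph, image, a, b, stats[a], stats[b])
        for a, b in graph.adjacency
    ]
    return pd.DataFrame(rows, columns=["a", "b"] + PAIR_FEATURE_NAMES)


def _one_pair_features(graph: SuperpixelGraph, image: np.ndarray,
                       a: int, b: int, sa: dict, sb: dict) -> dict:
    u = _union_stats(graph.labels, a, b, sa, sb)
    blen = graph.boundary_len.get((min(a, b), max(a, b)), 0)
    area_lo, area_hi = sorted([sa["area"], sb["area"]])
    scale = np.sqrt(sa["area"] + sb["area"])
    w = np.array([sa["area"], sb["area"]], dtype=float)
    weighted_sol = (w[0] * sa["solidity"] + w[1] * sb["solidity"]) / w.sum()
    mean_lo, mean_hi = sorted([sa["int_mean"], sb["int_mean"]])
    return {
        "a": a, "b": b,
        "area_min": area_lo, "area_max": area_hi,
        "area_ratio": area_lo / area_hi,
        "perim_min": min(sa["perimeter"], sb["perimeter"]),
        "perim_max": max(sa["perimeter"], sb["perimeter"]),
        "solidity_min": min(sa["solidity"], sb["solidity"]),
        "solidity_max": max(sa["solidity"], sb["solidity"]),
        "union_solidity": u["solidity"],
        "solidity_gain": u["solidity"] - weighted_sol,
        "ecc_min": min(sa["ecc"], sb["ecc"]),
        "ecc_max": max(sa["ecc"], sb["ecc"]),
        "union_ecc": u["ecc"],
        "union_convex_circ": u["convex_circ"],
        "boundary_frac": blen / min(sa["perimeter"], sb["perimeter"]),
        "centroid_dist_norm": float(
            np.linalg.norm(sa["centroid"] - sb["centroid"]) / max(scale, 1.0)),
        "int_mean_lo": mean_lo, "int_mean_hi": mean_hi,
        "int_mean_absdiff": mean_hi - mean_lo,
        "int_sd_min": min(sa["int_sd"], sb["int_sd"]),
        "int_sd_max": max(sa["int_sd"], sb["int_sd"]),
        "boundary_contrast": _boundary_contrast(graph.labels, image, a, b,
                                                sa, sb),
    }


def _boundary_contrast(labels: np.ndarray, image: np.ndarray,
                       a: int, b: int, sa: dict, sb: dict) -> float:
    """Mean intensity on the a|b interface minus the mean of the two
    region means (ridges between distinct cells are brighter)."""
    r0 = min(sa["bbox"][0], sb["bbox"][0])
    c0 = min(sa["bbox"][1], sb["bbox"][1])
    r1 = max(sa["bbox"][2], sb["bbox"][2])
    c1 = max(sa["bbox"][3], sb["bbox"][3])
    lab = labels[r0:r1, c0:c1]
    img = image[r0:r1, c0:c1]
    vals = []
    for axis in (0, 1):
        l1 = lab.take(range(lab.shape[axis] - 1), axis=axis)
        l2 = lab.take(range(1, lab.shape[axis]), axis=axis)
        i1 = img.take(range(img.shape[axis] - 1), axis=axis)
        i2 = img.take(range(1, img.shape[axis]), axis=axis)
        sel = ((l1 == a) & (l2 == b)) | ((l1 == b) & (l2 == a))
        if sel.any():
            vals.append((i1[sel] + i2[sel]) / 2.0)
    if not vals:
        return 0.0
    iface = float(np.concatenate(vals).mean())
    return iface - float((sa["int_mean"] + sb["int_mean"]) / 2.0)


def _fit_rf(X: np.ndarray, y: np.ndarray, seed: int, feature_names: list[str],
            schema: str):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.25,
                                          random_state=seed, stratify=y)
    clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(Xtr, ytr)
    acc = float(clf.score(Xte, yte))
    clf.feature_schema = schema
    clf.feature_names = feature_names
    clf.holdout_accuracy = acc
    logger.info("%s: held-out accuracy %.3f (n=%d)", schema, acc, len(y))
    return clf


def superpixel_truth_labels(graph: SuperpixelGraph,
                            truth_labels: np.ndarray) -> dict[int, int]:
    """Majority ground-truth cell id per superpixel (0 = background)."""
    out = {}
    for p in regionprops(graph.labels.astype(np.int64)):
        r0, c0, r1, c1 = p.bbox
        vals = truth_labels[r0:r1, c0:c1][p.image]
        ids, counts = np.unique(vals, return_counts=True)
        out[p.label] = int(ids[np.argmax(counts)])
    return out


def train_merge_classifier(sections, cfg: SegConfig, seed: int):
    """Fit the merge classifier on generator fixtures with truth.

    ``sections`` are SectionRecord fixtures (ideally with a nonzero
    touching-cell fraction).  Adjacent superpixel pairs are labelled
    "merge" when both map to the same ground-truth cell.  Returns a
    fitted random forest with a held-out accuracy report; deterministic
    given the seed.
    """
    frames, labels = [], []
    for rec in sections:
        graph, pre = _superpixels_for(rec.image, cfg)
        feats = pair_features(graph, pre)
        truth = superpixel_truth_labels(graph, rec.truth_labels)
        y = [int(truth[a] != 0 and truth[a] == truth[b])
             for a, b in zip(feats["a"], feats["b"])]
        frames.append(feats[PAIR_FEATURE_NAMES])
        labels.extend(y)
    X = pd.concat(frames, ignore_index=True).to_numpy(float)
    return _fit_rf(X, np.asarray(labels), seed, PAIR_FEATURE_NAMES,
                   PAIR_FEATURE_SCHEMA)


OBJECT_FEATURE_NAMES = [
    "area", "perimeter", "solidity", "ecc", "hull_fill",
    "int_mean", "int_sd", "contrast", "convex_circ",
]


def object_features(labels: np.ndarray, image: np.ndarray,
                    cfg: SegConfig) -> pd.DataFrame:
    """Per-object features for false-positive filtering (μm-calibrated
    area; intensity contrast against the neuropil target)."""
    rows = []
    px2 = cfg.pixel_size**2
    for p in regionprops(labels.astype(np.int64),
                         intensity_image=np.asarray(image, dtype=float)):
        hull = p.image_convex
        hull_perim = max(perimeter_crofton(hull, directions=4), 1.0)
        rows.append({
            "label": p.label,
            "area": p.area * px2,
            "perimeter": perimeter_crofton(p.image, directions=4) * cfg.pixel_size,
            "solidity": p.solidity,
            "ecc": p.eccentricity,
            "hull_fill": p.area / max(hull.sum(), 1),
            "int_mean": p.intensity_mean,
            "int_sd": float(np.std(p.image_intensity[p.image])),
            "contrast": cfg.neuropil_target - p.intensity_mean,
            "convex_circ": min(4 * np.pi * hull.sum() / hull_perim**2, 1.0),
        })
    return pd.DataFrame(rows, columns=["label"] + OBJECT_FEATURE_NAMES)


def train_fp_classifier(sections, cfg: SegConfig, seed: int,
                        merge_classifier=None):
    """Fit the false-positive filter on generator fixtures.

    Candidate objects are taken *before* the minimum-area filter so
    glia-scale distractors appear as negative examples; positives are
    candidates matching a ground-truth cell (IoU >= 0.5).
    """
    frames, labels = [], []
    for rec in sections:
        cand = _candidates(rec.image, cfg, merge_classifier)
        feats = object_features(cand, preprocess(rec.image, cfg), cfg)
        matched = _match_labels(cand, rec.truth_labels, iou=0.5)
        y = [int(lab in matched) for lab in feats["label"]]
        frames.append(feats[OBJECT_FEATURE_NAMES])
        labels.extend(y)
    X = pd.concat(frames, ignore_index=True).to_numpy(float)
    return _fit_rf(X, np.asarray(labels), seed, OBJECT_FEATURE_NAMES,
                   OBJECT_FEATURE_SCHEMA)


def merge_superpixels(graph: SuperpixelGraph, image: np.ndarray,
                      classifier, threshold: float = 0.5) -> np.ndarray:
    """Greedy supervised merging of adjacent superpixels.

    All adjacent pairs are scored; merges are applied in descending
    score above ``threshold``, recomputing the affected adjacency and
    features after every merge.  Deterministic given the fitted
    classifier (ties broken by pair id).
    """
    labels = graph.labels.copy()
    image = np.asarray(image, dtype=float)
    pairs = dict(graph.boundary_len)
    stats = _region_stats(labels, image)

    def score(pairlist):
        if not pairlist:
            return {}
        g = SuperpixelGraph(labels=labels, adjacency=sorted(pairlist),
                            boundary_len=pairs)
        feats = pd.DataFrame([
            _one_pair_features(g, image, a, b, stats[a], stats[b])
            for a, b in sorted(pairlist)
        ])
        proba = classifier.predict_proba(
            feats[PAIR_FEATURE_NAMES].to_numpy(float))[:, 1]
        return {(int(r.a), int(r.b)): p
                for r, p in zip(feats.itertuples(), proba)}

    scores = score(list(pairs))
    while scores:
        (a, b), s = max(scores.items(),
                        key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        if s < threshold:
            break
        labels[labels == b] = a
        affected = set()
        for (x, y_) in list(pairs):
            if b in (x, y_):
                blen = pairs.pop((x, y_))
                other = y_ if x == b else x
                if other == a:
                    continue
                key = (min(a, other), max(a, other))
                pairs[key] = pairs.get(key, 0) + blen
                affected.add(key)
        stats.pop(b, None)
        stats.update(_region_stats(
            np.where(labels == a, labels, 0).astype(labels.dtype), image))
        affected |= {k for k in pairs if a in k}
        scores = {k: v for k, v in scores.items() if a not in k and b not in k}
        scores.update(score([k for k in affected if k in pairs]))
    return labels


# ---------------------------------------------------------------------------
# stage 6: refinement and filtering
# ---------------------------------------------------------------------------

def refine_and_filter(masks: np.ndarray, image: np.ndarray, cfg: SegConfig,
                      fp_classifier=None) -> np.ndarray:
    """Post-processing of merged masks into final cell masks.

    Hole filling and opening per object, removal of objects below the
    glia-exclusion ``min_area``, Chan–Vese refinement on a local patch
    (the pre-refinement mask is kept with a warning if the contour
    collapses or drifts), and the false-positive filter.  Never
    increases the object count.
    """
    from skimage.segmentation import chan_vese

    image = np.asarray(image, dtype=float)
    out = np.zeros_like(masks, dtype=np.int32)
    next_label = 0
    for p in regionprops(masks.astype(np.int64)):
        r0, c0, r1, c1 = p.bbox
        pad = 5
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p = min(r1 + pad, masks.shape[0])
        c1p = min(c1 + pad, masks.shape[1])
        mask = np.zeros((r1p - r0p, c1p - c0p), dtype=bool)
        mask[r0 - r0p:r1 - r0p, c0 - c0p:c1 - c0p] = p.image
        mask = ndi.binary_fill_holes(mask)
        mask = morphology.opening(mask, morphology.disk(cfg.morph_radius))
        mask = ndi.binary_fill_holes(mask)
        if mask.sum() < cfg.min_area_px:
            continue
        if cfg.chan_vese_iters > 0:
            patch = image[r0p:r1p, c0p:c1p]
            refined = chan_vese(patch, mu=0.1,
                                max_num_iter=cfg.chan_vese_iters,
                                tol=cfg.chan_vese_tol,
                                init_level_set=mask.astype(float) - 0.5)
            if refined.any() and (~refined).any() and \
                    patch[refined].mean() > patch[~refined].mean():
                refined = ~refined  # keep the dark (cell) phase
            lab = cc_label(refined)
            keep = np.unique(lab[mask])
            refined = np.isin(lab, keep[keep > 0])
            inter = np.logical_and(refined, mask).sum()
            union = np.logical_or(refined, mask).sum()
            if union and inter / union >= 0.5:
                mask = ndi.binary_fill_holes(refined)
            else:
                logger.warning("Chan-Vese did not converge usefully for "
                               "object %d; keeping pre-refinement mask",
                               p.label)
        if mask.sum() < cfg.min_area_px:
            continue
        next_label += 1
        target = out[r0p:r1p, c0p:c1p]
        target[mask & (target == 0)] = next_label
    if fp_classifier is not None and next_label > 0:
        feats = object_features(out, image, cfg)
        keep = fp_classifier.predict(
            feats[OBJECT_FEATURE_NAMES].to_numpy(float)).astype(bool)
        drop = feats.loc[~keep, "label"].to_numpy()
        if len(drop):
            out[np.isin(out, drop)] = 0
    return _relabel(out)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _superpixels_for(image: np.ndarray, cfg: SegConfig):
    pre = preprocess(image, cfg)
    log_sum = multiscale_log_map(pre, cfg.log_sigmas, combine="sum")
    fg = extract_foreground(pre, log_sum, cfg)
    markers = detect_markers(pre, cfg, foreground=fg)
    relief = build_relief(pre, cfg)
    graph = watershed_superpixels(relief, markers, fg)
    return graph, pre


def _candidates(image: np.ndarray, cfg: SegConfig, merge_classifier=None):
    """Merged masks before area filtering / refinement."""
    pre = preprocess(image, cfg)
    log_sum = multiscale_log_map(pre, cfg.log_sigmas, combine="sum")
    fg = extract_foreground(pre, log_sum, cfg)
    markers = detect_markers(pre, cfg, foreground=fg)
    if markers.max() == 0:
        return np.zeros_like(markers, dtype=np.int32)
    graph = watershed_superpixels(build_relief(pre, cfg), markers, fg)
    if merge_classifier is not None:
        return merge_superpixels(graph, pre, merge_classifier,
                                 cfg.merge_threshold).astype(np.int32)
    return graph.labels.astype(np.int32)


def segment_cells(image: np.ndarray, cfg: SegConfig,
                  merge_classifier=None, fp_classifier=None) -> np.ndarray:
    """End-to-end delineation; returns the final cell label image.

    Deterministic given the configuration and fitted classifiers; a
    blank section yields an empty label image.  Stage errors are
    re-raised with the stage name.
    """
    stage = "pre-processing"
    try:
        pre = preprocess(image, cfg)
        stage = "foreground extraction"
        log_sum = multiscale_log_map(pre, cfg.log_sigmas, combine="sum")
        fg = extract_foreground(pre, log_sum, cfg)
        if not fg.any():
            return np.zeros(pre.shape, dtype=np.int32)
        stage = "marker definition"
        markers = detect_markers(pre, cfg, foreground=fg)
        if markers.max() == 0:
            return np.zeros(pre.shape, dtype=np.int32)
        stage = "watershed"
        graph = watershed_superpixels(build_relief(pre, cfg), markers, fg)
        stage = "superpixel merging"
        if merge_classifier is not None:
            merged = merge_superpixels(graph, pre, merge_classifier,
                                       cfg.merge_threshold)
        else:
            merged = graph.labels
        stage = "post-processing"
        return refine_and_filter(merged, pre, cfg, fp_classifier)
    except (ValueError, RuntimeError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc


def match_objects(pred_labels: np.ndarray, true_labels: np.ndarray,
                  iou: float = 0.5) -> dict:
    """Object-level evaluation by Hungarian matching on the IoU matrix.

    Returns precision, recall and the matched (pred, true) pairs at the
    given IoU threshold.
    """
    from scipy.optimize import linear_sum_assignment

    pred_ids = np.unique(pred_labels)
    pred_ids = pred_ids[pred_ids > 0]
    true_ids = np.unique(true_labels)
    true_ids = true_ids[true_ids > 0]
    if len(pred_ids) == 0 or len(true_ids) == 0:
        return {"precision": 0.0, "recall": 0.0, "matches": [],
                "n_pred": len(pred_ids), "n_true": len(true_ids)}
    iou_mat = _iou_matrix(pred_labels, true_labels, pred_ids, true_ids)
    ri, ci = linear_sum_assignment(-iou_mat)
    matches = [(int(pred_ids[r]), int(true_ids[c]))
               for r, c in zip(ri, ci) if iou_mat[r, c] >= iou]
    return {
        "precision": len(matches) / len(pred_ids),
        "recall": len(matches) / len(true_ids),
        "matches": matches, "n_pred": len(pred_ids), "n_true": len(true_ids),
    }


def _match_labels(pred_labels: np.ndarray, true_labels: np.ndarray,
                  iou: float) -> set[int]:
    return {a for a, _ in match_objects(pred_labels, true_labels, iou)["matches"]}


def _iou_matrix(pred: np.ndarray, true: np.ndarray,
                pred_ids: np.ndarray, true_ids: np.ndarray) -> np.ndarray:
    pmap = np.zeros(int(pred.max()) + 1, dtype=np.int64)
    pmap[pred_ids] = np.arange(1, len(pred_ids) + 1)
    tmap = np.zeros(int(true.max()) + 1, dtype=np.int64)
    tmap[true_ids] = np.arange(1, len(true_ids) + 1)
    p = pmap[pred.astype(np.int64)]
    t = tmap[true.astype(np.int64)]
    inter = np.zeros((len(pred_ids) + 1, len(true_ids) + 1), dtype=np.int64)
    np.add.at(inter, (p.ravel(), t.ravel()), 1)
    inter = inter[1:, 1:]
    p_area = np.bincount(p.ravel(), minlength=len(pred_ids) + 1)[1:]
    t_area = np.bincount(t.ravel(), minlength=len(true_ids) + 1)[1:]
    union = p_area[:, None] + t_area[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / union, 0.0)
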