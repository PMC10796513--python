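"""Group comparison by permutation: pseudo-observations, Welch-type
statistics, nonparametric Fisher combination, max-t FWER correction.

Cells within one image are not independent, so each image contributes a
single *pseudo-observation* per stratum: the mean of each feature over
that image's cells in a (layer × cell-type) stratum.  Pseudo-
observations are independent across images but heteroscedastic across
groups, so the univariate test statistic is the Welch one-way F for the
three age classes, and inference is by permutation of the group labels.
The p-value convention includes the identity permutation and counts
ties, p = (1 + #{b : T_b >= T_obs}) / (B + 1), which guarantees
validity and p >= 1/(B+1).

Univariate tests sharing one synchronized set of label shuffles are
combined per hypothesis with Fisher's nonparametric combination
(T_b = −2 Σ_j log p_{j,b}, with the partial p of each permutation
computed by within-feature rank), and families of combined hypotheses
(e.g. the six layers of one domain) are corrected by single-step
Westfall–Young max-t on the same shuffles, with per-hypothesis rank
standardisation so hypotheses with different feature counts are
comparable.  Significance level defaults to alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS, GROUP_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS", "PermutationScheme", "make_pseudo_observations",
    "welch_f", "univariate_perm_test", "npc_fisher", "maxt_adjust",
    "run_family", "FAMILIES", "significance_stars",
]

#: the three statistical domains and their features
DOMAINS = {
    "size": ["area", "major_axis", "minor_axis", "perimeter"],
    "shape": ["invAR", "extent", "eccentricity", "solidity", "convex_circularity"],
    "density": ["density_50", "density_100"],
}

FAMILIES = ("by_layer", "domain_by_layer", "domain_by_type_layer",
            "feature_by_type_layer")

LAYERS = ("I", "II", "III", "IV", "V", "VI")

ALPHA = 0.05


@dataclass(frozen=True)
class PermutationScheme:
    """Synchronized random label shuffles shared across a hypothesis
    family (required for max-t).  The identity permutation is always
    included as the first row."""

    B: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 19:
            raise ValueError("B must be >= 19")

    def permutations(self, n: int) -> np.ndarray:
        """(B + 1, n) index matrix; row 0 is the identity."""
        rng = np.random.default_rng(self.seed)
        perms = np.empty((self.B + 1, n), dtype=np.intp)
        perms[0] = np.arange(n)
        for b in range(1, self.B + 1):
            perms[b] = rng.permutation(n)
        return perms


def make_pseudo_observations(cells: pd.DataFrame,
                             features: list[str] | None = None) -> pd.DataFrame:
    """Per-image mean feature vectors, by layer and cell type.

    Returns one row per (image × layer × cell_type) stratum that has at
    least one contributing cell — strata with no cells are missing, not
    zero.  Rows with ``cell_type == "all"`` pool the four classes.
    """
    features = features or FEATURE_COLUMNS
    if len(cells) == 0:
        return pd.DataFrame(columns=["image_id", "animal", "group", "layer",
                                     "cell_type", "n_cells"] + features)
    cells = cells[cells["layer"].notna()]
    keys = ["image_id", "animal", "group", "layer"]

    def agg(df: pd.DataFrame, ctype_col: bool) -> pd.DataFrame:
        g = df.groupby(keys + (["cell_type"] if ctype_col else []), observed=True)
        out = g[features].mean()
        out["n_cells"] = g.size()
        out = out.reset_index()
        if not ctype_col:
            out["cell_type"] = "all"
        return out

    pooled = agg(cells, False)
    per_type = agg(cells, True)
    cols = keys + ["cell_type", "n_cells"] + features
    return pd.concat([pooled[cols], per_type[cols]], ignore_index=True)


def welch_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Welch one-way heteroscedasticity-robust F statistic.

    ``values``: (n,) or (n, F) observations; ``labels``: (n,) or
    (P, n) integer group codes (0..k−1) — one row per permutation.
    Returns the statistic with shape () / (F,) / (P,) / (P, F).
    Permutations where any group has fewer than two observations or a
    zero within-group variance yield +inf (counted as exceeding any
    observed value, hence conservative).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    squeeze_f = values.ndim == 1
    v = values[:, None] if squeeze_f else values          # (n, F)
    squeeze_p = labels.ndim == 1
    lab = labels[None, :] if squeeze_p else labels        # (P, n)
    groups = np.unique(lab[0])
    k = len(groups)
    P, F = lab.shape[0], v.shape[1]
    m = np.empty((k, P, F))
    w = np.empty((k, P, F))
    n_g = np.empty((k, P, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        for gi, g in enumerate(groups):
            sel = (lab == g)[:, :, None]                  # (P, n, 1)
            n_ = sel.sum(axis=1)                          # (P, 1)
            s1 = np.where(sel, v[None], 0.0).sum(axis=1)  # (P, F)
            s2 = np.where(sel, v[None] ** 2, 0.0).sum(axis=1)
            mean = s1 / n_
            var = (s2 - n_ * mean**2) / (n_ - 1)
            m[gi], w[gi], n_g[gi] = mean, n_ / var, n_
        W = w.sum(axis=0)                                 # (P, F)
        xbar = (w * m).sum(axis=0) / W
        A = (w * (m - xbar) ** 2).sum(axis=0) / (k - 1)
        corr = ((1.0 - w / W) ** 2 / (n_g - 1.0)).sum(axis=0)
        B_ = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * corr
        stat = A / B_
    pooled_const = np.ptp(v, axis=0) == 0                 # (F,)
    stat = np.where(pooled_const[None, :], 0.0, stat)
    bad = ~np.isfinite(stat) | (n_g.min(axis=0) < 2)
    stat = np.where(bad & ~pooled_const[None, :], np.inf, stat)
    if squeeze_f:
        stat = stat[:, 0]
    if squeeze_p:
        stat = stat[0]
    return stat


def _count_geq(stats: np.ndarray) -> np.ndarray:
    """For each row b: #{b' : stats[b'] >= stats[b]} (ties included),
    column-wise."""
    s = stats if stats.ndim == 2 else stats[:, None]
    order = np.argsort(s, axis=0, kind="stable")
    n = s.shape[0]
    counts = np.empty_like(s, dtype=float)
    # rank via sorted positions, handling ties by value comparison
    for j in range(s.shape[1]):
        col = s[:, j]
        sorted_vals = col[order[:, j]]
        # number of values >= x is n − (index of first value >= x)
        first_geq = np.searchsorted(sorted_vals, col, side="left")
        counts[:, j] = n - first_geq
    return counts if stats.ndim == 2 else counts[:, 0]


@dataclass
class PermTestResult:
    observed: float
    perm_stats: np.ndarray
    p_value: float


def univariate_perm_test(values: np.ndarray, groups: np.ndarray,
                         scheme: PermutationScheme) -> PermTestResult:
    """Permutation test of group equality for one feature.

    Group labels are randomly reallocated among the pseudo-observations
    (scheme-seeded, identity included) and the Welch F recomputed; the
    p-value is (1 + #{permuted stats >= observed}) / (B + 1).
    """
    values = np.asarray(values, dtype=float)
    codes = _group_codes(groups)
    _check_group_sizes(codes)
    perms = scheme.permutations(len(values))
    stats = welch_f(values, codes[perms])
    p = float(_count_geq(stats)[0] / len(stats))
    return PermTestResult(observed=float(stats[0]), perm_stats=stats, p_value=p)


def _group_codes(groups) -> np.ndarray:
    arr = np.asarray(groups)
    if arr.dtype.kind in "iu":
        return arr.astype(np.intp)
    codes = pd.Categorical(arr, categories=[g for g in GROUP_NAMES
                                            if g in set(arr)] or None).codes
    return codes.astype(np.intp)


def _check_group_sizes(codes: np.ndarray) -> None:
    uniq, counts = np.unique(codes, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 observations")


def npc_fisher(stat_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Fisher nonparametric combination of synchronized permutation tests.

    ``stat_matrix``: (B + 1, F) univariate statistics (row 0 observed)
    computed on the *same* label shuffles.  Each permutation's partial
    p per feature is its within-column proportion of ties-or-larger
    values; the combining statistic is T_b = −2 Σ_j log p_{j,b} and the
    combined p follows the same (1 + #{>=}) / (B + 1) convention.

    Returns (T, combined_p) with T of shape (B + 1,).
    """
    s = np.asarray(stat_matrix, dtype=float)
    if s.ndim != 2:
        raise ValueError("stat_matrix must be (B + 1, F)")
    n = s.shape[0]
    partial_p = _count_geq(s) / n          # in [1/n, 1]
    T = -2.0 * np.log(partial_p).sum(axis=1)
    combined_p = float(_count_geq(T)[0] / n)
    return T, combined_p


def maxt_adjust(T_matrix: np.ndarray) -> np.ndarray:
    """Single-step Westfall–Young max-t adjustment over one family.

    ``T_matrix``: (B + 1, H) combining statistics of the H hypotheses,
    all computed on the same synchronized shuffles (row 0 observed).
    Each hypothesis is rank-standardised to its per-permutation
    "p-scale" u_{h,b} = #{b' : T_{h,b'} >= T_{h,b}} / (B + 1), so
    hypotheses with different feature counts are comparable; the
    adjusted p of hypothesis h is the proportion of permutations whose
    most extreme (minimum) u across the family is <= u_{h,0}.
    Guarantees adjusted >= raw elementwise.
    """
    T = np.asarray(T_matrix, dtype=float)
    if T.ndim != 2 or T.shape[1] == 0:
        raise ValueError("family must contain >= 1 hypothesis")
    n = T.shape[0]
    u = _count_geq(T) / n                  # (B + 1, H), small = extreme
    m = u.min(axis=1)                      # (B + 1,)
    adj = np.array([(m <= u[0, h]).sum() / n for h in range(T.shape[1])])
    return adj


def significance_stars(p: float, alpha: float = ALPHA) -> str:
    """Figure-legend star convention: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= alpha:
        return "*"
    return ""


def _hypotheses_for_family(family: str) -> list[dict]:
    if family == "by_layer":
        # one combined test per layer over all features of all cells
        return [{"measure": "all_features", "features": FEATURE_COLUMNS,
                 "cell_type": "all", "layer": l} for l in LAYERS]
    if family == "domain_by_layer":
        return [{"measure": d, "features": f, "cell_type": "all", "layer": l}
                for d, f in DOMAINS.items() for l in LAYERS]
    if family == "domain_by_type_layer":
        from .synthetic import ARCHETYPE_NAMES
        return [{"measure": d, "features": f, "cell_type": t, "layer": l}
                for d, f in DOMAINS.items() for t in ARCHETYPE_NAMES
                for l in LAYERS]
    if family == "feature_by_type_layer":
        from .synthetic import ARCHETYPE_NAMES
        return [{"measure": feat, "features": [feat], "cell_type": t, "layer": l}
                for feat in FEATURE_COLUMNS for t in ARCHETYPE_NAMES
                for l in LAYERS]
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def run_family(pseudo: pd.DataFrame, family: str,
               scheme: PermutationScheme,
               alpha: float = ALPHA,
               measures=None, cell_types=None,
               unit: str = "image") -> pd.DataFrame:
    """Run one analysis family on a pseudo-observation table.

    Families: ``domain_by_layer`` (3 domains × 6 layers over all
    cells), ``domain_by_type_layer`` (3 × 4 types × 6 layers) and
    ``feature_by_type_layer`` (11 features × 4 types × 6 layers).
    Within each family the max-t multiplicity is taken across the six
    layers of each (measure × cell type) — e.g. comparing the three
    populations across six layers gives multiplicity six.

    Returns a tidy frame with combined and adjusted p per hypothesis;
    hypotheses whose strata lack two observations in some group are
    reported with NaN p-values and a diagnostic note.  ``measures`` /
    ``cell_types`` restrict the family to a subset (the max-t
    multiplicity across layers is unaffected).

    ``unit`` selects the permutation unit: ``"image"`` shuffles group
    labels over images (matching the pseudo-observation construction);
    ``"animal"`` shuffles labels over animals, each image inheriting
    its animal's permuted label — stricter when sections within an
    animal are correlated.
    """
    hypos = _hypotheses_for_family(family)
    if measures is not None:
        hypos = [h for h in hypos if h["measure"] in set(measures)]
    if cell_types is not None:
        hypos = [h for h in hypos if h["cell_type"] in set(cell_types)]
    if not hypos:
        raise ValueError("family filtered to zero hypotheses")
    images = pseudo[["image_id", "animal", "group"]].drop_duplicates() \
        .sort_values("image_id")
    image_ids = images["image_id"].to_numpy()
    codes = _group_codes(images["group"].to_numpy())
    if unit == "image":
        perms = scheme.permutations(len(image_ids))
        perm_labels = codes[perms]                    # (B + 1, n_images)
    elif unit == "animal":
        animals = images[["animal", "group"]].drop_duplicates() \
            .sort_values("animal")
        a_codes = _group_codes(animals["group"].to_numpy())
        a_perms = scheme.permutations(len(animals))
        a_pos = {a: i for i, a in enumerate(animals["animal"])}
        owner = images["animal"].map(a_pos).to_numpy()
        perm_labels = a_codes[a_perms][:, owner]      # images inherit
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    img_pos = {im: i for i, im in enumerate(image_ids)}

    rows, T_cols = [], {}
    for h in hypos:
        stratum = pseudo[(pseudo["layer"] == h["layer"])
                         & (pseudo["cell_type"] == h["cell_type"])]
        stratum = stratum.sort_values("image_id")
        note = ""
        T, p_comb = None, np.nan
        if len(stratum) == 0:
            note = "no observations"
        else:
            pos = stratum["image_id"].map(img_pos).to_numpy()
            lab = perm_labels[:, pos]
            obs_codes = lab[0]
            _, counts = np.unique(obs_codes, return_counts=True)
            if len(counts) < len(np.unique(codes)) or counts.min() < 2:
                note = "a group has < 2 observations"
            else:
                vals = stratum[h["features"]].to_numpy(float)
                stats = welch_f(vals, lab)
                if stats.ndim == 1:
                    stats = stats[:, None]
                T, p_comb = npc_fisher(stats)
        rows.append({
            "family": family, "measure": h["measure"],
            "cell_type": h["cell_type"], "layer": h["layer"],
            "n_obs": len(stratum),
            "p_combined": p_comb if T is not None else np.nan,
            "note": note,
        })
        if T is not None:
            T_cols[len(rows) - 1] = T
        elif note:
            logger.info("skipped %s / %s / layer %s: %s",
                        family, h["measure"], h["layer"], note)

    results = pd.DataFrame(rows)
    results["p_adjusted"] = np.nan
    # max-t across the six layers of each (measure, cell_type)
    for (_, _), idx in results.groupby(["measure", "cell_type"]).groups.items():
        tested = [i for i in idx if i in T_cols]
        if not tested:
            continue
        adj = maxt_adjust(np.column_stack([T_cols[i] for i in tested]))
        results.loc[tested, "p_adjusted"] = adj
    results["significant"] = results["p_adjusted"] <= alpha
    results["stars"] = results["p_adjusted"].map(
        lambda p: significance_stars(p, alpha) if np.isfinite(p) else "")
    return results
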