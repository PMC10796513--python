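"""Rule-based assignment of cell shape classes.

Each neuron is assigned exactly one of four classes — round, ellipsoid,
pyramidal, complex — from its shape-domain descriptors through an
ordered, size-invariant decision list:

1. *complex* if the outline is markedly non-convex
   (``solidity < t_sol`` or ``convex_circularity < t_cc``);
2. *round* if nearly isotropic (``invAR >= t_round``);
3. *pyramidal* if it fills its bounding box like a triangle
   (``extent <= t_ext``);
4. *ellipsoid* otherwise.

The default thresholds are a reconstruction calibrated on the synthetic
archetypes; they are shipped as a versioned, human-readable config so
they can be replaced wholesale when calibrating against real
annotations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["ShapeRuleSet", "DEFAULT_RULES", "classify_shape", "calibrate_rules"]

_REQUIRED = ("invAR", "extent", "solidity", "convex_circularity")


@dataclass(frozen=True)
class ShapeRuleSet:
    """Named thresholds of the ordered decision list (all in (0, 1))."""

    t_sol: float = 0.88
    t_cc: float = 0.75
    t_round: float = 0.85
    t_ext: float = 0.66
    version: str = "synthetic-calibration-1"

    def __post_init__(self) -> None:
        for name in ("t_sol", "t_cc", "t_round", "t_ext"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_RULES = ShapeRuleSet()


def classify_shape(records: pd.DataFrame | pd.Series,
                   rules: ShapeRuleSet = DEFAULT_RULES) -> pd.Series | str:
    """Apply the decision list; vectorised over a DataFrame of records.

    Accepts a DataFrame with the shape-domain columns (or a single
    Series/row) and returns the class label(s).  Missing fields raise
    ``ValueError``.
    """
    single = isinstance(records, pd.Series)
    df = records.to_frame().T if single else records
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing shape descriptors: {missing}")
    if df[list(_REQUIRED)].isna().any().any():
        raise ValueError("shape descriptors contain missing values")
    sol = df["solidity"].to_numpy(float)
    cc = df["convex_circularity"].to_numpy(float)
    inv = df["invAR"].to_numpy(float)
    ext = df["extent"].to_numpy(float)
    out = np.full(len(df), "ellipsoid", dtype=object)
    out[ext <= rules.t_ext] = "pyramidal"
    out[inv >= rules.t_round] = "round"
    out[(sol < rules.t_sol) | (cc < rules.t_cc)] = "complex"
    labels = pd.Series(out, index=df.index, name="shape_class")
    return str(labels.iloc[0]) if single else labels


def calibrate_rules(
    records: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    grid: dict[str, np.ndarray] | None = None,
    version: str = "calibrated",
) -> ShapeRuleSet:
    """Grid-search thresholds maximising macro-averaged accuracy.

    Ties are broken deterministically towards the smallest thresholds
    (grids are scanned in ascending order and only strict improvements
    are kept).  Requires at least two distinct truth classes.
    """
    labels = pd.Series(np.asarray(labels), index=records.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("calibration needs >= 2 classes")
    if grid is None:
        grid = {
            "t_sol": np.round(np.arange(0.80, 0.96, 0.02), 3),
            "t_cc": np.round(np.arange(0.65, 0.90, 0.025), 3),
            "t_round": np.round(np.arange(0.75, 0.95, 0.02), 3),
            "t_ext": np.round(np.arange(0.56, 0.72, 0.02), 3),
        }
    for k, v in grid.items():
        if len(np.atleast_1d(v)) == 0:
            raise ValueError(f"degenerate grid for {k}")

    def macro_acc(pred: pd.Series) -> float:
        return float(np.mean([
            (pred[labels == c] == c).mean() for c in classes
        ]))

    best, best_acc = None, -1.0
    for ts, tc, tr, te in product(grid["t_sol"], grid["t_cc"],
                                  grid["t_round"], grid["t_ext"]):
        rules = ShapeRuleSet(t_sol=float(ts), t_cc=float(tc),
                             t_round=float(tr), t_ext=float(te),
                             version=version)
        acc = macro_acc(classify_shape(records, rules))
        if acc > best_acc:
            best, best_acc = rules, acc
    assert best is not None
    return best
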