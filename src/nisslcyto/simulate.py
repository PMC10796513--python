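"""Calibration and power experiments for the statistical stack.

These simulations run the full pseudo-observation → permutation →
Fisher-combination → max-t chain on generator ground truth (bypassing
segmentation) and measure its operating characteristics: family-wise
error under the global null, the nominal level of a single combined
test, and power against a planted size effect.  Cohorts follow the
study design (4/4/3 animals per age class, two sections each) on a
narrow tissue column — a 0.4–0.6 mm wide strip through all six layers —
which keeps hundreds of replicates tractable without changing the
statistical structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import PermutationScheme, make_pseudo_observations, run_family, welch_f, npc_fisher
from .synthetic import (CohortSpec, GroupEffect, default_layers,
                        generate_cohort, identity_effects)

__all__ = ["fwer_null_simulation", "combined_test_null_simulation",
           "power_simulation", "simulation_cohort_spec"]


def simulation_cohort_spec(seed: int, width_px: int = 800,
                           **kwargs) -> CohortSpec:
    """Desk-scale cohort: full 1.85 mm six-layer depth, narrow strip."""
    return CohortSpec(image_size=(3700, width_px), seed=seed, **kwargs)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class NullCalibrationResult:
    rejection_rate: float
    n_replicates: int
    alpha: float

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.alpha * (1 - self.alpha) / self.n_replicates))


def fwer_null_simulation(n_cohorts: int = 500, B: int = 200, seed: int = 0,
                         alpha: float = 0.05,
                         width_px: int = 800) -> NullCalibrationResult:
    """Family-wise error of the six layer-wise combined tests.

    Each replicate draws a global-null cohort (identity group effects),
    builds pseudo-observations from ground truth, runs the six
    Fisher-combined layer hypotheses on synchronized shuffles and
    applies single-step max-t; the FWER estimate is the fraction of
    cohorts with at least one adjusted p <= alpha.
    """
    seeds = _child_seeds(seed, n_cohorts)
    hits = 0
    for s in seeds:
        spec = simulation_cohort_spec(seed=s, width_px=width_px)
        ds = generate_cohort(spec, render=False)
        pseudo = make_pseudo_observations(ds.cells)
        res = run_family(pseudo, "by_layer", PermutationScheme(B=B, seed=s))
        hits += bool((res["p_adjusted"] <= alpha).any())
    return NullCalibrationResult(hits / n_cohorts, n_cohorts, alpha)


def combined_test_null_simulation(n_datasets: int = 1000, B: int = 200,
                                  seed: int = 0, alpha: float = 0.05,
                                  group_sizes=(8, 8, 6),
                                  n_features: int = 4) -> NullCalibrationResult:
    """Type-I error of a single Fisher-combined permutation test.

    Each replicate draws image-level pseudo-observations for three
    groups i.i.d. from one (heteroscedastic-capable) normal model —
    the global null — and tests with the Welch statistic combined over
    ``n_features`` features on one set of shuffles.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(3), group_sizes)
    scales = 1.0 + np.arange(n_features)  # unequal feature scales
    hits = 0
    for _ in range(n_datasets):
        values = rng.normal(0.0, scales, size=(len(labels), n_features))
        scheme = PermutationScheme(B=B, seed=int(rng.integers(2**31)))
        perms = scheme.permutations(len(labels))
        stats = welch_f(values, labels[perms])
        _, p = npc_fisher(stats)
        hits += p <= alpha
    return NullCalibrationResult(hits / n_datasets, n_datasets, alpha)


@dataclass
class PowerResult:
    planted_rejections: np.ndarray   # (n_replicates,) count among planted layers
    null_rejections: np.ndarray      # (n_replicates,) count among other layers
    n_planted: int
    n_null: int

    @property
    def success_rate(self) -> float:
        """Fraction of replicates rejecting in >= 2 planted layers."""
        return float(np.mean(self.planted_rejections >= 2))

    @property
    def null_rejection_rate(self) -> float:
        return float(self.null_rejections.sum()
                     / (len(self.null_rejections) * self.n_null))


def power_simulation(n_replicates: int = 50, B: int = 999, seed: int = 0,
                     images_per_group: int = 30, alpha: float = 0.05,
                     area_factor: float = 0.8,
                     planted_layers=("I", "II", "III"),
                     width_px: int = 1200) -> PowerResult:
    """Power against a planted calf round-cell size effect.

    Calf round-cell *areas* are scaled by ``area_factor`` (the linear
    size multiplier is its square root) in the planted layers only.
    Each replicate tests the matched hypothesis family — the size
    domain of round cells across the six layers, with max-t correction
    over the layers — and records the adjusted rejections inside and
    outside the planted layers.
    """
    n_animals = images_per_group // 2
    effects = identity_effects()
    effects["calf"] = GroupEffect(
        group="calf",
        size_multiplier={"round": float(np.sqrt(area_factor))},
        restrict_layers=frozenset(planted_layers),
    )
    layers = default_layers()
    other_layers = [l.layer_id for l in layers
                    if l.layer_id not in planted_layers]
    seeds = _child_seeds(seed, n_replicates)
    planted_hits, null_hits = [], []
    for s in seeds:
        spec = simulation_cohort_spec(
            seed=s, width_px=width_px,
            n_animals=(n_animals, n_animals, n_animals))
        ds = generate_cohort(spec, layers, effects, render=False)
        pseudo = make_pseudo_observations(ds.cells)
        res = run_family(pseudo, "domain_by_type_layer",
                         PermutationScheme(B=B, seed=s),
                         measures=["size"], cell_types=["round"])
        size_rows = res.set_index("layer")
        rej = size_rows["p_adjusted"] <= alpha
        planted_hits.append(int(rej.loc[list(planted_layers)].sum()))
        null_hits.append(int(rej.loc[other_layers].sum()))
    return PowerResult(np.asarray(planted_hits), np.asarray(null_hits),
                       len(planted_layers), len(other_layers))
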