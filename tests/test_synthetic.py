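"""Generator contracts: planted shapes, cohort structure, group effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from nisslcyto import synthetic as syn


def test_invalid_archetype_name_rejected():
    with pytest.raises(ValueError, match="unknown archetype"):
        syn.ShapeArchetype("blob", 10.0, 0.1, 1.0, 0.1)


def test_round_zero_irregularity_is_circle():
    arch = syn.ShapeArchetype("round", 12.0, 0.0, 1.0, 0.0)
    poly = syn.sample_cell_shape(arch, np.random.default_rng(0))
    radii = np.hypot(*(poly - poly.mean(axis=0)).T)
    assert radii.max() / radii.min() == pytest.approx(1.0, abs=1e-6)


def test_ellipsoid_rasterized_aspect_ratio():
    """A planted aspect-0.5 ellipse rasterises to invAR 0.5 ± 0.05."""
    from skimage.draw import polygon as draw_polygon
    from skimage.measure import regionprops

    arch = syn.ShapeArchetype("ellipsoid", 30.0, 0.0, 0.5, 0.0)
    poly = syn.sample_cell_shape(arch, np.random.default_rng(1)) / 0.5  # px
    poly -= poly.min(axis=0) - 5
    img = np.zeros((120, 120), dtype=np.uint8)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
    img[rr, cc] = 1
    p = regionprops(img)[0]
    assert p.axis_minor_length / p.axis_major_length == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize("name", syn.ARCHETYPE_NAMES)
def test_mean_equivalent_diameter_matches_size_mean(name):
    arch = syn.default_archetypes()[name]
    polys = syn.sample_cell_polygons(arch, 1000, np.random.default_rng(2))
    d = 2.0 * np.sqrt(syn._shoelace_area(polys) / np.pi)
    se = d.std(ddof=1) / np.sqrt(len(d))
    assert abs(d.mean() - arch.size_mean) < 3 * se


def test_polygon_morphometrics_scale_equivariance():
    polys = syn.sample_cell_polygons(syn.default_archetypes()["complex"], 50,
                                     np.random.default_rng(3))
    f1 = syn.polygon_morphometrics(polys)
    f2 = syn.polygon_morphometrics(polys * 2.0)
    np.testing.assert_allclose(f2["area"], 4 * f1["area"], rtol=1e-9)
    np.testing.assert_allclose(f2["perimeter"], 2 * f1["perimeter"], rtol=1e-9)
    for col in ("invAR", "eccentricity", "solidity", "convex_circularity"):
        np.testing.assert_allclose(f2[col], f1[col], rtol=1e-9)


def test_render_zero_density_gives_pure_neuropil():
    layers = [syn.LayerSpec("I", 150.0, 0.0, (1.0, 0, 0, 0))]
    spec = syn.CohortSpec(image_size=(400, 300), seed=0,
                          noise=syn.NoiseModel(glia_per_mm2=0.0))
    rec = syn.render_section(layers, syn.identity_effects()["calf"], spec,
                             np.random.default_rng(0))
    assert len(rec.cells) == 0
    assert rec.truth_labels.max() == 0
    assert rec.image.mean() > 100  # bright neuropil only


def test_layer_two_is_most_cell_rich():
    """Across 20 sections, layer II holds the largest cell count."""
    counts = pd.Series(0, index=list(syn.LAYER_NAMES))
    spec = syn.CohortSpec(image_size=(3700, 800), seed=0)
    rng = np.random.default_rng(42)
    for _ in range(20):
        cells = syn.sample_section_truth(syn.default_layers(),
                                         syn.identity_effects()["adult"],
                                         spec, rng)
        counts = counts.add(cells.groupby("layer").size(), fill_value=0)
    assert counts.idxmax() == "II"
    assert counts["II"] > counts.drop("II").max()


def test_nontouching_cells_are_disjoint():
    """50 planted non-touching cells give exactly 50 components."""
    layers = [syn.LayerSpec("I", 300.0, 430.0, (0.25, 0.25, 0.25, 0.25))]
    spec = syn.CohortSpec(image_size=(600, 780), touching_fraction=0.0, seed=1,
                          noise=syn.NoiseModel(glia_per_mm2=0.0))
    rng = np.random.default_rng(9)
    for _ in range(10):  # retry until Poisson count hits exactly 50
        rec = syn.render_section(layers, syn.identity_effects()["adult"],
                                 spec, rng)
        if len(rec.cells) == 50:
            break
    assert len(rec.cells) >= 30
    _, n_components = ndi.label(rec.truth_labels > 0)
    assert n_components == len(rec.cells)


def test_infeasible_packing_raises():
    layers = [syn.LayerSpec("I", 100.0, 20000.0, (0, 0, 0, 1.0))]
    spec = syn.CohortSpec(image_size=(200, 200), seed=0)
    with pytest.raises(syn.PackingError):
        syn.render_section(layers, syn.identity_effects()["adult"], spec,
                           np.random.default_rng(0))


def test_default_cohort_structure():
    """11 animals in groups 4/4/3, two sections each -> 22 sections."""
    spec = syn.CohortSpec(image_size=(3700, 400), seed=5)
    ds = syn.generate_cohort(spec, render=False)
    assert len(ds.metadata) == 22
    sizes = ds.metadata.groupby("group")["animal"].nunique()
    assert sizes.to_dict() == {"calf": 4, "adult": 4, "old": 3}
    assert set(ds.metadata.groupby("animal")["section"].count()) == {2}


def test_cohort_determinism():
    spec = syn.CohortSpec(image_size=(3700, 400), seed=7)
    a = syn.generate_cohort(spec, render=False)
    b = syn.generate_cohort(spec, render=False)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    pd.testing.assert_frame_equal(a.metadata, b.metadata)


def test_render_determinism():
    layers = [syn.LayerSpec("I", 150.0, 300.0, (0.5, 0.5, 0, 0))]
    spec = syn.CohortSpec(image_size=(300, 300), seed=3)
    r1 = syn.render_section(layers, syn.identity_effects()["old"], spec,
                            np.random.default_rng(3))
    r2 = syn.render_section(layers, syn.identity_effects()["old"], spec,
                            np.random.default_rng(3))
    np.testing.assert_array_equal(r1.image, r2.image)
    np.testing.assert_array_equal(r1.truth_labels, r2.truth_labels)


def test_identity_effects_give_global_null():
    """Pooled group means agree within 3 SE under identity effects."""
    spec = syn.CohortSpec(image_size=(3700, 800), seed=11)
    cells = syn.generate_cohort(spec, render=False).cells
    for col in ("area", "invAR", "solidity"):
        g = cells.groupby("group")[col]
        means, sems = g.mean(), g.sem()
        spread = means.max() - means.min()
        assert spread < 3 * np.sqrt((sems**2).sum()), col


def test_size_multiplier_scales_area_quadratically():
    """Calf round-cell size x0.8 -> calf/adult area ratio 0.64 ± 0.05."""
    effects = syn.identity_effects()
    effects["calf"] = syn.GroupEffect(group="calf",
                                      size_multiplier={"round": 0.8})
    spec = syn.CohortSpec(image_size=(3700, 800), seed=13)
    cells = syn.generate_cohort(spec, group_effects=effects,
                                render=False).cells
    rounds = cells[cells["cell_type"] == "round"]
    ratio = (rounds[rounds.group == "calf"]["area"].mean()
             / rounds[rounds.group == "adult"]["area"].mean())
    assert ratio == pytest.approx(0.64, abs=0.05)


def test_effect_monotonicity_in_size_multiplier():
    areas = []
    for mult in (0.8, 1.0, 1.25):
        eff = syn.GroupEffect(group="adult",
                              size_multiplier={n: mult
                                               for n in syn.ARCHETYPE_NAMES})
        spec = syn.CohortSpec(image_size=(3700, 800), seed=17)
        cells = syn.sample_section_truth(syn.default_layers(), eff, spec,
                                         np.random.default_rng(17))
        areas.append(cells["area"].mean())
    assert areas[0] < areas[1] < areas[2]


def test_layer_map_partitions_tissue(rendered_section):
    rec = rendered_section
    assert set(np.unique(rec.layer_map)) <= {0, 1, 2}
    # bands are contiguous and ordered from the pial edge
    rows_one = np.where((rec.layer_map == 1).any(axis=1))[0]
    rows_two = np.where((rec.layer_map == 2).any(axis=1))[0]
    assert rows_one.max() < rows_two.min()
    # no cell centroid on background
    cy = (rec.cells["centroid_y"] / rec.pixel_size).round().astype(int)
    cx = (rec.cells["centroid_x"] / rec.pixel_size).round().astype(int)
    assert (rec.layer_map[cy.clip(0, 599), cx.clip(0, 499)] > 0).all()


def test_group_effect_validation():
    with pytest.raises(ValueError):
        syn.GroupEffect(group="calf", size_multiplier={"round": -1.0})
    with pytest.raises(ValueError):
        syn.GroupEffect(group="teen")
    assert syn.GroupEffect(group="calf").is_identity


def test_shape_shift_changes_aspect_ratio():
    arch = syn.default_archetypes()["ellipsoid"]
    eff = syn.GroupEffect(group="old",
                          shape_shift={"ellipsoid": {"aspect_ratio": 0.2}})
    shifted = eff.effective_archetype(arch, "III")
    assert shifted.aspect_ratio == pytest.approx(arch.aspect_ratio + 0.2)
    restricted = dataclasses.replace(eff, restrict_layers=frozenset({"I"}))
    assert restricted.effective_archetype(arch, "III") == arch
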