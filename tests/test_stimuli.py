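import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from numsense import stimuli
from numsense.stimuli import (
    ConstraintError,
    ControlSetSpec,
    audit_features,
    generate_control_set,
    make_item,
    mask_perimeter,
    pentagon_vertices,
    place_items,
)

FOUR_CONN = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


def test_canonical_item_is_5x5_square_minus_corners():
    item = make_item(ControlSetSpec.for_set(1))
    assert item.area == 21
    assert item.perimeter == 12
    r0, c0, r1, c1 = item.bounding_box
    assert (r1 - r0 + 1, c1 - c0 + 1) == (5, 5)


def test_set2_item_has_exact_requested_area():
    spec = ControlSetSpec.for_set(2)
    item = make_item(spec, target_area=20)  # 600 / 30 items
    assert item.area == 20
    assert make_item(spec, target_area=1).area == 1


@pytest.mark.parametrize("budget", [1, 2, 3, 4, 5, 6, 7, 8, 9, 12, 25, 45, 90, 180])
def test_perimeter_piece_hits_budget_exactly(budget):
    item = make_item(ControlSetSpec.for_set(3), target_perimeter=budget)
    assert item.perimeter == budget
    assert stimuli._is_4_connected(item.pixels)


@given(budget=st.integers(min_value=1, max_value=180))
@settings(max_examples=60, deadline=None)
def test_perimeter_piece_budget_property(budget):
    item = make_item(ControlSetSpec.for_set(3), target_perimeter=budget)
    assert item.perimeter == budget


@given(area=st.integers(min_value=1, max_value=600))
@settings(max_examples=60, deadline=None)
def test_disc_blob_area_property(area):
    item = make_item(ControlSetSpec.for_set(2), target_area=area)
    assert item.area == area
    assert stimuli._is_4_connected(item.pixels)


def test_single_pixel_item_has_area_and_perimeter_one():
    item = make_item(ControlSetSpec.for_set(2), target_area=1)
    assert item.area == 1 and item.perimeter == 1


def test_make_item_rejects_invalid_requests():
    with pytest.raises(ConstraintError):
        make_item(ControlSetSpec.for_set(1), target_area=20, target_perimeter=12)
    with pytest.raises(ConstraintError):
        make_item(ControlSetSpec.for_set(2), target_area=0)
    with pytest.raises(ConstraintError):
        make_item(ControlSetSpec.for_set(3), target_perimeter=300)
    with pytest.raises(ConstraintError):
        make_item(ControlSetSpec.for_set(4), shape_id="canonical_blob")
    with pytest.raises(ConstraintError):
        make_item(ControlSetSpec.for_set(2), target_area=5, shape_id="square")


def test_set1_every_item_audits_area_21_perimeter_12(rng):
    for img in generate_control_set(1, numerosities=[1, 7, 30], rng=rng):
        audit = audit_features(img)
        assert all(a == 21 for a in audit.item_areas)
        assert all(p == 12 for p in audit.item_perimeters)


def test_set1_n4_totals():
    rng = np.random.default_rng(0)
    (img,) = generate_control_set(1, numerosities=[4], rng=rng)
    audit = audit_features(img)
    assert audit.total_area == 84
    assert audit.total_perimeter == 48


def test_set2_total_area_is_exactly_600(rng):
    for img in generate_control_set(2, rng=rng):
        assert audit_features(img).total_area == 600


def test_set3_total_perimeter_is_exactly_180(rng):
    for img in generate_control_set(3, rng=rng):
        assert audit_features(img).total_perimeter == 180


@pytest.mark.parametrize("set_id", [1, 2, 3, 4])
def test_images_are_binary_with_numerosity_components(set_id, rng):
    with np.errstate(all="ignore"):
        images = generate_control_set(
            set_id, numerosities=[1, 2, 5, 12, 30], rng=rng
        )
    for img in images:
        assert set(np.unique(img.intensities)) <= {0.0, 1.0}
        _, n_comp = ndimage.label(img.intensities, structure=FOUR_CONN)
        assert n_comp == img.numerosity
        assert img.intensities.sum() == sum(it.area for it in img.items)


def test_scattered_placement_keeps_boxes_separated(rng):
    items = [make_item(ControlSetSpec.for_set(1)) for _ in range(30)]
    placed = place_items(items, 1, rng)
    boxes = [it.bounding_box for it in placed]
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            a, b = boxes[i], boxes[j]
            separated = (
                a[2] + 1 < b[0] or b[2] + 1 < a[0]
                or a[3] + 1 < b[1] or b[3] + 1 < a[1]
            )
            assert separated


def test_set4_five_items_sit_on_pentagon_vertices(rng):
    spec = ControlSetSpec.for_set(4)
    (img,) = generate_control_set(4, numerosities=[5], rng=rng)
    verts = pentagon_vertices(spec)
    centroids = np.array([it.centroid for it in img.items])
    for v in verts:
        dists = np.linalg.norm(centroids - v, axis=1)
        assert dists.min() < 1.6  # rasterization + frame clamping slack


def test_set4_centroid_hull_has_five_vertices(rng):
    (img,) = generate_control_set(4, numerosities=[10], rng=rng)
    audit = audit_features(img)
    assert len(audit.hull_vertices) == 5


def test_set4_interior_centroids_inside_pentagon(rng):
    spec = ControlSetSpec.for_set(4)
    verts = pentagon_vertices(spec)
    (img,) = generate_control_set(4, numerosities=[20], rng=rng)
    for it in img.items:
        assert stimuli._point_in_polygon(it.centroid, verts * 1.0 + 1e-9) or min(
            np.linalg.norm(verts - np.array(it.centroid), axis=1)
        ) < 1.6


def test_set4_small_numerosity_warns(rng):
    with pytest.warns(UserWarning, match="pentagonal"):
        generate_control_set(4, numerosities=[3], rng=rng)


def test_generation_is_deterministic_under_seed():
    imgs_a = generate_control_set(2, rng=np.random.default_rng(77))
    imgs_b = generate_control_set(2, rng=np.random.default_rng(77))
    for a, b in zip(imgs_a, imgs_b):
        assert np.array_equal(a.intensities, b.intensities)


def test_mask_perimeter_counts_boundary_pixels():
    # 3x3 solid square: 8 boundary pixels around 1 interior pixel
    square = frozenset((r, c) for r in range(3) for c in range(3))
    assert mask_perimeter(square) == 8
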