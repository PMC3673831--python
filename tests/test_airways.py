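"""Bronchial pipeline: segmentation, centerline, wall detection, Pi10."""

import numpy as np
import pytest
from scipy import ndimage, stats

from copdct import (
    compute_pi10,
    extract_centerline,
    filter_cross_sections,
    measure_wall,
    sample_cross_sections,
    segment_lumen,
)
from copdct.airways import WallCrossSection
from copdct.errors import (
    DegenerateMaskError,
    DegenerateRegressionError,
    GeometryError,
    SeedPointError,
)


# ---------------------------------------------------------------------------
# lumen segmentation
# ---------------------------------------------------------------------------

def test_segment_straight_tube_count(straight_tube_phantom):
    p = straight_tube_phantom
    seg = segment_lumen(p["insp"], (p["mid"], p["mid"], p["mid"]))
    assert not seg.failed
    truth_count = p["truth"].tubes[0].lumen_voxel_count
    assert abs(int(seg.mask.sum()) - truth_count) / truth_count < 0.05


def test_seed_in_wall_material_rejected(straight_tube_phantom):
    p = straight_tube_phantom
    # a point in the wall annulus (r + t/2 from the axis) has HU ~ 0
    with pytest.raises(SeedPointError):
        segment_lumen(p["insp"], (p["mid"] + 2.5, p["mid"], p["mid"]))


def test_seed_outside_volume_rejected(straight_tube_phantom):
    with pytest.raises(GeometryError):
        segment_lumen(straight_tube_phantom["insp"], (-5.0, 0.0, 0.0))


def test_segment_y_phantom_connected_contains_child_ends(y_phantom):
    seg = segment_lumen(y_phantom["insp"], y_phantom["seed_mm"])
    assert not seg.failed
    # 6-connected: a single labelled component
    _, n_labels = ndimage.label(seg.mask)
    assert n_labels == 1
    sp = np.asarray(y_phantom["insp"].spacing)
    for end in y_phantom["child_ends"]:
        # probe 1 mm inside the open end, along the tube toward the carina
        inner = np.asarray(end) + np.array([0.0, 0.0, -1.0])
        idx = tuple(np.round(inner / sp).astype(int))
        assert seg.mask[idx]


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

def test_centerline_straight_tube_single_branch(straight_tube_phantom):
    p = straight_tube_phantom
    seg = segment_lumen(p["insp"], (p["mid"], p["mid"], p["mid"]))
    tree = extract_centerline(seg.mask, p["insp"].spacing, (p["mid"], p["mid"], 0.5))
    assert len(tree.branches) == 1
    assert tree.n_bifurcations == 0
    assert tree.branches[0].generation_label == 0
    assert abs(tree.total_arc_length_mm - p["extent"]) / p["extent"] < 0.10


def test_centerline_y_topology(y_phantom):
    seg = segment_lumen(y_phantom["insp"], y_phantom["seed_mm"])
    tree = extract_centerline(seg.mask, y_phantom["insp"].spacing, y_phantom["seed_mm"])
    assert len(tree.branches) == 3
    assert tree.n_bifurcations == 1
    gens = sorted(b.generation_label for b in tree.branches)
    assert gens == [0, 1, 1]
    # the bifurcation lies near the construction's junction point
    bif = tree.bifurcations_mm[0]
    expected = np.array([y_phantom["mid"], y_phantom["mid"], y_phantom["z1"]])
    assert np.linalg.norm(bif - expected) < 4.0


def test_centerline_deterministic(y_phantom):
    seg = segment_lumen(y_phantom["insp"], y_phantom["seed_mm"])
    t1 = extract_centerline(seg.mask, y_phantom["insp"].spacing, y_phantom["seed_mm"])
    t2 = extract_centerline(seg.mask, y_phantom["insp"].spacing, y_phantom["seed_mm"])
    assert len(t1.branches) == len(t2.branches)
    for a, b in zip(t1.branches, t2.branches):
        assert np.array_equal(a.points_mm, b.points_mm)
        assert a.generation_label == b.generation_label


def test_thin_mask_degenerate():
    mask = np.zeros((20, 20, 20), bool)
    mask[10, 10, :] = True  # 1-voxel filament: no interior
    with pytest.raises(DegenerateMaskError):
        extract_centerline(mask, (0.5, 0.5, 0.5))


# ---------------------------------------------------------------------------
# cross-section sampling
# ---------------------------------------------------------------------------

def test_section_spacing_and_normals(straight_tube_phantom):
    p = straight_tube_phantom
    seg = segment_lumen(p["insp"], (p["mid"], p["mid"], p["mid"]))
    tree = extract_centerline(seg.mask, p["insp"].spacing, (p["mid"], p["mid"], 0.5))
    sites = sample_cross_sections(tree, 1.0)
    n_expected = p["extent"]  # ~1 per mm
    assert abs(len(sites) - n_expected) <= 3
    axis = np.array([0.0, 0.0, 1.0])
    # away from the smoothed ends, normals align with the tube axis
    for s in sites[3:-3]:
        assert abs(float(s.normal @ axis)) > 0.99
    halved = sample_cross_sections(tree, 2.0)
    assert abs(len(halved) - len(sites) / 2) <= 2


def test_short_branch_yields_no_sections():
    from copdct.airways import AirwayTree, Branch

    stub = Branch(points_mm=np.array([[0.0, 0, 0], [0.4, 0, 0]]), generation_label=2)
    tree = AirwayTree(branches=[stub], bifurcations_mm=np.empty((0, 3)), root_mm=np.zeros(3))
    assert sample_cross_sections(tree, 1.0) == []


# ---------------------------------------------------------------------------
# wall measurement
# ---------------------------------------------------------------------------

def test_wall_closed_forms(straight_tube_phantom):
    p = straight_tube_phantom
    r, t = p["radius"], p["thickness"]
    w = measure_wall(p["insp"], (p["mid"], p["mid"], p["mid"]), (0, 0, 1.0))
    assert w.status == "valid"
    pi_true = 2 * np.pi * r
    wa_true = np.pi * ((r + t) ** 2 - r**2)
    assert abs(w.lumen_perimeter_mm - pi_true) / pi_true < 0.05
    assert abs(w.wall_area_mm2 - wa_true) / wa_true < 0.07


def test_tilted_normal_inflates_perimeter_boundedly(straight_tube_phantom):
    p = straight_tube_phantom
    center = (p["mid"], p["mid"], p["mid"])
    straight = measure_wall(p["insp"], center, (0, 0, 1.0))
    tilt = np.deg2rad(5.0)
    tilted = measure_wall(p["insp"], center, (np.sin(tilt), 0, np.cos(tilt)))
    bound = straight.lumen_perimeter_mm / np.cos(tilt)
    assert tilted.lumen_perimeter_mm <= bound * 1.02
    assert tilted.lumen_perimeter_mm >= straight.lumen_perimeter_mm * 0.98


def test_center_in_parenchyma_excluded(straight_tube_phantom):
    p = straight_tube_phantom
    w = measure_wall(p["insp"], (2.0, 2.0, p["mid"]), (0, 0, 1.0))
    assert w.status == "excluded"
    assert w.exclusion_reason == "wall_detection_failed"
    assert w.n_missing_rays > 0.25 * 72


def test_center_outside_volume_geometry_error(straight_tube_phantom):
    with pytest.raises(GeometryError):
        measure_wall(straight_tube_phantom["insp"], (-10.0, 0, 0), (0, 0, 1.0))


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def _section(gen, bif_dist=np.inf, status="valid", pi=10.0, wa=16.0):
    return WallCrossSection(
        center_mm=np.zeros(3), normal=np.array([0, 0, 1.0]),
        inner_radii_mm=np.full(72, pi / (2 * np.pi)),
        outer_radii_mm=np.full(72, pi / (2 * np.pi) + 1),
        lumen_perimeter_mm=pi, wall_area_mm2=wa, status=status,
        generation_label=gen, bifurcation_distance_mm=bif_dist,
    )


def test_filter_trachea_only():
    sections = [_section(0) for _ in range(7)]
    valid, tally = filter_cross_sections(sections)
    assert valid == []
    assert tally["trachea"] == 7


def test_filter_y_labels_no_measurable_generation():
    sections = [_section(0), _section(1), _section(1)]
    valid, tally = filter_cross_sections(sections)
    assert valid == []
    assert tally == {"trachea": 1, "main_bronchus": 2}


def test_filter_hand_enumeration():
    sections = (
        [_section(0)] * 3                      # trachea
        + [_section(1)] * 4                    # main bronchi
        + [_section(2, bif_dist=1.0)] * 2      # too close to a bifurcation
        + [_section(2, status="excluded")] * 2  # failed wall detection
        + [_section(2, bif_dist=5.0)] * 5      # survivors
        + [_section(3, bif_dist=2.0)] * 1      # exactly at the margin: kept
    )
    valid, tally = filter_cross_sections(sections, bifurcation_margin_mm=2.0)
    assert len(valid) == 6
    assert tally == {
        "trachea": 3, "main_bronchus": 4,
        "branching_region": 2, "wall_detection_failed": 2,
    }


# ---------------------------------------------------------------------------
# Pi10
# ---------------------------------------------------------------------------

def test_pi10_two_point_line():
    s1 = _section(2, pi=8.0, wa=9.0)    # sqrt(WA) = 3.0
    s2 = _section(2, pi=12.0, wa=16.0)  # sqrt(WA) = 4.0
    res = compute_pi10([s1, s2])
    assert res.slope == pytest.approx(0.25)
    assert res.intercept == pytest.approx(1.0)
    assert res.pi10 == pytest.approx(3.5)


def test_pi10_degenerate_constant_perimeter():
    with pytest.raises(DegenerateRegressionError):
        compute_pi10([_section(2, pi=9.0), _section(2, pi=9.0)])


def test_pi10_order_and_duplication_invariant():
    secs = [_section(2, pi=p, wa=w) for p, w in [(8, 9), (10, 14), (12, 16)]]
    a = compute_pi10(secs)
    b = compute_pi10(secs[::-1])
    c = compute_pi10(secs + secs)
    assert a.pi10 == pytest.approx(b.pi10)
    assert a.pi10 == pytest.approx(c.pi10)


def test_pi10_matches_closed_form_regression(multi_tube_phantom):
    """Measured Pi10 on a noiseless multi-caliber phantom agrees with the
    regression through the analytic (2*pi*r, sqrt(WA)) triples."""
    p = multi_tube_phantom
    sections = []
    for x in p["xs"]:
        for z in np.arange(4.0, p["extent_z"] - 4.0, 1.0):
            sections.append(measure_wall(p["insp"], (x, 8.0, z), (0, 0, 1.0)))
    valid, tally = filter_cross_sections(sections)
    res = compute_pi10(valid, tally)
    pis = [2 * np.pi * r for r, _ in p["geometries"]]
    swa = [np.sqrt(np.pi * ((r + t) ** 2 - r**2)) for r, t in p["geometries"]]
    fit = stats.linregress(pis, swa)
    oracle = fit.intercept + 10 * fit.slope
    assert abs(res.pi10 - oracle) < 0.15


def test_measurement_scales_with_geometry(straight_tube_phantom):
    """Scaling tube geometry by k scales Pi and sqrt(WA) by k (within tol)."""
    from copdct import PhantomSpec, TubeSpec, generate_phantom

    k = 1.5
    g, sp = 64, 0.4
    extent = (g - 1) * sp
    mid = extent / 2
    spec = PhantomSpec(
        grid_shape=(g, g, g), spacing=(sp, sp, sp),
        tubes=[TubeSpec((mid, mid, 0.0), (mid, mid, extent), 2.0 * k, 1.0 * k,
                        generation_label=2)],
    )
    insp, _, _ = generate_phantom(spec, seed=0)
    base = measure_wall(straight_tube_phantom["insp"],
                        (straight_tube_phantom["mid"],) * 2 + (straight_tube_phantom["mid"],),
                        (0, 0, 1.0))
    scaled = measure_wall(insp, (mid, mid, mid), (0, 0, 1.0))
    assert scaled.lumen_perimeter_mm / base.lumen_perimeter_mm == pytest.approx(k, rel=0.05)
    assert scaled.sqrt_wall_area_mm / base.sqrt_wall_area_mm == pytest.approx(k, rel=0.05)
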