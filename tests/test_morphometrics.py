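"""Tests for the twelve-biomarker morphometrics panel."""

import math

import numpy as np
import pytest
from scipy import ndimage

from hdmi.core import RoiMask, VesselMask
from hdmi.graph import Node, SegmentChain, SkeletonGraph, build_graph, skeletonize
from hdmi.morphometrics import (
    bifurcation_angles,
    biomarker_set,
    fractal_dimension,
    murray_deviation,
    segment_metrics,
    tortuosity,
    vdr_svp,
    vessel_density,
)
from hdmi.synthetic import (
    TreeSpec,
    benign_phenotype,
    generate_phenotype_image,
    generate_tree,
    malignant_phenotype,
    rasterize_tree,
)
from conftest import recover_graph


def full_mask(data, pixel_size=1.0):
    return VesselMask(np.asarray(data, bool), RoiMask.full(np.shape(data), pixel_size),
                      pixel_size)


# ------------------------------------------------------------------ density

def test_vessel_density_extremes_and_counting():
    shape = (40, 50)
    assert vessel_density(full_mask(np.zeros(shape))) == 0.0
    assert vessel_density(full_mask(np.ones(shape))) == 1.0
    data = np.zeros((40, 25), bool)
    data.ravel()[:170] = True
    assert vessel_density(full_mask(data)) == pytest.approx(170 / 1000)


# ---------------------------------------------------------------- diameters

def test_thin_line_diameter_equals_twice_edt():
    """On a 1-px line the uncorrected local diameter is 2 x EDT x pixel size,
    constant along the line."""
    data = np.zeros((32, 64), bool)
    data[16, 5:60] = True
    mask = full_mask(data, pixel_size=100.0)
    g = build_graph(skeletonize(mask), 100.0)
    m = segment_metrics(g, mask, boundary_correction_px=0.0)[0]
    edt = ndimage.distance_transform_edt(data)
    interior = edt[16, 10:55]
    assert np.all(interior == interior[0])
    assert m.mean_diameter_um == pytest.approx(2 * interior[0] * 100.0, abs=15)


def test_edt_matches_brute_force_distance():
    """The distance transform underlying the diameters equals an explicit
    nearest-background search."""
    rng = np.random.default_rng(5)
    data = ndimage.binary_dilation(rng.random((32, 32)) > 0.95, iterations=2)
    edt = ndimage.distance_transform_edt(data)
    bg = np.argwhere(~data)
    for r, c in np.argwhere(data)[:40]:
        d = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1)).min()
        assert edt[r, c] == pytest.approx(d, rel=1e-12)


@pytest.mark.parametrize("radius_px", [3, 4])
def test_tube_diameter_recovered_within_one_pixel(radius_px):
    px = 100.0
    spec = TreeSpec(root_position=(30, 40), root_diameter=2 * radius_px * px,
                    depth=0, segment_length=20000, pixel_size=px,
                    initial_direction=25.0, seed=0)
    mask = rasterize_tree(generate_tree(spec), (256, 256))
    g = recover_graph(mask)
    m = segment_metrics(g, mask)[0]
    assert abs(m.mean_diameter_um - 2 * radius_px * px) < px


def test_segment_outside_mask_raises():
    data = np.zeros((16, 16), bool)
    data[8, 2:14] = True
    mask = full_mask(data)
    g = SkeletonGraph(
        nodes=[Node(0, "endpoint", (1, 1)), Node(1, "endpoint", (1, 5))],
        segments=[SegmentChain(0, np.array([[1, 1], [1, 5]]), 0, 1)],
        pixel_size=1.0, shape=(16, 16),
    )
    with pytest.raises(ValueError, match="outside mask"):
        segment_metrics(g, mask)


# --------------------------------------------------------------- tortuosity

def test_straight_segment_has_dm_one():
    data = np.zeros((32, 64), bool)
    data[16, 5:60] = True
    mask = full_mask(data)
    g = build_graph(skeletonize(mask), 1.0)
    dm, tau_mean, tau_max = tortuosity(g, mask=mask)
    assert tau_mean == pytest.approx(1.0, abs=1e-6)
    assert tau_max == pytest.approx(1.0, abs=1e-6)


def test_half_circle_arc_dm_is_pi_over_two():
    R = 40
    theta = np.linspace(0, np.pi, 400)
    pts = np.unique(
        np.round(np.stack([60 - R * np.sin(theta), 64 + R * np.cos(theta)], 1)
                 ).astype(int), axis=0)
    data = np.zeros((128, 128), bool)
    data[pts[:, 0], pts[:, 1]] = True
    data = ndimage.binary_dilation(data, np.ones((3, 3)), iterations=2)
    mask = full_mask(data)
    g = recover_graph(mask, min_spur_px=6)
    assert g.nv == 1
    _, tau_mean, _ = tortuosity(g, mask=mask)
    assert tau_mean == pytest.approx(math.pi / 2, abs=0.05)


def test_sinusoidal_segment_dm_within_two_percent_of_quadrature():
    spec = TreeSpec(root_position=(60, 256), root_diameter=200, depth=0,
                    tortuosity_amplitude=250, tortuosity_wavelength=2500,
                    tortuosity_phase=0.0, segment_length=10000, pixel_size=50,
                    initial_direction=20.0, seed=0)
    tree = generate_tree(spec)
    mask = rasterize_tree(tree, (512, 512))
    g = recover_graph(mask)
    _, tau_mean, _ = tortuosity(g, mask=mask)
    assert tau_mean == pytest.approx(tree.segment_dm[0], rel=0.02)


def test_no_eligible_segments_flags_missing():
    g = SkeletonGraph(nodes=[], segments=[], pixel_size=1.0, shape=(8, 8))
    dm, tau_mean, tau_max = tortuosity(g, metrics=[])
    assert math.isnan(tau_mean) and math.isnan(tau_max)


# ------------------------------------------------------------------- murray

class _FakeSeg:
    def __init__(self, sid):
        self.id = sid
        self.chain = np.array([[0, 0], [0, 10]])


def _fake_junction(diameters):
    """Graph with one branch node and len(diameters) incident segments."""
    from hdmi.morphometrics import SegmentMetrics

    segs = [_FakeSeg(i) for i in range(len(diameters))]
    node = Node(0, "branch", (0, 0))
    g = SkeletonGraph(
        nodes=[node] + [Node(i + 1, "endpoint", (0, 10)) for i in range(len(segs))],
        segments=[SegmentChain(i, np.array([[0, 0], [0, 5], [0, 10]]), 0, i + 1)
                  for i in range(len(segs))],
        pixel_size=1.0, shape=(16, 16),
    )
    metrics = [
        SegmentMetrics(segment_id=i, arc_length_um=10, chord_length_um=10,
                       dm=1.0, mean_diameter_um=d, max_diameter_um=d)
        for i, d in enumerate(diameters)
    ]
    return g, metrics


def test_murray_exact_balance_gives_zero():
    d = 10 * (0.5) ** (1 / 3)
    g, metrics = _fake_junction([10.0, d, d])
    _, md_mean, md_max = murray_deviation(g, metrics)
    assert md_mean == pytest.approx(0.0, abs=1e-12)


def test_murray_hand_arithmetic_example():
    g, metrics = _fake_junction([10.0, 5.0, 5.0])
    out, md_mean, _ = murray_deviation(g, metrics)
    assert md_mean == pytest.approx(0.75)
    assert out[0].parent_segment == 0


def test_murray_on_generated_tree_recovers_target():
    spec = TreeSpec(root_position=(40, 384), root_diameter=500, depth=2,
                    branch_angle=100, murray_deviation_target=0.3,
                    segment_length=4000, pixel_size=25,
                    initial_direction=5.0, seed=3)
    mask = rasterize_tree(generate_tree(spec), (768, 768))
    g = recover_graph(mask)
    _, md_mean, _ = murray_deviation(g, segment_metrics(g, mask))
    assert md_mean == pytest.approx(0.3, abs=0.07)


def test_no_branch_nodes_flags_missing():
    g = SkeletonGraph(nodes=[], segments=[], pixel_size=1.0, shape=(4, 4))
    _, md_mean, md_max = murray_deviation(g, [])
    assert math.isnan(md_mean) and math.isnan(md_max)


# ------------------------------------------------------------------- angles

def test_drawn_y_protractor_angle():
    """Y with arms at +-45 degrees from vertical measures 90 +- 5."""
    data = np.zeros((128, 128), bool)
    data[10:64, 64] = True
    for i in range(40):
        data[64 + i, 64 - i] = True
        data[64 + i, 64 + i] = True
    data = ndimage.binary_dilation(data, np.ones((3, 3)), iterations=2)
    data[8:62, 61:68] = True  # thicker stem so it is picked as the parent
    mask = full_mask(data)
    g = recover_graph(mask, min_spur_px=8)
    assert g.nb == 1
    m = segment_metrics(g, mask)
    _, ba_mean, _ = bifurcation_angles(g, m, k_px=35)
    assert ba_mean == pytest.approx(90.0, abs=5.0)


def test_collinear_children_measure_180_degrees():
    """T junction: the two equal-diameter children are opposite halves of the bar."""
    data = np.zeros((96, 96), bool)
    data[48, 8:88] = True       # horizontal bar
    data[10:49, 48] = True      # stem (slightly thicker => parent)
    data = ndimage.binary_dilation(data, np.ones((3, 3)))
    data[8:49, 46:51] = True
    mask = full_mask(data)
    g = recover_graph(mask, min_spur_px=6)
    assert g.nb == 1
    m = segment_metrics(g, mask)
    _, ba_mean, _ = bifurcation_angles(g, m, k_px=15)
    assert ba_mean == pytest.approx(180.0, abs=8.0)


def test_generated_angle_ordering_preserved():
    for seed in range(5):
        vals = {}
        for angle in (60, 120):
            spec = TreeSpec(root_position=(40, 256), root_diameter=220, depth=1,
                            branch_angle=angle, segment_length=4500, pixel_size=50,
                            initial_direction=float(seed * 7 - 14), seed=seed)
            mask = rasterize_tree(generate_tree(spec), (512, 512))
            g = recover_graph(mask)
            _, ba, _ = bifurcation_angles(g, segment_metrics(g, mask), k_px=30)
            vals[angle] = ba
        assert vals[60] < vals[120]


# ------------------------------------------------------------------ fractal

def test_fractal_dimension_of_line_square_sierpinski():
    roi = RoiMask.full((256, 256), 1.0)
    line = np.zeros((256, 256), bool)
    line[128, 10:250] = True
    assert fractal_dimension(VesselMask(line, roi, 1.0)) == pytest.approx(1.0, abs=0.1)

    sq = np.zeros((256, 256), bool)
    sq[20:236, 20:236] = True
    assert fractal_dimension(VesselMask(sq, RoiMask(sq, 1.0), 1.0)) \
        == pytest.approx(2.0, abs=0.1)

    n = 128  # Sierpinski depth 7
    x, y = np.meshgrid(np.arange(n), np.arange(n))
    sp = (x & y) == 0
    fd = fractal_dimension(VesselMask(sp, RoiMask.full((n, n), 1.0), 1.0))
    assert fd == pytest.approx(math.log(3) / math.log(2), abs=0.1)


def test_fractal_dimension_edge_cases():
    mask = full_mask(np.zeros((64, 64)))
    assert math.isnan(fractal_dimension(mask))
    line = np.zeros((64, 64), bool)
    line[32, 4:60] = True
    with pytest.raises(ValueError):
        fractal_dimension(full_mask(line), box_sizes=[2, 4])


# ---------------------------------------------------------------- VDR / SVP

def test_vdr_near_one_for_uniform_vessels():
    rng = np.random.default_rng(0)
    mask = full_mask(rng.random((512, 512)) < 0.2)
    vdr, _ = vdr_svp(mask)
    assert vdr == pytest.approx(1.0, abs=0.1)


def test_vdr_labels_central_and_peripheral_patterns():
    rr, cc = np.mgrid[0:128, 0:128]
    roi = RoiMask((rr - 64) ** 2 + (cc - 64) ** 2 <= 60 ** 2, 1.0)
    central = (rr - 64) ** 2 + (cc - 64) ** 2 <= 20 ** 2
    vdr, svp = vdr_svp(VesselMask(central, roi, 1.0))
    assert math.isinf(vdr) and svp == "intratumoral"

    ring = ((rr - 64) ** 2 + (cc - 64) ** 2 <= 60 ** 2) \
        & ((rr - 64) ** 2 + (cc - 64) ** 2 >= 55 ** 2)
    vdr, svp = vdr_svp(VesselMask(ring, roi, 1.0))
    assert vdr == 0.0 and svp == "peritumoral"


# ----------------------------------------------------------- panel assembly

@pytest.fixture(scope="module")
def phenotype_pair():
    out = {}
    for label, maker in (("benign", benign_phenotype), ("malignant", malignant_phenotype)):
        mask, _, _ = generate_phenotype_image(maker(), seed=0)
        g = recover_graph(mask)
        out[label] = (mask, g, biomarker_set(mask, g))
    return out


def test_biomarker_set_matches_standalone_operations(phenotype_pair):
    mask, g, panel = phenotype_pair["malignant"]
    metrics = segment_metrics(g, mask)
    assert panel.NB == g.nb and panel.NV == g.nv
    assert panel.VD == vessel_density(mask)
    assert panel.D_max_um == max(m.mean_diameter_um for m in metrics)
    _, tau_mean, tau_max = tortuosity(g, metrics)
    assert (panel.tau_mean, panel.tau_max) == (tau_mean, tau_max)
    _, md_mean, md_max = murray_deviation(g, metrics)
    assert (panel.MD_mean, panel.MD_max) == (md_mean, md_max)
    _, ba_mean, ba_max = bifurcation_angles(g, metrics, k_px=20)
    assert (panel.BA_mean, panel.BA_max) == (ba_mean, ba_max)
    assert panel.mvFD == fractal_dimension(mask)
    vdr, svp = vdr_svp(mask)
    assert (panel.VDR, panel.SVP) == (vdr, svp)
    assert not panel.missing


def test_biomarker_set_benign_below_malignant_density(phenotype_pair):
    assert phenotype_pair["benign"][2].VD < phenotype_pair["malignant"][2].VD


def test_empty_mask_flags_ratio_markers_missing():
    mask = full_mask(np.zeros((64, 64)))
    g = build_graph(np.zeros((64, 64), bool), 1.0)
    panel = biomarker_set(mask, g)
    assert panel.NB == 0 and panel.NV == 0 and panel.VD == 0.0
    assert {"tau_mean", "MD_max", "BA_mean", "mvFD", "VDR"} <= panel.missing
    assert math.isnan(panel.tau_mean)


def test_to_row_has_canonical_columns(phenotype_pair):
    row = phenotype_pair["benign"][2].to_row()
    from hdmi.synthetic import BIOMARKER_COLUMNS
    assert list(row)[:12] == BIOMARKER_COLUMNS
    assert list(row)[12] == "SVP"


# ------------------------------------------------------------- invariances

def test_rotation_by_90_degrees_preserves_biomarkers():
    spec = TreeSpec(root_position=(40, 256), root_diameter=400, depth=3,
                    branch_angle=80, tortuosity_amplitude=150,
                    tortuosity_wavelength=2500, tortuosity_phase=None,
                    segment_length=4000, pixel_size=50,
                    initial_direction=10.0, seed=4)
    mask = rasterize_tree(generate_tree(spec), (512, 512))
    rot = VesselMask(np.rot90(mask.data).copy(),
                     RoiMask(np.rot90(mask.roi.data).copy(), 50.0), 50.0)
    p1 = biomarker_set(mask, recover_graph(mask))
    p2 = biomarker_set(rot, recover_graph(rot))
    assert (p1.NV, p1.NB) == (p2.NV, p2.NB)
    assert p1.VD == p2.VD
    assert p1.mvFD == p2.mvFD
    for f in ("tau_mean", "BA_mean", "MD_mean"):
        assert getattr(p2, f) == pytest.approx(getattr(p1, f), rel=0.02)


def test_upsampling_preserves_micron_biomarkers():
    spec = TreeSpec(root_position=(20, 128), root_diameter=400, depth=2,
                    branch_angle=90, segment_length=3200, pixel_size=50,
                    initial_direction=10.0, seed=6)
    mask = rasterize_tree(generate_tree(spec), (256, 256))
    up = VesselMask(np.kron(mask.data, np.ones((2, 2), bool)),
                    RoiMask(np.kron(mask.roi.data, np.ones((2, 2), bool)), 25.0),
                    25.0)
    p1 = biomarker_set(mask, recover_graph(mask))
    p2 = biomarker_set(up, recover_graph(up, min_spur_px=10))
    assert p2.D_max_um == pytest.approx(p1.D_max_um, rel=0.05)
    assert p2.tau_mean == pytest.approx(p1.tau_mean, rel=0.05)
    assert p2.VD == pytest.approx(p1.VD, rel=0.05)
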