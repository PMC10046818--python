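import numpy as np
import pytest

from hdmi.core import RoiMask, VesselMask
from hdmi.graph import build_graph, prune_graph, skeletonize
from hdmi.synthetic import TreeSpec, generate_tree, rasterize_tree


def tree_mask(spec: TreeSpec, canvas=(512, 512)) -> VesselMask:
    return rasterize_tree(generate_tree(spec), canvas)


def recover_graph(mask: VesselMask, min_spur_px: int = 5):
    skel = skeletonize(mask)
    return prune_graph(build_graph(skel, mask.pixel_size), min_spur_px)


@pytest.fixture(scope="session")
def simple_tree_spec():
    """Depth-3 binary tree, 8 px root radius, no tortuosity."""
    return TreeSpec(
        root_position=(30, 256), root_diameter=400, depth=3,
        branch_angle=90, segment_length=4000, length_taper=0.8,
        pixel_size=50, seed=0,
    )


@pytest.fixture(scope="session")
def simple_tree(simple_tree_spec):
    return generate_tree(simple_tree_spec)


@pytest.fixture(scope="session")
def simple_mask(simple_tree):
    return rasterize_tree(simple_tree, (512, 512))


@pytest.fixture(scope="session")
def simple_graph(simple_mask):
    return recover_graph(simple_mask)


def full_roi(shape, pixel_size=1.0):
    return RoiMask.full(shape, pixel_size)


def paint_oracle(tree, canvas_shape, pixel_size) -> np.ndarray:
    """Independent rasterization oracle: full-canvas point-to-edge distances.

    A pixel is painted iff its center lies within the segment radius of any
    centerline polyline edge — computed here without bounding boxes or
    chunking, unlike the production painter.
    """
    rows, cols = canvas_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    painted = np.zeros(rows * cols, dtype=bool)
    for seg in tree.segments:
        pts = seg.points / pixel_size
        r = seg.radius / pixel_size
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d = np.linalg.norm(pix - a, axis=1)
            else:
                t = np.clip((pix - a) @ ab / denom, 0.0, 1.0)
                d = np.linalg.norm(pix - (a + t[:, None] * ab), axis=1)
            painted |= d <= r
    return painted.reshape(canvas_shape)
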