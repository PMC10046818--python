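"""Synthetic vasculature, slow-time ensembles, and biomarker cohorts.

Patient microvessel data are not publicly available, so every stage of the
pipeline is exercised against this generator, which produces

* branching vascular trees with controllable diameter taper (Murray's law
  with a prescribed deviation), bifurcation angle, sinusoidal tortuosity and
  segment length — together with exact ground truth for every morphometric
  the pipeline later measures;
* rasterized vessel masks (pixel-center-in-capsule inclusion, so the painted
  area has an exact per-pixel oracle) and speckled intensity images;
* slow-time ensembles built as low-rank tissue clutter + moving blood
  scatterers + white noise, with the three addends returned separately;
* label-conditional biomarker cohorts drawn from published benign/malignant
  summary statistics (truncated normals within each biomarker's domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import RoiMask, SlowTimeStack, VesselMask

__all__ = [
    "TreeSpec",
    "Segment",
    "VesselTree",
    "BloodPath",
    "PhenotypeSpec",
    "BIOMARKER_COLUMNS",
    "COHORT_SUMMARY",
    "BIOMARKER_DOMAINS",
    "generate_tree",
    "rasterize_tree",
    "speckle_intensity",
    "synthesize_slowtime",
    "sample_cohort",
    "benign_phenotype",
    "malignant_phenotype",
    "generate_phenotype_image",
]


# --------------------------------------------------------------------------
# tree specification and ground truth containers
# --------------------------------------------------------------------------

@dataclass
class TreeSpec:
    """Parameters of one synthetic vascular tree.

    Lengths are µm unless stated otherwise. ``depth`` counts bifurcation
    generations: depth 0 is a single unbranched root segment, depth d gives
    2**(d+1) - 1 segments and 2**d - 1 bifurcations.

    The diameter recursion follows Murray's law with a prescribed deviation:
    at every bifurcation the two (equal-diameter) children satisfy
    ``sum(d_c**gamma) = (1 - delta) * d_p**gamma`` with
    ``delta = murray_deviation_target``, so the bounded deviation index
    |d_p^3 - sum d_c^3| / max(d_p^3, sum d_c^3) equals ``delta`` exactly
    when ``murray_exponent == 3``. Children are made smaller than the parent
    (vessels taper downstream), which keeps the largest-diameter branch at a
    junction the true parent.

    Tortuosity is a single sinusoid of ``tortuosity_amplitude`` /
    ``tortuosity_wavelength`` applied perpendicular to each segment chord
    (closed-form arc length, so tortuosity ground truth has an independent
    quadrature oracle). ``tortuosity_phase=None`` draws a random phase per
    segment.
    """

    root_position: tuple[float, float] = (10.0, 128.0)  # (row, col) pixels
    root_diameter: float = 400.0                        # µm
    depth: int = 3
    branch_angle: float = 90.0                          # degrees, child-to-child
    murray_exponent: float = 3.0
    murray_deviation_target: float = 0.0                # in [0, 1)
    tortuosity_amplitude: float = 0.0                   # µm
    tortuosity_wavelength: float = 2000.0               # µm
    tortuosity_phase: float | None = 0.0                # radians; None = random
    segment_length: float = 4000.0                      # µm at generation 0
    length_taper: float = 0.8                           # per generation
    pixel_size: float = 50.0                            # µm/pixel
    initial_direction: float = 0.0                      # deg; 0 points +row
    angle_jitter: float = 0.0                           # deg, uniform +-
    length_jitter: float = 0.0                          # fractional, uniform +-
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 < self.branch_angle < 180.0):
            raise ValueError("branch_angle must be in (0, 180) degrees")
        if not (0.0 <= self.murray_deviation_target < 1.0):
            raise ValueError("murray_deviation_target must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.root_diameter <= 0:
            raise ValueError("root_diameter must be positive")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if self.tortuosity_amplitude > 0 and self.tortuosity_wavelength <= 0:
            raise ValueError("tortuosity_wavelength must be positive")


@dataclass
class Segment:
    """One vessel segment: a dense centerline polyline with a radius."""

    points: np.ndarray          # (N, 2) float, (row, col) in µm
    radius: float               # µm (constant along the segment)
    parent: int | None          # index of parent segment, None for root
    generation: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("polyline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def dm(self) -> float:
        """Distance-metric tortuosity: arc length / chord length."""
        chord = self.chord_length
        return self.arc_length / chord if chord > 0 else float("inf")


@dataclass
class VesselTree:
    """A generated tree plus the exact ground truth of its morphometrics."""

    segments: list[Segment]
    spec: TreeSpec
    # per-bifurcation ground truth, one entry per internal node
    bifurcation_angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    murray_deviations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def nv(self) -> int:
        """True number of vessel segments."""
        return len(self.segments)

    @property
    def nb(self) -> int:
        """True number of branch points."""
        return len(self.bifurcation_angles)

    @property
    def segment_dm(self) -> np.ndarray:
        return np.array([s.dm for s in self.segments])

    @property
    def segment_diameters(self) -> np.ndarray:
        return np.array([2.0 * s.radius for s in self.segments])

    def ground_truth(self) -> dict:
        return {
            "nb": self.nb,
            "nv": self.nv,
            "dm": self.segment_dm,
            "diameters_um": self.segment_diameters,
            "bifurcation_angles_deg": self.bifurcation_angles,
            "murray_deviations": self.murray_deviations,
        }


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def _segment_polyline(
    start: np.ndarray,
    direction_deg: float,
    length: float,
    amplitude: float,
    wavelength: float,
    phase: float,
    step: float,
) -> np.ndarray:
    """Sinusoidally perturbed straight segment, sampled every ``step`` µm."""
    u = _unit(direction_deg)
    if amplitude == 0:
        return np.stack([start, start + length * u])
    n = np.array([-u[1], u[0]])  # left normal
    m = max(2, int(math.ceil(length / step)) + 1)
    t = np.linspace(0.0, length, m)
    off = amplitude * np.sin(2.0 * math.pi * t / wavelength + phase)
    off = off - off[0]  # segment starts exactly at `start`
    return start[None, :] + t[:, None] * u[None, :] + off[:, None] * n[None, :]


def generate_tree(spec: TreeSpec, canvas_shape: tuple[int, int] | None = None) -> VesselTree:
    """Grow a binary vascular tree from ``spec``.

    Deterministic under ``spec.seed``. If ``canvas_shape`` (pixels) is given,
    a tree whose tube (centerline inflated by its radius) leaves the canvas
    raises ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)
    gamma = spec.murray_exponent
    delta = spec.murray_deviation_target
    # children smaller than parent: sum d_c^gamma = (1 - delta) d_p^gamma
    child_factor = ((1.0 - delta) / 2.0) ** (1.0 / gamma)

    # polyline sampling: capsule rasterization is exact for any density, so
    # only the sinusoid needs resolving (40 points per wavelength)
    step = spec.tortuosity_wavelength / 40.0

    root_start = np.asarray(spec.root_position, dtype=float) * spec.pixel_size
    segments: list[Segment] = []
    angles: list[float] = []
    deviations: list[float] = []

    # frontier entries: (parent index, start point µm, direction deg, diameter µm, generation)
    frontier = [(None, root_start, spec.initial_direction, spec.root_diameter, 0)]
    while frontier:
        parent_idx, start, direction, diameter, gen = frontier.pop(0)
        length = spec.segment_length * spec.length_taper ** gen
        if spec.length_jitter > 0:
            length *= 1.0 + spec.length_jitter * rng.uniform(-1.0, 1.0)
        phase = (
            spec.tortuosity_phase
            if spec.tortuosity_phase is not None
            else float(rng.uniform(0.0, 2.0 * math.pi))
        )
        pts = _segment_polyline(
            start, direction, length,
            spec.tortuosity_amplitude, spec.tortuosity_wavelength, phase, step,
        )
        seg = Segment(points=pts, radius=diameter / 2.0, parent=parent_idx, generation=gen)
        idx = len(segments)
        segments.append(seg)

        if gen < spec.depth:
            half = spec.branch_angle / 2.0
            jit = spec.angle_jitter * rng.uniform(-1.0, 1.0) if spec.angle_jitter > 0 else 0.0
            d_child = diameter * child_factor
            end = pts[-1]
            frontier.append((idx, end, direction - half + jit, d_child, gen + 1))
            frontier.append((idx, end, direction + half + jit, d_child, gen + 1))
            # record ground truth with the bounded cubed-diameter index
            dp3 = diameter ** 3
            dc3 = 2.0 * d_child ** 3
            deviations.append(abs(dp3 - dc3) / max(dp3, dc3))
            angles.append(spec.branch_angle)

    if canvas_shape is not None:
        lo = np.array([0.0, 0.0])
        hi = np.array(canvas_shape, dtype=float) * spec.pixel_size
        for seg in segments:
            if ((seg.points - seg.radius < lo).any()
                    or (seg.points + seg.radius > hi).any()):
                raise ValueError("tree exits the stated canvas")

    return VesselTree(
        segments=segments,
        spec=spec,
        bifurcation_angles=np.asarray(angles, dtype=float),
        murray_deviations=np.asarray(deviations, dtype=float),
    )


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _paint_segment(canvas: np.ndarray, pts_px: np.ndarray, radius_px: float) -> None:
    """Paint pixels whose centers lie within radius_px of the polyline.

    Inclusion rule: Euclidean distance from the pixel center (integer
    coordinates) to the nearest polyline *edge* is <= radius_px. This is the
    exact capsule-union of the polyline, so a brute-force per-pixel oracle
    reproduces the painted set bit for bit.
    """
    rows, cols = canvas.shape
    rmin = max(0, int(math.floor(pts_px[:, 0].min() - radius_px - 1)))
    rmax = min(rows - 1, int(math.ceil(pts_px[:, 0].max() + radius_px + 1)))
    cmin = max(0, int(math.floor(pts_px[:, 1].min() - radius_px - 1)))
    cmax = min(cols - 1, int(math.ceil(pts_px[:, 1].max() + radius_px + 1)))
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    p = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)  # (M, 2)

    a = pts_px[:-1]                      # (K, 2)
    b = pts_px[1:]
    ab = b - a
    ab2 = (ab ** 2).sum(axis=1)
    ab2[ab2 == 0] = 1.0                  # degenerate edges: treat as points

    dmin = np.full(p.shape[0], np.inf)
    chunk = 64                           # bound the (M, K) temporary
    for k0 in range(0, a.shape[0], chunk):
        a_ = a[k0:k0 + chunk]
        ab_ = ab[k0:k0 + chunk]
        ab2_ = ab2[k0:k0 + chunk]
        ap = p[:, None, :] - a_[None, :, :]          # (M, k, 2)
        t = (ap * ab_[None, :, :]).sum(axis=2) / ab2_[None, :]
        t = np.clip(t, 0.0, 1.0)
        closest = a_[None, :, :] + t[:, :, None] * ab_[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2).min(axis=1)
        dmin = np.minimum(dmin, d)

    inside = (dmin <= radius_px).reshape(rr.shape)
    canvas[rmin:rmax + 1, cmin:cmax + 1] |= inside


def rasterize_tree(
    tree: VesselTree,
    canvas_shape: tuple[int, int],
    roi: RoiMask | None = None,
    pixel_size: float | None = None,
) -> VesselMask:
    """Rasterize a tree onto a canvas as disc-swept tubes.

    A pixel is painted when its center lies within the local radius of a
    segment centerline (capsule inclusion). The mask is restricted to the
    ROI (full canvas when ``roi`` is None).
    """
    px = pixel_size if pixel_size is not None else tree.spec.pixel_size
    if roi is None:
        roi = RoiMask.full(canvas_shape, px)
    if roi.data.shape != tuple(canvas_shape):
        raise ValueError("ROI shape differs from canvas shape")
    canvas = np.zeros(canvas_shape, dtype=bool)
    for seg in tree.segments:
        _paint_segment(canvas, seg.points / px, seg.radius / px)
    return VesselMask(data=canvas, roi=roi, pixel_size=px)


def speckle_intensity(
    mask: VesselMask,
    speckle_sigma: float = 0.3,
    background: float = 0.05,
    seed: int = 0,
    vessel_level: float = 1.0,
) -> np.ndarray:
    """Speckled intensity image from a binary mask.

    Vessel pixels get multiplicative speckle (1 + sigma*N(0,1), clipped at 0)
    around ``vessel_level``; everywhere receives Rayleigh-like background
    noise of mean ``background``. Emulates residual noise of a power image;
    no acoustic propagation is modelled.
    """
    rng = np.random.default_rng(seed)
    img = mask.data.astype(float) * vessel_level
    img *= np.clip(1.0 + speckle_sigma * rng.standard_normal(img.shape), 0.0, None)
    img += background * np.abs(rng.standard_normal(img.shape))
    return img


# --------------------------------------------------------------------------
# slow-time ensembles
# --------------------------------------------------------------------------

@dataclass
class BloodPath:
    """A moving blood scatterer: Gaussian blob translating at fixed velocity."""

    start: tuple[float, float]        # (row, col) px at frame 0
    velocity: tuple[float, float]     # px per frame
    amplitude: float = 1.0
    sigma: float = 1.0                # blob width, px


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, smooth: float = 8.0) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), smooth)
    f /= np.linalg.norm(f) + 1e-300
    return f


def synthesize_slowtime(
    shape: tuple[int, int],
    n_frames: int,
    tissue_rank: int = 2,
    blood_paths: list[BloodPath] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    tissue_amplitude: float = 100.0,
    frame_rate: float = 1000.0,
    pixel_size: float = 100.0,
    orthogonal_blood: bool = False,
) -> SlowTimeStack:
    """Slow-time ensemble = low-rank tissue + moving blood + white noise.

    Tissue is a sum of ``tissue_rank`` outer products of smooth random
    spatial fields with slow temporal cosines (frequencies k/(4T), so the
    clutter subspace is genuinely low-rank and slow). ``tissue_amplitude``
    sets the clutter-to-blood scale (clutter dominates by construction, as
    in vivo). The three addends are kept in ``stack.components`` so filter
    tests can compare against the exact decomposition.

    ``orthogonal_blood`` projects the blood term's slow-time profiles off the
    span of the tissue temporal modes, making tissue and blood exactly
    separable by a rank cutoff — a validation construction, not a physical
    claim.
    """
    if tissue_rank < 0:
        raise ValueError("tissue_rank must be >= 0")
    if n_frames <= tissue_rank:
        raise ValueError("need n_frames > tissue_rank")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    t = np.arange(n_frames)

    tissue = np.zeros((rows, cols, n_frames))
    temporal_modes = []
    for k in range(tissue_rank):
        spatial = _smooth_field(shape, rng)
        temporal = np.cos(2.0 * math.pi * (k + 0.25) / (4.0 * n_frames) * t
                          + rng.uniform(0, 2 * math.pi))
        temporal_modes.append(temporal)
        tissue += tissue_amplitude * spatial[:, :, None] * temporal[None, None, :]

    blood = np.zeros((rows, cols, n_frames))
    rr, cc = np.mgrid[0:rows, 0:cols]
    for path in blood_paths or []:
        p0 = np.asarray(path.start, dtype=float)
        v = np.asarray(path.velocity, dtype=float)
        for j in range(n_frames):
            pos = p0 + v * j
            if not (0 <= pos[0] <= rows - 1 and 0 <= pos[1] <= cols - 1):
                raise ValueError("blood path leaves the field of view")
            blood[:, :, j] += path.amplitude * np.exp(
                -((rr - pos[0]) ** 2 + (cc - pos[1]) ** 2) / (2.0 * path.sigma ** 2)
            )

    if orthogonal_blood and temporal_modes and blood.any():
        q, _ = np.linalg.qr(np.stack(temporal_modes, axis=1))  # (frames, rank)
        bc = blood.reshape(rows * cols, n_frames)
        bc -= (bc @ q) @ q.T
        blood = bc.reshape(rows, cols, n_frames)

    noise = (noise_sigma * rng.standard_normal((rows, cols, n_frames))
             if noise_sigma > 0 else np.zeros((rows, cols, n_frames)))

    return SlowTimeStack(
        data=tissue + blood + noise,
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        components={"tissue": tissue, "blood": blood, "noise": noise},
    )


# --------------------------------------------------------------------------
# biomarker cohorts
# --------------------------------------------------------------------------

#: Canonical biomarker column order used everywhere (reports, cohorts, stats).
BIOMARKER_COLUMNS = [
    "NB", "NV", "VD", "D_max_um", "VDR", "tau_max", "tau_mean",
    "mvFD", "BA_mean", "BA_max", "MD_mean", "MD_max",
]

#: Per-label summary statistics (mean, SD) of the 12 biomarkers in benign vs
#: malignant thyroid nodules, as published for the 57/35-nodule cohort the
#: generator emulates.
COHORT_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "NB":       {"benign": (29.00, 8.49),   "malignant": (42.50, 41.72)},
    "NV":       {"benign": (49.00, 1.41),   "malignant": (65.50, 64.35)},
    "VD":       {"benign": (0.17, 0.08),    "malignant": (0.24, 0.07)},
    "D_max_um": {"benign": (624.59, 48.48), "malignant": (624.04, 9.65)},
    "VDR":      {"benign": (0.96, 0.23),    "malignant": (1.09, 0.49)},
    "tau_max":  {"benign": (1.36, 0.004),   "malignant": (1.42, 0.14)},
    "tau_mean": {"benign": (1.05, 0.01),    "malignant": (1.06, 0.01)},
    "mvFD":     {"benign": (1.43, 0.01),    "malignant": (1.46, 0.14)},
    "BA_mean":  {"benign": (108.31, 96.00), "malignant": (94.41, 6.55)},
    "BA_max":   {"benign": (169.12, 2.66),  "malignant": (149.11, 29.37)},
    "MD_mean":  {"benign": (0.36, 0.02),    "malignant": (0.38, 0.03)},
    "MD_max":   {"benign": (0.81, 0.12),    "malignant": (0.84, 0.13)},
}

#: Legal domain of each biomarker: (low, high, integer-valued).
BIOMARKER_DOMAINS: dict[str, tuple[float, float, bool]] = {
    "NB":       (0.0, np.inf, True),
    "NV":       (0.0, np.inf, True),
    "VD":       (0.0, 1.0, False),
    "D_max_um": (0.0, np.inf, False),
    "VDR":      (0.0, np.inf, False),
    "tau_max":  (1.0, np.inf, False),
    "tau_mean": (1.0, np.inf, False),
    "mvFD":     (0.0, 2.0, False),
    "BA_mean":  (1e-9, 180.0, False),
    "BA_max":   (1e-9, 180.0, False),
    "MD_mean":  (0.0, 1.0, False),
    "MD_max":   (0.0, 1.0, False),
}

#: Clinical covariate summaries for the same cohort: age (years) and nodule
#: size (mm) as (mean, SD); TI-RADS score as per-label category counts.
CLINICAL_SUMMARY = {
    "age": {"benign": (55.9, 15.2), "malignant": (42.7, 13.6)},
    "nodule_size": {"benign": (21.75, 12.50), "malignant": (19.97, 13.12)},
    "tirads": {
        "benign": {2: 3, 3: 8, 4: 27, 5: 16},
        "malignant": {2: 1, 3: 0, 4: 9, 5: 24},
    },
}


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n_benign: int,
    n_malignant: int,
    summary_table: dict | None = None,
    seed: int = 0,
    include_clinical: bool = False,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a label-conditional per-nodule biomarker cohort.

    Each biomarker is drawn from a normal with the per-label (mean, SD) of
    ``summary_table`` (default: the published benign/malignant summaries),
    truncated to the biomarker's legal domain; count-valued biomarkers are
    rounded to non-negative integers. ``correlation``, if given, imposes a
    Gaussian copula across the 12 biomarkers (none by default — only
    marginal summaries are published).

    Returns a DataFrame with columns ``id``, ``label``, the 12 biomarkers in
    canonical order and, when requested, ``age``, ``nodule_size``,
    ``tirads``.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one nodule per class")
    table = summary_table if summary_table is not None else COHORT_SUMMARY
    rng = np.random.default_rng(seed)
    p = len(BIOMARKER_COLUMNS)
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (p, p):
            raise ValueError(f"correlation must be {p}x{p}")

    frames = []
    offset = 0
    for label, n in (("benign", n_benign), ("malignant", n_malignant)):
        cols: dict[str, np.ndarray] = {}
        if correlation is not None:
            z = rng.multivariate_normal(np.zeros(p), correlation, size=n)
            u = sstats.norm.cdf(z)
        for j, name in enumerate(BIOMARKER_COLUMNS):
            mean, sd = table[name][label]
            lo, hi, integer = BIOMARKER_DOMAINS[name]
            if correlation is not None and sd > 0:
                a, b = (lo - mean) / sd, (hi - mean) / sd
                x = sstats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
            else:
                x = _truncated_normal(mean, sd, lo, hi, n, rng)
            if integer:
                x = np.maximum(np.round(x), 0).astype(int)
            cols[name] = x
        df = pd.DataFrame(cols)
        df.insert(0, "label", label)
        df.insert(0, "id", [f"n{offset + i:04d}" for i in range(n)])
        if include_clinical:
            am, asd = CLINICAL_SUMMARY["age"][label]
            sm, ssd = CLINICAL_SUMMARY["nodule_size"][label]
            df["age"] = np.round(_truncated_normal(am, asd, 18, 95, n, rng), 1)
            df["nodule_size"] = np.round(_truncated_normal(sm, ssd, 3, 80, n, rng), 1)
            counts = CLINICAL_SUMMARY["tirads"][label]
            cats = np.array(sorted(counts))
            pr = np.array([counts[c] for c in cats], dtype=float)
            df["tirads"] = rng.choice(cats, size=n, p=pr / pr.sum())
        frames.append(df)
        offset += n
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# benign / malignant phenotype images
# --------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """Knobs for a benign-like or malignant-like synthetic nodule image.

    Defaults encode the qualitative contrast the pipeline must detect:
    malignant vasculature is denser (more trees, deeper branching), more
    tortuous, bifurcates at narrower angles, and violates Murray's law more
    strongly than benign vasculature.
    """

    label: str = "benign"
    n_trees: int = 2
    depth: int = 3
    angle_mean: float = 120.0            # degrees
    murray_deviation_mean: float = 0.15
    tortuosity_amplitude: float = 20.0   # µm
    tortuosity_wavelength: float = 2400.0
    root_diameter: float = 380.0         # µm
    segment_length: float = 1600.0       # µm
    length_taper: float = 0.7
    speckle_sigma: float = 0.25
    background: float = 0.04
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 40.0             # µm/pixel
    roi_fraction: float = 0.42           # ellipse semi-axes / canvas

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")
        if self.n_trees < 1 or self.depth < 0:
            raise ValueError("n_trees >= 1 and depth >= 0 required")


def benign_phenotype(**overrides) -> PhenotypeSpec:
    return PhenotypeSpec(label="benign", **overrides)


def malignant_phenotype(**overrides) -> PhenotypeSpec:
    base = dict(
        label="malignant",
        n_trees=4,
        depth=4,
        angle_mean=60.0,
        murray_deviation_mean=0.55,
        tortuosity_amplitude=80.0,
        tortuosity_wavelength=1600.0,
        root_diameter=500.0,
        segment_length=1500.0,
        length_taper=0.75,
    )
    base.update(overrides)
    return PhenotypeSpec(**base)


def elliptical_roi(shape: tuple[int, int], fraction: float, pixel_size: float) -> RoiMask:
    """Centered elliptical ROI with semi-axes ``fraction`` of the canvas."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    e = (((rr - rows / 2) / (fraction * rows)) ** 2
         + ((cc - cols / 2) / (fraction * cols)) ** 2) <= 1.0
    return RoiMask(e, pixel_size)


def generate_phenotype_image(
    phenotype: PhenotypeSpec, seed: int = 0
) -> tuple[VesselMask, np.ndarray, dict]:
    """Rasterized phenotype nodule: (vessel mask, intensity image, truth).

    Trees are rooted on a ring inside an elliptical ROI and grow inward with
    jittered orientation; the mask is clipped to the ROI, so the returned
    ground truth describes the trees as generated (before clipping).
    """
    rng = np.random.default_rng(seed)
    shape, px = phenotype.shape, phenotype.pixel_size
    roi = elliptical_roi(shape, phenotype.roi_fraction, px)
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])

    trees = []
    canvas = np.zeros(shape, dtype=bool)
    rotation = rng.uniform(0, 2 * math.pi)
    for i in range(phenotype.n_trees):
        # roots stratified around the ROI rim so trees rarely collide
        theta = rotation + 2 * math.pi * (i + 0.15 * rng.uniform(-1, 1)) / phenotype.n_trees
        radius = 0.75 * phenotype.roi_fraction * min(shape)
        root = center + radius * np.array([math.cos(theta), math.sin(theta)])
        inward = math.degrees(math.atan2(center[1] - root[1], center[0] - root[0]))
        spec = TreeSpec(
            root_position=(float(root[0]), float(root[1])),
            root_diameter=phenotype.root_diameter,
            depth=phenotype.depth,
            branch_angle=phenotype.angle_mean,
            murray_deviation_target=phenotype.murray_deviation_mean,
            tortuosity_amplitude=phenotype.tortuosity_amplitude,
            tortuosity_wavelength=phenotype.tortuosity_wavelength,
            tortuosity_phase=None,
            segment_length=phenotype.segment_length,
            length_taper=phenotype.length_taper,
            pixel_size=px,
            initial_direction=inward + rng.uniform(-15, 15),
            angle_jitter=6.0,
            length_jitter=0.15,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tree = generate_tree(spec)
        trees.append(tree)
        for seg in tree.segments:
            _paint_segment(canvas, seg.points / px, seg.radius / px)

    mask = VesselMask(data=canvas, roi=roi, pixel_size=px)
    intensity = speckle_intensity(
        mask,
        speckle_sigma=phenotype.speckle_sigma,
        background=phenotype.background,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    roi_area = roi.area_px
    truth = {
        "label": phenotype.label,
        "nb": sum(t.nb for t in trees),
        "nv": sum(t.nv for t in trees),
        "vd": float(mask.data.sum()) / roi_area,
        "dm": np.concatenate([t.segment_dm for t in trees]),
        "bifurcation_angles_deg": np.concatenate([t.bifurcation_angles for t in trees]),
        "murray_deviations": np.concatenate([t.murray_deviations for t in trees]),
        "diameters_um": np.concatenate([t.segment_diameters for t in trees]),
        "trees": trees,
    }
    return mask, intensity, truth
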