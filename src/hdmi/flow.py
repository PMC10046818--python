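"""Flow image formation: SVD clutter filtering and power-image integration.

A slow-time ensemble mixes high-amplitude, slowly varying tissue echo with
weak signal from moving blood. Reshaping the stack into the Casorati matrix
(pixels x frames) and truncating its leading singular components removes the
low-rank tissue subspace; averaging squared magnitude over frames then yields
a microvessel power image. The filter family and cutoff rule are engineering
choices of this package (a fixed-rank cutoff by default, with an optional
turning-point heuristic), not a claim about any particular scanner chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PowerImage, SlowTimeStack

__all__ = [
    "ClutterFilter",
    "svd_clutter_filter",
    "power_image",
    "denoise_background",
    "suggest_rank_cutoff",
]


@dataclass
class ClutterFilter:
    """A fitted clutter filter: projection off a slow-time subspace.

    ``basis`` holds orthonormal temporal vectors (frames x r) spanning the
    rejected subspace — the leading ``low_rank_cutoff`` right singular
    vectors of the Casorati matrix (tissue) and, when a high cutoff is set,
    the trailing ones (noise). Application is the orthogonal projection
    ``C (I - B B^T)``, so a fitted filter is exactly idempotent and linear.
    Re-fitting on already-filtered data would instead truncate the next
    components; keep the fitted object when reapplication matters.
    """

    basis: np.ndarray
    low_rank_cutoff: int
    high_cutoff: int | None = None

    @classmethod
    def fit(
        cls,
        stack: SlowTimeStack,
        low_rank_cutoff: int,
        high_cutoff: int | None = None,
    ) -> "ClutterFilter":
        c = stack.casorati()
        n_max = min(c.shape)
        if not (0 <= low_rank_cutoff < n_max):
            raise ValueError(f"low_rank_cutoff must be in [0, {n_max})")
        if high_cutoff is not None and high_cutoff <= low_rank_cutoff:
            raise ValueError("high_cutoff must exceed low_rank_cutoff")
        if low_rank_cutoff == 0 and high_cutoff is None:
            basis = np.zeros((stack.n_frames, 0))
        else:
            _, _, vh = np.linalg.svd(c, full_matrices=False)
            rows = list(range(low_rank_cutoff))
            if high_cutoff is not None:
                rows += list(range(high_cutoff, vh.shape[0]))
            basis = vh[rows].T.conj()
        return cls(basis=basis, low_rank_cutoff=low_rank_cutoff,
                   high_cutoff=high_cutoff)

    def apply(self, stack: SlowTimeStack) -> SlowTimeStack:
        c = stack.casorati()
        if self.basis.shape[1]:
            c = c - (c @ self.basis) @ self.basis.T.conj()
        return SlowTimeStack(
            data=c.reshape(stack.data.shape),
            frame_rate=stack.frame_rate,
            pixel_size=stack.pixel_size,
        )


def svd_clutter_filter(
    stack: SlowTimeStack,
    low_rank_cutoff: int,
    high_cutoff: int | None = None,
) -> SlowTimeStack:
    """Remove the leading singular components of the Casorati matrix.

    Components with index < ``low_rank_cutoff`` (tissue clutter) are
    rejected; if ``high_cutoff`` is given, components with index >=
    ``high_cutoff`` (noise tail) are rejected as well. ``low_rank_cutoff=0``
    with no high cutoff is the identity. Equivalent to
    ``ClutterFilter.fit(stack, ...).apply(stack)``; output energy never
    exceeds input energy.
    """
    return ClutterFilter.fit(stack, low_rank_cutoff, high_cutoff).apply(stack)


def suggest_rank_cutoff(stack: SlowTimeStack) -> int:
    """Turning-point heuristic for the tissue cutoff.

    Returns the index of maximum curvature (discrete second difference) of
    the log singular-value curve — the knee where the steep tissue decay
    flattens into the blood/noise plateau. Offered as an optional strategy;
    the pipeline default is a fixed integer cutoff.
    """
    s = np.linalg.svd(stack.casorati(), compute_uv=False)
    logs = np.log(np.maximum(s, np.finfo(float).tiny))
    if len(logs) < 3:
        return 1
    curvature = logs[:-2] - 2 * logs[1:-1] + logs[2:]
    return int(np.argmax(curvature) + 1)


def power_image(stack: SlowTimeStack) -> PowerImage:
    """Per-pixel mean squared magnitude across frames."""
    vals = np.mean(np.abs(stack.data) ** 2, axis=2)
    return PowerImage(values=vals, pixel_size=stack.pixel_size)


def denoise_background(
    img: PowerImage,
    method: str = "rolling_top_hat",
    radius_or_quantile: float = 15,
) -> PowerImage:
    """Suppress slowly varying background in a power image.

    ``rolling_top_hat``: morphological white top-hat with a disc of the
    given radius (pixels) — removes structures wider than the disc while
    retaining narrow bright vessels.

    ``noise_floor_subtraction``: subtract the given intensity quantile and
    clip at zero — monotone in the quantile (raising it never increases any
    pixel).
    """
    v = img.values
    if method == "rolling_top_hat":
        from skimage.morphology import disk, white_tophat

        radius = int(radius_or_quantile)
        if radius <= 0:
            raise ValueError("top-hat radius must be positive")
        if 2 * radius + 1 > min(v.shape):
            raise ValueError("top-hat radius larger than image")
        out = white_tophat(v, footprint=disk(radius))
    elif method == "noise_floor_subtraction":
        q = float(radius_or_quantile)
        if not (0.0 <= q <= 1.0):
            raise ValueError("quantile must be in [0, 1]")
        floor = np.quantile(v, q)
        out = np.clip(v - floor, 0.0, None)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return PowerImage(values=out, pixel_size=img.pixel_size)
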