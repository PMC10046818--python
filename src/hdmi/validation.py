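"""Reproducible validation experiments for the whole pipeline.

Each function generates its own synthetic inputs from a seed, runs the
relevant pipeline stage(s), and returns summary metrics. The test suite
asserts tolerances on these numbers and the reproduction script reports
them; both therefore exercise exactly the same code paths as a user would.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import rankdata

from .config import PipelineConfig
from .core import PowerImage, RoiMask, VesselMask
from .flow import ClutterFilter, svd_clutter_filter
from .graph import build_graph, prune_graph, skeletonize
from .morphometrics import (
    bifurcation_angles,
    fractal_dimension,
    murray_deviation,
    segment_metrics,
    tortuosity,
)
from .pipeline import quantify_image
from .stats import (
    evaluate,
    run_models,
    select_features,
    split_cohort,
    train_svm,
    wilcoxon_rank_sum,
)
from .synthetic import (
    BIOMARKER_COLUMNS,
    BloodPath,
    TreeSpec,
    benign_phenotype,
    generate_phenotype_image,
    generate_tree,
    malignant_phenotype,
    rasterize_tree,
    sample_cohort,
    synthesize_slowtime,
)

__all__ = [
    "recover_tree_graph",
    "dm_recovery",
    "ba_recovery",
    "md_recovery",
    "diameter_recovery",
    "count_recovery",
    "fractal_oracles",
    "clutter_filter_metrics",
    "wilcoxon_exact_agreement",
    "wilcoxon_type1_error",
    "classifier_plumbing",
    "phenotype_direction",
    "cohort_model_auc",
    "determinism_check",
]


def recover_tree_graph(mask: VesselMask, min_spur_px: int = 5):
    return prune_graph(build_graph(skeletonize(mask), mask.pixel_size), min_spur_px)


# ----------------------------------------------------------- tree recovery

def dm_recovery(n_trees: int = 25, seed: int = 0) -> dict:
    """Tortuosity of sinusoidal tubes vs the closed-form arc-length integral."""
    a, lam, chord = 250.0, 2500.0, 10000.0
    k = 2 * math.pi / lam
    arc, _ = quad(lambda s: math.sqrt(1 + (a * k) ** 2 * math.cos(k * s) ** 2),
                  0, chord)
    dm_true = arc / chord
    rel = []
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        spec = TreeSpec(root_position=(60, 256), root_diameter=200, depth=0,
                        tortuosity_amplitude=a, tortuosity_wavelength=lam,
                        tortuosity_phase=0.0, segment_length=chord, pixel_size=50,
                        initial_direction=float(rng.uniform(-30, 30)), seed=i)
        mask = rasterize_tree(generate_tree(spec), (512, 512))
        g = recover_tree_graph(mask)
        _, tau_mean, _ = tortuosity(g, mask=mask)
        rel.append(abs(tau_mean - dm_true) / dm_true)
    return {"max_rel_err": float(max(rel)), "mean_rel_err": float(np.mean(rel)),
            "dm_true": dm_true, "n": n_trees}


def ba_recovery(angle_deg: float, n_trees: int = 25, seed: int = 0,
                probe_px: float = 30.0) -> dict:
    """Bifurcation-angle recovery on single-bifurcation trees."""
    errs = []
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        spec = TreeSpec(root_position=(40, 256), root_diameter=220, depth=1,
                        branch_angle=angle_deg, segment_length=4500, pixel_size=50,
                        initial_direction=float(rng.uniform(-20, 20)), seed=i)
        mask = rasterize_tree(generate_tree(spec), (512, 512))
        g = recover_tree_graph(mask)
        _, ba_mean, _ = bifurcation_angles(g, segment_metrics(g, mask), k_px=probe_px)
        errs.append(ba_mean - angle_deg)
    return {"mean_abs_err_deg": float(abs(np.mean(errs))),
            "max_abs_err_deg": float(np.max(np.abs(errs))), "n": n_trees}


def md_recovery(target: float, n_trees: int = 25, seed: int = 0) -> dict:
    """Murray-deviation recovery on depth-2 trees at 25 µm/pixel."""
    vals = []
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        spec = TreeSpec(root_position=(40, 384), root_diameter=500, depth=2,
                        branch_angle=100, murray_deviation_target=target,
                        segment_length=4000, pixel_size=25,
                        initial_direction=float(rng.uniform(-20, 20)), seed=i)
        mask = rasterize_tree(generate_tree(spec), (768, 768))
        g = recover_tree_graph(mask)
        _, md_mean, _ = murray_deviation(g, segment_metrics(g, mask))
        vals.append(md_mean)
    return {"mean_abs_err": float(abs(np.mean(vals) - target)),
            "mean_md": float(np.mean(vals)), "n": n_trees}


def diameter_recovery(radii_px=(2, 3, 4, 6), seed: int = 0) -> dict:
    """Tube diameter recovery (µm) across radii and orientations."""
    px = 50.0
    rng = np.random.default_rng(seed)
    errs_px = []
    for r in radii_px:
        for _ in range(4):
            spec = TreeSpec(root_position=(60, 100), root_diameter=2 * r * px,
                            depth=0, segment_length=10000, pixel_size=px,
                            initial_direction=float(rng.uniform(0, 45)), seed=0)
            mask = rasterize_tree(generate_tree(spec), (512, 512))
            g = recover_tree_graph(mask)
            m = segment_metrics(g, mask)[0]
            errs_px.append(abs(m.mean_diameter_um - 2 * r * px) / px)
    return {"max_err_px": float(max(errs_px)), "n": len(errs_px)}


def count_recovery(n_trees: int = 25, seed: int = 0) -> dict:
    """NB and NV equality with ground truth on noise-free rasterizations."""
    exact = 0
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        spec = TreeSpec(root_position=(30, 256), root_diameter=400,
                        depth=int(rng.integers(2, 4)),
                        branch_angle=float(rng.uniform(70, 120)),
                        segment_length=4000, length_taper=0.8, pixel_size=50,
                        initial_direction=float(rng.uniform(-15, 15)), seed=i)
        tree = generate_tree(spec)
        g = recover_tree_graph(rasterize_tree(tree, (512, 512)))
        exact += int((g.nb, g.nv) == (tree.nb, tree.nv))
    return {"exact_fraction": exact / n_trees, "n": n_trees}


# --------------------------------------------------------------- fractal dim

def fractal_oracles() -> dict:
    line = np.zeros((256, 256), bool)
    line[128, 10:250] = True
    fd_line = fractal_dimension(VesselMask(line, RoiMask.full((256, 256), 1.0), 1.0))

    sq = np.zeros((256, 256), bool)
    sq[20:236, 20:236] = True
    fd_square = fractal_dimension(VesselMask(sq, RoiMask(sq, 1.0), 1.0))

    n = 128  # depth-7 Sierpinski raster via the bitwise-AND construction
    x, y = np.meshgrid(np.arange(n), np.arange(n))
    sp = (x & y) == 0
    fd_sier = fractal_dimension(VesselMask(sp, RoiMask.full((n, n), 1.0), 1.0))
    return {"line": fd_line, "square": fd_square, "sierpinski": fd_sier,
            "sierpinski_true": math.log(3) / math.log(2)}


# ------------------------------------------------------------ clutter filter

def clutter_filter_metrics(seed: int = 0) -> dict:
    tissue_only = synthesize_slowtime((24, 24), 30, tissue_rank=3,
                                      noise_sigma=0.0, seed=seed)
    resid = svd_clutter_filter(tissue_only, 3)
    tissue_residual = float((resid.data ** 2).sum() / (tissue_only.data ** 2).sum())

    mix = synthesize_slowtime(
        (32, 32), 48, tissue_rank=2,
        blood_paths=[BloodPath((8, 4), (0.1, 0.5), amplitude=1.0, sigma=1.5)],
        noise_sigma=0.0, seed=seed + 1, orthogonal_blood=True,
    )
    filt = ClutterFilter.fit(mix, 2)
    once = filt.apply(mix)
    twice = filt.apply(once)
    e_blood = (mix.components["blood"] ** 2).sum()
    blood_err = float(abs((once.data ** 2).sum() - e_blood) / e_blood)
    idem = float(np.abs(twice.data - once.data).max()
                 / max(np.abs(once.data).max(), 1e-300))
    from .core import SlowTimeStack
    scaled = svd_clutter_filter(SlowTimeStack(data=2.5 * mix.data), 2)
    lin = float(np.abs(scaled.data - 2.5 * once.data).max()
                / max(np.abs(once.data).max(), 1e-300))
    return {"tissue_residual": tissue_residual, "blood_rel_err": blood_err,
            "idempotence": idem, "linearity": lin}


# ------------------------------------------------------------------ wilcoxon

def _brute_force_p(x, y) -> float:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_exact_agreement(max_total: int = 10, seed: int = 0) -> dict:
    """Auto-mode p-values vs full enumeration for every (n_x, n_y) shape."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_cfg = 0
    for nx in range(1, max_total):
        for ny in range(1, max_total - nx + 1):
            for ties in (False, True):
                x = rng.normal(size=nx)
                y = rng.normal(0.5, size=ny)
                if ties:
                    x, y = np.round(x), np.round(y)
                p = wilcoxon_rank_sum(x, y, "auto")
                worst = max(worst, abs(p - _brute_force_p(x, y)))
                n_cfg += 1
    return {"max_abs_diff": worst, "n_configurations": n_cfg}


def wilcoxon_type1_error(n_perm: int = 1000, seed: int = 0,
                         n_benign: int = 57, n_malignant: int = 35,
                         alpha: float = 0.05) -> dict:
    """Per-feature rejection rate of the screen under the permutation null,
    pooled over the 12 independent noise features."""
    rng = np.random.default_rng(seed)
    n = n_benign + n_malignant
    rejections = 0
    for _ in range(n_perm):
        x = rng.normal(size=(n, len(BIOMARKER_COLUMNS)))
        labels = np.zeros(n, bool)
        labels[rng.choice(n, n_malignant, replace=False)] = True
        for j in range(x.shape[1]):
            p = wilcoxon_rank_sum(x[~labels, j], x[labels, j], "normal_approx")
            rejections += p < alpha
    rate = rejections / (n_perm * len(BIOMARKER_COLUMNS))
    mc_se = math.sqrt(alpha * (1 - alpha) / n_perm)
    return {"rejection_rate": rate, "alpha": alpha, "mc_se_at_n_perm": mc_se,
            "n_perm": n_perm}


# ---------------------------------------------------------------- classifier

def classifier_plumbing(seed: int = 0) -> dict:
    import pandas as pd

    rng = np.random.default_rng(seed)

    def cohort(n, sep):
        half = n // 2
        return pd.DataFrame({
            "id": [f"n{i}" for i in range(n)],
            "label": ["benign"] * half + ["malignant"] * (n - half),
            "f1": np.concatenate([rng.normal(-sep, 1, half),
                                  rng.normal(sep, 1, n - half)]),
            "f2": rng.normal(0, 1, n),
        })

    sep_train, sep_test = split_cohort(cohort(120, 4.0), seed=seed)
    model = train_svm(sep_train, ["f1", "f2"], seed=seed)
    sep_report = evaluate(model, sep_test)

    # null behavior: scores drawn independently of the labels
    from .stats import delong_ci
    y_null = rng.random(200) < 0.5
    s_null = rng.normal(size=200)
    null_auc, _ = delong_ci(y_null, s_null)

    # cutoff vs exhaustive scan over every scored threshold
    y = (sep_test.label == "malignant").to_numpy()
    s = model.scores(sep_test)
    best = min(
        math.hypot(((s >= t) & ~y).sum() / (~y).sum(),
                   1 - ((s >= t) & y).sum() / y.sum())
        for t in np.concatenate([[np.inf], np.unique(s)])
    )
    fpr = ((s >= sep_report.cutoff) & ~y).sum() / (~y).sum()
    tpr = ((s >= sep_report.cutoff) & y).sum() / y.sum()
    cutoff_gap = abs(math.hypot(fpr, 1 - tpr) - best)

    scaler = model.pipeline.named_steps["scale"]
    xt = sep_train[model.features].to_numpy(float)
    leakage_gap = float(
        np.abs(scaler.mean_ - xt.mean(axis=0)).max()
        + np.abs(scaler.scale_ - xt.std(axis=0)).max()
    )
    return {"separable_auc": sep_report.auc, "null_auc": float(null_auc),
            "cutoff_oracle_gap": float(cutoff_gap), "leakage_gap": leakage_gap}


# --------------------------------------------------------------- end to end

def phenotype_direction(n_pairs: int = 20, seed: int = 0,
                        config: PipelineConfig | None = None) -> dict:
    """Fraction of paired benign/malignant images with the expected ordering
    of each recovered biomarker (higher in malignant except BA_mean)."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    rows = {"benign": [], "malignant": []}
    for label, maker in (("benign", benign_phenotype),
                         ("malignant", malignant_phenotype)):
        for _ in range(n_pairs):
            mask, intensity, _ = generate_phenotype_image(
                maker(), seed=int(rng.integers(0, 2 ** 31 - 1)))
            img = PowerImage(values=intensity, pixel_size=mask.pixel_size)
            _, _, markers = quantify_image(img, mask.roi, cfg)
            rows[label].append(markers.to_row())
    out = {}
    for feature in ("NV", "NB", "VD", "mvFD", "MD_max", "BA_mean"):
        b = np.array([r[feature] for r in rows["benign"]])
        m = np.array([r[feature] for r in rows["malignant"]])
        wins = (m < b) if feature == "BA_mean" else (m > b)
        out[feature] = float(wins.mean())
    out["n_pairs"] = n_pairs
    return out


def cohort_model_auc(n_benign: int = 124, n_malignant: int = 76,
                     seed: int = 0) -> dict:
    """Full screening + SVM pipeline on a summary-statistics cohort."""
    cohort = sample_cohort(n_benign, n_malignant, seed=seed)
    report, _ = run_models(cohort, seed=seed)
    selected, _ = select_features(cohort)
    return {"test_auc": report.auc, "n_selected": len(selected),
            "n": n_benign + n_malignant}


def determinism_check(seed: int = 0) -> dict:
    """Bit-identical regeneration of every stochastic artifact under a seed."""
    t1 = generate_tree(TreeSpec(depth=3, tortuosity_amplitude=50,
                                tortuosity_phase=None, angle_jitter=5, seed=seed))
    t2 = generate_tree(TreeSpec(depth=3, tortuosity_amplitude=50,
                                tortuosity_phase=None, angle_jitter=5, seed=seed))
    tree_ok = all(np.array_equal(a.points, b.points)
                  for a, b in zip(t1.segments, t2.segments))

    s1 = synthesize_slowtime((16, 16), 20, tissue_rank=2, noise_sigma=0.3, seed=seed)
    s2 = synthesize_slowtime((16, 16), 20, tissue_rank=2, noise_sigma=0.3, seed=seed)
    stack_ok = np.array_equal(s1.data, s2.data)

    m1, i1, _ = generate_phenotype_image(malignant_phenotype(), seed=seed)
    m2, i2, _ = generate_phenotype_image(malignant_phenotype(), seed=seed)
    image_ok = np.array_equal(m1.data, m2.data) and np.array_equal(i1, i2)

    c1 = sample_cohort(20, 15, seed=seed, include_clinical=True)
    c2 = sample_cohort(20, 15, seed=seed, include_clinical=True)
    cohort_ok = c1.equals(c2)
    return {"tree": tree_ok, "stack": stack_ok, "image": image_ok,
            "cohort": cohort_ok,
            "all_identical": tree_ok and stack_ok and image_ok and cohort_ok}
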