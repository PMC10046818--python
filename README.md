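# hdmi-quant

Quantitative morphometrics for contrast-free high-definition microvessel
images (HDMI), aimed at distinguishing benign from malignant nodule
vasculature. Malignant angiogenesis produces denser, more tortuous, more
finely branched vessel networks that bifurcate at narrower angles and deviate
from Murray's law; this package turns a microvessel image (or the slow-time
ultrasound ensemble behind it) into twelve per-nodule biomarkers capturing
those properties, screens them statistically, and classifies nodules with a
Gaussian-kernel SVM.

Intended for researchers in quantitative ultrasound / vascular image analysis
who need a tested, fully synthetic-verifiable reference pipeline: every stage
is validated against generated vasculature with exact ground truth, since
clinical microvessel data are generally restricted.

## Pipeline

1. **Flow image formation** (optional): a slow-time stack `(rows, cols,
   frames)` is reshaped into its Casorati matrix and tissue clutter is
   removed by zeroing the leading singular components (`svd_clutter_filter`);
   averaging squared magnitude over frames gives the power image.
2. **Vessel enhancement**: multiscale Frangi vesselness with
   gamma-normalized Hessian eigenvalues, Otsu-seeded hysteresis
   binarization, morphological cleanup (`segment_vessels`).
3. **Skeleton graph**: topology-preserving thinning, branch-pixel
   clustering, chain tracing, spur pruning (`build_graph`, `prune_graph`).
4. **Morphometrics** (`biomarker_set`): the twelve biomarkers

   | symbol | meaning |
   |---|---|
   | NB, NV | number of branch points / vessel segments |
   | VD | vessel area / ROI area |
   | D_max (µm) | largest per-segment mean diameter, 2 × centerline-to-border distance |
   | VDR, SVP | center-to-periphery vessel density ratio, and the intratumoral/peritumoral label it implies |
   | τ_mean, τ_max | distance-metric tortuosity: segment arc length / endpoint chord |
   | mvFD | box-counting fractal dimension of the vessel mask |
   | BA_mean, BA_max | bifurcation angle between the two dominant children (degrees) |
   | MD_mean, MD_max | Murray deviation \|d_p³ − Σd_c³\| / max(d_p³, Σd_c³) at each bifurcation |

5. **Statistics** (`hdmi.stats`): two-sided Wilcoxon rank-sum screening
   (exact enumeration for small samples, tie-corrected normal approximation
   otherwise), stratified 70/30 split, Gaussian-kernel SVM with 5-fold
   cross-validated hyperparameters, ROC with trapezoidal AUC, DeLong 95% CI,
   and the operating point nearest the (FPR 0, TPR 1) corner. Clinical
   covariates (age, nodule size, TI-RADS) can be appended to the screened
   biomarkers for a combined model.

A synthetic vasculature module (`hdmi.synthetic`) generates branching trees
with controllable diameter taper, bifurcation angle, sinusoidal tortuosity
and Murray deviation — with exact ground truth for every biomarker — plus
benign/malignant phenotype images, slow-time ensembles with returned
tissue/blood/noise addends, and biomarker cohorts drawn from published
benign/malignant summary statistics.

## Worked example

```python
from hdmi import PipelineConfig, PowerImage, quantify_image
from hdmi.synthetic import (benign_phenotype, malignant_phenotype,
                            generate_phenotype_image, sample_cohort)
from hdmi.stats import run_models, select_features

config = PipelineConfig()
for maker in (benign_phenotype, malignant_phenotype):
    spec = maker()
    mask, intensity, truth = generate_phenotype_image(spec, seed=1)
    img = PowerImage(values=intensity, pixel_size=spec.pixel_size)
    _, graph, markers = quantify_image(img, mask.roi, config)
    print(f"{spec.label:9s}  NV={markers.NV:3d} NB={markers.NB:3d} "
          f"VD={markers.VD:.3f} mvFD={markers.mvFD:.2f} "
          f"BA_mean={markers.BA_mean:.1f} MD_max={markers.MD_max:.2f}")

cohort = sample_cohort(n_benign=124, n_malignant=76, seed=1)
report, _ = run_models(cohort, seed=1)
print("test AUC =", round(report.auc, 4))
```

prints

```
benign     NV= 29 NB= 15 VD=0.097 mvFD=1.42 BA_mean=119.4 MD_max=0.39
malignant  NV=116 NB= 62 VD=0.171 mvFD=1.60 BA_mean=94.7 MD_max=0.95
test AUC = 1.0
```

The malignant phenotype shows the expected signature — four times the
segment and branch-point count, higher vessel density and fractal dimension,
a ~25° narrower mean bifurcation angle, and a Murray deviation approaching 1
— and a cohort drawn from the published benign/malignant summary statistics
separates essentially perfectly at this sample size.

The same stages are available from the shell:

```sh
hdmi simulate phenotype --label malignant --seed 1 --out demo/
hdmi enhance --image demo/malignant_intensity.tif --roi demo/malignant_roi.png --out demo/mask.png
hdmi graph --mask demo/mask.png --min-spur 5 --out demo/graph.json
hdmi pipeline --n-benign 10 --n-malignant 10 --seed 1 --out demo/run/
```

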