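# ctperf — single-energy CT pulmonary perfusion imaging

`ctperf` computes maps of regional pulmonary perfusion from ordinary
(single-energy) contrast-enhanced CT. The idea: acquire an end-inspiratory
breath-hold CT before and after intravenous iodinated contrast, deformably
register the two scans, and subtract them voxel by voxel — the Hounsfield-unit
(HU) enhancement is a surrogate for regional blood flow. The catch is that two
breath-holds never land at exactly the same lung inflation, and parenchymal HU
falls as the lung inflates, so a raw subtraction confounds contrast with
inflation. `ctperf` removes that confound with a **voxel-wise linear model of
HU against total lung volume**, fitted from three precontrast breath-holds
(end-expiration, midinspiration, end-inspiration) brought into correspondence
by deformable registration:

    HU_v(V) = a_v + b_v · V        (b_v < 0: deeper breath, darker lung)

The precontrast end-inspiratory scan is replaced by the model's prediction at
the postcontrast lung volume (interpolation or logged extrapolation), and the
perfusion map is

    E_v = CT_post,deformed(v) − HU_v(V_post).

The package is aimed at researchers in functional lung imaging and
radiotherapy planning who want a transparent, fully testable implementation of
this pipeline:

* **`ctperf.core`** — volumes/transforms, NIfTI + MetaImage I/O, warping,
  Gaussian pyramids, field composition; cubic B-spline free-form deformations.
* **`ctperf.registration`** — multi-resolution B-spline registration with
  normalized cross correlation or mutual information plus a bending-energy
  penalty; Jacobian-determinant folding diagnostics.
* **`ctperf.segmentation`** — threshold lung masks (HU < −250), lung volumes,
  inter-scan volume differences.
* **`ctperf.hu_correction`** — the voxel-wise HU-vs-volume model, HU
  correction, and subtraction perfusion.
* **`ctperf.validation`** — landmark target registration error (TRE).
* **`ctperf.analysis`** — coefficient of variation (heterogeneity),
  ventral-to-dorsal gradient via five coronal slabs with OLS regression,
  two-sample group tests.
* **`ctperf.phantom`** — a synthetic four-scan thorax with exact ground truth
  (deformations, HU model, enhancement, landmarks) for validation.
* **`ctperf.datasets`** — reference canine cohort measurements (lung volumes
  and perfusion CoVs for seven normal and seven diseased-lung subjects).

## Worked example

```python
from ctperf import PhantomSpec, generate_series, run_study, compute_tre

# a synthetic subject: 64³ voxels at 3.5 mm, lung volumes 1356/1865/2067 cm³
scans, truth = generate_series(PhantomSpec(seed=0))
result = run_study(scans)   # segment → register ×3 → align → fit → correct
                            # → warp → subtract → analyze
print({k: round(v, 2) for k, v in result["analysis"].items()
       if isinstance(v, float)})

report = compute_tre(truth.landmarks, result["transforms"]["post_to_ins"],
                     scans["end_ins_pre"].spacing)
print(f"perfusion DIR TRE: {report.mean:.2f} ± {report.sd:.2f} mm")
```

prints (seed 0):

```
{'mean_enhancement_hu': 37.66, 'sd_enhancement_hu': 25.93, 'cov': 0.69,
 'negative_fraction': 0.03, 'gradient_slope_hu': -9.01,
 'gradient_intercept_hu': 42.58, 'gradient_r_squared': 0.77,
 'gradient_p_value': 0.05}
perfusion DIR TRE: 0.82 ± 0.46 mm
```

Read: the mean enhancement over the analysis mask is ≈38 HU (the generator's
parenchymal ground truth is 35 HU; the excess is perivascular partial-volume
enhancement, which also flattens the slab gradient on this mask — on the
pure-parenchyma truth mask the gradient comes back with R² > 0.99, which is
what the validation studies score), perfusion decreases from the dependent
ventral side toward the dorsal side (negative slope), only ~3% of lung voxels
come out with negative enhancement, and the postcontrast-to-precontrast
registration lands at a quarter-voxel mean error on ground-truth landmarks.

The same pipeline runs from the shell on real or synthetic volumes:

```bash
ctperf phantom --seed 0 --out phantom/           # write a synthetic series
ctperf run --phantom-seed 0 --out runs/demo      # full eight-stage pipeline
ctperf analyze --perfusion runs/demo/perfusion.nii.gz \
               --mask runs/demo/mask_end_ins_pre.nii.gz
```

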