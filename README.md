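# bodycomp

Scriptable, semi-automatic quantification of body composition on a single
abdominal MR slice at the level of the third lumbar vertebra (L3).

## The problem

Sarcopenic obesity — obesity combined with low skeletal muscle mass — is
usually assessed on imaging by measuring cross-sectional areas at L3: the
muscle area (MA), subcutaneous fat area (SA) and visceral fat area (VA) at
this single level are established proxies for whole-body muscle and fat
volume. Fully manual tracing is slow and fully automatic segmentation is
hard to trust, so clinical workflows often use a semi-automatic compromise:
an operator draws a *rough* region of interest (ROI) around each compartment
and the software refines it by intensity thresholding. `bodycomp`
implements that workflow as a library and command-line tool:

1. **execution** — read a single-frame DICOM slice (pixel spacing from
   `PixelSpacing`, modality rescale applied; MONOCHROME1 images are
   inverted on load so bright always means high signal);
2. **setting** — linear window/level mapping to the 8-bit display range and
   per-compartment inclusive threshold bands
   (`display = round(255 · clip((v − (L − W/2))/W, 0, 1))`);
3. **confirmation** — each rough polygon is rasterized (pixel-center
   even-odd rule) and intersected with its threshold band; the three final
   masks are merged into one disjoint label map (priority M > S > V, with a
   warning on overlap);
4. **extraction** — color-overlaid label images (PNG/TIFF/BMP/JPG),
   confirmed-ROI polygon files (JSON) and a quantification CSV with
   areas `MA`, `SA`, `VA` (mm², pixel count × spacing²) and the ratio
   indexes `MA/SA`, `MA/VA`, `MA/(SA+VA)`.

On T1-weighted images subcutaneous and visceral fat share one intensity
band; their separation is carried entirely by the rough ROIs — the reason
the workflow is *semi*-automatic.

Cohort evaluation mirrors the standard study design: groups defined by
BMI ≥ 25.0 kg/m² with ALT ≥ 35 IU/L (sarcopenic obesity) versus
BMI 18.0–23.0 kg/m² with ALT < 35 IU/L (healthy); independent two-sample
t-tests per measure; and two-observer reliability via the intraclass
correlation coefficient ICC(2,1) (two-way random effects, absolute
agreement, single rater) with its F-based 95% CI and the conventional
banding (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent).

Because no patient data ship with the package, a **phantom** module
generates synthetic 512×512 slices (0.74×0.74 mm pixels) with analytically
known elliptical compartment geometry, plus simulated cohorts and rater
pairs, so the entire pipeline and all statistics are testable end-to-end.

## Worked example

```python
from bodycomp import PhantomSpec, make_phantom_slice, quantify_slice

res = make_phantom_slice(PhantomSpec(noise_sd=5.0, seed=1))
rec, labels = quantify_slice(res.image, res.rough_rois)
print(f"MA = {rec.areas.MA:.1f} mm2 (analytic {res.analytic_areas.MA:.1f})")
print(f"SA = {rec.areas.SA:.1f} mm2 (analytic {res.analytic_areas.SA:.1f})")
print(f"VA = {rec.areas.VA:.1f} mm2 (analytic {res.analytic_areas.VA:.1f})")
r = rec.ratios
print(f"MA/SA = {r.MA_SA:.3f}  MA/VA = {r.MA_VA:.3f}  MA/(SA+VA) = {r.MA_SAVA:.3f}")
```

prints

```
MA = 10288.3 mm2 (analytic 10294.5)
SA = 15510.2 mm2 (analytic 15510.6)
VA = 2884.8 mm2 (analytic 2873.0)
MA/SA = 0.663  MA/VA = 3.566  MA/(SA+VA) = 0.559
```

— the pipeline recovers the phantom's closed-form compartment areas to
within 0.5% at the default noise level (the residual is rasterization
error at the elliptical boundaries). The same run from the shell:

```sh
bodycomp phantom --seed 3 --outdir bundle
bodycomp quantify --dicom bundle/phantom.dcm \
    --roi bundle/rough_M.json --roi bundle/rough_S.json --roi bundle/rough_V.json \
    --outdir out
# -> MA=10288.3 SA=15510.2 VA=2884.8 mm2
```

which writes `out/phantom-3_labels.png`, per-compartment confirmed-ROI
JSON files and `out/phantom-3_quant.csv`. `bodycomp cohort` and
`bodycomp icc` consume such CSVs and emit the group-comparison and
reliability tables.

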