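# oxyvoxel

Agent-based tumor tissue voxels with reaction–diffusion oxygen:
steady-state oxygenation, voxel-to-morphology matching, and inference of
the vascular-supply or cellular-uptake dynamics behind short-time pO₂
fluctuations.

## The problem

Oximetric radiology (e.g. EPR imaging with a triaryl-methyl tracer)
reports one number per ~1 mm³ voxel: the average tissue pO₂, sampled every
few minutes. Those voxel averages fluctuate fast and hard — drops of tens
of mmHg within 3 minutes — but the image cannot say *why*: is the
vasculature transiently cutting its oxygen supply (cycling,
perfusion-limited hypoxia), or are tumor cells transiently consuming
more? Answering that requires a cell-scale model of the tissue inside the
voxel.

`oxyvoxel` builds that bridge. A 1 mm² voxel cross-section is populated
with immobile vessels (radius 20 µm) and tumor/stromal cells (7.5 /
3.75 µm) at prescribed area fractions, placed randomly and relaxed to
remove overlaps via repulsive Hookean contact forces under overdamped
dynamics. Oxygen obeys

    ∂γ/∂t = Σᵢ δ_V(t)·γ_max·χ_{R_V}(x, Vᵢ)  +  D_γ Δγ
            − Σⱼ δ_T(t)·T_max·γ/(κ_m+γ)·χ_{R_T}(x, Tⱼ)
            − Σₖ S_max·γ/(κ_m+γ)·χ_{R_S}(x, Sₖ)

solved by forward Euler on a 201×201 grid (Δx = 5 µm, Δt = 0.05 s,
no-flux boundaries; vessel-covered nodes are bounded by their
intravascular level δ_V·γ_max — see `docs/methods.md`). A field is
"stabilized" when the normalized step-to-step L₂ error ε̄ⁿ falls to 10⁻¹⁰.

On top of the simulator:

- **tissue library** — sweep all 1530 compositions (vascularity 0.5–5%,
  tumor 10–95%, stromal 5–95%, total ≤ 100%), stabilize each, classify
  into five 12-mmHg oxygenation classes, and match voxel readings to
  morphologies;
- **schedule fitting** — given a measured 9-point pO₂ series at
  t = 4, 7, …, 28 min, fit a piecewise-constant influx schedule δ_V(t) ∈
  [0,1] or uptake schedule δ_T(t) ∈ [0,50], one 3–4-minute segment at a
  time, by 1-D mesh-adaptive pattern search (poll ± mesh, double on
  success, halve on failure); goodness of fit is the normalized L₂ error
  ‖γ_E − γ_opt‖₂/‖γ_E‖₂;
- **robustness analysis** — apply a fitted schedule verbatim to every
  tissue whose stationary pO₂ lies within ±3.5 mmHg of the measured
  anchor and count those reproducing the series with GoF < 0.2;
- **synthetic fixtures** — the experimental series behind the four
  published regions of interest are unpublished (only their anchors
  36.312, 22.89, 13.99, 1.83 mmHg are printed), so a generator produces
  labelled synthetic stand-ins and forward-simulated ground truth for
  recovery testing.

## Worked example

```python
import numpy as np
import oxyvoxel as ov

params = ov.default_params()
comp = ov.TissueComposition(vascular=3.5, tumor=55, stromal=30)
layout = ov.resolve_overlaps(ov.sample_layout(comp, params, seed=7), params)
masks = ov.build_indicator_masks(layout, params)
field, report = ov.stabilize(layout, params, masks=masks)
print(f"stabilized at {report.average_po2:.2f} mmHg "
      f"in {report.iterations} steps (error {report.final_error:.2e})")

# a fluctuating voxel series anchored at the tissue's own level
roi = ov.make_roi_series(ov.ROIFixtureSpec(
    anchor_po2=report.average_po2, fluctuation_style="drop_recover",
    amplitude=20.0, seed=1))
model = ov.FluctuationModel(roi, layout, params)
res = model.fit("influx")
print(res.summary())
```

prints (numbers from this exact script):

```
stabilized at 31.28 mmHg in 18442 steps (error 1.00e-10)
Oxygen fluctuation schedule fit
===============================
mechanism:        influx (delta_V in [0,1])
ROI label:        synthetic-drop_recover
stabilized pO2:   31.28 mmHg
goodness of fit:  0.002568 (relative)
evaluations:      142

  segment   rate  target_mmHg  simulated_mmHg  abs_error_mmHg
  0-4 min      1        31.28           31.28       1.658e-05
  4-7 min      1        31.28           31.28       1.713e-05
 7-10 min 0.3623        11.28           11.28        0.003593
10-13 min 0.8633        26.28           26.28        0.005987
13-16 min      1        31.28            31.1          0.1772
16-19 min      1        31.28           31.27         0.01092
19-22 min 0.4282        13.28           13.28        0.002137
22-25 min 0.9243        28.28           28.28        0.000578
25-28 min      1        31.28           31.17          0.1119
```

The fitted rates say: to make this tissue's average pO₂ plunge from 31 to
11 mmHg and recover within consecutive 3-minute windows, the vascular
oxygen supply must drop to ~36% of maximum and restore — fast vascular
modulation reproduces the fluctuation almost exactly (GoF 2.6·10⁻³).
Fitting a deep large-amplitude series with the cellular-uptake mechanism
instead (`model.fit("uptake")`) pushes δ_T to its 50-fold bound on the
dip segments and still cannot reach the lowest values — the model's core
scientific behavior: vascular supply, not cell metabolism, explains large
fast pO₂ fluctuations.

The same pipeline is scriptable from a shell:

```bash
oxyvoxel generate-tissue --vascular 3.5 --tumor 55 --stromal 30 --seed 7 --out layout.csv
oxyvoxel stabilize --layout layout.csv --out field.h5 --report report.json
oxyvoxel make-fixture --anchor 36.312 --style drop_recover --amplitude 30 --out roi1.csv
oxyvoxel fit-schedule --layout layout.csv --series roi1.csv --mode influx --out fit.json
```

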