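# rawindex

Regional Aortic Weakness (RAW) scoring for abdominal aortic aneurysms
(AAA).

Rupture-risk management of AAA today rests on the maximum diameter, which
says nothing about *where* the wall is weak. The RAW index is an
image-derived, assumption-free regional score: the aneurysm wall is divided
into 24 tracked patches (6 axial stations along the lumen centerline × 4
circumferential quadrants LA/LP/RA/RP), and each patch receives a 0–10
weakness score built from three region-averaged descriptors —
intraluminal-thrombus (ILT) thickness, time-averaged wall shear stress
(TAWSS), and the maximum principal Green–Lagrange strain of the tracked
wall. This package implements the complete scoring pipeline, the ex vivo
tensile-curve analysis used to validate it (ultimate tensile strength and
hysteresis energy loss), the accompanying statistics, and a synthetic AAA
generator with analytic ground truth so every stage is testable without
patient imaging data.

Intended users: vascular-biomechanics researchers working with segmented
lumen/outer-wall surface meshes, tracked wall motion, and CFD-derived wall
shear stress.

## The score

Per patch, each descriptor is ranked into quartile categories 1–4 within a
reference distribution (patient-specific, population, or the half-integer
*combined* category — the mean of both ranks). The TAWSS category is
inverted, low shear being the risk marker, and

```
RAW = ([ILT_cat + STRAIN_cat + (5 − TAWSS_cat)] − 3) / 9 × 10
```

spans 0–10; RAW > 6 marks a high-weakness region. The descriptors are

* **ILT thickness** — distance from each outer-wall node to its lumen
  neighborhood inside a search radius (default 5 mm),
* **TAWSS** — `(1/T) ∫ |τ(t)| dt` per face over one cardiac cycle,
* **max principal strain** — largest eigenvalue of
  `E = (FᵀF − I)/2`, with the in-plane deformation gradient `F` computed
  per tracked triangle and maximised over the cycle.

Validation utilities mirror common biomedical practice: Shapiro–Wilk-gated
t / Mann–Whitney U comparisons, Pearson/Spearman correlation, and ROC AUC
by the rank identity with a seeded bootstrap CI. Ex vivo strength is read
from stress–strain curves (UTS at the first discontinuity or maximum;
tissue with UTS < 0.3 MPa counts as weak) and viscoelasticity as the
hysteresis-to-loading area ratio.

## Worked example

```sh
rawindex run-all --synthetic --seed 1 --out demo_out
# 24 patches, mean RAW 4.86, 8 high-weakness; outputs in demo_out
```

`demo_out/patch_table.csv` then holds one row per patch (excerpt):

```
patch  ilt_mm  strain  tawss_pa  ilt_category  strain_category  tawss_category  raw_rounded risk_class
  LA1   0.774    0.03     0.647             1                2               4         1.11        low
  LA2   3.491    0.03     0.188             3                1               2         4.44        low
  LA3   4.715    0.03     0.077             4                3               1         8.89       high
  RA3   4.684    0.03     0.075             4                4               1        10.00       high
```

Reading the rows: patch LA3, in the dilated sac, combines thick thrombus
(4.7 mm, category 4), low shear (0.08 Pa, inverted category 1 → 4 risk
points) and mid-range strain into RAW = 8.89 — a high-weakness region —
while the neck patch LA1 scores 1.11. `demo_out/wall_raw.vtk` carries the
RAW map (plus the raw descriptor fields) on the wall surface for ParaView.
The same stages are available individually (`synth`, `patch`, `metrics`,
`raw`, `exvivo`, `validate`) and as a library; the quartile/RAW core is
exposed as scikit-learn-style estimators (`QuartileCategorizer`,
`RawIndexModel`) that compose with sklearn pipelines.

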