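# sdctperf

Semiautomated pulmonary-perfusion analysis for spectral (dual-layer
detector) CT, aimed at the imaging work-up of pulmonary hypertension (PH).
Given a per-case iodine-density image (IDI), a virtual-non-contrast image
(VNC), a lung mask and MPA/LA reference-ROI masks, the package

1. measures the mean iodine density in the main pulmonary artery (ID_MPA)
   and left atrium (ID_LA);
2. partitions the lung into malperfused (**PerfDef**: ID ≤ 5% of ID_MPA),
   normally perfused (**PerfNorm**: up to 50% of ID_LA) and vessel
   (**Ves**) compartments;
3. computes per-compartment histogram features — standardized mean ID,
   Fisher skewness g1 = m3/m2^{3/2}, excess kurtosis m4/m2² − 3 — and the
   VNC emphysema extent (LAA-950: % of lung < −950 HU);
4. forms the **δ-index**

       δ = (ID skewness_PerfDef + 1.36) / (emphysema % + 1.0)

   which separates homogeneous perfusion defects caused by vascular
   obstruction (CTEPH: high δ) from those explained by emphysematous lung
   disease (low δ);
5. applies the staged cutoff classification (PerfNorm volume < 71.6% →
   PH; PerfDef skewness ≥ −0.335 → groups 3/4; δ ≥ 0.502 → CTEPH) and
   provides ROC/AUC with Youden-index cutoff estimation for re-deriving
   operating points on new cohorts.

Because no clinical volumes are publicly available for this method, the
package ships a synthetic phantom-cohort generator (`synthetic_cohort`)
that reproduces the per-subgroup intensity phenotypes — wedge-shaped
homogeneous defects (CTEPH-like), diffuse heterogeneous defects
(PAH-like), emphysema-coupled defects (lung-disease-like) — with full
voxel-level ground truth, so the entire pipeline is testable end to end.

Audience: radiology/imaging researchers working on dual-energy CT
perfusion biomarkers, and anyone needing a reference implementation of
ID-threshold lung compartment analysis.

## Worked example

```python
import sdctperf as sp

case = sp.generate_phantom(sp.preset_profile("g4"), shape=(64, 64, 64), seed=1)
rec = sp.extract_case_features(case)
print(f"V_PerfNorm {rec.v_perfnorm_pct:.1f}%  skew_PerfDef {rec.skew_def:.3f}  "
      f"emphysema {rec.emphysema_pct:.2f}%  delta {rec.delta_index:.3f}")
print(sp.classify_case(rec).pred_subgroup)
```

prints

```
V_PerfNorm 57.2%  skew_PerfDef 0.220  emphysema 0.40%  delta 1.131
g4
```

Reading: 57.2% of the lung is normally perfused (< 71.6% → PH suspicion),
the malperfused compartment's iodine histogram is near-symmetric
(skewness ≥ −0.335 → a homogeneous defect, the group-3/4 pattern), there
is almost no emphysema to explain it, so δ = (0.220 + 1.36)/(0.40 + 1.0)
= 1.131 ≥ 0.502 and the case is called CTEPH (group 4) — matching the
phantom's ground truth.

The same workflow is available from the shell:

```bash
sdctperf simulate --counts g3=20,g4=20 --grid 64 --seed 7 --out cohort/
sdctperf features --cohort cohort/cohort.csv --out features.csv
sdctperf classify --features features.csv --skip-stage1 --out predictions.csv
sdctperf roc --features features.csv --positive g4 --out roc.json
```

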