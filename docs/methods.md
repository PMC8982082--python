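# Methods

## The measurement model

`sdctperf` analyses co-registered spectral-CT reconstructions of the chest:
an iodine-density image (IDI, mg iodine/mL per voxel, a surrogate of
pulmonary perfusion) and a virtual-non-contrast image (VNC, Hounsfield
units), together with a lung mask and two vascular reference-ROI masks over
the main pulmonary artery (MPA) and the left atrium (LA).

All thresholds are anchored to the patient's own contrast transit: with
ID_MPA and ID_LA the mean iodine densities over the two reference ROIs, a
lung voxel with iodine density *x* is labelled

* **PerfDef** (malperfused) if *x* ≤ 0.05·ID_MPA,
* **PerfNorm** (normally perfused) if 0.05·ID_MPA < *x* ≤ 0.50·ID_LA,
* **Ves** (vessel compartment) if *x* > 0.50·ID_LA.

The thresholds are recomputed per case, never pooled. The three labels form
an exact partition of the lung mask, so the corresponding volume
percentages sum to 100. Boundary conventions (PerfDef closed at the lower
threshold, PerfNorm half-open, Ves open above) make tie handling
deterministic. Sub-zero iodine densities — spectral decomposition noise —
are physically sub-zero perfusion estimates; they are kept, assigned to
PerfDef, and counted in `n_negative_clamped`. The upper bound of PerfNorm
uses 50% of the **LA** mean; a `upper_reference="mpa"` switch exposes the
alternative reading for sensitivity analysis, but only the LA bound makes
the three compartments a complete partition.

Per compartment the package computes first-order histogram features on the
raw voxel values (no binning): the mean ID standardized by ID_MPA, Fisher
moment skewness g1 = m3/m2^{3/2}, and excess kurtosis m4/m2² − 3, using
population (n-denominator) central moments. Excess kurtosis is the
convention under which near-uniform defect histograms print negative
values; no small-sample bias correction is applied because compartments
contain 10^4–10^7 voxels. Compartments with fewer than 3 voxels or zero
variance yield NaN features with an explicit reason; downstream
classification refuses missing inputs rather than guessing.

Emphysema is the standard LAA-950 metric on the VNC image: the percentage
of lung voxels strictly below −950 HU.

## The delta-index and staged classification

The delta-index relates defect homogeneity to emphysema extent:

    δ = (skew_PerfDef + 1.36) / (emphysema_pct + 1.0)

with emphysema on the percent (0–100) scale. The +1.36 translation moves
skewness past the smallest value observed in the defining clinical cohort
(−1.35) into the strictly positive range; the +1.0 guards the divisor. Both
constants are frozen as the published definition; `delta_index(...,
translation=)` allows cohort-specific re-derivation. The percent scale of
the emphysema term follows from internal consistency: with the group-3
median inputs (skewness 0.03, emphysema 8.4%), the percent reading gives
δ ≈ 0.148, the same order as the reported group-3 median 0.17, while a
fraction reading would give ≈ 1.28.

Staged classification mirrors the clinical stepwise read:

1. **PH suspicion** — PerfNorm volume < 71.6% of lung volume (a weak rule,
   clinically AUC ≈ 0.67; `skip_stage1=True` bypasses it for known-PH
   populations);
2. **groups 3/4** — PerfDef ID skewness ≥ −0.335 (homogeneous defects);
3. **CTEPH (group 4)** — δ ≥ 0.502, else group 3.

Groups 1 and 2 are pooled as "other": their heterogeneous perfusion
patterns are not separable by these features. Tie rules at the cutoffs
(≥ for skewness and δ, strict < for the volume rule) are this package's
choice; the cutoff directions follow from the reported group medians.

ROC analysis uses the Mann-Whitney pair-counting AUC (ties count one half),
a percentile bootstrap over cases (default 2000 seeded resamples) for the
95% CI, and the Youden index J = sensitivity + specificity − 1 maximized
over observed score thresholds with the rule "positive iff score ≥ t",
ties broken toward the smallest threshold.

## The synthetic phantom cohort

No clinical volumes accompany the method, so the generator produces phantom
cases that carry the intensity structure the analysis depends on, with full
voxel-level ground truth. Anatomy is schematic — two ellipsoidal lungs, a
cylindrical MPA and a spherical LA in the mediastinum, with measurement
ROIs covering the central 50% of each structure's cross-section. What is
modelled carefully is the per-subgroup distribution of iodine density and
VNC attenuation:

* **Vessel anchors**: MPA 14.1 mg/mL, LA 8.9 mg/mL (clinical medians)
  plus additive noise, giving thresholds near 0.705 and 4.45 mg/mL.
* **Normal parenchyma**: lognormal with mean 0.091·ID_MPA and CV 0.20.
  The lognormal (rather than Gaussian) choice reflects the right-skewed
  parenchymal ID histograms seen clinically and keeps parenchyma from
  leaking mass below the malperfusion threshold, which would otherwise
  contaminate the defect histogram with a spurious right shoulder.
* **Defect geometry and intensity**:
  - group 4 (CTEPH-like): one wedge per lung — a cone with apex at the
    hilum widening toward the pleura — with homogeneous Gaussian intensity
    (mean 0.30 mg/mL, CV 0.25), giving within-defect skewness near 0;
  - groups 1/2 and controls (heterogeneous): many small random blobs with
    left-skewed scaled-Beta intensity (mean 0.47 mg/mL, CV 0.24, support
    below the malperfusion threshold), giving skewness ≈ −0.55;
  - group 3: large homogeneous blobs, with the emphysema voxel set carved
    from the first-placed blobs so that emphysema ⊆ defect.
* **Defect / emphysema extents** per subgroup follow the reported group
  medians (defect: control 25.6%, g1 33.7%, g2-Ipc 21.4%, g2-Cpc 37.2%,
  g3 53.7%, g4 42.5%; emphysema: g3 8.4%, g4 0.4%, others 0.1–0.3%).
  Realized voxel fractions are trimmed to the target count exactly where
  geometry permits and are always within ±0.05.
* **VNC**: parenchyma N(−860, 10) HU, emphysema N(−975, 10) HU, soft
  tissue N(40, 10) HU. With these parameters essentially all emphysema
  voxels and essentially no normal voxels fall below −950 HU.
* **Noise**: additive N(0, 0.02 mg/mL) on the IDI everywhere, unclipped —
  negative iodine densities are retained and handled by segmentation.

Determinism: a case is a pure function of (profile, grid shape, spacing,
seed). Cohorts derive per-case seeds as
`SeedSequence([master_seed, case_index])` reduced mod 2³¹; this mapping is
stable across versions.

### What the phantoms do not emulate

Airway and vessel trees, lobar anatomy, beam-hardening and motion
pseudodefects, systemic-collateral reperfusion of occluded territories,
scanner-specific spectral noise texture, and inter-patient anatomical
variability. Passing end-to-end tests therefore demonstrates that the
implementation applies the published rules correctly and that the rules
separate the encoded phenotypes; it does not re-establish the clinical
accuracy figures, which were measured on a 182-patient cohort that is not
public.

## Problem sizes and numerical choices

Default test and acceptance cohorts use 64³ grids with 1 mm isotropic
voxels (≈ 42,000 lung voxels per case) and 20 cases per subgroup arm —
large enough that moment estimates are stable to three decimals, small
enough for quick iteration. Grid-consistency checks compare affines with
absolute tolerance 1e-4. Feature moments are computed in float64 regardless
of storage dtype (volumes are written as float32 images / uint8 masks).
The generator refuses grids below 32 voxels per axis, fractions that cannot
be realized within ±0.05, and profiles whose 5%-MPA threshold does not fall
below the 50%-LA threshold.

## Known limitations

Lung masks are inputs; automatic lung segmentation and the manual editing
step of the clinical workflow are out of scope. The stage-1 volume rule is
weak by construction and is exposed mainly for completeness. The published
cutoffs are tied to the defining cohort's scanner and contrast protocol;
on other data they should be re-derived with `roc_with_youden`.
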