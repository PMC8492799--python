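# bbbleak

Quantification of subtle blood–brain-barrier (BBB) leakage from
dual-time-resolution dynamic contrast-enhanced MRI (DCE-MRI), and analysis of
how baseline leakage relates to cognitive decline — the imaging-to-statistics
chain used to study cerebral small vessel disease (cSVD), implemented
end-to-end on synthetic data.

In cSVD, BBB leakage rates sit at or below the noise floor of voxel-wise
pharmacokinetic fitting (order 10⁻⁴ min⁻¹), which is exactly why the method
here combines a Patlak fit with a histogram-based noise correction rather
than trusting individual voxels. Because patient DCE-MRI data of this kind
are not public, the package ships a digital phantom and a synthetic cohort
generator with known ground truth, so every stage of the chain is testable.

## Who this is for

Researchers in quantitative MRI / imaging biomarkers who want a tested,
reusable reference implementation of:

- the **Patlak graphical method** for leakage mapping from a dual
  (fast + slow) dynamic acquisition,
- the **noise-corrected histogram** leakage measures (mean *K*ᵢ and leakage
  volume *v*<sub>L</sub>),
- **compound cognitive-decline z-scores** and covariate-adjusted linear
  association models,

plus the simulation machinery to validate all of it against ground truth.

## The model

**Signal → concentration.** Tissue and blood signal follow the spoiled
gradient-echo (SPGR) steady-state equation with
R₁(t) = 1/T₁₀ + r₁·C(t). Per voxel, the pre-contrast baseline S₀ and the
T₁ map determine the inversion of signal to gadolinium concentration C(t).

**Vascular input.** Whole-blood concentration C_b(t) is averaged over the
superior-sagittal-sinus mask and converted to plasma concentration with the
hematocrit correction C_p = C_b / (1 − Hct).

**Patlak fit.** For each voxel, ordinary least squares of

```
Ct(t)/Cp(t) = Ki · [ ∫₀ᵗ Cp dτ / Cp(t) ]  +  vp
```

over the post-bolus window gives the leakage rate *K*ᵢ (slope, min⁻¹) and
plasma volume fraction *v*ₚ (intercept). Negative slopes are deliberately
retained.

**Histogram noise correction.** Per brain region (NAWM, WMH, cortical and
deep grey matter) the signed *K*ᵢ histogram is corrected by mirroring the
negative half onto the positive axis and subtracting bin-by-bin (clamped at
zero). The remaining mass gives the two leakage measures: **mean *K*ᵢ** (the
detectable leakage rate, reported in 10⁻⁴ min⁻¹) and **v<sub>L</sub>** (the
leakage volume, the remaining area as % of region voxels).

**Cognition and association.** Raw decline = baseline − follow-up per
neuropsychological test (time-based Stroop/Trail-Making scores inverted so
positive = worsening), z-standardized over the cohort, averaged into
memory / executive / processing-speed domain compounds (a domain tolerates
one missing test; more than one makes it absent) and an overall compound.
Standardized regression coefficients B with 95% CIs relate each leakage
measure to each compound, univariable and adjusted for age, sex, education,
relative WMH volume and relative brain volume.

## Worked example

Simulate a phantom acquisition, quantify it, and summarize leakage:

```bash
bbbleak --seed 3 simulate --out phantom/
bbbleak quantify --fast phantom/dynamic_fast.nii.gz \
                 --slow phantom/dynamic_slow.nii.gz \
                 --t1 phantom/t1_map.nii.gz --masks phantom/labels.nii.gz \
                 --out quant/
bbbleak leakage --ki quant/ki.nii.gz --labels phantom/labels.nii.gz \
                --out leakage.csv
```

`leakage.csv` then contains (default phantom, ~1% signal noise):

```
region,n_total,v_l_percent,mean_ki_e-4_per_min,flags
NAWM,4608,73.22048611111111,4.288974510966213,
WMH,512,85.9375,3.9472727272727273,
CGM,2560,68.359375,3.467542857142858,
DGM,1024,78.80859375,4.033333333333333,
```

Every tissue voxel in the default phantom truly leaks (ground-truth *K*ᵢ
2.3–3.4 ×10⁻⁴ min⁻¹), but at a per-voxel fit noise of ~2.6 ×10⁻⁴ min⁻¹ only
~70–86% of voxels remain detectable after the noise correction — that
fraction is v<sub>L</sub>; the corrected mean *K*ᵢ (3.5–4.3 ×10⁻⁴ min⁻¹)
reflects the detectable (upper) part of the distribution, which is why it
sits above the ground-truth means. At zero noise the same chain recovers
every region's *K*ᵢ to better than 0.01% (see the tests).

`bbbleak --seed 3 run-all --out full/` runs the whole chain — phantom,
Ki maps, leakage table, synthetic 51-patient cohort, compound scores, and
the 4 regions × 2 measures × 4 outcomes association grid (univariable and
adjusted) — and writes a manifest with per-file checksums; reruns with the
same seed are bit-identical.

The same operations are available as a library
(`from bbbleak import patlak_fit, noise_correct, fit_association, ...`).

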