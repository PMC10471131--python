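# cmrquant

Quantitative cardiac MRI analysis for small heart-failure cohorts, built
around the protocol used to characterise diet-induced heart failure in
cynomolgus macaques: MOLLI T1 mapping, extracellular-volume (ECV) mapping,
dual-bolus first-pass perfusion quantified by Fermi-constrained
deconvolution, echo-based classification into healthy / HFpEF / HFrEF, and
the cohort statistics used to compare the groups.  A digital short-axis
phantom and a cohort simulator make every stage testable without animal
data, which is also how the package validates itself.

## What it computes

**T1 mapping.**  MOLLI magnitude images (schemes such as 5(3)3 pre-contrast
and 4(1)3(1)2 post-contrast, with recovery heartbeats adjustable for the
~150 bpm heart rate of macaques) are fit per pixel to the apparent
inversion recovery

    S(TI) = |A − B·exp(−TI/T1*)|

with polarity restoration over every candidate sign-flip split, then
corrected to true T1 with the Look-Locker relation `T1 = T1*·(B/A − 1)`.

**ECV mapping.**  With `ΔR1 = 1/T1_post − 1/T1_pre` and serum hematocrit:

    ECV = (1 − Hct) · ΔR1_myo / ΔR1_blood

computed pixel-wise over the myocardium against a blood-pool ROI mean.

**Perfusion and MPR.**  The tissue concentration curve is modelled as the
convolution of the arterial input function (AIF) with a Fermi impulse
response R(t) whose initial amplitude equals myocardial blood flow
(ml/min/g).  The AIF is measured from a low-dose bolus and rescaled by the
dose ratio (0.01 : 0.09 mmol/kg → ×9) before deconvolution; maps are fit
pixel by pixel, and myocardial perfusion reserve is MPR = stress / rest.

**Classification and statistics.**  Subjects are classified from echo
scalars (EF < 65% → HFrEF; otherwise HFpEF when ≥ 2 of: E′/A′ or E/A < 0.8
or > 3; septal E′ < 7 cm/s; E/E′ > 10), then compared by one-way ANOVA,
age-adjusted ANCOVA with partial correlation, and ROC analysis with the
Youden-index cutoff.

## Worked example

```
$ cmrquant simulate cohort --seed 7 --out cohort.csv
wrote cohort.csv (30 subjects, 3 groups)
$ cmrquant cohort-stats --cohort cohort.csv --out report.json
wrote report.json; ECV ANOVA p = 2.34e-06; AUC = {'HF_vs_healthy': 0.935, 'HFrEF_vs_HFpEF': 0.73}
```

The simulated cohort draws each subject's variables from the published
group means/SDs (e.g. ECV 20.79 ± 3.65 % healthy, 27.06 ± 3.37 % HFpEF,
31.11 ± 4.50 % HFrEF).  The report shows ECV separating the three groups
strongly (ANOVA p ≪ 0.001) and discriminating pooled heart failure from
healthy with AUC ≈ 0.94 in this draw.

The image pipeline runs the same way:

```
$ cmrquant run --seed 7 --out demo/
$ cmrquant t1map --stack demo/healthy/molli_pre.nii --mask myo.nii --out t1_pre.nii
wrote t1_pre.nii; ROI mean T1 = 1197.7 ms over 360 px
$ cmrquant perfuse --dyn dyn.nii --aif aif.csv --mask myo.nii --out mbf.nii
wrote mbf.nii; global perfusion = 1.31 ml/min/g over 128 px
```

Here the phantom's ground-truth native myocardial T1 is 1200 ms and its
rest flow 1.31 ml/min/g, so the printed ROI means are sub-percent-accurate
recoveries through the full simulate → fit chain.

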