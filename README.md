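# rvstrain

Automatic analysis and classification of right-ventricular (RV)
longitudinal strain curves from speckle-tracking echocardiography.

In arrhythmogenic right ventricular cardiomyopathy (ARVC) and related
myocardial diseases, the *shape* of the regional strain curve carries
diagnostic information beyond its amplitude: a delayed onset of
mechanical shortening, a reduced systolic peak and shortening that
continues after pulmonary valve closure mark progressively abnormal
deformation. Scoring these features by eye is slow and operator
dependent. `rvstrain` extracts them automatically and applies the
points-based deformation-pattern classification (types I/II/III) used
in clinical RV strain analysis.

## The algorithm

Each curve is a time series of longitudinal strain ε(t) in percent
(negative = shortening) with three event annotations: QRS-complex onset
(electrical activation), pulmonary valve opening (PVO, optional) and
pulmonary valve closure (PVC, end of systole).

1. **Preprocessing** — the curve is restricted to [QRS onset, end of
   recording], re-referenced so QRS onset is *t* = 0 and linearly
   interpolated onto a uniform 1000-sample grid.
2. **Onset of shortening** — all local maxima of ε(t) strictly before
   PVC are found (a sample larger than both neighbours; plateaus count
   once, at their first sample). With no peak the onset is 0 (at QRS
   onset); with one peak, that peak's time. With several, a moving
   candidate walks the peaks in time order: if the next peak lies more
   than 1.5% absolute strain below the candidate, the candidate is the
   onset; otherwise the walk advances.
3. **Amplitudes** — peak strain PS = min ε(t) over the whole window;
   systolic peak strain SPS = min ε(t) for t ≤ PVC; post-systolic
   index

       PSI = 100 · (PS − SPS) / PS       (PSI = 0 when PS = SPS)

4. **Classification** — onset, PSI and SPS each earn 0–2 points against
   configurable numeric bands; totals 0–1 → type I (normal), 2–3 →
   type II, 4–6 → type III. One rule precedes all scoring: SPS ≥ −10%
   scores 4 points outright and forces type III (onset and PSI are then
   not scored). The band cut-offs ship in
   `src/rvstrain/data/default_rubric.yaml` and can be replaced per run.

The package also provides two-rater agreement statistics (Bland–Altman,
median/IQR of differences, Spearman ρ, ICC(2,1), fraction of differences
within one imaging frame) for validating automatic against manual onset
annotation, and a synthetic curve generator with exact ground truth for
testing every stage without clinical data.

## Worked example

```bash
rvstrain simulate --n 4 --segments 3 --mix 0.5,0.25,0.25 --seed 17 --out-dir cohort
rvstrain classify --manifest cohort/manifest.json --out metrics.csv
```

`metrics.csv` holds one row per curve:

```
subject_id,segment,onset_ms,peak_strain_pct,systolic_peak_strain_pct,psi_pct,points_onset,points_psi,points_sps,points_total,type,errors
S001,basal,66.5,-26.16,-25.77,1.51,0,0,0,0,I,
S001,mid,66.5,-25.46,-24.35,4.36,0,0,0,0,I,
S001,apical,66.5,-29.49,-27.43,7.0,0,0,0,0,I,
S002,basal,107.3,-21.36,-17.26,19.19,0,1,1,2,II,
```

S001's curves shorten early (onset 66.5 ms after QRS onset), reach a
deep systolic peak (SPS ≈ −26%) and have almost no post-systolic
shortening (PSI ≈ 1.5%): 0 points, type I. S002's basal curve has a
reduced systolic peak (−17.3%, 1 point) and a fifth of its shortening
after valve closure (PSI 19.2%, 1 point): 2 points, type II.

Comparing the detected onsets against the generator's ground truth:

```bash
rvstrain agree --pairs pairs.csv --out report.json
# n=12 median|diff|=4.2 ms (IQR 2.6-5.8) rho=0.993 ICC=0.992 within 1 frame: 92%
```

i.e. with the default mild noise the detector lands a median 4.2 ms from
the true onset — a third of the 13.3 ms frame duration at the default
75 Hz framerate.

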