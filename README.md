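# cmrdiast

Volumetric assessment of left-ventricular **diastolic function** from routine
cine cardiac MR, with ASE-rule dysfunction grading and the full
echo-vs-CMR method-agreement statistics — plus a fully seeded synthetic
cohort generator so every stage is testable without patient data.

## Who this is for

Cardiac imaging researchers who have LV time–volume curves (one cavity
volume per cardiac phase over a single R-R interval, e.g. from a 3-D model
fit or slice-summed short-axis segmentations) and want transmitral-style
diastolic indices from them; and anyone running a method-comparison study
between volumetric CMR indices and echocardiographic Doppler measures.

## The indices

The derivative dV/dt of the time-volume curve shows an early filling wave
(E) and, unless fused, an atrial wave (A), mirroring transmitral Doppler
inflow. With end-systole (ES) at the volume minimum:

- **E, A** (mL/s) — first and second peak filling rate after ES;
  **RTPE, RTPA** (ms) — their delays from ES
- **NE = E/EDV, NA = A/EDV** (s⁻¹) — peaks normalised to chamber size
- **DT** (ms) — deceleration time: from the E peak to where the fitted
  E-wave downslope crosses the zero-rate baseline
- **DVR** (ms) — diastolic volume recovery: from ES until 80 % of the
  stroke volume has refilled
- **E′** (mm/s) — longitudinal relaxation rate: the peak early-diastolic
  lengthening rate of the apex-to-mitral-annulus distance (septal and
  lateral guide points); **E/E′** carries units mL/mm because the
  volumetric E is a flow rate, not a velocity

Diastolic function is graded from echo tissue-Doppler criteria
(septal e′ < 8 cm/s, lateral e′ < 10 cm/s, mean E/e′ ≥ 10): all three →
type II (reduced); two, or one plus LV hypertrophy (LVMi > 115 g/m² men,
> 95 g/m² women) → type I (impaired); otherwise normal.

The statistics module implements summary-or-raw one-way ANOVA, the
Freeman–Halton r×c Fisher exact test, Pearson regression (echo as
predictor), Bland–Altman limits of agreement, rank-statistic ROC AUC with
tie correction, and the single-measure absolute-agreement two-way random
ICC — ICC(2,1).

## Worked example

```bash
cmrdiast simulate --n 102 --seed 11 --out cohort.csv --curves-dir curves
cmrdiast analyze curves/normal_curve.csv \
    --lateral-track curves/normal_lateral_track.csv --out indices.json
cmrdiast report cohort.csv --out report.json
```

`indices.json` for the synthetic normal-morphology exemplar curve prints
(values rounded):

```
E 187.45 mL/s   NE 1.43 1/s   A 148.23 mL/s   E/A 1.26
DT 273.5 ms     DVR 914.7 ms  RTPE 270 ms     RTPA 900 ms
E' lateral 78.5 mm/s          E/E' lateral 2.39 mL/mm
EDV 130.9 mL    SV 90.3 mL    ES at 570 ms
```

i.e. a broad early wave peaking 270 ms after end-systole at 187 mL/s, an
atrial wave at 148 mL/s, and an annulus lengthening at 78.5 mm/s — a
normal E-dominant filling pattern (E/A 1.26, E/E′ 2.4 mL/mm).

The cohort report on the 102-subject simulated cohort prints grade counts
`{normal: 67, impaired: 23, reduced: 12}`, an echo-vs-CMR E/A correlation
r = 0.78 (p < 10⁻²¹), a Bland–Altman bias of +0.07 (limits −0.58 to
+0.72) toward a higher E/A by CMR, and a lateral E/E′ ROC AUC of 0.64 for
echo-graded reduced vs normal function — the generator draws most
variables independently within grade, so between-method couplings beyond
the configured E/A correlation are conservative (see
`docs/methods.md`).

## Layout

| module | contents |
| --- | --- |
| `volume_curves` | `VolumeCurve`, `MaskStack`, cyclic differentiation, ES detection |
| `diastolic_indices` | E/A/DT/DVR detection and `analyze_curve` orchestration |
| `annulus_kinematics` | apex–annulus distance tracks and E′ |
| `echo_grading` | echo measures, ASE criteria, dysfunction grades |
| `validation_stats` | ANOVA, Fisher r×c, Pearson, Bland–Altman, ROC, ICC, paired t |
| `synthetic_cohort` | raised-cosine waveform simulator with analytic ground truth; grade-conditional cohort generator |
| `io` / `cli` | CSV formats, mask-stack loader, cohort pipeline, `cmrdiast` CLI |
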