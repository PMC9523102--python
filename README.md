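# nirswave

Wavelet-domain analysis of fNIRS hemodynamic oscillations for motor
rehabilitation studies: cortical **activation**, hemispheric
**lateralization** and interregional **phase coherence**, with
surrogate-based significance and group-level statistics — plus a
synthetic-data generator with saved ground truth for validating every
stage.

## The problem

After stroke, upper-limb motor training reorganizes cortical activity.
Functional near-infrared spectroscopy (fNIRS) tracks this through slow
(0.01–0.08 Hz) oscillations of oxy-/deoxyhemoglobin concentration
(ΔO2Hb/ΔHHb) measured over both hemispheres, here on a 38-channel
montage (18 sources, 16 detectors, 30 mm separation, 10 Hz) covering
prefrontal (PFC), dorsolateral prefrontal (DLPFC), superior frontal
(SFC), premotor (PMC), primary motor (M1), primary somatosensory (S1)
and occipital (OC) cortex on each side. Since lesion side varies,
channels are relabeled per subject as ipsilesional (I) or
contralesional (C), giving 14 effective regions. Subjects are grouped
by manual muscle test grade (0–1 severe, 2–3 moderate, ≥4 mild), and
a 10-min resting state is compared with a 10-min training state.

## The measures

After cleaning (0.0095–2 Hz zero-phase Butterworth, seeded PCA+ICA
denoising with a band-power retention criterion, 3-s moving-average
despiking with cubic-spline repair), a Morlet continuous wavelet
transform (ω0 = 6, 16 voices/octave) yields per channel:

- **WA** (wavelet amplitude): time- then band-averaged |W(f, t)| over
  0.01–0.08 Hz, cone of influence excluded — the activation measure,
  in the signal's concentration units;
- **LI** (lateralization index) per homologous region pair:

      LI = (ΣWA_C − ΣWA_I) / (ΣWA_C + ΣWA_I)  ∈ [−1, 1]

  (+1 contralesional-only, −1 ipsilesional-only activation);
- **WPCO** (wavelet phase coherence) per region pair: band-averaged
  resultant length of the wavelet phase difference,
  R(f) = √(⟨cos Δφ⟩² + ⟨sin Δφ⟩²) ∈ [0, 1], tested against 50
  amplitude-adjusted Fourier-transform (AAFT) surrogates with the
  mean + 2 SD rule.

Within each group, rest vs. training is compared per region/pair with
a one-way ANOVA at the Bonferroni-adjusted threshold 0.05/3 = 0.0167,
with Kolmogorov–Smirnov and Levene checks reported as advisory.

## Worked example

```python
from nirswave import SyntheticConfig, RunConfig, generate_subject, run_subject

syn = SyntheticConfig(training_gain={"ISFC": 1.5},
                      coupling=[("ISFC", "CSFC", 8.0)], seed=1)
rec, truth = generate_subject(syn, 0)          # 38 ch × 1200 s at 10 Hz
res = run_subject(RunConfig(chromophores=("o2hb",), seed=1), rec)

print(res.wa.pivot_table(index="region", columns="state", values="wa")
          .loc[["ISFC", "CSFC", "IM1"]].round(3))
```

```
state    rest  training
region
ISFC    0.123     0.192
CSFC    0.080     0.077
IM1     0.151     0.148
```

The planted 1.5× training gain on ISFC is visible (0.123 → 0.192,
ratio ≈ 1.56) while unmodulated regions stay flat. The corresponding
training-state SFC lateralization is negative — ipsilesional
dominance, as planted:

```
region     li
   SFC -0.426
```

and the planted ISFC–CSFC coupling (von-Mises κ = 8) is recovered by
the surrogate test in the resting state:

```
region_a region_b  wpco  threshold  significant
    ISFC     CSFC 0.875      0.548         True
```

WPCO 0.875 far exceeds the AAFT-surrogate threshold 0.548; uncoupled
pairs sit near the null (≈0.3 at 600 s) and are not flagged.

## Command line

```bash
nirswave simulate --out cohort/ --seed 1            # synthetic cohort + truth
nirswave analyze  --input cohort/SYN01.tsv --out out/ --seed 1
nirswave compare  --input cohort/ --out stats/ --seed 1
nirswave run-all  --out study/ --seed 1
```

Configuration comes from one YAML file (`--config`, see
`src/nirswave/data/default_config.yaml`) with `--set key=value`
overrides; every tunable defaults to the study conditions
(0.0095–2 Hz filter, 0.01–0.08 Hz band, 3-s despike window,
50 surrogates, mean+2SD, 0.05/3).

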