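# placenta-dwr

Combined diffusion-relaxation analysis of placental MRI for studying
imminent preterm birth.  The package is aimed at quantitative-MRI
researchers who acquire multi-echo multi-b diffusion data of the
placenta and want a tested, reproducible path from 4D volumes to cohort
statistics — plus a synthetic placenta/cohort generator so the whole
pipeline can be validated without patient data.

## What it computes

Each voxel's magnitude signal S(TE, b) is modelled two ways:

* **T2\*-ADC** (mono-exponential):

      S = S0 · e^(−(TE − TE_min)/T2*) · e^(−b·ADC)

* **T2\*-IVIM** (two compartments — fast pseudo-diffusion from
  perfusing blood, slow true diffusion from tissue):

      S = S0 · [ f · e^(−(TE − TE_min)/T2*_fast) · e^(−b·D*)
               + (1 − f) · e^(−(TE − TE_min)/T2*_slow) · e^(−b·ADC) ]

with compartments labelled so D\* > ADC and f the fast fraction.
Fractional anisotropy comes from a single-tensor fit of the
shortest-echo-time volumes.  Fits are bounded trust-region least
squares; when the noise SD is known they fit the exact Rician
expectation of the magnitude, which removes the noise-floor bias at
realistic SNR (see `docs/methods.md`).

Downstream, T2\* maps are thresholded at 200 ms (supraphysiological
values excluded), maps are reduced to parenchyma-ROI means, and the
cohort module runs gestational-age trends, case-control and
membrane-status contrasts, and a latency-ratio split of the cases
(scanned close to vs far from delivery), all as two-sided OLS at
α = 0.05.

## Worked example

`examples/` contains one short script per capability.  Running
`python examples/04_cohort_statistics.py` simulates the default cohort
(23 preterm cases — 14 PPROM, 9 intact membranes — and 52 term
controls) and prints:

```
cohort: 75 subjects (14 pprom / 9 intact / 52 control)

control T2* vs gestation: -2.58 ms/week, p = 3.65e-28  (declines with gestation)
case effect on t2_star :     -14.52  p = 0.000 *
case effect on adc     : +1.211e-05  p = 0.735
case effect on f       : -0.0006971  p = 0.915
case effect on fa      : +0.0003319  p = 0.903

latency split: 15 cases below zero (scanned close to delivery), 8 above
perfusion fraction, below-zero minus above-zero: -0.0468, p = 0.001
```

Reading this: control placental T2\* falls by ~2.6 ms per gestational
week; cases carry a large additional T2\* reduction (−14.5 ms adjusted
for gestation) while ADC, perfusion fraction and FA show no
case-control difference; and within the cases, perfusion fraction is
lower in those scanned close to delivery — the qualitative signature
the analysis is designed to detect.

The other examples cover the acquisition scheme
(`01_acquisition_scheme.py`: 60 diffusion preparations × 4 echo times =
240 volumes), single-voxel forward modelling and fitting
(`02_forward_models_and_fitting.py`) and the phantom → fit → ROI chain
(`03_phantom_to_roi.py`).

A thin CLI wraps the same library:

```bash
placenta-dwirelax scheme build --out-prefix /tmp/scheme
placenta-dwirelax simulate subject --ga 28 --group pprom --seed 1 --out-dir /tmp/subj
placenta-dwirelax fit --model t2ivim --data /tmp/subj/dwi.nii.gz \
    --mask /tmp/subj/mask.nii.gz --scheme-prefix /tmp/subj/scheme --out-dir /tmp/subj/maps
placenta-dwirelax run --seed 0 --out-dir /tmp/study
```

## Layout

```
src/placenta_dwr/
  protocol.py    acquisition scheme: build / read / write sidecars
  models.py      forward signal models and parameter types
  synthetic.py   noise, phantoms, cohort generator (GeneratorConfig)
  fitting.py     voxel-wise NLLS fits, Rician expectation, volume fitting
  roi.py         T2* thresholding and ROI summaries
  cohort.py      trends, contrasts, latency scoring and split
  io.py          NIfTI and cohort-table I/O, manifests
  pipeline.py    end-to-end synthetic study (PipelineConfig)
  cli.py         placenta-dwirelax command-line interface
```

`docs/methods.md` documents the models, the fitting choices, the
generator's assumptions and known limitations.
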