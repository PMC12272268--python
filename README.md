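# synt1w

Synthetic T1-weighted MRI of the cervical spinal cord: closed-form
reconstruction of MPRAGE-contrast images from quantitative maps, cord
cross-sectional-area (CSA) morphometry, and the statistical battery used to
validate synthetic against acquired contrasts — agreement, longitudinal
atrophy modeling, and trial sample-size estimation.

## Who this is for

Quantitative multi-parameter mapping (MPM) protocols yield voxelwise maps of
proton density (PD), the longitudinal relaxation rate R1 = 1/T1, and the
effective transverse relaxation rate R2\* = 1/T2\*. From these, a synthetic
T1-weighted (synT1-w) image with any MPRAGE contrast can be computed without
acquiring a separate MPRAGE scan — saving roughly ten minutes of scanner
time per session. The catch is that morphometric measures such as the
cervical cord CSA, a neurodegeneration biomarker in spinal cord injury and
multiple sclerosis, can be systematically biased on synthetic contrast
relative to the acquired reference. This package implements the full
workflow for quantifying and minimizing that bias, and for checking that the
synthetic contrast supports the same longitudinal inferences: atrophy rates,
group differences, and the sample size of a hypothetical treatment trial.

Because no public dataset accompanies this workflow, the package ships a
first-class synthetic-data module: quantitative-map phantoms with exact
analytic ground truth for cord geometry, and a longitudinal two-group cohort
simulator with the generative structure the analyses assume.

## The signal model

The MPRAGE steady-state signal at the central echo of a linearly ordered
readout train is

    S = PD · sin(α) · exp(−TE · R2*) · Q

with the longitudinal factor

    Q = [E4·(1 − 2·E1 + E1·E2) + T1*·R1·(1 + E1·E2·E3 − E1·E2·E4 − E4)] / (1 + E1·E2·E3)

where

    T1* = (R1 − ln cos α / ES)⁻¹          apparent relaxation in the spoiled train
    E1  = exp(−(TI − τ/2)·R1)             inversion → start of readout
    E2  = exp(−TD·R1)                     post-readout delay
    E3  = exp(−τ/T1*)                     full readout train
    E4  = exp(−τ/(2·T1*))                 half train (to the central echo)
    τ   = n·ES,   TD = TR − (TI − τ/2) − τ

α is the flip angle, TI/TR/TE the inversion/repetition/echo times, ES the
echo spacing and n the partition count. `Q` is the fixed point of one
preparation cycle (perfect inversion → free relaxation → spoiled excitation
train → delay); a pulse-by-pulse iteration of that cycle is included as an
independent verification oracle. Settings with TD < 0 are not realizable as
an acquisition but remain valid for reconstruction — synthesis is free of
pulse-timing constraints — and are flagged accordingly.

Downstream, cord CSA is measured by threshold segmentation and per-slice
areas corrected by the cosine of the angle between the cord centerline and
the slice normal; reconstruction parameters are calibrated by exhaustive
grid search minimizing |mean ΔCSA| against a reference; agreement is
summarized by Bland-Altman bias and 95% limits of agreement plus a JZS
Bayesian two-sample t-test on group biases; trajectories are fit with a
linear mixed-effects model (level + group×(time + time²) + age×time +
scanner, subject random effects); and trial sizes follow the
baseline-adjusted ANCOVA formula n = 2·(z₁₋α/₂ + z₁₋β)²·σ²·(1 − ρ²)/Δ².

## Worked example

```python
import warnings
from synt1w import (DEFAULT_TISSUES, SequenceParams, derive_timing, synthesize_voxel)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    params = SequenceParams.from_ms(flip_angle_deg=14, TE_ms=0, TR_ms=1400,
                                    TI_ms=900, ES_ms=14, n_partitions=176)
    print(derive_timing(params))
    for name, tissue in DEFAULT_TISSUES.items():
        print(name, round(synthesize_voxel(tissue, params), 4))
```

prints

```
TimingDerivation(tau=2.464, TD=-0.7319999999999998, feasible=False)
cord 0.0533
csf 0.0238
background 0.0205
```

i.e. the calibration-optimal setting implies a 2464 ms readout and a
−732 ms delay — impossible to acquire, fine to reconstruct — and produces
the expected T1-weighted ordering (cord bright, CSF dark). The
`examples/` directory contains one narrative script per capability:
contrast synthesis, phantom CSA measurement with angle correction,
parameter calibration, agreement/precision analysis, and atrophy modeling
with trial sizing. For instance, `python examples/measure_phantom_csa.py`
prints

```
analytic perpendicular CSA : 50.27 mm^2
analytic oblique-cut CSA   : 58.04 mm^2 (inflated by 1/cos 30.0 deg)
measured raw CSA           : 58.67 mm^2
measured corrected CSA     : 51.99 mm^2
mean centerline angle      : 29.8 deg
```

showing the centerline-angle correction removing the 1/cos(30°) obliquity
inflation to within voxel digitization.

## Layout

- `src/synt1w/signal.py` — closed-form MPRAGE synthesis (the model above)
- `src/synt1w/bloch.py` — pulse-by-pulse steady-state verification oracle
- `src/synt1w/maps.py` — quantitative-map container and NIfTI I/O
- `src/synt1w/phantom.py`, `src/synt1w/cohort.py` — synthetic data: geometry
  phantoms with analytic ground truth, longitudinal cohort simulator
- `src/synt1w/morphometry.py` — segmentation, per-slice CSA, angle correction
- `src/synt1w/optimize.py` — parameter grid search against reference CSA
- `src/synt1w/agreement.py` — Bland-Altman, JZS Bayes factor, repeatability
- `src/synt1w/atrophy.py` — mixed-effects trajectory model and contrasts
- `src/synt1w/power.py` — ANCOVA sample size and Monte-Carlo power
- `src/synt1w/cli.py` — thin command-line interface
- `docs/methods.md` — modeling assumptions, defaults, numerical choices
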