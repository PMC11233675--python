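# volatempo

Longitudinal volatilomics of in-vitro gut fermentations: PARAFAC2-based
deconvolution of GC-MS headspace data and repeated-measures ASCA modelling of
time-resolved VOC dynamics, with bootstrap-validated score and loading
envelopes, hierarchical temporal profiling, and fatty-acid release-kinetics
summaries.

## Who this is for

Researchers monitoring volatile organic compounds (VOCs) over the course of
batch fermentations — e.g. gut-microbiota models fermenting dietary fibres,
sampled by headspace SPME GC-MS at several time points in replicate vessels —
who need to (a) resolve co-eluting, retention-shifted chromatographic peaks
into compound spectra and abundances, and (b) model how the volatilome
evolves over time and differs between substrates, with honest uncertainty on
the multivariate summaries.

## The models at the core

**PARAFAC2.** Interval-segmented GC-MS data form a three-way array
X (I × J × K): elution scans × m/z fragments × samples.  PARAFAC2 models
each sample slab as

    X_k ≈ B_k diag(c_k) Aᵀ,

with shared non-negative spectra A (J × F), sample-specific elution profiles
B_k (I_k × F) constrained to a constant cross-product B_kᵀB_k, and
non-negative concentrations c_k.  The constant cross-product is what lets
peaks shift in retention time between samples without losing a common
spectral identity.  The number of components F per interval is chosen by
fit together with the core-consistency diagnostic (corcondia ≤ 100), which
collapses for over-factored models.  Estimated spectra are matched against
an MSP library by weighted cosine (weight m/z¹·intensity⁰·⁵) and
cross-checked via Kovats retention indices interpolated on a C8–C20
n-alkane ladder.

**RM-ASCA.** After detection-consistency and coefficient-of-variation
filtering and scaling, each VOC is modelled with a linear mixed model

    y = time + time:group + (1 | vessel),

where time is categorical against the baseline time point and the
time × group interaction omits both the baseline and the reference group —
encoding that all vessels start from the same state.  The fitted fixed
effects form effect matrices (time, interaction, combined), each summarised
by PCA (simultaneous component analysis); nonparametric bootstrap over
fermentation vessels yields 95% confidence envelopes for the group score
trajectories and the loadings, and the top/bottom-loading VOCs per
component identify what is produced and consumed.

## Worked example

Deconvolve a simulated three-compound interval (12 samples, retention
shifts of ±5 scans, 20 dB SNR), then model a simulated 3-group × 7-time ×
3-vessel study in which 10 of 40 VOCs rise with group-dependent amplitude:

```python
import numpy as np
from volatempo import (Parafac2, RMASCA, asca_benchmark, scale_matrix,
                       simulate_tensor)

tensor, truth = simulate_tensor(n_scans=120, mz_axis=np.arange(35, 95),
                                n_samples=12, n_components=3,
                                shift_range_scans=5, noise_snr_db=20.0, seed=7)
print(Parafac2(tensor, 3).fit(seed=0, n_restarts=5).summary())

table, truth = asca_benchmark(seed=0)
fit = RMASCA(scale_matrix(table, method="none"), n_components=3).fit()
print(fit.summary())
env = fit.bootstrap(n_resamples=200, seed=0)
print("groups separated at:", env.separated_timepoints(1), "h")
```

prints

```
PARAFAC2 Results
================
components:        3
samples (K):       12
m/z bins (J):      60
fit %:             99.0645
core consistency:  100.00
iterations:        409
converged:         True
cross-product dev: 2.315e-15

RM-ASCA Results
===============
engine:            ols
baseline time:     0 h
reference group:   FM
observations:      63
variables:         40
time         effect: PC1 72.88%, PC2 7.86%, PC3 6.88%
interaction  effect: PC1 75.33%, PC2 4.95%, PC3 4.70%
combined     effect: PC1 90.17%, PC2 1.64%, PC3 1.36%
groups separated at: [8.0, 12.0, 16.0, 20.0, 24.0] h
```

The PARAFAC2 fit explains 99.06% of the slab variance (the remaining ~1% is
the injected 20 dB noise) with core consistency 100 — the three-component
model is trilinear-consistent, and the near-zero cross-product deviation
confirms the coupling constraint.  In the RM-ASCA fit, PC1 of the combined
effect matrix carries 90% of the modelled time × group variation, and the
bootstrap envelopes separate the substrate groups from 8 h of fermentation
onward — the rising VOCs have diverged beyond replicate-vessel uncertainty.

A full pipeline (simulate → deconvolve → filter → asca → cluster →
kinetics) is driven by configuration:

```bash
volatempo run --seed 1 --outdir out/
```

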