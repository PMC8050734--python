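# circashift

Diurnal rhythm detection and phase-entrainment analysis for two-condition
omics time series.

## The problem

Time of eating is a dominant zeitgeber for peripheral tissues: feeding
mice only in the daytime (inverted feeding, DRF) can re-time diurnal
rhythms of the transcriptome and metabolome away from the light-dark
cycle, and different tissues re-time at very different speeds. Measuring
that *degree of entrainment* from omics time series requires a chain of
statistical steps: detect which features oscillate under each feeding
condition, compare rhythm parameters between conditions, fold the phase
difference onto the circle, classify each feature as phase-locked,
intermediate or phase-inverted, and ask which pathways shift coherently.
`circashift` implements that chain as a tested, reusable library with a
seeded synthetic-data generator, so every stage can be validated against
ground truth without any external download.

## The model

Each feature's diurnal profile is a cosinor,

    y(t) = M + A cos(2pi (t - phi) / tau) + error,

with mesor `M`, amplitude `A >= 0`, acrophase `phi in [0, tau)` and
period `tau` (24 h diurnal, 12 h ultradian, or scanned over 20-28 h for
free-running data). Rhythmicity is scored per condition by an ensemble
of three tests — cosinor F, single-frequency Lomb-Scargle, and a
cosine-template Kendall rank test — combined by the Fisher statistic and
calibrated against seeded timepoint permutations; BH q-values are
computed per batch. For features rhythmic under both conditions
("dual-oscillating", q < 0.05 twice), the two conditions are fit jointly,

    y = (M_A + dM x) + (A_A + dA x) cos(2pi (t - phi_A - dphi x)/tau),

with `x` the condition indicator, giving Wald tests for each difference.
The signed shift `dphi` is folded, `fold(d) = min(|d| mod 24, 24 - |d| mod 24)`,
so a 14-h advance equals a 10-h delay, and classified: 0-4 h
phase-locked, (4, 8) h intermediate, 8-12 h phase-inverted. The
phase-inverted fraction of dual-oscillating features is the tissue's
degree of entrainment. Phase set enrichment scores each gene set's
folded shifts on the circle by the Kuiper statistic (permutation p
against the non-member background) together with a *magnitude* — the
circular mean resultant length `R = |mean(exp(i theta))|` in [0, 1] —
and cistrome-style target sets are tested by one-sided Fisher exact
overrepresentation.

## Worked example

`examples/02_phase_entrainment.py` simulates a visceral-adipose-like
dataset (600 features, half rhythmic, 80.46% of them generated
phase-inverted, multiplicative noise with sigma = 0.2) and runs the full
pipeline:

```
dual-oscillating features (q < 0.05 in both conditions): 278
  phase_locked      58  (20.86%)
  intermediate      15  (5.40%)
  phase_inverted   205  (73.74%)
folded phase-shift histogram (1-h bins, 0-12 h):
  [16, 19, 15, 8, 3, 1, 2, 9, 45, 54, 53, 53]
recovered inverted fraction: 73.74% (generative 80.46%)
```

278 of the 300 planted rhythmic features are recovered as
dual-oscillating; the folded-shift histogram is strongly bimodal with
most mass in the 8-12 h bins, and the recovered inverted fraction sits a
few points below the generative value because phase-estimation noise
bleeds features across the 8-h class boundary (see
`docs/methods.md`). The other example scripts cover detection, the
joint comparison, phase set enrichment and 12-h "licensed" oscillators.

The same stages are available as a thin CLI:

```sh
circashift --out-dir run simulate --archetype VAT --n-features 600 --seed 7
circashift --out-dir run entrain --matrix run/matrix.tsv --design run/design.tsv \
    --condition-a NRF --condition-b DRF --q-threshold 0.05
```

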