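# zcbat

Zero-crossing bat echolocation analysis: rule-based call filters, pulse
parameter measurement, quadratic discriminant species identification with
majority-vote sequence labels, and internal/external validation with
bootstrap confidence intervals — plus a synthetic call/noise generator so
the whole chain is testable without access to proprietary call libraries.

## Who this is for

Bat acoustic surveys record ultrasound with zero-crossing
(frequency-division) detectors, which emit one time–frequency dot per N
signal cycles and no amplitude. Ecologists and consultants then (1) filter
the recordings with a rule set that selects pulses and measures their
parameters, (2) classify pulses and pulse sequences to species with a
statistical model, and (3) report cross-validated classification rates.
`zcbat` implements that chain end to end and makes its two most
underappreciated levers explicit: the *filter* (which changes both which
pulses are selected and how the same pulse is measured) and the *call
library* (models validated on their own training library look much better
than they are).

## The model

Pulses are measured by five parameters: duration Dur (ms),
total bandwidth Sweep = Fmax − Fmin (kHz), and three properties of the
*body* — the flattest portion of the pulse, found by minimizing the
absolute endpoint slope over all dot segments of at least `Body Over`
microseconds: frequency at the end of the body Fc (kHz), body slope
Sc = F_B/T_B (octaves/s, positive for down-sweeps), and the post-body
duration Tail (ms).

Classification is a quadratic discriminant analysis: species k has a
Gaussian N(μ_k, Σ_k) over the (R² < 0.5 screened) parameters, priors
equalized, pulses assigned by highest posterior

    P(k | x) ∝ π_k |Σ_k|^(−1/2) exp(−½ (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k)),

and a sequence assigned to the species winning a strict majority (>50%)
of its pulse votes, else labelled `UNKNOWN`. Per species i with N_i
sequences, the correct/incorrect/unknown rates are n_i/N_i, n_j/N_i and
(N_i−n_i−n_j)/N_i; overall rates are the unweighted species mean; 90%
intervals come from bootstrapping sequences (5th/95th quantiles over
B replicates). See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from zcbat import (
    LibraryRecipe, species_presets, synth_library,
    load_preset, apply_filter, feature_matrix_from_result, loocv,
)

recipe = LibraryRecipe(
    species=species_presets(),        # 11 species; MYSO uses published stats
    sequences_per_species=8,
    shift_delta=1.0,                  # early/late mean shift, SD units
)
early, late = synth_library(recipe, np.random.default_rng(1))

west2 = load_preset("WEST2")          # strictest of BM/BCID/WEST1/WEST2
result = apply_filter(early, west2)
print(result.n_sequences, result.n_pulses)
# 87 757

fm = feature_matrix_from_result(result, min_seqs_per_species=2)
rates = loocv(fm)
print(round(rates.rate("correct"), 3), round(rates.rate("unknown"), 3))
# 0.693 0.295
```

The filter retained 87 of 88 synthetic sequences (757 pulses); sequence
leave-one-out puts the overall correct rate at 69.3% with 29.5% rejected
as unknown — species in the crowded 39–46 kHz Myotis band split their
pulse votes, which the strict-majority rule converts into `UNKNOWN` rather
than misidentification (incorrect rate 1.1%).

A thin CLI wraps the same calls:

```bash
zcbat synth --species MYSO,EPFU,LABO --sequences 8 --seed 7 \
      --out-a early.csv --out-b late.csv \
      --manifest-a early.json --manifest-b late.json
zcbat filter --library early.csv --manifest early.json --filter WEST2 --out sel.json
zcbat validate --train early.csv --train-manifest early.json \
      --filter WEST2 --boot 200 --seed 7 --out rates.json
```

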