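# vqent

Entropy-based estimation of event-related desynchronization /
synchronization (ERD/S) from motor-imagery EEG, built around a
**vector-quantized entropy estimator (VQEnt)** with the classical
sample-entropy and fuzzy-entropy baselines and the power-ratio ERD/S for
reference.

## Who this is for

Researchers analyzing cue-paced motor-imagery (MI) EEG — e.g. two-class
left/right-hand paradigms recorded with a sensorimotor montage — who want
single-trial ERD/S trajectories that do not depend on a reference power
level, plus the downstream analyses: parameter tuning, LDA
classification, channel relevance, and cluster-based permutation
statistics. A synthetic MI-EEG generator with known ground truth is
included, so every part of the pipeline is testable without any
recording.

## The method

A windowed signal of `N` samples is unfolded into `Q = N − M` delay
vectors `x̃_q ∈ R^M`. The classical estimators compare all vector pairs:

    SampEn = −ln( π(M+1, ρ) / π(M, ρ) )

where `π(M, ρ)` is the fraction of ordered pairs `q ≠ q′` whose Chebyshev
distance lies below the tolerance `ρ·σ` (σ the standard deviation of the
measured signal); FuzzyEn replaces the hard count with the Gaussian
membership `exp(−(d/ρσ)²)`.

**VQEnt** instead compresses the `Q` delay vectors into a codebook of
`Q′ ≤ Q` codes by a single greedy pass (a vector is admitted iff it is
farther than the tolerance from every code so far), fits a one-pass
probabilistic model over the codes — Gaussian-similarity memberships,
membership-weighted moments `(μ_q′, σ²_q′)`, likelihood and prior, and a
Bayes posterior `p(x̄_q′ | X)` — and reports the Shannon entropy of that
posterior:

    VQEnt = −Σ_q′ p(x̄_q′|X) ln p(x̄_q′|X),   0 ≤ VQEnt ≤ ln Q′.

Sliding this over a trial (window length τ, 90 % overlap, tolerance fixed
from the whole trial) yields a per-trial entropy ERD/S trajectory: during
motor imagery the contralateral mu rhythm desynchronizes, the signal
excursions shrink relative to the fixed tolerance, and the entropy course
dips together with band power.

## Worked example

```python
import numpy as np
from vqent import (SynthSpec, generate, bandpass, plan_windows,
                   entropy_erds, EntropyParams)

spec = SynthSpec(n_trials_per_class=25, n_channels=2, seed=3)
trials = bandpass(generate(spec))              # 4-40 Hz, zero phase
plan = plan_windows(trials.duration, tau=1.0, overlap=0.9, rate=trials.rate)
course = entropy_erds(trials, plan, EntropyParams(M=2, rho=0.3, estimator="vqent"))

labels = trials.label_array()
t = course.time_axis
mi = (t >= 2.5) & (t < 4.5)
c3, c4 = trials.channel_index("C3"), trials.channel_index("C4")
contra = np.where(labels == "right", c3, c4)
ipsi = np.where(labels == "right", c4, c3)
idx = np.arange(trials.n_trials)
print(f"contralateral MI entropy: {np.nanmean(course.per_trial[idx, contra][:, mi]):.3f} nats")
print(f"ipsilateral   MI entropy: {np.nanmean(course.per_trial[idx, ipsi][:, mi]):.3f} nats")
```

prints

```
contralateral MI entropy: 2.836 nats
ipsilateral   MI entropy: 3.235 nats
```

— the contralateral channel (C3 for right-hand imagery, C4 for left) is
about 0.4 nats lower during the MI interval, the entropy signature of the
programmed ERD. With `estimator="sampen"` or `"fuzzyen"` the same dip
appears at smaller magnitude.

The same pipeline is available from the shell:

```
vqent simulate --n-per-class 25 --n-channels 4 --seed 3 --out trials.npz
vqent erds trials.npz --estimator vqent --tau 1.0 --out course.csv
vqent classify trials.npz --estimator vqent
vqent demo --out-dir report/        # full synthetic workflow + plots
```

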