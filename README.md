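# erpstates

Response-locked ERP microstate analysis for speech production research.

When event-related potentials (ERPs) are aligned to the acoustic onset of
a spoken response, the alignment point lags the true onset of
articulation by a phoneme-dependent amount — the articulatory-to-acoustic
interval (AAI).  Voiceless stop onsets (/p, t, k/) trap airflow before
the burst releases, so their AAI is long; fricative onsets (/s/-clusters)
emit acoustic energy almost as soon as articulation starts.  The
consequence is that two conditions with identical brain dynamics can look
different in response-locked ERPs simply because their topographic
microstates are shifted relative to the vocal onset.  `erpstates`
implements the topographic toolchain that detects and quantifies this
shift, for EEG researchers working with response-locked paradigms.

## What it computes

For average-referenced scalp maps `u(t)` over `N` electrodes:

* **GFP** (global field power): the spatial standard deviation,
  `GFP(t) = sqrt((1/N) * Σᵢ (uᵢ(t) − ū(t))²)`.
* **Spatial correlation** `r`: Pearson correlation across electrodes of
  two average-referenced maps.
* **DISS/GDI** (global map dissimilarity): the RMS difference of the two
  GFP-normalized maps, a strength-independent distance in [0, 2] with
  `DISS² = 2(1 − r)`.
* **TANOVA**: a point-by-point paired randomization test on DISS between
  condition grand averages (subject-level condition flips; α = 0.01 with
  a ≥ 10 ms consecutive-significance criterion).
* **Segmentation**: polarity-sensitive modified k-means clustering of the
  concatenated condition grand averages into K template maps
  (GFP-weighted updates, multi-restart, ≥ 10 ms temporal smoothing),
  summarized by the global explained variance
  `GEV = Σₜ (GFP(t)·r(u(t), T_label(t)))² / Σₜ GFP(t)²`.
* **Back-fitting**: each time frame of an individual ERP or single trial
  is labelled with its best-correlating template; per-map durations (in
  time frames, TF; 1 TF ≈ 1.95 ms at 512 Hz) over the fixed window are
  the dependent variable that carries the AAI.
* **Statistics**: linear mixed models of vocal RTs and map durations with
  mode (stop vs fricative) × place (p/t/k) fixed effects and crossed
  subject/item random intercepts, plus planned place contrasts.

A synthetic-data generator produces multi-subject, two-condition,
response-locked datasets with four planted template maps (D→B→C→A tiling
a 150-TF epoch), a configurable onset shift of the final map A between
conditions (default 46 TF ≈ 90 ms), realistic background-EEG noise, and
vocal RTs drawn from the empirical per-phoneme means and SDs of a delayed
production task — so every analysis stage can be validated against a
known ground truth.

## Worked example

```python
import erpstates as es
from erpstates.backfitting import backfit_epochs, backfit_evoked

cfg = es.GeneratorConfig(n_subjects=12, n_trials_per_condition=30, seed=401)
ds = es.simulate_epochs(cfg)

evokeds = es.average_by(ds.epochs)                      # per subject x condition
gas = {c: es.grand_average([e for e in evokeds if e.condition == c])
       for c in ("stop", "fricative")}

seg = es.segment(list(gas.values()), k=4, n_restarts=50, seed=2)
print(f"GEV = {seg.gev:.3f}")

durations = {}
for c, ga in gas.items():
    _, rows = backfit_evoked(ga, seg.templates, seg.template_labels)
    durations[c] = rows.set_index("map")["duration_tf"]
shift = durations["stop"]["A"] - durations["fricative"]["A"]
print(f"grand-average map-A shift: {shift} TF "
      f"(~{es.tf_to_ms(shift, 512, 10)} ms)")

trials = backfit_epochs(ds.epochs, seg.templates, seg.template_labels)
a = trials[trials["map"] == "A"]
single = (a[a.condition == "stop"].duration_tf.mean()
          - a[a.condition == "fricative"].duration_tf.mean())
print(f"single-trial map-A shift: {single:.1f} TF")
```

Output:

```
GEV = 0.992
grand-average map-A shift: 46 TF (~90 ms)
single-trial map-A shift: 22.2 TF
```

The grand averages recover the planted 46-TF (≈ 90 ms) shift of the final
pre-vocal microstate exactly, while the noisy single trials show the same
effect attenuated — the expected behaviour when trial-level topographic
noise pushes per-trial durations toward the uniform split.

The same pipeline is available from the shell:

```bash
erpstates run-all --config config.yaml --seed 7 --out results/
```

which chains simulate → preprocess → tanova → segment → backfit → stats
and writes every intermediate artifact plus a manifest.

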