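# naaquant

Tools for studying **calcium-triggered nuclear actin assembly (NAA)** from
fluorescence time-lapse microscopy, plus the companion electron-microscopy
readout of chromatin compaction.

After GPCR stimulation or pharmacological calcium release, mammalian cells
transiently polymerize actin filaments inside the nucleus. Live-cell
experiments read this out with a nuclear actin chromobody (whose signal turns
from homogeneous to strongly heterogeneous as filaments form) together with a
calcium sensor such as GCaMP6f. `naaquant` implements the quantitative core
of that analysis for researchers who want to reproduce, stress-test or reuse
it:

* **`naaquant.simkit`** — a stochastic simulator of two-channel nuclear
  time-lapses. The nucleus is a 2-D disc (diameter 10 µm); filaments
  nucleate as a homogeneous Poisson process (mean inter-arrival 20 s)
  starting 16 s after the stimulus, elongate at 1.5 µm/s until the nuclear
  boundary, persist for an exponential lifetime (mean 50 s), and are
  rendered additively over a homogeneous background with a Gaussian PSF and
  per-pixel Poisson shot noise. A difference-of-exponentials calcium
  transient supplies the second channel (nuclear compartment delayed
  relative to cytoplasm).
* **`naaquant.quant`** — the NAA statistic: the **spatial intensity
  variance** `Var(I)` of the actin-probe pixels inside the nuclear ROI
  (population convention, divide by *N*), min–max normalization of traces
  by their changing range, calcium ROI means, and NAA-positive cell calling
  (post-stimulus peak > baseline mean + *k*·SD, default *k* = 5) with
  percent-positive summaries.
* **`naaquant.temporal`** — onset detection (sustained half-max crossing
  with linear interpolation), the calcium→NAA lag
  `lag = t_onset(NAA) − t_onset(Ca²⁺)`, and the validation that the
  heterogeneity trace rank-correlates with ground-truth filament mass.
* **`naaquant.emchromatin`** — four-class pixel classification of EM nucleus
  images (heterochromatin / euchromatin / nucleolus / background) by
  deterministic k-means over intensity-texture features, and the
  **heterochromatin area fraction** of the nucleus; includes a synthetic
  EM-image generator with known ground truth.
* **`naaquant.workbench`** — YAML-configured, fully seeded pipeline
  (`simulate → quantify → lag → score`) and the `naaquant` CLI
  (`simulate`, `quantify`, `lag`, `score`, `em-synth`, `em-quant`,
  `run-all`).

## Worked example

```python
import naaquant as nq

# simulate one responding cell with the default study conditions
stack, truth = nq.simulate_timelapse()          # 81 frames, 3 s interval
mask = nq.NucleusGeometry().nucleus_mask()

het = nq.heterogeneity_trace(stack, mask)       # spatial intensity variance
ca  = nq.roi_mean_trace(stack, mask)            # nuclear calcium

lag = nq.estimate_lag(nq.normalize_by_range(ca), nq.normalize_by_range(het))
proxy = nq.validate_heterogeneity_proxy(truth, het)
score = nq.score_cell(het, stimulus_time_s=60.0)

print(lag.lag_s)              # 53.49  -> NAA onset ~53 s after calcium onset
print(proxy.spearman_rho)     # 0.937  -> heterogeneity tracks filament mass
print(score.positive,         # True   -> cell called NAA-positive:
      score.peak_raw_heterogeneity,   # 247.6 (peak variance)
      score.baseline_mean,            # 100.5 (shot-noise floor = mean photons)
      score.baseline_sd)              # 1.63
```

The pre-stimulus variance equals the mean photon count (pure Poisson noise,
Fano factor 1); filament formation roughly doubles it, the positive lag shows
NAA following the calcium transient, and the rank correlation confirms the
variance is a faithful proxy for how much F-actin is present.

The same analysis from the shell:

```bash
naaquant simulate --out cell --seed 1
naaquant run-all --out run --seed 1          # full pipeline + manifest
naaquant em-synth --fraction 0.35 --seed 1 --out em.tif
naaquant em-quant --image em.tif --nucleus-mask em.nucleus.tif --out stats.csv
```

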