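# tfbsbench

Training, affinity-based calibration and benchmarking of transcription-factor
binding-site (TFBS) recognition models on ChIP-Seq peaks.

ChIP-Seq reports *where* a transcription factor binds, but only indirectly
*which* short DNA segment inside each peak is the actual binding site, and it
gives no principled score threshold below which predictions are noise. This
package implements, for factors like FoxA2, the full comparative workflow a
regulatory-genomics group would run:

- **Pattern matching** — models trained on a curated alignment of
  experimentally confirmed sites anchored on the degenerate core `TRTTTRYH`
  (R = A/G, Y = C/T): a mononucleotide position weight matrix with
  leave-one-out matrix-length optimization (**oPWM**), a dinucleotide PWM
  over the 16 adjacent-pair letters, and a **SiteGA**-style linear
  discriminant over locally positioned dinucleotide frequencies whose
  feature set is selected by a genetic algorithm.
- **Pattern discovery** — de-novo greedy gapless multiple local alignment of
  the peaks themselves, maximizing the Kullback Discrete Information Content
  (**KDIC**, mononucleotide) or **KDDIC** (dinucleotide), with multi-start
  bootstrapping, optional peak-shape weighting and a jack-knife length
  search.
- **Calibration** — per-model recognition thresholds derived from EMSA
  competition curves: an oligo's EMSA score is the slope of band intensity
  against ln(competitor concentration) normalized to the self-competition
  control; oligos scoring < 0.25 are non-sites and a model's threshold is
  the highest model score among them (a site must score strictly higher).
- **Benchmarking** — recognized-peak fractions, peak-level ROC/AUC and the
  Matthews correlation coefficient against per-peak first-order
  Markov-shuffled backgrounds, pairwise model-combination categories
  (overlapping / single-model / non-overlapping detections), and a χ² test
  of whether non-overlapping joint detections exceed their tenfold-shuffle
  expectation — the signature of heterogeneous homotypic site clusters.
- **Synthetic data** — every input above can be generated with known ground
  truth: Markov background peaks with implanted motif instances (including
  enforced 2-site clusters and coverage heights), aligned training sites,
  and noisy EMSA competition curves whose slope-ratio estimator is exact at
  zero noise.

## Model scores

All models expose a min–max rescaled score in [0, 1] for a fixed-length
window, so thresholds live on a common axis. For a PWM with log-odds
weights `w[j, a]`, a window `x` scores

```
raw(x)   = Σ_j w[j, x_j]            (adjacent pairs for the dinucleotide PWM)
score(x) = (raw − s_min) / (s_max − s_min)
```

and KDIC of a gapless alignment with pseudocounted column frequencies
`f[j, a]` over background `q` is `Σ_j Σ_a f[j,a] · ln(f[j,a]/q_a)` nats.

## Worked example

```python
import numpy as np
from tfbsbench import simulate, pwm, discovery, scan, benchmark

chain = simulate.MarkovChain(0, np.full(4, 0.25))
motif = simulate.default_foxa_motif()                    # TRTTTRYH core
peaks = simulate.implant_sites(
    simulate.generate_background(chain, 200, 200, seed=1),
    motif, {1: 0.5, 2: 0.5}, seed=2).peaks

sites = simulate.generate_training_sites(motif, 53, 3, seed=3)
opwm = pwm.build_mono_pwm(sites)                          # pattern matching
found = discovery.greedy_discover(peaks, 12, seed=4)      # pattern discovery
print(f"KDIC {found.objective:.2f} nats, "
      f"{len(found.occurrences)} occurrences")

background = benchmark.make_shuffled_background(peaks, 1, 1, seed=5)[0]
_, auc = benchmark.roc_curve(peaks, background, opwm)
print(f"oPWM AUC vs shuffled background: {auc:.3f}")
print(f"recognized at 0.8: "
      f"{scan.recognized_fraction(peaks, opwm, 0.8):.2f}")
```

prints (seeds as above):

```
KDIC 5.72 nats, 200 occurrences
oPWM AUC vs shuffled background: 0.703
recognized at 0.8: 0.82
```

i.e. the de-novo alignment keeps all 200 peaks at 5.72 nats of information,
the curated-set PWM separates real from shuffled peaks with AUC 0.70 (the
default 6-bit motif is a deliberately hard target in 200-bp peaks), and 82%
of peaks carry a window scoring above 0.8.

The same workflow is available as a CLI:

```
tfbsbench all --seed 7 --outdir run/
```

writes the synthetic dataset, four trained models, EMSA-derived thresholds,
per-model hit lists (TSV/BED), and a benchmark report (ROC points, CC,
combination categories, χ² cluster test) — all plain text, byte-identical
under a fixed seed.

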