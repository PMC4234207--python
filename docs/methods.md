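# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the design decisions behind `tfbsbench`, in the order data
flows through the pipeline.

## Sequence conventions

Coordinates are 0-based half-open (BED convention) everywhere. Sequences
are uppercase IUPAC; models are defined over A/C/G/T only, and any scoring
window containing an ambiguous letter is skipped rather than imputed.
Reverse-strand scores are computed on the reverse complement, so every
reported hit coordinate refers to the forward strand.

## Pattern-matching models

**Mononucleotide PWM.** Column frequencies are estimated with an absolute
pseudocount spread by background composition,
`f[j,a] = (n[j,a] + pc·q_a) / (N + pc)` with `pc = 1` by default, and
weights are natural-log odds `w = ln(f/q)`. Because the pseudocount is
absolute, weights are not exactly invariant under duplicating the training
set; they are a pure function of column frequencies only when the
pseudocount is scaled with `N`. The log base is irrelevant downstream
because every model's raw score is min–max rescaled to [0, 1] using its
attainable extremes `s_min = Σ_j min_a w[j,a]`, `s_max = Σ_j max_a w[j,a]`.
A matrix whose extremes coincide (all columns uniform) carries no
information and is rejected at build time.

**Matrix-length optimization (oPWM).** Candidate lengths are windows
centered on the alignment core. For each length, a leave-one-out pass
scores every held-out site under the matrix trained on the remaining
sites; the threshold is the largest value passed by at least `tp_anchor`
(default 0.9) of held-out sites, and the false-positive rate is the
fraction of background windows (both strands of per-peak Markov shuffles)
passing that threshold under the full-data matrix. The shortest length
among FP-rate ties wins (parsimony). The fixed 0.9 anchor is one point of
the TP/FP trade-off curve; averaging over several anchors changes the
chosen length by at most the tie-break in our synthetic checks.

**Dinucleotide PWM.** Identical machinery over the 16 adjacent-pair
letters ((L−1) columns). On sites generated column-independently its
rescaled scores correlate > 0.95 with the mononucleotide PWM; its advantage
appears exactly when adjacent positions are dependent.

**SiteGA.** A window is described by K *locally positioned dinucleotide
frequencies* — the frequency of one dinucleotide inside one sub-window
(2–8 bp by default) — and scored by a Fisher linear discriminant
`w ∝ (S + λI)^{-1}(μ_site − μ_bg)` with the intercept at the midpoint of
projected class means. The ridge `λ` is `ridge · trace(S)/K` (relative
scaling keeps it unitless); a singular scatter triggers an automatic
hundred-fold λ escalation, logged. The feature set is selected by a
genetic algorithm (defaults: population 50, 100 generations, crossover 0.7,
mutation 0.1, elitism 2, tournament 3) whose fitness is the leave-one-out
correlation coefficient of the discriminant. LOO refits are computed in
closed form by Sherman–Morrison downdates of the regularized pooled
scatter, making the exact LOO O(nK²) per individual instead of O(nK³·n);
this is what keeps the GA at desk scale. Mutation jitters window bounds by
±2 or redraws the dinucleotide; crossover exchanges features uniformly;
duplicate features are repaired by redraw; the best individual ever seen
is returned, so the fitness trace is non-decreasing by construction.
The final score rescaling uses the training-time raw-score range extended
by a 5% margin and clamps to [0, 1]; windows far outside the training
distribution therefore saturate rather than extrapolate.

## Pattern discovery

The discoverer maintains one occurrence per selected peak (OOPS with
drop) and greedily sweeps: for each peak, every (offset, strand) candidate
is evaluated with that occurrence swapped in, and the peak is dropped when
even its best candidate lowers the objective. Two non-obvious choices:

- **Search objective.** The KDIC formula `Σ_j Σ_a f ln(f/q)` is a pure
  KL sum and is independent of the number of aligned sequences, so under
  OOPS-with-drop it is maximized by shrinking the alignment to a few
  near-identical windows. The search therefore maximizes the size-weighted
  form `N·KDIC` (the multinomial log-likelihood ratio of the alignment
  against background); the marginal gain of adding an occurrence is then
  its log-odds score under the current profile, which is exactly the
  behaviour one wants from an occurrence model with drop. Reported
  `objective` values remain plain KDIC/KDDIC of the final occurrence set;
  the per-sweep trace records the search objective, which is provably
  non-decreasing within a start.
- **Phase-shift move.** Per-peak greedy swaps cannot slide the whole
  alignment register, and shifted registers are strong local optima (in
  our checks, every start locked one column off without this move). After
  sweep convergence the search tries global register shifts of ±1, ±2
  (dropping occurrences that would fall off a peak) and resumes sweeping
  when a shift improves the objective.

Each start seeds the alignment with random occurrences in a bootstrap
subsample (default half) of the peaks; defaults are 10 starts, at most 100
sweeps, pseudocount 1. Peak-shape weighting multiplies an occurrence's
column counts by the peak's max-normalized coverage profile value at the
occurrence midpoint; absent profiles weigh 1. Ties between candidate
offsets break to the smallest offset, '+' strand first, which makes runs
deterministic under a fixed seed. The discovered motif's orientation is
arbitrary: reverse-complementing every peak yields the mirrored occurrence
set with the same objective.

The length search reruns discovery per candidate length and applies the
same leave-one-out FP rule as the oPWM length search to the
discovered occurrence sets.

## EMSA calibration

Band intensity is regressed on ln(concentration) by ordinary least
squares; concentration is the log-transformed variable because competition
series are log-spaced (2, 5, 20 ng). The EMSA score is the competitor
slope divided by the self-competition control slope; negative ratios (a
rising curve, i.e. measurement noise around zero binding) clamp to 0 with
a warning. Affinity classes are non-site (< 0.25, strictly), weak
(0.25–0.75) and strong (> 0.75); the non-site edge corresponds to 1.5×
the assay's technical error and is configurable, with a sensitivity helper
that re-derives thresholds at alternative edges (0.17, 0.34) and reports
the benchmark CC at each. A model's calibrated threshold is the *highest*
model score among non-site oligos, and a prediction passes only with a
strictly greater score — the threshold value itself belongs to a non-site.

## Synthetic data: what it emulates and what it does not

The default ground-truth motif is FoxA-like: a `TRTTTRYH` core whose
consensus-compatible letters carry 0.85 of each column's mass (split per
IUPAC degeneracy) plus two mildly informative flank columns per side
(favoured letter 0.4). This motif carries 6.1 bits of information — a
realistic, deliberately hard target. Peaks are drawn from order-0/1 Markov
chains with add-one smoothing; heights follow a shifted negative binomial
(minimum 15, emulating coverage filters); implants never overlap one
another, are placed uniformly, and strands are uniform. Homotypic-cluster
conditions implant exactly two sites per peak.

Competition curves follow the linear form
`I(c) = I0·(1 − A·s0·ln c)·ε`, `ε ~ lognormal(0, noise_sd)`, with the
control slope scale `s0 = 0.2` chosen so intensities stay positive for
affinities up to 1.5 at 20 ng. Linearity in ln(c) is what makes the
slope-ratio estimator *exactly* unbiased at zero noise — an exponential
competition form would not have that property. An oligo's true affinity is
determined by its sequence through the additive binding-energy model
`A = exp((s_best − s_consensus)/T)` (T = 3), so a random oligo that happens
to contain a strong site is a strong binder, as in the physical assay;
panel classes are rejection-sampled into the affinity bins.

The generators do *not* emulate read-level noise, peak-calling artifacts,
chromatin context, cooperative/tethered binding, or any quantitative
height–affinity relation (heights are independent of site content by
default). Passing tests on this data show the algorithms are correct and
the comparative directions hold under their stated dependence structures —
not that the same effect sizes would be measured on real ChIP-Seq data.

## Benchmarking choices

Shuffled backgrounds are generated per peak (one order-1 chain per peak,
length preserved), not from a pooled chain, so per-peak composition is
retained; ten folds by default. ROC is peak-level: the TP rate is the
fraction of real peaks whose best window passes the threshold, the FP rate
the same on shuffled peaks, swept over the union of observed best scores;
AUC is trapezoidal. CC is the Matthews coefficient; a zero marginal yields
a flagged 0 with a warning. In pairwise combination analysis, category a
(cross-model overlapping pair) takes precedence over d (both models detect,
no overlap); overlap means ≥ 1 shared bp, strand-agnostic; within one model,
hits are pruned greedily best-score-first so same-model hits never overlap.
Per-peak site counts merge cross-model overlapping hits into one site
(connected components of the overlap graph). The chance-overlap statistic
is d/(a+d); expected counts pool all shuffle folds, and the χ² test uses
the raw 2×2 table `[[d, a], [d', a']]`, 1 df, no continuity correction.

## Study conditions of the comparative experiments

- *Dinucleotide advantage*: sites with uniform letter columns but
  P(next = current) = 0.7 between adjacent positions; mono- and
  dinucleotide PWMs trained on 200 sites, AUC on 300 held-out sites vs
  background windows.
- *Distant dependence*: 20-bp sites whose only signal is an identical
  doubled letter (AA/CC/GG/TT) at two distant windows — every
  mononucleotide marginal is uniform, so a PWM is blind by construction
  while SiteGA's windowed dinucleotide features are not.
- *Union gain*: peaks mixing two site subtypes that share a sharp
  (0.97-mass) core but have swapped flank preferences; the matching model
  is trained on curated subtype-A sites, the discovery model on the peaks
  themselves; thresholds sit at the 93rd percentile of shuffled-peak best
  scores (a fixed 7% peak-level FP rate) for both models.
- *Cluster overlap*: 500 peaks with two implants each, subtype drawn per
  implant; one PWM per subtype, same threshold rule. The shared sharp core
  makes chance co-detections on shuffled peaks land on the same window,
  while subtype flanks make real cluster detections complementary — the
  observed non-overlap fraction then exceeds the shuffle expectation.
- *De-novo recovery*: the recovery checks use a high-information variant of
  the default motif (core mass 0.97, flanks 0.7; 12.3 bits). An oracle
  analysis — placing windows by the *true* motif's log-odds argmax — shows
  exact placement in 200-bp peaks tops out near 0.81 at 10 bits, so
  demanding ≥ 80% exact recovery is only meaningful for motifs of roughly
  ≥ 12 bits; below that the limit is information-theoretic, not
  algorithmic.

## Known limitations

- The GA explores K-sets of LPD features with fixed K; it does not search
  over K, and feature interactions enter only through the linear
  discriminant.
- The discoverer models exactly one occurrence per kept peak; multi-site
  peaks contribute their strongest instance during training (clusters are
  handled downstream by scanning, not by discovery).
- min–max score rescaling is sensitive to single extreme matrix cells;
  with pseudocounts this is benign, but imported matrices with hard zeros
  should be pseudocounted before use.
- `chi2_2x2` applies no continuity correction; for very small counts the
  p-values are anti-conservative, and the chance-overlap test flags (rather
  than fixes) tables with an empty joint-detection margin.
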