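# Methods note

This note documents the synthetic signal model behind `casplex.simulate`,
the numerical conventions used throughout the package, and their known
limitations. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## 1. Kinetic signal model

Collateral-cleavage reporter fluorescence in a well is modeled as a
saturating exponential plus white noise, with a per-batch multiplicative
scale:

    RFU(t) = b · ( B + L · A_hi · (1 − e^(−k t)) ) + ε,   ε ~ N(0, σ²)

* `t` — minutes since reaction start; reads every `sample_interval`
  minutes from 0 to `duration`.
* `B` — instrument/background offset shared by every well.
* `A_hi` — full-scale cleavage amplitude of a homozygous-target well.
* `L ∈ {1, f_med, f_low}` — the activation level of the well's channel
  given the genotype: `1` when both alleles carry the channel's target,
  `f_med` for heterozygotes on the allele-dosage-sensitive FAM channel,
  `f_low` when the target allele is absent (residual off-target
  activation).
* `b` — batch scale, drawn once per batch as lognormal with
  `sd(log b) = batch_scale_sd`, applied to **all** wells of the batch
  including standards and NTCs. This is the effect the
  standard-normalized genotype score is designed to cancel, and the
  cancellation is exact in this model (tested to 1e-9 relative).
* `ε` — i.i.d. Gaussian read noise, σ expressed as a fraction of `A_hi`.

Channel level map: FAM follows G1 allele count (0 → low, 1 → med,
2 → high); HEX is high iff any G2 allele is present; TEX is high iff any
non-G2 allele is present (so only G2/G2 is TEX-low). NTC wells are
background plus noise only.

### Parameter defaults

| parameter          | default | units              | rationale |
|--------------------|---------|--------------------|-----------|
| `background`       | 200     | RFU                | typical plate-reader baseline, small vs `A_hi` |
| `amplitude_hi`     | 10000   | RFU                | full-scale saturating signal |
| `rate`             | 0.1     | 1/min              | near-saturation by 30–45 min, matching visual kinetics of Cas13/Cas12 reporter assays |
| `f_med`            | 0.5     | —                  | heterozygote ≈ half target dose; centers het scores in the (0.2, 0.8) band |
| `f_low`            | 0.02    | —                  | small residual off-target activation, well under the 0.05 low threshold |
| `sample_interval`  | 5       | min                | common kinetic-read cadence; 13 reads over 60 min |
| `duration`         | 60      | min                | scoring window end |
| `batch_scale_sd`   | 0.15    | log-units          | realistic day-to-day / lot-to-lot gain variation |
| noise `"low"`      | 0.001·A_hi | RFU σ           | clean research-grade runs |
| noise `"moderate"` | 0.003·A_hi | RFU σ           | routine runs; see calibration below |

### Noise-preset calibration

The noise presets are deliberately calibrated against the max-slope
statistic rather than chosen by eye. The score takes the **maximum** of
~11 consecutive-pair slopes; for a flat (no-signal) channel each slope
difference is N(0, 2σ²/Δt²) and the expected maximum of 11 such draws is
≈ 1.6·√2·σ/Δt. The normalizing standard slope is
`A_hi·(e^(−5k) − e^(−10k))/5 ≈ 0.048·A_hi` per minute at `k = 0.1`. A wt
channel's expected score is therefore roughly

    E[score_wt] ≈ f_low + 1.6·√2·σ / (5 · 0.048·A_hi)

With σ = 0.003·A_hi ("moderate") this is ≈ 0.04, safely below the 0.05
low/high threshold; σ much above ~0.004·A_hi would push noise-only
channels across the threshold and make the decision table structurally
unreliable regardless of assay quality. The presets were fixed from this
analysis before any end-to-end accuracy was measured.

### What the generator does and does not emulate

Emulated: genotype-dependent channel activation with allele dosage on
FAM, saturating enzyme kinetics, additive read noise, multiplicative
batch effects shared by samples/standards/NTCs, technical replicates,
standards (sG1G1, sG2G2) and NTC wells per batch.

Not emulated: lag phases and substrate depletion shapes beyond a single
exponential, pipetting volume errors uncorrelated within a batch,
cross-channel spectral bleed-through, temperature drift within a run,
well-position effects, sample-quality (input RNA/DNA amount) variation,
and dropout/failed wells. Accuracies on this generator are therefore an
upper bound on real-world performance; the generator's role is to
exercise the pipeline's logic, not to predict clinical error rates.

## 2. Scoring and calling conventions

* Max slope uses **consecutive-pair** finite differences, not a fitted
  line, over the closed window [5, 60] min; both endpoints of a pair must
  lie in the window. Negative slopes are allowed (scores are floored at 0
  only after normalization).
* Background subtraction uses the per-batch NTC mean trace when NTCs are
  present, else the trace's first read (`background_mode="auto"`).
* Normalization divides by the **mean** of the standard replicates' max
  slopes; a standard mean below `STANDARD_EPS = 1e-9` raises rather than
  producing unbounded scores.
* Thresholds: FAM wt `< 0.2`, het in the **closed** interval
  `[0.2, 0.8]`, hom `> 0.8`; HEX/TEX low is **strictly** below 0.05. The
  boundary values 0.2, 0.8 and 0.05 therefore resolve deterministically
  (0.2 → het, 0.05 → high).
* QC order: the all-low check (everything below its low threshold) runs
  before table lookup, so a dead reaction reports `INVALID / all-low/QC`
  rather than `no-genotype-combination`.
* Scores are serialized at 4 decimal places; calling from a round-tripped
  file can in principle flip a score sitting within 5e-5 of a threshold.

## 3. Classifier conventions

* Trees are CART (`sklearn.tree.DecisionTreeClassifier`, Gini, unlimited
  depth); each of the 40 trees gets its own bootstrap resample and its
  own random (channel, start, length ≥ 3) intervals, `max(8, ⌈√T⌉)` of
  them, with mean/sd/least-squares-slope features.
* Majority vote with ties broken toward the alphabetically first class
  (classes come from `np.unique`, which sorts).
* Stratified splits compute the per-class validation size as
  `n − floor(train_frac·n)` rather than `ceil((1−train_frac)·n)` because
  `1 − 0.7` is not exactly 0.3 in binary floating point.
* All randomness in `fit`/`evaluate` flows from a single
  `np.random.default_rng(seed)`; child seeds are drawn below 2³¹.
* Evaluation sizes (20 traces per genotype, 100 splits, 40 trees) are
  this package's choices, small enough that the whole protocol runs in
  seconds yet large enough for a stable mean.

## 4. Lateral-flow conventions

* Brightness normalization scales the image so the blank region's mean
  gray equals 210, clips to [0, 255], then rounds to 8-bit **before**
  inversion (255 − g), matching a standard densitometry workflow; the
  band/control intensity ratio is then invariant to global exposure
  changes (tested for gains 0.5–1.5×).
* Band *absence* (low inverted-intensity ratio) indicates target
  detection; detection thresholds follow the reporter enzyme —
  0.4 for LwaCas13a (G1 assay), 0.5 for LbaCas12a (G2 assay).
* Analysis rectangles are 0-based, half-open, must not overlap and must
  cover ≥ 25 px to keep mean grays stable against pixel noise.

## 5. Design-rule conventions

* Spacers are reverse complements of the target window; lengths 28
  (LwaCas13a), 30 (PsmCas13b), 20 (LbaCas12a). Direct-repeat end: 5′ for
  Lwa/Lba, 3′ for Psm. Spacer positions are 1-based counting from the
  DR-proximal end.
* SNP-discriminating guides put the variant at spacer position 3 and add
  synthetic mismatches at singletons and pairs from {1, 2, 4, 5}
  (10 candidates). The mismatch base is the transversion that pairs with
  **neither** allele (A→C, C→A, G→U, U→G).
* Deletion tiling: "full" mode requires the 6-bp deletion entirely inside
  the 30-nt window (30 − 6 + 1 = 25 designs at 1-nt steps); "partial"
  requires ≥ 1 bp overlap (35 designs).
* Cas12a PAMs: {TTTV, TCTV, TTCV, CTTV} with V ∈ {A, C, G}, scanned on
  both strands; minus-strand sites are reported in forward coordinates.
* Primer Tm uses Biopython `Tm_NN` with the DNA_NN3 nearest-neighbor
  table, Na = 50 mM, primer 250 nM (`dnac2 = 0`), salt correction
  method 5 — a standard parameterization for RPA-range oligos. Pairs are
  ranked by forward/reverse Tm agreement; an empty list (not an error)
  signals an infeasible template.

## 6. Limitations

* Synthetic-only validation: no clinical or wet-lab data ship with the
  package, and the generator omits several real noise sources (§1), so
  reported accuracies characterize the algorithms, not the assay.
* The decision table is brittle by construction outside its six expected
  patterns; any unexpected pattern is INVALID rather than a best guess.
* The interval forest is trained per cohort; models are portable via
  `save`/`load` (pickled, format-tagged) but pickles are only safe to
  load from trusted sources.
* Tm values are model estimates; RPA tolerates wider ranges than PCR and
  empirical screening of emitted candidates is still required.
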