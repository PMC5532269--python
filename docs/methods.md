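# Methods

This note documents the models, conventions and defaults behind each stage,
the design choices made where the design was genuinely open, and what the
synthetic data does and does not emulate.

## Study design and data model

All analyses assume a dense bulk RNA-seq time course: `n_timepoints = 21`
samples spaced `dt_hours = 6` apart (0–120 h) in `n_replicates = 2`
biological replicates — 42 libraries. Counts are normalised to CPM
(counts per million; per-sample library size) and transformed as
y = log2(CPM + 0.5). The prior count 0.5 bounds the transform at low
expression; no precision weights are applied. A gene is "expressed" if its
CPM exceeds 1 (strictly) in at least two libraries. Most statistics operate
on the **replicate-mean profile**: the 21-point average of y over
replicates; replicates are never concatenated along the time axis.

Sub-daily structure is scored per gene as the RMS residual from a loess
smooth of the replicate-mean profile — a local *linear* fit with tricube
weights and a 24 h bandwidth (≈ 5 points at 6-hourly sampling), without
robustness iterations: robust re-weighting treats exactly the brief
excursions being scored as outliers and absorbs them. Genes in the top 5%
of deviation are flagged.

## Moderated differential expression and the slRNA screen

Per gene, a one-way layout over time points gives group means and a pooled
residual variance s²_g with d = 42 − 21 = 21 df. Hyperparameters of the
scaled-F marginal (prior df d₀, prior variance s₀²) come from closed-form
moments of z = log s²:

* E[z] = log s₀² + [ψ(d/2) − log(d/2)] − [ψ(d₀/2) − log(d₀/2)]
* Var[z] = ψ′(d/2) + ψ′(d₀/2)

so d₀ = 2·ψ′⁻¹(Var̂[z] − ψ′(d/2)) (Newton inversion of the trigamma).
When the observed Var̂[z] does not exceed ψ′(d/2) there is no evidence of
gene-level variance spread; the documented sentinel is d₀ = ∞ with
s̃² = s₀² for every gene. The moderated t for a contrast of two time-point
means uses s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) and d₀ + d df. The closed-form
moment estimator was chosen over iterative maximum likelihood because it is
deterministic, a two-line computation, and accurate at these scales (the
test suite verifies s₀² recovery within 5% at 5,000 genes and reasonable
d₀ recovery from conjugate-prior draws).

Multiple testing: Benjamini–Hochberg within each contrast across genes; the
adjustment scope is a package choice (the screen's inventors did not state
one).

The slRNA screen evaluates, for each window start w ∈ {0, 24, 48, 72, 96}:
the three intra-window contrasts w vs w+6, w+12, w+18, and all 15 pairwise
contrasts among {0, 24, …, 120}. A gene is an slRNA iff ≥ 1 intra-window
contrast has adjusted p strictly below α = 10⁻⁴ while **no** daily pairwise
contrast does. "Differentially expressed for more than half of the window"
is operationalised as ≥ 2 of the 3 measured sub-daily offsets — the smallest
majority of measurable sub-window time. Each window is anchored at its own
start (w vs w+6 etc.), since the screen is applied per 24 h period.

Note a deliberate consequence of the definition: a gene cycling with a
period that divides 24 h takes identical values at all 24-hourly samples
and *is* an slRNA as well as a cycRNA. The simulator's truth tables encode
this (planted 24 h sinusoids count toward slRNA truth).

## Periodogram cycRNA detection

Each replicate's profile is piecewise-linearly interpolated onto 120 evenly
spaced points spanning [0, 120] h (Δt = 120/119 ≈ 1.008 h) — linear rather
than spline because 21 support points give splines room to overshoot. After
mean removal, the periodogram P(k) = |DFT(x)ₖ|²/N is evaluated at
k = 1…60 and the dominant period is N·Δt/k* at the power-maximising bin k*.
On this grid the bin nearest a 24 h rhythm (k = 5) reads as 24.2 h.
Only the mean is removed: slow monotone trends land at k ≤ 2
(periods ≥ 60 h), which the strict < 36 h ceiling (k ≥ 4) already excludes,
so no polynomial detrending is applied. A cycRNA requires the *identical*
dominant bin in both replicates (no tolerance window — a deliberate,
conservative choice) and period < 36 h. Constant profiles yield an
undefined-period sentinel, never an exception.

With 21-point noise interpolated to 120 points, neighbouring samples are
strongly dependent; dominant bins of pure-noise genes concentrate at low k,
and the replicate-agreement rule leaves a ~3–5% false-call rate among
aperiodic controls at the default conditions (measured by the acceptance
script), against ≥ 90% detection of planted 24 h sinusoids of amplitude
1 log2 unit.

## Lagged cross-correlation

Sign convention: **positive lag = the source leads the target** (required
for driver semantics; stated in output headers). For lag ℓ ∈ [−L, +L],
r(ℓ) is the Pearson correlation of the overlapping segments x[0:N−ℓ] and
y[ℓ:N]; no padding or wrap-around. Ties break toward the smallest |ℓ|, then
toward positive ℓ. Lags whose overlap has zero variance are skipped; if all
are, the result is an undefined sentinel.

* TF→target delays run on the native 21-point grid (lag quantum 6 h,
  default L = 3 samples = 18 h) with passing threshold r > 0.8, compared to
  per-lag 95% quantiles of 500 random same-size gene selections.
* TF activity profiles are the per-time-point median over the target set of
  y(t) − y(0) on replicate-mean profiles (0 at t = 0 by construction).
* lncRNA target inference runs on 100-point interpolated profiles
  (lag quantum ≈ 1.2 h), lags restricted to [0, 18 h] so only lncRNA-led
  relationships count; default threshold ±0.9 with 0.8 available — both
  values are in circulation for this analysis and the choice is exposed as
  configuration. Candidate lncRNAs are the top 50 by the sum of two
  descending ranks (median expression; variance), truncated from the union
  of the two top-50 lists.

## Genome-layout analyses

* **Bidirectional pairs**: opposite strands, head-to-head (the minus-strand
  gene's TSS at or upstream of the plus-strand gene's TSS — divergent
  transcription, not merely opposite strands at close range), TSS distance
  strictly < 2,000 bp; distance 0 (coincident TSSs) is admitted. Greedy
  nearest-distance matching makes pairing a matching (each gene in ≤ 1
  pair). Pair statistics (temporal r, |Δ median expression|, biotype class)
  are compared against seeded random gene pairs.
* **Drivers**: the pair's best-lag correlation is computed once (a → b);
  a positive lag with r above threshold makes the minus-strand member the
  driver, negative the plus-strand member; lag 0 or sub-threshold peak
  correlation → no driver.
* **Co-expression regions**: per chromosome, expressed genes are ordered by
  TSS; "contiguous" means consecutive *among expressed genes*, not in the
  full annotation. A region is a maximal run in which every adjacent pair
  of neighbours has replicate-mean temporal r strictly > 0.5 (neighbour
  chain, not all-pairs), with ≥ 5 genes (inclusive bound). The region span
  runs from the first member's TSS to the last member's gene end. Region
  mean profiles (per-gene-centred) are correlated (> 0.5) to group regions
  into connected-component modules labelled increasing/decreasing by the
  end-minus-start change.
* **TADs** are consumed as BED intervals; a region is "contained" iff its
  interval is a subset of a single TAD interval (both 0-based half-open),
  else "spans-boundary" or "no-overlap". A wholesale chromosome-naming
  mismatch raises an error listing both naming styles.

## Novel-lncRNA filter

Steps in the published order (each a pure per-transcript predicate, so the
sequence equals the conjunction — asserted on random fixtures): class code
∈ {j, i, o, u, x}; ≥ 2 exons; length ≥ 200 nt and longest ORF ≤ 300 nt;
coding potential ≤ 0 (scores are inputs, CPC sign convention; missing
scores pass through with a warning). ORF search is sense-strand only
(assembled transcripts are stranded) across the three frames: an ATG
extended to the first in-frame TAA/TAG/TGA, length counted in nucleotides
*including* the stop codon — the 300 nt ≈ 100-codon convention is ambiguous
either way, so the inclusive reading is declared and constant. A codon
containing N cannot act as start or stop. Boundary semantics are strict as
printed: removal applies to length < 200 nt, ORF > 300 nt, score > 0.

## Synthetic data

The simulator emulates the study design, not any particular dataset: counts
are negative binomial with gene-common dispersion φ (variance m + φm²)
around mean CPM profiles assembled from planted log2-scale effects, with
per-replicate biological noise (log2 sd `noise_sd`) and log-normal library
sizes (CV 10%) around `library_size_mean`. Defaults, chosen once for
testability at desk scale:

| parameter | default | rationale |
|---|---|---|
| `n_timepoints` × `dt_hours` | 21 × 6 h | the emulated design (0–120 h) |
| `n_replicates` | 2 | biological duplicate |
| `library_size_mean` | 5×10⁶ | keeps counting noise well below biological noise |
| `nb_dispersion` | 0.005 | mild technical overdispersion |
| `noise_sd` | 0.2 log2 | standard test condition for all recovery properties |
| `baseline_log2_cpm` ± sd | 6 ± 1 | moderately expressed genes |
| pulse amplitude / duration | 1.5 log2 / 18 h | sub-24 h, detectable at α = 10⁻⁴ |
| sinusoid amplitude / period | 1.0 log2 / 24 h | cycRNA-class plants |
| block length / amplitude | 6 genes / 1.0 log2 sd | positive-control regions |

Pulses are raised cosines inside a window contained in one 24 h period, so
expression returns *exactly* to baseline at the window edges and 24-hourly
samples see no change — the slRNA concept by construction. Genes sit on
three synthetic chromosomes at ~10 kb spacing with jitter; head-to-head
pairs are placed at exactly the requested TSS distance, blocks on
consecutive slots, and every planted unit is spread evenly among baseline
fillers so that no two planted signals are adjacent by accident. The
no-signal calibration scenario uses zero dispersion and deep libraries so
that counting noise is negligible and the moderated-t assumptions hold —
the regime in which a type-I-rate check is interpretable.

Not emulated: read-level data (FASTQ), isoform structure, batch effects,
real genome annotation (gene density, overlapping loci), expression-
dependent variance trends, and correlated replicate artefacts. Passing the
recovery tests therefore demonstrates correctness of the detectors under
the stated noise model, not performance on any real dataset; the headline
gene counts of real studies depend on full-depth data and annotation
versions and are out of scope at desk scale.

## Problem sizes and determinism

The test suite and acceptance script run each scenario at desk scale,
chosen as the package's standard validation conditions: 2,000 genes for the
slRNA, cycRNA and block scenarios (50 pulses; 30 sinusoids with 500
aperiodic controls; 10 blocks of 6), 600 genes for the lag scenario
(30 targets at +6 h), 400 for pairs (12 pairs), 5,000 for the global null.
All randomness flows from explicit seeds through numpy `SeedSequence`
spawning; k-means uses 25 seeded restarts; PCA uses deterministic SVD with
a fixed sign convention. Pipeline outputs are written with fixed float
formatting, making a rerun under the same seed byte-identical (asserted in
the test suite).

## Known limitations

* The empirical-Bayes moment estimator assumes a common variance scale; a
  strong expression–variance trend (real RNA-seq at low counts) would call
  for a trended prior, which is not implemented.
* Replicate agreement for cycRNAs requires the identical Fourier bin;
  rhythms falling between bins, or at periods near the 36 h ceiling, can be
  missed in one replicate.
* The lagged-correlation screen has a 6 h lag quantum on the native grid;
  delays shorter than one sampling interval are indistinguishable from
  lag 0 (hence "driver none" for identical profiles).
* Greedy nearest-distance pair matching is order-stable but not globally
  optimal when three or more candidate genes chain within the window.
* With smooth, strongly correlated planted classes packed densely (the
  multi-signal demo at small gene counts), distinct planted signals can
  legitimately merge into one co-expression run; block-recovery guarantees
  are therefore stated for the dedicated block scenario.
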