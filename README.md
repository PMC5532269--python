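# teb — temporal embryoid-body transcriptomics

`teb` is an analysis toolkit for **dense RNA-seq time courses** of the kind
used to profile spontaneously differentiating mouse embryonic stem cells:
21 time points sampled every 6 hours over 0–120 h, in biological duplicate.
At this temporal resolution whole classes of expression behaviour become
visible that 24-hourly sampling cannot resolve, and `teb` implements the
corresponding detectors as a tested, reusable pipeline:

* **slRNAs (short-lived RNAs)** — genes significantly differentially
  expressed *within* a 24 h window (w vs w+6/+12/+18 h) but at **no**
  comparison between 24-hourly time points;
* **cycRNAs (cycling RNAs)** — genes whose interpolated profiles share the
  same periodogram-dominant period (< 36 h) in both biological replicates;
* **lagged regulator→target inference** — the time delay at which a
  transcription factor's (or lncRNA's) expression changes best predict its
  targets', with a random-gene-set null envelope;
* **bidirectional promoter pairs** — head-to-head gene pairs with TSSs
  < 2,000 bp apart, their temporal correlation and apparent "driver" gene;
* **genomic co-expression regions** — runs of ≥ 5 contiguous expressed genes
  whose neighbours correlate at r > 0.5 over time, tested for containment in
  topologically associating domains (TADs);
* a **three-step novel-lncRNA filter** for assembled transcripts (class
  codes j/i/o/u/x, multi-exonic, ≥ 200 nt, ORF ≤ 300 nt, coding potential ≤ 0).

Because the analyses are bespoke, the package ships a first-class
**synthetic-data module** that generates negative-binomial counts with
planted pulses, sinusoids, lagged pairs, head-to-head pairs and contiguous
co-expression blocks — so every detector can be validated against known
truth. It is aimed at computational biologists analysing their own dense
time courses or benchmarking detectors for transient/cyclic transcription.

## The statistics in brief

**Differential expression.** Each gene is a one-way layout over time points
on y = log2(CPM + 0.5). Per-gene residual variances s²_g (d residual df) are
shrunk by empirical Bayes: marginally s²_g ~ s₀² F(d, d₀), and (d₀, s₀²) are
estimated in closed form from the mean and variance of log s²_g using
digamma/trigamma moments. The moderated statistic for contrast b − a is

    t_g = (ȳ_gb − ȳ_ga) / √( s̃²_g (1/n_a + 1/n_b) ),
    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),   df = d₀ + d,

with Benjamini–Hochberg adjustment across genes within each contrast.
The slRNA screen requires an adjusted p < 10⁻⁴ at ≥ 1 intra-window offset
and none among all 15 pairwise 24-hourly contrasts; "sustained" slRNAs are
significant at ≥ 2 of the 3 offsets of one window.

**Periodicity.** Each replicate's 21-point profile is linearly interpolated
to 120 evenly spaced points over [0, 120] h, mean-centred, and the
periodogram P(k) = |Σₙ xₙ e^(−2πikn/N)|²/N computed for k = 1…60. The
dominant period is N·Δt/k at the power-maximising bin; a cycRNA needs the
identical dominant bin in both replicates and a period strictly below 36 h.

**Lagged correlation.** For integer lag ℓ ≥ 0, r(ℓ) is the Pearson
correlation of x[0:N−ℓ] with y[ℓ:N] (source leading; no padding). The best
lag maximises r (ties → smallest |ℓ|, then positive). TF→target delays use
the native 6 h grid (r > 0.8); lncRNA target inference uses 100-point
interpolated profiles with lags restricted to [0, 18 h] and r thresholds
±0.9 (0.8 available as a preset).

## Worked example

Simulate the default multi-signal study (800 genes, every planted class at
once), run the full pipeline, and score recovery against the planted truth:

```python
from teb.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="demo", seed=5,
                                     simulate=True, sim_n_genes=800))
print(report.to_frame().to_string(index=False))
```

prints

```
          class  tp  fp  fn  precision  recall
         cycrna  20  16   0   0.555556     1.0
         lagged  28  27   0   0.509091     1.0
          pairs  10   0   0   1.000000     1.0
        regions   8   0   0   1.000000     1.0
regions_relaxed   8   0   0   1.000000     1.0
          slrna  54   0   6   1.000000     0.9
```

Reading this: all 20 planted 24 h sinusoids are called cycRNA (the extra 16
calls are other planted dynamic genes whose replicate periodograms happen to
agree — in this dense multi-signal study only ~2% of plain noise genes are
false calls); all 10 head-to-head pairs and all 8 contiguous blocks are
recovered exactly; 54 of 60 slRNA-class genes (40 pulses + 20 sinusoids
whose period divides 24 h) pass the strict adjusted-p < 10⁻⁴ screen with no
false positives. Per-stage outputs (`de.tsv`, `slrna.tsv`, `cycrna.tsv`,
`pairs.tsv`, `regions.tsv`, `lncrna_targets.tsv`, …) are written to `demo/`.

The same stages are available on the command line:

```bash
teb simulate --outdir demo --seed 5 --n-genes 800
teb de      --counts demo/counts.tsv --meta demo/meta.tsv --out de.tsv --slrna-out slrna.tsv
teb cycrna  --counts demo/counts.tsv --meta demo/meta.tsv --out cyc.tsv
teb regions --counts demo/counts.tsv --meta demo/meta.tsv --annotation demo/annotation.gtf --out regions.tsv
teb run     --config cfg.yaml   # full pipeline from a YAML config
```

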