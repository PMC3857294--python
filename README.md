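# chipbias

Simulation-driven diagnostics of background artifacts in yeast ChIP-seq:
**expression bias** (spurious enrichment over highly transcribed gene
bodies, present even in negative controls), **nucleosomal periodicity**
(coverage oscillation at the nucleosome repeat caused by preferential
shearing of linker DNA), **amplification magnification** (library PCR
exaggerating whatever representation bias the immunoprecipitated material
already carries), and the downstream consequence that matters most in
practice: **false-positive differential binding targets** that track
transcriptional induction rather than real binding, and how the choice of
normalization control — sequencing *input* versus a *mock ChIP* — changes
how many of them survive.

The package is for people analysing (or simulating) ChIP-seq in compact
genomes who want to ask: how much of my gene-body signal is background,
which control removes it, and what would my differential-binding analysis
report if there were *no* true binding change at all?

## The model

Everything is driven by a mechanistic fragment simulator on a toy genome
(200 genes, 20 divergent promoter pairs by default; ~15% of genes induced
≥ 5× in a "treatment" condition). Each sample draws fragments from a
three-component mixture:

* **uniform background** over the genome;
* **expression-bias component** — a gene is selected with probability
  ∝ TR<sup>γ</sup> (TR = per-gene transcription-rate proxy, the quantity a
  RNAPII Ser5P ChIP measures) and the fragment midpoint is uniform within
  its body. Mixture weight *w*<sub>expr</sub> is 0.50 for mock ChIP, 0.15
  for input, 0.30 for a factor ChIP, 0.90 for the RNAPII-style sample;
* **true-binding component** (factor ChIP only) — Gaussian around promoter
  binding sites, with condition-responsive affinity at induced genes and an
  exponential tail (length scale 500 bp) into the induced divergent
  partner's gene body.

Independently, both fragment ends are relocated into the nearest nucleosome
linker with odds (linker_pref − 1):1 (repeat 165 bp, +1 dyad at TSS + 60 bp,
20-bp linkers), and libraries can be "amplified" by repeated
coverage-weighted resampling with weight ∝ coverage<sup>α−1</sup>.

On top of the simulator, the analysis stack provides binned RPM coverage
(10-bp bins, 75-bp read extension), TSS metagene profiles with 95% CIs,
reads/kb/million gene-body occupancy and top-*k* rankings, scalar bias
statistics (high-TR/other occupancy ratio; Spearman ρ of occupancy vs TR),
lag-domain periodicity estimation, divergent-promoter asymmetry scores,
simulated standard-curve qPCR, and a simplified, fully specified
peak-caller (sliding-window Poisson test against a MACS-style local λ, BH
correction) plus an MA-normalization differential-binding step.

## Worked example

```sh
python analysis/01_simulate_dataset.py     # writes results/dataset/
python analysis/03_bias_and_periodicity.py
python analysis/06_differential_binding.py
```

`03_bias_and_periodicity.py` prints (seed 1):

```
     sample  expr_bias_ratio  expr_bias_rho  period_bp  period_amplitude
      input            1.586          0.818      160.0             0.602
       mock            3.978          0.944      160.0             0.631
    tf_chip            3.067          0.802      170.0             0.267
rnapii_chip           15.005          0.973      160.0             0.621

correction    rho
      none  0.758
     input  0.534
      mock -0.158
-> mock subtraction removes more TR coupling

periodicity over low-TR genes: amplitude 0.601 -> 0.000 after input
subtraction (100% drop)
```

Reading: every sample — including both negative controls — is enriched over
the 100 highest-TR gene bodies (ratio > 1), mock more than input (4.0 vs
1.6); the factor ChIP's occupancy rank-correlates with transcription rate
at ρ = 0.76 until a control is subtracted, and mock subtraction removes
that coupling almost completely while input subtraction leaves ρ = 0.53.
All samples oscillate at ~160 bp ≈ the 165-bp nucleosome repeat, and
subtracting the input track removes that periodicity from the RNAPII-style
track.

`06_differential_binding.py` then runs the four-pair design (ChIP vs
input-control and ChIP vs mock-control, two conditions, two stringencies)
and prints a summary in which the mock branch yields fewer
differential-binding targets and a lower percentage of them inside gene
bodies at both stringencies, while ~90% of the gene-body DBTs fall in the
upper-right (induced-RNAPII, induced-expression) quadrant — apparent
binding that is nothing but condition-specific expression bias.

There is also a thin CLI (`chipbias simulate|profile|diagnose|dbt|run`)
over the same library functions for running the steps on BED + GFF3 + TR
tables from disk.

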