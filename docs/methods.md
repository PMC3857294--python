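# Methods

## What is being modelled

ChIP-seq in budding yeast routinely shows enrichment over the bodies of
highly transcribed genes in samples where no true binding is expected —
mock immunoprecipitations, sequencing input, ChIPs of cytoplasmic
proteins. This package treats that *expression bias*, together with
linker-shearing periodicity and PCR magnification, as generative
mechanisms: a simulator encodes them explicitly, and the analysis layer
quantifies how they surface in profiles, rankings, peak calls and
differential-binding comparisons, and how well each control type removes
them. Nothing here attempts to decide *why* open chromatin is
preferentially recovered (crosslinking proximity, antibody
cross-reactivity, solubility); the simulator is agnostic about mechanism
and only reproduces the observable consequences.

## Synthetic genome

`build_toy_genome(n_genes=200, n_divergent_pairs=20, seed)` lays out genes
of 400–2000 bp with ≥ 500 bp intergenic spacers on two chromosomes
(~420 kb total), all coordinates multiples of 10 so gene limits align with
the 10-bp analysis bins. Twenty divergent pairs share a 200–390 bp
promoter between outward-facing TSSs. Per-gene transcription rates (TR,
arbitrary units) are log-uniform over three decades. A designated "Up"
subset — one member of every divergent pair plus evenly spaced singles,
~15% of genes — draws its basal TR from the middle of the range
(10^1.3–10^2.3) and is multiplied by 5–20× under the treatment condition,
placing induced genes near the top of the treatment TR distribution, which
is how stress-induced genes behave relative to constitutively high-TR
genes. All other genes keep identical TR in both conditions, so the two TR
vectors are strongly but not perfectly rank-correlated.

Binding sites sit at every shared divergent promoter midpoint and at
100 bp upstream of every fifth single gene, with log-normal affinities.

Nucleosomes are phased from each TSS: the +1 dyad at TSS + 60 bp,
successive dyads every 165 bp (the repeat), each particle protecting
145 bp, leaving 20-bp linkers; dyads are tiled while they fall inside the
gene body (the +1 particle may protrude slightly past the TSS). Intergenic
DNA is unphased. This is a deliberate simplification — real nucleosome
maps drift out of phase along the gene — which makes metagene periodicity
*stronger* than in real data; what passing tests show is that the
estimator detects phased periodicity and that subtraction removes it, not
that real phasing has any particular amplitude.

## Fragment mixture

For a sample of kind *k* in condition *c*, each of `n_fragments`
(default 2 × 10⁵) fragments independently draws a component:

* background (weight 1 − w_expr(k) − w_peak(k)): midpoint uniform over the
  genome;
* expression bias (w_expr: input 0.15, mock 0.50, factor ChIP 0.30,
  RNAPII-style 0.90): gene ∝ TR_c^γ (γ = 1 by default; whether the bias
  saturates in TR is unknown, so γ is exposed rather than fixed), midpoint
  uniform in the gene body. Uniform-in-body (rather than 5′-weighted)
  matches the flat elevation of observed profiles and is the simplest
  choice;
* true binding (factor ChIP only, w_peak = 0.40): site ∝ affinity,
  midpoint Gaussian (σ = 50 bp) at the site. Sites of genes induced in the
  simulated condition get a 4× affinity boost (condition-responsive
  recruitment). When the induced gene belongs to a divergent pair, a
  fraction `tail_weight` (0.3) of that site's fragments instead fall along
  a truncated-exponential tail (scale `tail_decay` = 500 bp) inside the
  induced partner's body — the binding summit stays dominant, the tail
  tapers toward the 3′ end. The tail exists only under treatment, so the
  same genome simulated under control is the symmetric negative control.

Fragment lengths are truncated normal (200 ± 40 bp, minimum 50). Both
fragment ends are then relocated to the nearest linker (within one
repeat) with probability (linker_pref − 1)/linker_pref — odds
(linker_pref − 1):1 of relocating versus staying — so linker_pref = 1 is
exactly a no-op and the default 5 relocates 80% of eligible ends. The
relocation applies to every component: shearing does not know where a
fragment came from.

One RNG stream per (config seed, sample id); nothing touches global
random state.

## Read-style coverage

Analyses that look at profile *shape* (metagene, periodicity, peak
summits) use single-end "reads": each fragment contributes its
strand-chosen end, extended 75 bp 3′-ward, counted into 10-bp bins with
every overlapped bin incremented. This mirrors standard single-end ChIP
processing. The distinction matters numerically: whole-fragment coverage
convolves end positions with a ~200-bp box, which attenuates a 165-bp
oscillation essentially to zero (the box-filter transfer function crosses
zero near its width), while a 75-bp extension preserves ~70% of the
amplitude. Per-gene *occupancy* (reads per kb per million mapped) instead
counts fragment midpoints — one count per fragment — so its units match
read counting; RPM normalization divides bins by the mapped total × 10⁶.
Subtraction of an RPM control is binwise and floored at zero, since
negative coverage has no downstream interpretation.

## Diagnostics

**Expression bias** is reported as the ratio of mean occupancy of the
top-100-TR set over the complement, plus the genome-wide Spearman ρ of
occupancy vs TR. These are this package's operationalization of a
phenomenon usually shown visually; reports label them as such. ρ is
rank-based, hence invariant to monotone distortions of occupancy.

**Periodicity** detrends the gene-set mean TSS profile with a centred
moving average spanning the middle of the lag range (100–260 bp), then
maximizes the normalized autocorrelation r(ℓ) = Σxₜxₜ₊ℓ/Σxₜ² over the
range. Lag-domain estimation is preferred to a spectrum because the
1.5-kb window holds only ~9 repeats. A permutation helper returns the 95th
percentile of the amplitude under bin shuffling as a significance bound.
For before/after-subtraction comparisons the window is 1.2 kb restricted
to genes long enough to contain it, over the low-TR tercile (where
control-level signal dominates); unrestricted windows run past short
genes into neighbouring loci and contaminate the residual.

**Correction comparison** computes ρ(gene-body signal, TR) for the
uncorrected track and after input/mock subtraction and reports which
control shrinks |ρ| more.

**Divergent asymmetry**: per pair with exactly one Up member, integrate
RPM over the first 1 kb of each partner's body downstream of the shared
promoter; score = (AUC_up − AUC_other)/(sum) ∈ [−1, 1], mean ± SE over
pairs. 1 kb fits the toy gene lengths while capturing most of a 500-bp
tail.

**qPCR**: template = fragments fully containing the 80–100 bp amplicon;
Ct = intercept + slope·log₁₀(template) + N(0, 0.15 cycles), three
technical replicates, censored at cycle 40. Relative quantification
inverts the curve and reports log₂ fold change of mean target over mean
control quantity, with sd over biological replicates.

**Amplification** resamples the library to its original size with weight
∝ (midpoint coverage in 100-bp bins)^(α−1), repeated per round. α = 1 or
0 rounds is the identity in distribution. This is the minimal monotone
model of PCR favouring well-represented loci; it makes no attempt at
duplicate-level realism.

## Peak calling and differential binding

The peak caller slides a 300-bp window at 10-bp steps, counts ChIP
fragment midpoints, and tests against λ = max(genome-wide expected rate,
control-local rate in the same window, 1-kb and 10-kb spans, scaled to
ChIP depth) with the Poisson upper tail, BH-corrected over all windows
genome-wide. The window-sized local term exists because sub-kilobase hot
loci are otherwise diluted by the 1-kb average, which destroys null
calibration on gene-dense genomes (this mirrors the peak-size local λ in
standard callers). Overlapping significant windows merge; the summit is
the densest bin; fold enrichment is the best window's k/λ. Peak lists are
nested across thresholds by construction.

Differential binding follows the MA scheme: candidate regions are the
merged union of the two conditions' peak lists, tiled to ≤ 500 bp so a
promoter summit and adjacent gene-body signal are scored separately; a
region is a *common peak* if it overlaps a peak from each list. A
least-squares line M = a + b·A fitted on common peaks recentres all
candidates (common-peak mean of the recentred M is exactly zero);
candidates where the rescaled control meets or exceeds the treatment are
ignored, the rest are Poisson-tested against the rescaled control and
BH-corrected, with a default −log₁₀(q) ≥ 5 cut-off. DBT summits are
classified gene_body (inside [start, end)), promoter (≤ 500 bp upstream of
a TSS, strand-aware — unspecified in the field, 500 bp is conventional for
yeast's compact genome), or intergenic. The OLS fit is deliberately the
simplest faithful surrogate; when differential regions are a large,
A-correlated fraction of the common peaks it partially absorbs them, a
known hazard of the approach.

The four-pair design runs ChIP-vs-input and ChIP-vs-mock branches at low
(q = 2) and high (q = 20) stringency, then MA-normalizes treatment against
control *within each branch* and summarizes DBT counts and gene-body
percentages. Because the mock control carries the expression bias itself,
bias-driven gene-body candidates are suppressed at the peak-calling stage
in the mock branch, which is the entire mechanism behind the branch
ordering.

## Problem sizes and numerical choices

Default analyses use 200 genes / 2 × 10⁵ fragments per sample; the
four-pair comparison uses 10⁵ per sample and five replicate genomes; null
calibration uses a 4 × 10⁴-fragment chip against a 4×-deeper control (a
deep control is standard practice, and conditioning the Poisson test on an
estimated λ is only calibrated when the control estimate is much less
noisy than the chip count). q-values are floored at 10⁻³⁰⁰ before taking
−log₁₀. Count-based M/A use 0.5 pseudocounts. Ties in top-k rankings break
by lexical gene id, making every ranking deterministic. All TSV outputs
carry the parameter hash of the producing run and are byte-reproducible
for a fixed config.

## Limitations

The generator emulates the *structure* of the artifacts, not the full
texture of real data: no mappability or GC effects, no sequence-level
errors, perfectly phased nucleosomes, a single global TR axis rather than
pathway-structured regulation, and true binding restricted to promoter
point sites. Consequently, passing tests demonstrate that the estimators
and the control-choice logic behave correctly when the named mechanisms
are present in known amounts — they do not certify effect sizes on real
libraries. Exact reproduction of the original study's deposited-data
counts is likewise out of scope; the qualitative orderings (mock > input
bias, mock branch yielding fewer and less gene-body-concentrated DBTs,
periodicity removed by input subtraction, amplification magnifying fold
changes) are the reproduced objects.
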