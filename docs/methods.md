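# Methods

## Pipeline statistics

**Presence filter.** A probe is retained when *all* of its detection flags
in at least one sample group (tumor or normal) are 'P'. 'M' (marginal) is
treated as not detected — the strict reading of a "100% present" rule.
Matrices without flags skip the stage.

**Quantile normalization.** Columns are mapped onto the reference vector
of per-rank cross-column means. Within-column ties receive the mean of
their tied rank slots' reference values, so equal inputs stay equal. Two
exactness caveats follow from the tie rule: the "all columns share one
sorted vector" property and idempotence are exact (≤ 1e-12) only for
tie-free input; columns with different tie patterns legitimately differ in
their tied entries. Ranks are always preserved. Note also the usual
caveat that quantile normalization attenuates genuine fold changes when a
large, directionally coherent fraction of the transcriptome changes; at
the simulator's defaults (~15% of genes shifted one way) the attenuation
is mild but visible in the recovered log2FCs.

**Moderated paired t.** For gene g with n paired log2 ratios, s²_g on
d_g = n−1 df, the prior (d₀, s₀²) is estimated by moment matching on
log s²_g: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of
var(e) over ψ′(d_g/2) determines d₀ via trigamma inversion (Newton, with
the asymptotic endpoints 1/y and 1/√y for extreme arguments), and s₀²
follows from mean(e). If the observed spread of log s²_g does not exceed
chi-square sampling noise the moment equation has no positive root and the
prior degenerates to d₀ = ∞ (all variances shrunk to s₀²) — the correct
limit for homogeneous variances and the reason the null simulation is
calibrated. Genes with s²_g = 0 are excluded from hyperparameter
estimation; an all-zero gene reports t = 0, p = 1. p-values are two-sided
from t(d₀ + d_g). The dual differential threshold is |log2FC| ≥ 1
(inclusive — a linear fold change of exactly 2 counts) and p < 0.05
(strict, unadjusted: the screening threshold, not an FDR).

Count-based differential models (negative-binomial tools built for
sequencing read counts) are out of scope by design: single-channel array
intensities are continuous and approximately log-normal, which is the
moderated t's home turf.

**Correlation filter.** Pearson r over all samples (tumor and normal
pooled — three samples per condition are unusable alone), two-sided p via
t = r√(n−2)/√(1−r²) on n−2 df. Both filters are strict inequalities; at
n = 6 the smallest significant |r| is t₀.₀₂₅,₄/√(t² + 4) ≈ 0.8114, so the
p criterion strictly dominates the |r| > 0.7 criterion. Constant genes
are skipped with a logged warning.

**Enrichment.** Upper-tail hypergeometric P[X ≥ k] (scipy's survival
function, computed in log space internally; underflow clamped to the
smallest positive float), BH step-up FDR per category across the tested
sets. Sets are intersected with the universe; k = 0 rows are never
emitted (they carry p = 1 and only bloat rankings, so they are also never
counted as tests). The pipeline's background universe is the measured
*coding* genes, because every query (a DEM list or a DEL's co-expressed
DEM set) is a coding-gene list; counting lncRNA annotations in K or N
would inflate set sizes with members a query can never contain. A
per-category measured-and-annotated restriction and the DAVID-style EASE
variant (test k−1) are available as options.

**Ranking and frequency counting.** Function predictions and trans
predictions are pooled across lncRNAs, stably sorted by (p, lncRNA id,
set id), ranked, and truncated to the top 500. Frequencies are counted
within the retained list; the core TF is the argmax frequency, with ties
broken lexicographically and flagged. The term-frequency table reports
both the appearance count and the summed overlap of the counted rows,
since "count" is ambiguous between the two in this analysis style.

**Cis rule.** Distance is the gap between gene-body intervals (0-based
half-open; overlap/abutment = 0), same chromosome, ≤ 100 kb inclusive,
strand ignored (the window is symmetric, so "upstream and downstream"
is covered without needing a TSS/strand convention the protocol never
states). Cis pairs are exactly the co-expression edges that also satisfy
the window rule — a projection of the network, verified against a
brute-force double loop.

## The synthetic study

The generator emulates the study regime this pipeline is built for: three
tumor/normal tissue pairs on a combined array, planted ≥ 2-fold changes,
and one dysregulated co-expression program. For gene g in sample s:

    x_gs = μ_g + a_pair(s) + b_g,pair(s) + δ_g·1[s tumor] + λ·f_m(g),s + ε_gs

| parameter | default | meaning |
|---|---|---|
| μ_g | N(8, 2²) | baseline log2 intensity |
| τ (pair_sd) | 0.5 | array-level shift per sample pair (removed by QN) |
| φ (subject_sd) | 2.0 | per-gene between-subject effect, shared within a pair |
| δ_g | ±U[1, 3] | planted log2 fold change (0 for non-DE genes) |
| λ (module_loading) | 2.0 | module factor loading |
| σ (noise_sd) | 0.3 | residual per-sample noise |
| n_pairs / n_mrna / n_lncrna | 3 / 200 / 60 | design size |
| module | 10 mRNA + 30 lncRNA | one co-expression program, coherent DE sign |
| frac_de (non-module) | 0.15 mRNA, 0.95 lncRNA | additional DE genes |
| core TF | coverage 0.8 of module mRNAs, regulon 40 | planted mega-regulon |
| decoy TFs | 10 × 5 targets | ordinary regulons |
| terms | 1 planted (80 genes) + 19 decoys (15) | annotation collections |
| cis pairs | 5, gap U[0, 100 kb] | planted adjacent module pairs |

Design choices that matter, and why:

- **Between-subject variance (φ) is the load-bearing realism.** With only
  the condition effect and iid noise, any two planted DE genes share most
  of their cross-sample variance and virtually *every* DEL–DEM pair passes
  |r| > 0.8 — the network saturates and no ranking statistic can
  discriminate. The subject effect cancels exactly in paired ratios (so
  differential power is untouched; this is why the design is paired) while
  keeping the background network density near 0.2.
- **The module factor is subject-level activity** (drawn per pair, shared
  by the tumor and normal sample of a subject) and, for module members, it
  *replaces* the independent subject effect (their residual subject sd is
  √max(φ²−λ², 0), zero at the default λ = φ). This keeps module genes
  marginally exchangeable with every other gene — otherwise their extra
  factor variance systematically under-correlates them with outside
  lncRNAs and the planted TF is penalized rather than favored. A
  per-sample factor draw remains available (`module_factor_per="sample"`)
  and is what the closed-form module correlation λ²/(λ² + σ²) refers to;
  it is not the default because at n = 3 pairs it inflates module genes'
  paired-ratio variance ~12-fold and the generator's own planted DE
  becomes undetectable.
- **Module DE is sign-coherent** (one random direction per module): a
  program that is jointly up- or down-regulated. With mixed signs the
  shared factor and opposing condition effects cancel each other's
  correlation and the module is invisible to the network stage.
- **Regulon sizes are asymmetric on purpose.** The core TF is a
  master-regulator profile — its targets cover 80% of the module program
  and extend to 40 of 200 coding genes — while decoys have ordinary small
  regulons. This is the scaled-down shape of the real phenomenon (a
  cell-cycle master regulator has thousands of ChIP-supported targets);
  it is also what makes the frequency statistic identifiable at this
  scale, since a decoy that happens to contain even one module gene
  "rides" the whole module block of predictions.
- **Most lncRNAs are differential** (module 30 + 95% of the rest). The
  network stages only ever see DELs; at 60 simulated lncRNAs a realistic
  2–5% DE rate would leave a handful of DELs and no rankable list.
- **Gene placement**: non-planted genes sit on a grid whose spacing
  exceeds the cis window plus the largest gene span, so the planted cis
  pairs (placed at a gap drawn uniformly in [0, 100 kb]) are *exactly*
  the same-chromosome lncRNA–mRNA pairs within the window.

What the defaults deliver, measured over seeds: ~85–90% of planted DE
genes called; ~70% of planted module edges retained; the planted core TF
is the argmax-frequency TF in ~91% of 100 random seeds (19/20 on seeds
1–20); the planted term tops the function-prediction frequency table in
~16/20 seeds; planted cis pairs survive the full DE → co-expression →
window chain about half the time at σ = 0.3 (all of the time at
σ = 0.1 — the chain, not the window rule, is the bottleneck; the window
rule itself is exactly oracle-equivalent).

What the simulator does **not** model: probe-level Agilent noise,
dye/batch effects, background correction, within-array replicate probes,
copy-number structure, correlated decoy regulons, or annotation
incompleteness. Passing recovery tests here therefore says the pipeline's
inference chain is internally sound at this design size — not that three
tissue pairs suffice for reliable network inference on real tumors, where
all of the ignored effects act at once.

## Problem sizes in the checks

The calibration simulations use 10,000 genes × 3 pairs (null: no planted
effects, σ = 0.3, expecting p < 0.05 for ~5% and the dual filter < 0.5%;
power: planted |log2FC| = 2, expecting ≥ 95% called). Core-TF recovery
runs the full pipeline on 20 seeds of the default 260-gene design.
Hypergeometric exactness is enumerated exhaustively for all universes
N ≤ 12; the cis rule is checked against a brute-force double loop on 100
random ≤ 50-gene annotations. These sizes keep the whole suite and the
acceptance script in the minutes range while leaving every statistic in
the regime it is actually used in.

## Known limitations

- At n = 3 pairs the co-expression p-filter has only 4 df; the retained
  network is noisy and the frequency statistic inherits that noise (the
  ~9% core-TF misidentification rate is a property of the design size,
  not a bug).
- The moderated-t hyperparameter fit assumes a single variance prior;
  bimodal variance structure (e.g. a large module with per-sample factor
  variance) drags d₀ down for all genes.
- Quantile normalization assumes most genes unchanged; strongly
  imbalanced differential fractions bias recovered fold changes toward
  zero.
- BH FDR is computed per category over tested (k ≥ 1) sets only; with
  few sets per category the adjustment is coarse.
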