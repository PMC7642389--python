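# Methods

This note records the models, numerical choices and known limitations of
`regulonscope`, in the spirit of a methods section a maintainer can audit.

## Signal model for ChIP-exo

ChIP-exo trims immunoprecipitated chromatin with λ exonuclease up to the
protein–DNA crosslink, so a binding site leaves strand-paired 5′-end read
accumulations: a plus-strand border upstream of the site center and a
minus-strand border downstream. We model each site as Poisson read spikes of
mean `occupancy × reads_per_occupancy / 2` at `center − b` (plus strand) and
`center + b` (minus strand), with `b` the border offset (default 10 bp), over
a uniform Poisson background (default 0.02 reads/bp combined — exo background
is sparse; most genomic positions carry no reads). This is a geometry model,
not a sequencing model: no read lengths, mappability, or PCR duplicates.

**Peak calling** is defined so that an independent brute-force enumerator can
reproduce it exactly:

* smoothed track: moving sum of combined-strand counts over `2b + 1` bp;
* summit: leftmost strict local maximum of the smoothed track (strictly
  greater than every window position to its left, ≥ every one to its right,
  and positive) — the leftmost-of-plateau rule makes ties deterministic;
* strand-pair support: ≥ 1 plus-strand read in `[i − b, i]` and ≥ 1
  minus-strand read in `[i, i + b]`;
* noise level: the smallest value among the top `f` (default 5%) of *nonzero*
  combined position signals, a rank-based quantile boundary. Zeros are
  excluded because they dominate any genome and would pin the noise at 0; the
  alternative reading (mean of the top 5%) is available via the exposed
  quantile machinery but is not the default;
* peak signal: tallest raw combined position in the peak window; peaks with
  S/N = signal / noise < 1.5 are removed (strict).

Replicates are filtered first and merged second (the filter is defined
per analysis); merging pairs summits within `merge_max_dist` (20 bp), closest
first, recording `replicate_support`. Downstream stages (motif, regulon)
consume only peaks reproduced in every replicate — the point of biological
duplicates; unmatched peaks remain in the peak table flagged with support 1.

Nearest-gene assignment measures distance from the summit to the closest gene
boundary; a summit inside a gene body is intragenic. Exact distance ties
prefer the gene starting after the summit (downstream in plus orientation),
then the smaller start coordinate.

## Differential expression

FPKM follows the classic definition `counts / (length_kb × library_millions)`
with library size defaulting to the column sum. The test is a per-gene
negative-binomial likelihood-ratio test: group means are estimated with
library-size offsets, the dispersion is a pooled within-group
method-of-moments estimate (`α = (s² − m)/m²`, clipped to [0, 10]; α ≤ 1e−8
falls back to Poisson), and 2·Δlog-likelihood is referred to χ²₁. It is a
deliberate stand-in with the same interface and thresholds as a
transcript-quantification pipeline's differential step, not a reimplementation
of any published tool.

One departure from the naive formula matters at toy-genome scale: with 60
genes and several planted 10-fold operons, total-count normalization absorbs
the planted signal into the library size and shifts every null gene by up to
−1 log₂ unit (composition bias). `test_differential` therefore uses
median-of-ratios size factors (the estimator DESeq-style tools use for
exactly this reason) for its offsets and for the FPKM depth term inside fold
changes. On genome-scale data with a small DE fraction the two normalizations
agree closely.

Fold changes use a 0.5-FPKM pseudo-count for stability near zero. The DEG
filter is strict (`|log₂FC| > 1.0` and `p < 0.05`) on raw p-values;
Benjamini–Hochberg is available behind a flag but off by default, matching
the filter the pipeline is specified with. DEG percentages are reported to
one decimal of the total gene count. (Of the printed percentages the design
is checked against, only the internally consistent ones — 13.0, 5.3, 4.1,
4.4 of 5195 — are asserted; the remaining printed values are inconsistent
with that denominator by 0.1 and are not reproduced.)

Clustering of DEGs: rows are z-scored log₂(FPKM + 1), distance is
1 − Pearson correlation (constant rows get correlation 0 by convention),
average linkage, and the deterministic scipy dendrogram leaf order (no
optimal-leaf reordering, so reruns are byte-identical).

## Motif discovery

ZOOPS EM at fixed width 20 bp on peak windows of width + 2 × 20 bp centered
on summits. Both strands are scanned; inputs are first put in a canonical
orientation (lexicographic minimum of sequence and reverse complement),
which is a no-op for a both-strand model but makes the output exactly
invariant to reverse-complementing the input. The M-step adds a pseudo-count
of 0.25 per base per column; because of it the EM objective asserted
non-decreasing at every iteration is the Dirichlet-penalized log-likelihood
(MAP-EM), the quantity the algorithm actually ascends. Ten seeded restarts,
best final likelihood kept; the site-occurrence rate γ is re-estimated each
iteration and clamped to [0.01, 0.99].

Information content uses a uniform background: IC_j = 2 + Σ_b p_bj log₂ p_bj,
in [0, 2]. The consensus upper-cases positions with IC > 1 bit; column
argmax ties break alphabetically. Palindromicity is the mean per-position
total-variation distance between the PWM and its reverse complement; note it
is frame-sensitive — an EM solution shifted a few bp off the true site (a
likelihood-equivalent solution for ZOOPS) scores worse than the same motif in
frame, so recovery comparisons align over small shifts and both strands.

On pure random sequences the EM still sharpens its best column to ~0.9 bits
(finite-sample overfitting inherent to the model — the reason MEME reports
E-values); the meaningful null-level statistic is the per-position *average*
IC, ≈ 0.42 bits versus ~1.4 bits at planted core positions.

## Regulon integration and prioritization

A TU is bound when a reproducible peak summit lies in its body or strand-aware
promoter window (default 300 bp upstream — a typical bacterial promoter
span; configurable). A summit between divergent promoters is assigned to
both TUs; every peak is either assigned somewhere or reported as an orphan.

Mode assignment from the deletion-vs-wild-type DE table: bound + significant
member up ⇒ repressed by the TF (deleting a repressor raises expression);
bound + down ⇒ activated; bound with no significant member ⇒ bound-only;
unbound with a significant member ⇒ indirect. TU direction is the majority
vote of significant members, ties resolved by the strongest |log₂FC|; the
TU's representative response is the strongest significant member in the
majority direction. Whether DE in the plain medium, the acid medium, or
either qualifies is a policy knob (default *either*: the stronger significant
comparison represents the gene).

The five-category cascade flags operons for: (1) promoter divergence between
strains (a boolean input table — the cross-strain genome comparison that
produces it is outside this package), (2) ≥ `fc_threshold` (default 10)
linear fold up-regulation on TF deletion, (3) annotated acid-resistance
regulators, (4) membrane-synthesis genes, (5) unknown function. The
shortlist is the union, ordered by flag count; adding a flag can only grow
it. A curated category table for the seven-operon / eleven-gene worked
example ships with the package; genes without metadata default to unknown
function (logged).

## Synthetic data: what it emulates and what it does not

The default scenario is study-shaped: a 100 kb genome with 60 genes in
1–3-gene operons; 33 planted palindromic sites split 21 intergenic
(promoter-proximal where space allows) / 12 intragenic; ChIP-exo and RNA-seq
in biological duplicate; a 2-strain × 2-media count design at 2 × 10⁶ reads
per sample with NB dispersion 0.01; two strongly TF-repressed operons at
log₂FC 3.32 (≈ 10-fold, the headline effect size), one mild one at 1.14
(≈ 2.2-fold), three more repressed and four activated TUs at |log₂FC| 2.0,
four unbound TUs with indirect effects, and ±1.5 acid-condition effects on
six TUs. The planted motif is a 20 bp perfect palindrome
(`AATTTGTATG` + reverse complement) with 0.9 core / 0.55 flank base
probabilities (core IC ≈ 1.37 bits, flanks ≈ 0.29).

Ground-truth binding is *geometric*: a TU counts as bound when a planted
site center falls in its body or 300 bp promoter window — the same rule
integration applies — so a site serving one promoter also marks a divergent
neighbor as bound, and intragenic sites mark their host TU. Defining truth
by the planting bookkeeping instead would contradict the mapping rule the
pipeline is specified to use.

Not emulated: read-level artifacts (FASTQ, mapping, duplicates), operon-
internal promoters, condition-dependent binding, genome-scale gene counts
(so composition effects are exaggerated relative to real data, see above),
and continuous occupancy–expression coupling (occupancy and planted fold
change are independent). Passing the planted-truth tests therefore certifies
the inference logic under the stated noise model, not performance on real
sequencing runs.

## Assays

ΔΔCt: replicates are averaged on the Ct (log) scale, ΔCt = Ct_target −
Ct_reference per (strain, condition), fold = 2^−(ΔCt_test − ΔCt_baseline);
no amplification-efficiency correction. Specific fluorescence is GFP/OD₆₀₀
with OD ≤ 0 rows excluded. The MIC is the lowest tested concentration whose
mean OD is below the growth threshold (default 0.1 absorbance units —
"growth stops" is otherwise undefined; configurable) with all higher tested
concentrations also below it; growth at the top of the tested range returns
an above-range sentinel, and non-monotone profiles yield the envelope MIC
with the violations listed as warnings. A Welch two-sided t-test is provided
for per-dose strain comparisons as a convenience, with no claim it matches
any particular published analysis.

## Problem sizes and determinism

All stochastic stages draw from `numpy` Generators seeded via
`SeedSequence`; a scenario, config and seed reproduce every output
byte-for-byte (timestamps live only in the run manifest). The shipped
validation runs use: the 100 kb default scenario for site recovery and
regulon-mode accuracy; 5 × 100-gene single-operon simulations (20 effect
genes each) for log₂FC recovery; 25–50 null simulations of 60 genes for the
false-positive rate; 10 seeds × 33 sequences for motif recovery; and 100
random ≤ 5 kb tracks for the peak-caller/brute-force equivalence check.
These sizes were chosen so the full validation completes in about a minute
on a laptop core while keeping every recovery estimate's sampling error well
inside the asserted margins.

## Known limitations

* The NB test has only method-of-moments dispersion with no
  shrinkage across genes; at 2 replicates its p-values are approximate
  (the strict fold-change filter does most of the false-positive control).
* The S/N filter is a hard threshold with no FDR calibration, faithful to
  the procedure it implements.
* ZOOPS EM can converge to a shifted frame of the true motif; consensus
  comparisons should align over shifts, and the palindrome score of a
  shifted solution understates the motif's true symmetry.
* MIC resolution is limited to the tested concentration grid; no
  interpolation is attempted.
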