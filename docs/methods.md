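# Methods

This note documents the models, statistics and design choices behind
`prc2screen`, what the synthetic benchmark does and does not show, and
the package's numerical conventions.

## Coordinates and formats

All genomic coordinates are 0-based, half-open (BED/bedGraph native). A
minus-strand TSS is `end − 1` of its BED record. Readers are strict —
malformed lines, negative values, duplicate identifiers and overlapping
intervals are rejected with line numbers rather than coerced — because
silently repaired input hides generator and pipeline bugs. Gene identity
is the raw case-sensitive token; no symbol aliasing is attempted. Output
tables are TSV with ≥6 significant digits.

## Differential probability

The pipeline's significance currency is an empirical probability of
differential expression rather than a parametric p-value. For one
two-group contrast on a normalized matrix:

* every unordered pair of replicates *within* a condition, for every
  gene, contributes a null point
  `(|M₀|, D₀) = (|log2((x_i+c)/(x_j+c))|, |x_i − x_j|)` — the noise an
  effectless gene shows;
* a gene with observed `(|M|, D)` (group means, same pseudocount
  `c = 1`) gets `P_DE` = fraction of null points it **strictly**
  dominates (`|M₀| < |M|` and `D₀ < D`).

This is the NOISeq construction: deterministic (full enumeration, no
sampling), distribution-free, and monotone in both effect coordinates.
Strict dominance makes an exactly-null gene score 0, and boundary ties
resolve conservatively downward. Swapping the group labels negates `M`
and leaves `D` and `P_DE` unchanged. The statistic is intentionally
conservative for weakly expressed genes: their absolute differences `D`
cannot dominate the noise cloud of strongly expressed genes, which is
why classifier sensitivity concentrates on the well-expressed planted
responders (see the benchmark section).

Normalization scales each sample to the common depth: `library_size`
(counts) matches totals to the across-sample mean total; `average`
(array intensities, the BeadStudio convention) matches sample means to
the grand mean. On a fixed gene panel the two coincide; both names are
kept as the idioms of their platforms. Within-sample rank order is
always preserved.

## Response-class grammar

Classification uses three contrasts per perturbation axis: induction
under control (`I_ctrl`: +IFN vs −IFN in the control arm), induction
under perturbation (`I_pert`), and the basal perturbation effect
(`B_pert`: perturbed −IFN vs control −IFN). With fold cutoff
`θ_FC = 2` (inclusive `≥`, matching the printed "≥ 2-fold") and
probability cutoff `θ_P = 0.9` (strict `>`):

* `isg` — induction passes in the control **or** a perturbed arm.
  Responsiveness may exist only after perturbation (e.g. rescue of a
  BRG1-deficient line, or PRC2 depletion), so the OR is essential.
* `z_basal` / `br_basal` — the basal contrast passes.
* `z_induction` / `br_induction` — `isg` and the induction-fold ratio
  `2^(M_Ipert − M_Ictrl) ≥ θ_FC` with `P_DE(I_pert) > θ_P`. The exact
  numeric rule behind "enhanced induction" is not published; this
  ratio-with-significance form is the package's operationalization and
  both cutoffs are configuration keys.

Labels are a pure function of flags: a "BrS" part if any BRG1 flag, a
"ZR" part if any SUZ12 flag, joined `Br`-then-`Z` with "/", suffix
"-ISG" for responders and "G" otherwise; no flags gives "N-ISG"/"N".
A responder carrying only a basal repression flag also receives the
"ZR-ISG" form — the published grammar never prints this combination and
collapsing basal-and-induced repression into one part keeps labels a
function of flag presence.

Cross-line specificity counts, over the union of genes carrying a label
anywhere, how many lines carry each (gene, label) pair, and reports the
fractions private to one line and to at most two. Probability-profile
clustering across lines uses agglomerative hierarchical clustering
(Euclidean, average linkage — the MeV-era defaults) with genes pre-sorted
by id so leaf order is deterministic.

## Promoter chromatin

`bin_promoter_signal` averages a bedGraph track into `b = 100` bp bins
across ±`W` (default 5000) bp of the TSS via an exact interval prefix
integral: each bin value is the per-base integral over the bin divided
by `b`, uncovered bases contributing 0. Minus-strand rows are reversed
so index 0 is always most-upstream; windows clipped at coordinate 0 are
flagged. Binning conserves mass by construction (tested).

A promoter is H3K27me3-positive when `max(bin)/control ≥ 1.5`
(inclusive — "1.5× above control" read as threshold attainment). The
control level is the mean of the matched control track over the same
window; without a control track the fallback is the genome-wide
5%-trimmed, length-weighted mean of the signal itself. Which reference
the original array analysis used is ambiguous; both modes are
implemented and the matched-control mode is the default throughout.

Class comparisons use `scipy.stats` under the package surface:
Fisher's exact test (two-sided by point-probability enumeration; sample
odds ratio `ad/bc`, infinities allowed) and Mann-Whitney U (exact
enumeration when `n+m ≤ 12` without ties, tie-corrected normal
approximation otherwise). Independent brute-force enumeration oracles
live in the test suite only. Basal-expression strata split genes at a
configurable silent threshold `τ` (default 1 normalized unit) and then
into rank tertiles with stable gene-id tie-breaks; remainder genes go to
the lower strata.

## Bivalency states and CIDs

Features are the concatenated per-bin z-scored H3K27me3 and H3K4me3
matrices (zero-variance columns zeroed): per-mark standardization stops
the marks' different dynamic ranges from dominating the Euclidean
geometry. K-means (Lloyd, `k = 10`, 50 seeded restarts, empty clusters
re-seeded — `sklearn.cluster.KMeans`) yields raw clusters, which are
re-indexed as CIDs 1..k by decreasing mean SUZ12-knockdown log2FC (ties
by raw index); the non-increasing CID-mean invariant is asserted on
every run. `k = 10` follows the published cluster count; the restart
count is the package's choice since the original initialization is not
described. Induced proportions compare CIDs 1–4 vs 5–10 (split
configurable), optionally restricted to a focal pathway, and
`random_geneset_profile` draws 1000 random same-size gene sets (size
defaulting to the median of the comparison groups) as the background
meta-profile.

The knockdown response used for CID ordering, induced flags and the
enrichment ranking is the knockdown-vs-control contrast **under IFN**:
that arm exposes both basally derepressed genes and responders whose
induction PRC2 had silenced.

## Preranked enrichment

The ranked list keeps genes with `M > 0` and `P_DE > 0.5`, sorted by
`P_DE` descending (ties: `M` descending, then gene id), weighted by
`P_DE` with exponent `p = 1` (exponent 0 gives the unweighted
Kolmogorov–Smirnov form). The running sum adds `w_i^p / Σ_hits w^p` at
hits and subtracts `1/(N − N_hits)` at misses; the ES is the extremum of
greatest absolute deviation, with exact-magnitude ties (within a 1e-12
relative tolerance, needed under cumsum round-off) resolved toward the
positive peak and then the earliest index. Round-off can leave the
extremum epsilon outside [−1, 1]; it is clipped at the contract
boundary.

Significance uses gene-tag permutation — the only null available to a
preranked list: `n_perm = 1000` same-size uniform subsets of the ranked
list. The nominal p is add-one on same-sign null scores,
`p = (1 + #{same sign, |null| ≥ |ES|}) / (1 + #{same sign})`, so a
top-loaded set's p is exactly `1/(1 + n_same_sign)`, not `1/(1+n_perm)`:
typically ~10% of null extrema are negative. NES divides ES by the mean
|null ES| of the same sign; the pooled-null FDR q follows the published
GSEA procedure (same-sign pooled null NES fraction over observed
fraction, clipped to [0, 1], monotonized in |NES|). A set covering the
whole list is degenerate (every permutation reproduces it): ES = 1,
p = 1, NES = 1 analytically. The leading edge is the set members at
ranks up to (ES > 0) or from (ES < 0) the peak.

The pathway screen applies the published cuts (`p < 0.01`, `q < 0.05`)
per cell line, records lines whose ranking filter empties as "no
enrichment computable", derives per-(line, set) seeds from the master
seed via `numpy.random.SeedSequence` spawn keys, and reports a
gene × line induced matrix (`P_DE > 0.9`, `M > 0`) for the focal set.

## Synthetic benchmark

`simulate_experiment` draws a 2×2 factorial (control/SUZ12-knockdown ×
none/IFNγ, 3 biological replicates — the published design) of
negative-binomial counts with variance `μ + φμ²` (Poisson at `φ = 0`),
log-uniform baselines on [10, 1000], per-sample log-normal library-size
jitter (σ = 0.1), and planted classes at defaults chosen to mirror the
study conditions: 5% N-ISG, 5% ZR-ISG, 5% ZRG, 10% silent; induction
fold 8, derepression fold 4, dispersion φ = 0.05. Intensity mode swaps
the count law for a log-normal. Promoter chromatin states link to
classes (ZR-ISGs bivalent with probability `p_link = 0.9`, ZRGs
H3K27me3-only, N-ISGs H3K4me3-only), encoding the central hypothesis —
PRC2-repressed responders are bivalent — while letting tests probe its
violation by lowering `p_link`.

`simulate_chromatin` lays genes on one synthetic chromosome at 12 kb
spacing (no ±5 kb window overlap) on alternating strands and builds each
mark as a Gaussian bump (amplitude `A`, width σ = 500 bp) over a flat
background `B`, with the bump evaluated at
`max(0, |bin center − TSS| − b/2)` — a plateau at the two TSS-flanking
bins — so the noise-free maximum bin/control ratio equals `A` exactly.
Mark tracks carry multiplicative log-normal noise; the control track is
noise-free flat at `B`. Panels share a core ZR-ISG set plus line-private
sets at a configured unique fraction; silent genes are excluded from
panel lines because a responder re-planted on a silent baseline would be
undetectable by construction. Gene-set collections pair the planted
responders (the focal "CCRI-like" pathway, optionally contaminated) with
uniform random decoys.

All generator outputs are pure functions of config + seed.

**What the benchmark does not show.** Counts are i.i.d. negative
binomial without batch effects, gene–gene correlation, length/GC bias or
probe effects; chromatin bumps are symmetric, unimodal, and aligned to
the TSS with bins matching the analysis grid exactly; every planted
effect has one shared fold. Passing the recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated
assumptions, not robustness to the full messiness of real array/ChIP
data.

## Benchmark results and frozen bounds

Problem sizes were chosen to exercise the defaults while keeping the
full suite to a few minutes on one CPU: recovery runs use the default
2000-gene configuration over 20 seeds; calibration uses 500 random sets
(200 permutations each) and 1000-gene pure-null draws; oracle sweeps
cover all 2×2 tables with total ≤ 20 and 1000 random ranked-list
instances with N ≤ 50. An initial calibration run at the default
configuration measured ZR-ISG sensitivity ≈ 0.68 (precision ≈ 1.0),
positivity accuracy ≈ 0.998 at noise 0.1, CID 1–4 vs 5–10 induced
proportions ≈ 0.16 vs 0.007, and focal-set detection in ≥ 18/20 seeds;
the regression bounds frozen in `tests/test_acceptance.py` sit safely
below those values and sensitivity degrades monotonically as planted
folds shrink toward 1 (≈ 0.68 → 0.51 → 0.10 for folds 8/4 → 4/2 →
2/1.4).

## Known limitations

* `P_DE` shares NOISeq's global-noise assumption: the null cloud pools
  all genes, so weakly expressed genes are scored conservatively and no
  per-gene dispersion is modelled (dispersion-model DE is out of scope).
* The 1.5× positivity rule depends on the control definition; with the
  trimmed-mean fallback a globally enriched signal deflates calls.
* Gene-tag permutation ignores inter-gene correlation, as in published
  preranked GSEA; nominal p calibration holds for independent rankings.
* K-means with Euclidean geometry on z-scored bins is scale-stable but
  still sensitive to `k`; CIDs are only meaningful relative to the
  chosen `k = 10`.
* The microarray branch (intensity mode) reuses the count pipeline after
  average normalization; probe-level effects are not modelled.
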