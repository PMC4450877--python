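# prc2screen

Polycomb Repressive Complex 2 (PRC2) deposits the repressive H3K27me3
histone mark and, in many cancer cell lines, silences interferon-γ
stimulated genes (ISGs) and cytokine pathway genes. `prc2screen`
implements, as a reusable and fully tested pipeline, the computational
route from a factorial perturbation experiment to PRC2-repressed
immune-gene calls:

1. **Differential probability** — from a 2×2 design (control vs
   SUZ12-knockdown × unstimulated vs IFNγ, ≥2 replicates per cell), each
   contrast yields per gene the log fold change `M = log2((μ_A+c)/(μ_B+c))`,
   the absolute difference `D = |μ_A − μ_B|`, and an empirical probability
   of differential expression `P_DE ∈ [0,1]`: the fraction of the
   within-condition replicate-pair noise cloud `(|M₀|, D₀)` that the gene
   strictly dominates (NOISeq-style, fully enumerated, deterministic).
2. **Response-class grammar** — genes are classified from per-arm
   contrasts with inclusive 2-fold cutoffs and strict `P_DE > 0.9`:
   `N-ISG` (IFN-responsive, PRC2-independent), `ZR-ISG`
   (SUZ12-Repressed ISG: induction appears or is enhanced ≥2-fold only
   after knockdown), `ZRG` (basally derepressed by knockdown), with
   BRG1-axis analogues (`BrS…`) and cross-cell-line specificity summaries.
3. **Promoter chromatin** — ChIP signal is averaged into 100-bp bins
   within ±5 kb of the TSS (strand-oriented, coverage-weighted); a
   promoter is H3K27me3-positive when at least one bin reaches 1.5× the
   matched control level; class associations use Fisher's exact test and
   Mann-Whitney.
4. **Bivalency states** — K-means (k = 10) on per-bin standardized
   H3K27me3 + H3K4me3 features; clusters are re-indexed as CIDs by
   decreasing mean knockdown log2FC, and the proportion of
   knockdown-induced genes in CIDs 1–4 vs 5–10 is compared, with
   1000-random-gene-set background profiles.
5. **Preranked GSEA** — genes with `M > 0` and `P_DE > 0.5` are ranked by
   decreasing `P_DE`; the weighted running-sum enrichment score, gene-tag
   permutation null, sign-matched NES, pooled FDR q and leading edge drive
   a per-cell-line pathway screen (`p < 0.01`, `q < 0.05`).

Because no public accession accompanies the original datasets, the
package ships a first-class synthetic-data generator
(`prc2screen.simulate`) that plants known gene classes (negative-binomial
counts, configurable folds), promoter chromatin states linked to those
classes, multi-line panels with shared/private responder sets, and gene-set
collections — so every stage is benchmarked against planted ground truth.

## Worked example

```python
import prc2screen as p2

matrix, truth = p2.simulate_experiment(p2.SimConfig(seed=1))
con = p2.standard_contrasts(matrix, "SIM1", 1.0)
params = p2.ParamConfig()
classes = p2.classify_factorial(con["i_ctrl"], params,
                                i_suz12=con["i_kd"], b_suz12=con["b_kd"])
print(classes.table["label"].value_counts().to_string())
```

prints

```
N         1788
N-ISG       76
ZR-ISG      73
ZRG         63
```

i.e. of 2000 simulated genes (100 planted per responder class), 73 of the
100 planted SUZ12-repressed ISGs are recovered with zero false ZR-ISG
calls; the misses are low-expression genes whose absolute effect cannot
dominate the replicate noise cloud. Continuing with the chromatin stage:

```python
tracks, tss = p2.simulate_chromatin(truth, p2.ChromConfig(seed=1, noise_sigma=0.1))
k27 = p2.bin_promoter_signal(tracks["h3k27me3"], tss, 5000, 100, "h3k27me3")
pos = p2.call_positivity(k27, p2.control_levels(tracks["control"], tss), 1.5)
```

yields `63/73 ZR-ISGs vs 0/76 N-ISGs` H3K27me3-positive
(Fisher p = 7.8e-32): the planted bivalent chromatin of PRC2-repressed
responders is recovered by the 1.5× bin rule.

The same flow is available from the shell:

```sh
prc2screen run-all --out-dir out --seed 7        # end-to-end, 3-line panel
prc2screen simulate --out-dir fixtures --seed 1  # fixture bundle only
```

`run-all` writes per-stage TSVs (contrasts, classes, positivity,
bivalency CIDs, enrichment) plus `summary.tsv`; the same seed reproduces
the bundle byte-for-byte.

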