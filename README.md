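# admixnet

Ancestry-level gene-flow analysis for population genetics.

Unsupervised clustering tools such as ADMIXTURE summarize genome-wide
genotypes as K ancestry components, each with its own allele-frequency
vector (the `.P` matrix) and per-individual proportions (the `.Q` matrix).
Phylogenetic trees built on those components assume a strictly bifurcating
history; gene flow between ancestries breaks that assumption. `admixnet`
provides the statistics used to detect and quantify such gene flow directly
from the ancestry-level summaries — no individual genotypes required:

* **f3 admixture scans.**  f3(X; A, B) = E[(p_X − p_A)(p_X − p_B)] over
  markers; a significantly negative value signals that X is admixed between
  populations related to A and B.  Per marker we use the unbiased estimator
  (p_X − p_A)(p_X − p_B) − h_X/n_X with the target-heterozygosity correction
  h_X = n_X p_X(1 − p_X)/(n_X − 1), an *exact* closed-form finite-sample
  variance, and equal-weight (Stouffer) combination of marker z-scores,
  Z = Σ_m z_m / √M, tested one-sided with Bonferroni correction across all
  K·C(K−1, 2) target/parent configurations (2,907 for K = 19).  Effective
  allele counts come from the Q matrix: n_k = 2 Σ_i q_ik.
* **f4-ratio mixture proportions.**  α = f4(A, O; X, C)/f4(A, O; B, C)
  estimated *per marker*; because each ratio is a ratio of dependent
  (asymptotically normal) quantities, its distribution is Cauchy-like with
  no finite moments, so the pipeline reports the sample median (location)
  and IQR (twice the Cauchy scale) rather than a mean — the mean is
  inconsistent, as `compare_mean_vs_median` demonstrates by simulation.
* **Tree-likeness of the F_ST matrix.**  Hudson-type ratio-of-averages
  pairwise F_ST, Bandelt–Dress split decomposition into weighted splits
  (NEXUS export for SplitsTree-style viewers), the quartet-based Q-residual
  score, and a leave-one-out table ranking which ancestry contributes most
  to non-tree-like structure.
* **TreeMix plumbing.**  Export of rounded allele-count input files, and
  tallying of subtree (clade) frequencies across collections of output
  trees, including frequency-weighted combination of migration-edge weights.
* **A synthetic-demography simulator** (Balding–Nichols drift on a rooted
  tree plus explicit admixture events) supplying ground truth for every
  stage.

## Worked example

Simulate the bundled nine-ancestry demography — eight ancestries on a
drift tree plus a "Cushitic" leaf formed from 41.2% of a Nilo-Saharan-like
source and 58.8% of an Arabian-like source — then ask the pipeline to find
and quantify the event:

```bash
admixnet simulate --markers 20000 --seed 7 --outdir demo
admixnet f3scan  --p-file demo/simulated.P --labels demo/labels.txt \
                 --counts 200 --outdir demo/f3
admixnet mixture --p-file demo/simulated.P --labels demo/labels.txt \
                 --counts 200 --admixed Cushitic --proxy-b NiloSaharan \
                 --proxy-c Arabian --sibling-a Omotic --outgroup Khoisan \
                 --outdir demo/mix
admixnet network --p-file demo/simulated.P --labels demo/labels.txt \
                 --counts 200 --outdir demo/net
```

which logs

```
INFO admixnet: 252 configurations, 6 significant
INFO admixnet: median alpha 0.417 (IQR 0.638): 41.7% NiloSaharan / 58.3% Arabian; 19268 markers used, 732 dropped
INFO admixnet: 18 splits; full Q-residual 0.0221481; top contributor Cushitic
```

Reading: the exhaustive f3 scan over all 252 target/parent configurations
flags the admixed target (all six significantly negative combined z-scores
have Cushitic as target); the median per-marker f4 ratio recovers the
planted mixture proportion 0.412 as 0.417 (markers with zero denominator are
dropped, not imputed); and the leave-one-out Q-residual ranks Cushitic as
the ancestry whose removal makes the F_ST matrix most tree-like.  The same
steps run unchanged on real ADMIXTURE `.P`/`.Q` output (pass `--q-file` to
derive effective allele counts instead of `--counts`), and
`admixnet treemix-prep` / `treemix-tally` / `weighted-weights` handle the
TreeMix side.

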