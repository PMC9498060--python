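# dmne — degree-matrix network entropy

`dmne` detects **critical transitions (tipping points)** in stage-course
gene expression data and ranks the genes that drive them. The setting is
a progressive disease observed as cohorts: a healthy **reference** cohort
and diseased **case** cohorts sampled at successive stages (e.g. rat
tissue at 4, 8, 12, 16 and 20 weeks). Before a system tips irreversibly
into the disease state it passes through a *pre-disease / critical state*
in which a group of genes — a **dynamic network biomarker (DNB)** module —
starts to co-fluctuate: intra-group correlation and variance rise while
correlation to the rest of the transcriptome falls. Mean expression often
barely moves, so differential-expression tests miss it; network-level
statistics can see it.

## Method

1. **Sample-specific networks (SSN).** For a target sample and every gene
   pair $(g_i, g_j)$, draw one-dimensional boxes around the target's two
   expression values, each holding exactly $k_{box} = \mathrm{round}(0.1\,n)$
   samples (the target plus its nearest neighbours). With $n_x = n_y = k_{box}$
   and overlap $n_{xy}$, the dependence statistic is

   $$r_{ij} = \frac{n_{xy}}{n} - \frac{n_x n_y}{n^2},\qquad
     z_{ij} = \frac{n_{xy} - n_x n_y / n}
     {\sqrt{n_x n_y (n-n_x)(n-n_y) / (n^2 (n-1))}}.$$

   Since the target always lies in both boxes, the default edge rule is an
   exact one-sided tail test of the remaining overlap under its
   $\mathrm{Hypergeom}(n-1, k_{box}-1, k_{box}-1)$ independence null at
   level $\alpha = 0.01$ (the classical $z$-threshold and the literal
   $r > 0$ rules are available as options).
2. **Degree matrices and local networks.** One network per reference
   sample yields the reference network degree matrix (NDM). Each gene's
   local network is the gene plus its most reproducible co-edge partners
   across the reference networks. Per stage, the case samples are added
   to the reference cloud and degrees are recomputed for both cohorts on
   that shared cloud.
3. **Entropy.** Degrees become node probabilities via per-gene Gaussian
   CDFs, $p_i \propto \Phi(x_i; \mu_i, \sigma_i)$, normalised within each
   local network, and each local network contributes
   $H = -\tfrac{1}{M}\sum_i x_i p_i \ln(x_i p_i)$. The global entropy is
   the mean over local networks, and the stage score is the differential
   entropy $\Delta H_T = H^{n+1}_T - H^n$ against the reference baseline.
4. **Detection.** Stages whose score is a strict local maximum standing
   `min_ratio` robust SDs above the curve median are flagged as critical;
   the top-scoring genes there are reported as DNBs, and genes with high
   scores but no mean-expression shift are flagged as **dark genes**.

A seeded synthetic generator (`dmne.generate`) plants a DNB module with
exactly these signatures and provides ground truth for end-to-end tests.

## Worked example

```python
from dmne import DMNE, SyntheticConfig, generate

x, meta, truth = generate(SyntheticConfig(seed=20))  # planted transition at stage 2
res = DMNE(x, meta).fit()
print(res.summary())
```

```
Degree-matrix network entropy (DMNE) results
====================================================
genes: 300   reference samples: 25   stages: 5
edge rule: significance (alpha=0.01, box fraction=0.1)

stage    H_ref      H_pert     dmne_score  flagged
    1    0.18292    0.17946    -0.00346
    2    0.18144    0.18381     0.00237  *
    3    0.18502    0.18132    -0.00370
    4    0.18071    0.17762    -0.00309
    5    0.18389    0.18062    -0.00327

critical stages: 2
  stage 2: 5 DNBs (top: G261, G221, G140, G178, G073), 15 dark genes
```

`H_ref` / `H_pert` are the reference and perturbed global network
entropies per stage (nats); their difference is the DMNE score. Here the
score rises only at the planted critical stage 2, which the detector
flags (`*`). `res.gene_scores` holds the per-gene score landscape,
`res.dnbs[2]` the ranked biomarker candidates and `res.dark_genes[2]`
the high-score genes without differential expression. With only five
case samples per stage the per-gene ranking is noisy; the stage-level
curve is the robust readout (see `docs/methods.md` for measured
detection rates).

The same pipeline runs from the shell:

```bash
dmne simulate --out-dir sim --seed 20
dmne run --expression sim/expression.tsv --metadata sim/metadata.tsv --out-dir results
```

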