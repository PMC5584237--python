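# lncmeth

Promoter-methylation-driven analysis of long non-coding RNA (lncRNA)
dysregulation in tumors: from 450K-style beta values to competing-endogenous-RNA
(ceRNA) networks and prognostic risk models.

## The problem

In many cancers, lncRNA expression is controlled epigenetically: hypermethylation
of a lncRNA promoter tends to silence it, hypomethylation to activate it.
`lncmeth` implements a complete, testable pipeline for characterizing this
regulation from matched tumor/normal multi-omics profiles:

1. **Promoter methylation.** The promoter of a lncRNA is the 2 kb window
   upstream of its TSS (strand-aware). Array probes are mapped into promoters;
   a probe missing in more than 30% of samples is dropped and remaining gaps
   are probe-mean imputed. The methylation level of a lncRNA in a sample is
   the mean beta value β = Methy/(Methy + Unmethy) of its promoter probes.
   Tumor and normal level distributions are compared with a two-sample
   Kolmogorov–Smirnov test.
2. **Differential calling (SAM).** For each feature, d = (x̄_T − x̄_N)/(s + s₀)
   with pooled standard error s and exchangeability constant s₀; q-values come
   from label permutations, FDR(t) = E_perm[#{|d*| ≥ t}] / #{|d| ≥ t} with a
   running-minimum monotonization. Calls: differentially methylated lncRNAs
   (q ≤ 0.05 and |Δβ| ≥ 0.1), differentially expressed genes (q ≤ 0.05 and
   fold change ≥ 2 or ≤ 0.5), differentially expressed lncRNAs (q ≤ 0.05).
3. **Four-way classification.** lncRNAs that are both differentially
   methylated and expressed are split into high-up, high-down, low-up and
   low-down groups (methylation direction × expression direction); the
   high/low methylation split defines HMLncs and LMLncs.
4. **ceRNA networks.** A lncRNA–mRNA pair is an edge of the background
   network iff PCC > 0, correlation p ≤ 0.01, the pair shares ≥ 2 miRNAs, and
   the shared-miRNA count is hypergeometrically significant
   (P = 1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n) ≤ 0.01). The four groups seed
   four sub-networks; mRNAs with degree ≥ 5 are hubs.
5. **Enrichment.** Nearest-gene cis assignment with hypergeometric set
   enrichment (BH FDR ≤ 0.05), a GO `is_a` term graph with connected
   components, and miRNA–disease enrichment at raw p < 0.05.
6. **Survival.** Each hub module is fitted with a multivariate Cox model on
   z-scored log2 expression; the prognostic index PI = Σ β_g x_g splits
   patients at the median into high/low risk, compared by Kaplan–Meier and
   the log-rank test. Trained coefficients can be transferred to an
   independent cohort.

A first-class synthetic-data module generates a complete seeded study —
annotation, probes, beta values, expression, interactions, ontology tables,
clinical follow-up — with planted truth (methylation shifts coupled to
expression, ceRNA triangles with injected shared miRNAs and latent-factor
co-expression, module-dependent hazards), so every stage is testable without
any downloads.

## Worked example

```sh
lncmeth simulate --seed 42 --outdir demo/data
lncmeth run-all --indir demo/data --outdir demo/run --seed 0
```

prints (log excerpts):

```
promoter_meth: 200 lncRNAs profiled, K-S D=0.0450 p=0.982
differential: 80 DML, 82 DEL, 162 DEG, 80 classified
cerna: background 345 edges; per-group sizes {'high-up': 53, 'high-down': 118,
       'low-up': 54, 'low-down': 120}
survival: high-up has no hub mRNAs; module skipped
survival: high-down module (6 hubs) log-rank p=9.555e-11
survival: low-up has no hub mRNAs; module skipped
survival: low-down module (6 hubs) log-rank p=0.1092
```

The seed-42 study plants 20 lncRNAs in each of the four groups: all 80 are
recovered (80 DML; 80 of 82 DEL are planted; 40 HMLncs + 40 LMLncs).
`network_summary.tsv` is the per-group interaction table:

```
group      lncRNAs  miRNAs  mRNAs  interaction_pairs  mean_lncrna_degree
high-up    20       44      53     53                 2.65
high-down  20       12      6      118                5.9
low-up     20       48      54     54                 2.7
low-down   20       10      6      120                6.0
```

The two down-regulated groups share planted partner-mRNA modules, so only
they contain hub mRNAs (degree ≥ 5) — the up groups have none and their
survival analysis is skipped, which the run log states explicitly. The
high-down module genes carry a planted hazard coefficient, so its median
PI split separates survival strongly (log-rank p ≈ 1e-10), while the
low-down module's coefficient is zero and its split is not significant
(p ≈ 0.11). Every output lands in `demo/run/` along with `manifest.json`
(stage counts plus SHA-256 of every file); re-running the same command
reproduces every byte.

The library can be driven directly too:

```python
from lncmeth.simulate import SimulationConfig, simulate_all
from lncmeth import differential

ds = simulate_all(SimulationConfig(seed=42))
res = differential.sam_qvalues(ds.lnc_expr, ds.sample_groups, b=1000,
                               seed=1, log2_stat=True)
dels = differential.call_del(res)
```

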