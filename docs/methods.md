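# Methods

## Scope and data model

`lncmeth` analyses matched tumor/normal cohorts with four molecular layers:
promoter methylation (450K-style beta values per CpG probe), lncRNA
expression, mRNA expression, and miRNA interaction tables, plus clinical
follow-up. Internally all genomic coordinates are 0-based half-open; GTF
input is converted at the boundary. Matrices are features × samples with
`NA` as the missing token.

## Promoter methylation

The promoter is the `window` (default 2000 bp) region immediately upstream
of the TSS: `[TSS−w, TSS)` on +, `[TSS, TSS+w)` on −, clipped at coordinate
0. Intervals are half-open, so a probe exactly at the TSS of a plus-strand
gene is excluded; a probe may serve several overlapping promoters. For a
multi-transcript gene the TSS is the gene boundary on its strand (the
5′-most position), a configurable choice since transcript-level collapse is
not uniquely defined.

Probes missing in strictly more than `max_missing_frac` (default 30%) of
samples are removed; remaining gaps are filled with the probe's mean over
observed samples, making the filter/imputation step idempotent. The lncRNA
methylation level is the unweighted mean beta of its promoter probes;
lncRNAs with no measured promoter probe are dropped from methylation stages
only (their count is logged). The tumor/normal comparison feeds per-lncRNA
group means into a two-sample Kolmogorov–Smirnov test — one value per lncRNA
per group, so unequal sample counts do not distort the comparison.

## SAM differential statistic

For feature *i*, d = (x̄_T − x̄_N)/(s + s₀) with

    s = sqrt{ (1/n_T + 1/n_N) · [SS_T + SS_N] / (n_T + n_N − 2) }.

s₀ is the median of the per-feature s values — a deterministic
simplification of the percentile search in the original formulation; an
explicit `s0` argument overrides it. Significance comes from group-label
permutations with group sizes fixed (B Monte-Carlo shuffles, default 1000,
or `b="exact"` full enumeration up to 20 000 assignments). For threshold t,

    FDR(t) = E_perm[ #{ |d*| ≥ t } ] / max(1, #{ |d| ≥ t }),

and a feature's q is the minimum FDR over all thresholds that would call it
(running minimum along the |d| ordering, clipped to [0,1]); ties in |d|
share a q. The expectation over permutations (rather than the median) is
used so that the single-feature exact case reduces to the permutation tail
fraction; `center="median"` is available. s₀ is estimated once from the
observed labelling and reused for all permutations.

Expression matrices (RNA-seq-scale, lognormal-like) are heavy-tailed on the
linear scale, so d, s and the permutation machinery operate on log2(x+1)
(`log2_stat=True`); the fold change is always computed from linear group
means with a pseudocount ε = 0.01. Methylation betas are bounded and are
analysed untransformed; their effect size ("delta") is the signed
tumor−normal difference of promoter means.

Calls: DML iff q ≤ 0.05 and |Δβ| ≥ 0.1 (sign → high/low methylation);
DEG iff q ≤ 0.05 and FC ≥ 2 or ≤ 0.5; DEL iff q ≤ 0.05 (direction from the
mean difference; no fold-change requirement). All thresholds are inclusive.
The DML ∩ DEL intersection is cross-classified into high-up / high-down /
low-up / low-down; lncRNAs with only one call are `unclassified`.

## ceRNA network

Candidate pairs are DEL × DEG pairs sharing at least one miRNA. An edge
requires, conjunctively: PCC > 0; two-sided correlation p ≤ 0.01 (t
transform on n−2 df); shared-miRNA count m ≥ `min_shared` (default 2,
reading "more than one common miRNA" literally; configurable to 1); and
hypergeometric tail P(X ≥ m) ≤ 0.01 with universe N = all distinct miRNAs in
the union of the two loaded interaction tables (the natural closed universe
of the data at hand), M and n the two partner-set sizes. Correlations are
computed across tumor samples only by default (`sample_scope="all"`
switches), on log2(x+1) expression in the pipeline. Interaction tables are
deduplicated before any set operation.

Sub-networks are induced on a seed lncRNA group plus its background
neighbors; seeds without edges stay as isolated nodes. Hubs are mRNA nodes
with degree ≥ 5; the mean lncRNA degree of a network is edge count / lncRNA
count. Because the criteria are conjunctive, loosening any single threshold
can only add edges (tested as a monotonicity property).

## Enrichment

Cis regulation is approximated by nearest-gene assignment — the
protein-coding gene with minimal |ΔTSS| on the same chromosome within 1 Mb,
ties broken toward the smaller coordinate — followed by gene-level
hypergeometric enrichment. This is a deliberately transparent stand-in for
region-based web tools: it keeps the cis stage auditable and testable. Gene
set enrichment uses the same tail probability with Benjamini–Hochberg FDR
over all tested terms (significant at FDR ≤ 0.05); the universe defaults to
all genes of the loaded annotation. miRNA–disease enrichment uses raw
p < 0.05 without multiplicity adjustment, with N = all miRNAs in the
annotation table. Significant terms are linked by their `is_a` relations
restricted to the significant set; components are weakly connected
components. Ontology annotations are used as given — no true-path
propagation up the DAG.

## Survival

Module genes (the hub mRNAs of a sub-network) are z-scored on log2(x+1)
expression and fitted with a multivariate Cox proportional-hazards model
(lifelines backend, Efron tie handling; ties are absent in continuous
synthetic times). The prognostic index PI = Σ β_g x_g splits patients at
the median: PI > median → high risk, PI ≤ median → low risk (median ties go
to low; a split leaving a group empty raises a degeneracy error). Risk
groups are compared with Kaplan–Meier curves and the two-group log-rank
test. A fitted model (β plus the training standardization) can be
transferred to split an independent cohort, mirroring external validation.
An empty hub set raises "no hub mRNAs" — sub-networks without hubs cannot
be assessed, which the pipeline records rather than treats as failure.

**Known limitation — fit-then-split optimism.** Fitting a multivariate Cox
model and median-splitting by the fitted risk score *on the same cohort* is
optimistically biased: with 6 correlated covariates and ~70 events the null
rejection rate at p < 0.05 is ≈ 35%, not 5%. With a single covariate the
split does not depend on the fitted coefficient at all and the procedure is
exactly null-calibrated — which is how the package's null-calibration test
is constructed. In-cohort module p-values should therefore be read as
descriptive; the transfer mode (train on one cohort, split another)
provides honest assessment.

## Synthetic data generator

The generator emulates the full study on one synthetic chromosome, features
on a 20 kb grid with jitter so nearest-gene assignments are unambiguous.
Defaults are the package's study conditions: 40 tumor / 20 normal samples,
200 lncRNAs (20 planted per group), 300 genes, 100 miRNAs, 2000 probes,
Δβ = 0.25, expression effect 1.5 (log2), 3 shared miRNAs and latent-factor
correlation 0.6 per true ceRNA pair, 2% missingness.

* **Methylation.** Per-probe baselines are Beta-distributed
  (method-of-moments: mean μ_p, common concentration κ = 50). Probes inside
  planted promoters get tumor means μ_p ± Δβ, clipped into (0,1) with a
  warning when clipping bites; baselines of planted probes are drawn so the
  shift fits without clipping. Missingness is completely at random.
* **Expression.** log2 expression = feature baseline N(5, 1.5²) + residual
  N(0, 0.8²); matrices are written as 2^log2 (linear scale). Planted
  lncRNAs and their partner mRNAs are shifted ±1.5 log2 in tumors. True
  ceRNA pairs share a latent tumor-sample factor with loading √ρ, giving a
  log-scale pair correlation ≈ ρ = 0.6. Up-group lncRNAs have exclusive
  partner mRNAs (3 each), the two down groups share a class-level module
  (6 mRNAs coupled to a class factor) — so down-group sub-networks contain
  hub mRNAs and up-group ones do not, reproducing the structural asymmetry
  the survival stage must handle. A further 20% of unused mRNAs receive
  random shifts to populate the DEG background.
* **Interactions.** Every lncRNA/mRNA draws 3 background miRNAs from the
  100-miRNA universe; each true pair gets 3 injected common miRNAs (class
  miRNAs for the down groups). At these densities a planted overlap is
  hypergeometrically significant (p ≈ 0.002) while random pairs rarely share
  2 miRNAs (p ≈ 0.003 before the correlation gate), so planted triangles are
  recoverable by construction without being trivial.
* **Clinical.** Tumor-only survival: times are exponential with log-hazard
  Σ_g β_g z_g over the high-down module genes (z-scored log2 expression;
  β = `survival_beta`, default 0.5; the low-down module's coefficients are
  zero so its split should not validate). Censoring picks a `censor_rate`
  fraction (default 0.3) of samples and replaces their time with a uniform
  draw below the event time — achieving the target rate exactly in
  expectation.
* **Ontology tables.** Random term→gene, `is_a` and disease→miRNA tables
  with one planted term per down-class module and one planted disease drawn
  from the high-down group's miRNA repertoire, giving the enrichment stage
  known positives.

Each modality draws from its own child stream of the master seed
(`default_rng([seed, stream])`), so changing one modality's size never
perturbs another's draws; fixed seeds reproduce every output byte.

**What the generator does not emulate:** probe type I/II chemistry and
dye-bias, copy-number or purity confounding, batch effects, count-level
sequencing noise, miRNA expression, overlapping transcripts on real genome
geometry, or correlated (informative) censoring. Passing tests therefore
demonstrate correctness and calibration of the algorithms under the planted
model, not performance on real cohorts.

## Numerical and design choices

* Hypergeometric tails via the exact survival function (log-space
  internally); verified against subset enumeration for every universe ≤ 12.
* Correlation p-values from the t transform; PCC validated against the
  covariance form to 1e-12.
* Permutation masks are drawn without replacement per permutation; the
  observed labelling is not forcibly included (its inclusion is a
  convention; at B = 1000 the difference is below the Monte-Carlo noise).
* q monotonization by running minimum guarantees q non-increasing in |d|.
* Median split: ties at the median go to the low-risk group,
  deterministically.
* Degenerate inputs fail loudly: empty groups, constant covariates, zero
  events, zero-variance expression rows (skipped with a log entry in the
  network stage), inconsistent count arguments.
* Problem sizes in tests and the acceptance script (200-feature matrices,
  B ≤ 1000, seed suites of 3–20) were chosen to make the statistical checks
  stable at interactive runtimes.
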