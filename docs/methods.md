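# Methods

## The estimation problem

`heightmr` implements a two-sample-weights, one-sample-data Mendelian
randomization (MR) design: adult height is instrumented by a panel of
independent height-associated SNPs whose per-allele effects w_j (in SD units
of height) are taken from external GWAS, and the causal log-odds effect θ of
height on lung-cancer risk is estimated in case-control genotype data, per
study, then pooled by fixed-effect meta-analysis. Two estimators are
provided and should agree closely on the same data:

* **One-sample weighted score.** GRS_i = Σ_j w_j x_ij is the genetically
  predicted height of subject i (x_ij the tall-allele dosage). Logistic
  regression of case status on the score, adjusted for study covariates,
  gives the odds ratio per SD of genetically predicted height. The score is
  deliberately not re-standardized: its natural unit is one height SD, so
  the coefficient is directly the causal log-OR of interest.
* **Summary-data IVW.** Per-SNP outcome effects β_Yj (log-OR per allele,
  from per-SNP logistic scans) are combined with the exposure effects
  β_Xj = w_j as θ̂ = Σ β_Xj β_Yj /se²_Yj / Σ β²_Xj /se²_Yj — the
  precision-weighted mean of Wald ratios β_Yj/β_Xj, equivalently weighted
  least squares of β_Y on β_X through the origin. First-order SEs are used
  (no exposure-uncertainty term; the no-measurement-error convention) and
  no residual over-dispersion scaling, i.e. the fixed-effect IVW of the
  first-generation summary-MR toolkits.

Exposure effects default to the instrument table (the external GWAS
weights). An in-sample mode re-estimates β_Xj by regressing measured height
on dosage in controls; it exists for diagnostics, not estimation — with a
few thousand controls the per-SNP instrument F-statistic is far below 1
(each SNP explains ~0.02% of height variance), and ratios built from such
noisy denominators are severely attenuated. This is why the package treats
the external weights as the exposure association, exactly as the underlying
study design does.

## Instrument curation

Variant-level QC keeps a SNP iff call rate ≥ 0.95, MAF ≥ 0.05 and the exact
conditional Hardy-Weinberg test in controls has p ≥ 1e-6 (thresholds
inclusive on the keep side; exclusion reasons are reported per SNP in the
order call_rate, maf, hwe). The HWE test is the exact conditional test
without mid-p correction, the standard flavor in GWAS QC. LD pruning is
greedy in ascending height-GWAS p-value — deterministic and biased toward
the strongest instruments — keeping a candidate iff r² ≤ 0.1 with every SNP
already kept; an absent LD pair is treated as r² = 0. Instruments missing
from a study may be replaced by a proxy with r² > 0.9 (highest r² wins,
ties to the smaller rsID). Strand harmonization flips dosages (x → 2 − x)
when alleles are swapped, resolves opposite-strand reports by
complementing, and orients palindromic (A/T, C/G) variants by allele
frequency only when both frequencies are outside [0.42, 0.58], otherwise
excluding them. A sensitivity mode removes instruments that are BMI SNPs or
within r² > 0.1 of one, to sever the height panel from adiposity loci.

## Secondary analyses

Tertiles of the weighted score are formed on all participants pooled across
studies (rank boundaries at ⌈n/3⌉ and ⌈2n/3⌉, ties by stable input order,
so group sizes differ by at most one) and entered as Q2/Q3 indicators
against Q1; the trend test treats the 0/1/2 ordinal coding as a single
covariate, by default as a Wald test (a Rao score variant is available —
the two are asymptotically equivalent and agree in practice). Departure
from log-linearity is tested by a likelihood-ratio test of a restricted
cubic spline (Harrell/Durrleman–Simon basis) against the linear model, with
4 knots at the 5th/35th/65th/95th percentiles of the score, hence 2 df.

Pleiotropy screening iterates: estimate θ̂ by IVW, compute Cochran's
Q = Σ_j (β²_Xj/se²_Yj)(β_Yj/β_Xj − θ̂)², and while the Q test rejects at
α = 0.05 remove the SNP with the largest Q contribution and re-estimate.
Removal is capped at 20% of the panel to prevent degenerate whittling;
hitting the cap is flagged, not fatal. Both α and the cap are configurable
because the exact historical filtering rule of this design is not uniquely
pinned down; greedy max-contribution removal with an α-stopping rule is the
conventional reading.

Gene-set over-representation uses the hypergeometric upper tail with the
background defaulting to the union of the collection's genes (overridable —
published P/Q values depend on the pathway-database snapshot and are not
reproduction targets), gene ratio k / (mapped input genes), and
Benjamini-Hochberg step-up q-values.

Logistic models are fitted by Newton/IRLS with step-halving (log-likelihood
is monotone over iterations), tolerance 1e-8 on the log-likelihood change,
at most 50 iterations; SEs from the observed information. Separation is
detected scale-invariantly (a coefficient exceeding 15 in
per-SD units while steps are not shrinking) and raised as an error, as is a
rank-deficient design. 95% CIs use the normal quantile 1.959964 throughout.

## The generative model

The synthetic generator emulates the study conditions rather than any real
cohort:

* **Genotypes.** Unlinked SNPs, dosage ~ Binomial(2, maf), maf ~ U(0.05,
  0.5) — instruments are LD-pruned, so linkage equilibrium is the intended
  regime. An optional block mode adds exchangeable within-block LD through
  a Gaussian copula to exercise the pruning code.
* **Height.** Per-allele effects drawn N(0, 1) and rescaled so the centered
  genetic score has variance h² = 0.02 (bracketing the ~1.4–2.1% a
  realistic panel explains); residual N(0, 1 − h² − γ_h²) noise gives unit
  marginal variance, so height is a z-score by construction.
* **Disease.** Liability-logistic: P(case) = expit(α + θ·height + γ_y·u +
  δ·Σ_pleio x), with u ~ N(0,1) a shared confounder (loading γ_h on height,
  γ_y on liability; both 0 by default) and δ a per-allele direct effect for
  optionally planted pleiotropic SNPs. α is calibrated by bisection on the
  simulated population pool so prevalence matches the configured 10%
  (arbitrary but configurable; case-control slopes are insensitive to it).
  Cases and controls are sampled from the pool without replacement at exact
  quotas; cases get subtype labels (adenocarcinoma/squamous/other at
  0.67/0.21/0.12, mirroring the cohort mix the design targets).
* **Covariates.** Age, sex, pack-years and principal components are
  status-independent by default, so adjusted and crude estimates agree in
  expectation; a confounded-covariate loading exists for testing
  adjustment. Defaults: two studies, 1500 cases/1500 controls each, 100
  SNPs, θ = log(1.19).
* **Determinism.** Everything is a pure function of the config including
  the seed; study s uses seed + s·10007, and written TSV/JSON outputs are
  byte-identical across runs.

What the generator does **not** emulate: realistic LD from reference
panels, population stratification (PCs are noise covariates here, not
ancestry axes), imputation uncertainty (dosages are hard genotypes unless
you degrade them), age/sex/smoking effects on risk, and genotyping error.
Passing recovery tests therefore shows the estimators and their wiring are
correct under the assumed data-generating model — not that the biological
conclusion would survive violations the generator cannot produce.

## Replicated experiments and problem sizes

`heightmr.experiments` reruns the pipeline over independently seeded
replicates (replicate r uses seed + r·1000003). Averages of odds ratios are
taken on the log-odds scale and exponentiated, the meta-analytic
convention; the arithmetic mean of ORs carries a Jensen offset of roughly
exp(se²/2) that reflects the averaging scale, not the estimator. Problem
sizes were chosen as the smallest at which Monte-Carlo error is comfortably
inside the assertion bands: 200 replicates of two 3000-subject studies for
recovery and confounding contrasts (MC SE of the mean log-OR ≈ 0.013), 1000
single-study replicates of 1000+1000 for null calibration (SE of a 5%
rejection rate ≈ 0.7%).

The pleiotropy-completeness experiment draws summary statistics directly
from their sampling distribution at consortium-scale precision (se_y = 0.01
per allele, se_x = 0.004): a per-allele direct effect of 0.05 then has
noncentrality ≈ 25 per SNP and the filter's behavior is measurable. At
desk-scale outcome SEs (~0.06 per allele) the same direct effect is < 1 SE
and no outlier test can flag it — detectability of weak pleiotropy is a
sample-size property, not a property of the filter.

## Known limitations

* First-order Wald-ratio SEs ignore exposure-effect uncertainty; fine for
  external weights from very large GWAS, anti-conservative otherwise.
* The fixed-effect IVW has no over-dispersion protection beyond the
  explicit Q filter; random-effects or robust MR estimators (Egger,
  weighted median) are out of scope.
* Non-collapsibility of the odds ratio makes marginal per-SNP log-ORs very
  slightly attenuated relative to θ (≲1% at these effect sizes); the
  recovery experiments absorb this within their tolerance rather than
  correcting for it.
* The greedy LD pruner is order-deterministic, not a maximum-independent-set
  solver; with pathological LD graphs a different order could keep more
  SNPs.
* Tertile cutpoints on pooled scores assume the studies' scores are on the
  same scale (true when all studies share one instrument table).
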