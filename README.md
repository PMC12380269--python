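# graftmatch

Case matching and outcome analysis for observational transplant cohorts.

## The problem

Kidneys from deceased donors at the very top of the risk-index scale
(KDPI 98–100%) are discarded far more often than they are transplanted,
yet the recipients who do accept them are older and sicker than recipients
of moderately-high-risk kidneys (KDPI 85–97%), so naive outcome comparisons
are confounded. To compare like with like, treated cases (highest-risk
kidneys) must be matched to controls on the recipient covariates known to
drive allograft survival: age, BMI, cold ischemia time, HLA mismatch count,
ethnicity and sex.

`graftmatch` implements an unsupervised **nearest-centroid clustering
matcher** for this problem, alongside a propensity-score baseline, balance
diagnostics and the downstream survival analyses, plus a synthetic registry
generator so the full pipeline is testable without access to restricted
national registry data.

## The matching algorithm

Let $x_i \in \mathbb{R}^p$ be the encoded covariate vector of subject $i$
(continuous and count covariates z-scored on the pooled sample, nominal
covariates one-hot). Each treated case $t$ is declared the **centroid of
its own cluster** — with $T$ treated cases the algorithm initialises $T$
clusters. Every control $c$ joins the cluster whose centroid is nearest:

$$t(c) = \arg\min_{t}\; d(x_c, x_t), \qquad
  d(u,v) = \sum_j |u_j - v_j| \;\;\text{(Manhattan; cosine optional)}$$

Because each control is assigned exactly once, clusters partition the
control pool and the matching is **without replacement** by construction.
Clusters that attract fewer than `min_size` (default 5) controls are
discarded; in each surviving cluster the $k$ (default 5) controls with the
smallest distance to the centroid are retained, giving a 1:5 matched cohort
with provenance distances. All ties break on subject id, so results are
independent of row order.

The comparison arm is classical propensity-score matching: a
maximum-likelihood logistic model of cohort membership on the same encoded
covariates, followed by greedy 1:k nearest-neighbour matching on the score
(with or without replacement, seeded order).

Balance is assessed per covariate with pooled-variance t-tests /
uncorrected Pearson chi-square and absolute standardized mean differences
$|m_1-m_2| / \sqrt{(s_1^2+s_2^2)/2}$. Outcomes use death-censored
Kaplan–Meier graft survival (death with a functioning graft censors),
log-rank tests, stratified five-year tables, Cox proportional-hazards
regression (Efron ties) and failure-etiology odds ratios with Woolf 95%
confidence intervals.

## Worked example

```python
import graftmatch as gm

cfg = gm.default_config(n_treated=500, n_control=5000, rng_seed=42)
registry = gm.generate_registry(cfg)
treated, control = gm.split_cohorts(registry)

cohort = gm.cluster_match(treated, control, metric="manhattan", k=5, min_size=5)
before, after = gm.balance_table(registry, cohort)

matched = registry.loc[cohort.subject_ids]
```

This prints (via the calls shown in `examples` below):

```text
matched sets: 408, matched controls: 2040
mean SMD before = 0.098, after = 0.014
    covariate  p_value   smd
          age    0.427 0.044
          bmi    0.934 0.004
cold_ischemia    0.972 0.002
 hla_mismatch    0.908 0.006
    ethnicity    0.996 0.023
          sex    0.985 0.001
5-year death-censored graft survival (treated): 52.1%
5-year death-censored graft survival (control): 59.0%
chronic rejection OR 0.92 [0.71, 1.20] p=0.56
```

Of 500 treated cases, 408 anchored clusters with at least five controls and
each kept its five nearest, 1:5 exactly and without reuse. Matching removed
the built-in age imbalance (treated 64±8 vs control 61±10 years): the mean
standardized mean difference across the six matching covariates fell from
0.098 to 0.014 and no covariate differs significantly afterwards. The
five-year (60-month) death-censored graft survival estimates sit at the
generator's calibrated targets (51.7% / 58%), and the final line is the
crude odds ratio that chronic rejection caused a given graft failure,
computed from published failure counts (94 of 332 treated failures vs 445
of 1487 control failures).

The same pipeline is scriptable from the shell:

```bash
graftmatch generate --n-treated 500 --n-control 5000 --seed 42 --out registry.csv
graftmatch match --input registry.csv --method cluster_manhattan --out matched.csv
graftmatch all --seed 42 --out runs/full     # generate + match + balance + outcomes
```

The matchers are scikit-learn estimators (`CentroidMatcher`,
`PropensityMatcher`) with `fit(X, y)` / `get_params` / fitted
`matched_cohort_` attributes, so they compose with sklearn tooling.

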